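"""Two-library proportion-test differential expression (Kal's Z-test).

Each unigene's uniquely mapped fragment count is compared between the
control and NaCl libraries of one organ as a difference of two proportions
of the library totals:

    z = (p1 - p2) / sqrt(p1 (1 - p1) / N1 + p2 (1 - p2) / N2)

with p_i = x_i / N_i, a two-sided standard-normal P-value, Bonferroni
correction over the organ's expressed-gene universe, and a DE call at
corrected P <= alpha. This is the single-library SAGE-style comparison:
sampling variability only, no biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix, ORGAN_SAMPLES


def kal_z(x1, N1, x2, N2, variance: str = "unpooled"):
    """Z statistic and two-sided P for one count in each of two libraries.

    Accepts scalars or arrays. With the default unpooled variance, a
    one-sided zero (x1=0, x2>0) stays defined because the non-zero side
    still contributes variance; (0, 0) is undefined and returns NaN (the
    batch caller excludes such genes from the tested universe).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    if np.any(N1 <= 0) or np.any(N2 <= 0):
        raise ValueError("library totals must be positive")
    if np.any(x1 > N1) or np.any(x2 > N2):
        raise ValueError("counts cannot exceed library totals")
    p1 = x1 / N1
    p2 = x2 / N2
    if variance == "unpooled":
        var = p1 * (1 - p1) / N1 + p2 * (1 - p2) / N2
    elif variance == "pooled":
        p = (x1 + x2) / (N1 + N2)
        var = p * (1 - p) * (1 / N1 + 1 / N2)
    else:
        raise ValueError(f"unknown variance form: {variance!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / np.sqrt(var)
    z = np.where(var > 0, z, np.nan)
    p_raw = 2 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p_raw)
    return z, p_raw


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: p_adj = min(1, m * p_raw), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if m < p.size:
        raise ValueError("m must be at least the number of supplied p-values")
    return np.minimum(1.0, m * p)


def call_de(cm: CountMatrix, organ: str, alpha: float = 0.05,
            variance: str = "unpooled") -> pd.DataFrame:
    """Per-unigene DE table for one organ.

    The tested universe is the organ's expressed genes (x1 + x2 >= 1); the
    Bonferroni family size m is the universe size. ``direction`` is "up"
    when the NaCl proportion exceeds the control proportion.
    """
    if organ not in ORGAN_SAMPLES:
        raise ValueError(f"unknown organ {organ!r}")
    ctrl, nacl = ORGAN_SAMPLES[organ]
    for s in (ctrl, nacl):
        if s not in cm.counts.columns:
            raise ValueError(f"sample {s!r} missing from count matrix")
    x1 = cm.counts[ctrl]
    x2 = cm.counts[nacl]
    N1 = int(x1.sum())
    N2 = int(x2.sum())
    expressed = (x1 + x2) >= 1
    x1e = x1[expressed].to_numpy()
    x2e = x2[expressed].to_numpy()
    m = int(expressed.sum())

    df = pd.DataFrame(index=cm.counts.index[expressed])
    df.index.name = "gene_id"
    df["organ"] = organ
    df["x1"] = x1e
    df["x2"] = x2e
    df["N1"] = N1
    df["N2"] = N2
    if m == 0:
        for colname in ("z", "p_raw", "p_adj"):
            df[colname] = np.array([], dtype=float)
        df["direction"] = np.array([], dtype=object)
        df["is_de"] = np.array([], dtype=bool)
        return df
    z, p_raw = kal_z(x1e, N1, x2e, N2, variance=variance)
    p_adj = bonferroni(p_raw, m)
    # alpha <= 0 calls nothing even where the corrected P underflows to 0
    is_de = (p_adj <= alpha) if alpha > 0 else np.zeros(m, dtype=bool)
    p2_gt_p1 = (x2e / N2) > (x1e / N1)
    df["z"] = z
    df["p_raw"] = p_raw
    df["p_adj"] = p_adj
    df["direction"] = np.where(is_de, np.where(p2_gt_p1, "up", "down"), "none")
    df["is_de"] = is_de
    return df


@dataclass
class DEVenn:
    """Cross-organ partition of DE calls into disjoint categories."""

    up_shoot_only: set = field(default_factory=set)
    up_root_only: set = field(default_factory=set)
    up_both: set = field(default_factory=set)
    down_shoot_only: set = field(default_factory=set)
    down_root_only: set = field(default_factory=set)
    down_both: set = field(default_factory=set)
    discordant: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "up_shoot_only", "up_root_only", "up_both",
            "down_shoot_only", "down_root_only", "down_both", "discordant")}

    def all_de(self) -> set:
        out = set()
        for k in self.counts():
            out |= getattr(self, k)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tgene_ids\n")
            for k, n in self.counts().items():
                fh.write(f"{k}\t{n}\t{','.join(sorted(getattr(self, k)))}\n")


def de_venn(shoot: pd.DataFrame, root: pd.DataFrame) -> DEVenn:
    """Partition DE genes of both organs (Figure-3-style Venn logic)."""
    def split(df):
        de = df[df["is_de"]]
        return (set(de.index[de["direction"] == "up"]),
                set(de.index[de["direction"] == "down"]))

    up_s, down_s = split(shoot)
    up_r, down_r = split(root)
    de_s = up_s | down_s
    de_r = up_r | down_r
    return DEVenn(
        up_shoot_only=up_s - de_r,
        up_root_only=up_r - de_s,
        up_both=up_s & up_r,
        down_shoot_only=down_s - de_r,
        down_root_only=down_r - de_s,
        down_both=down_s & down_r,
        discordant=(up_s & down_r) | (down_s & up_r),
    )
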