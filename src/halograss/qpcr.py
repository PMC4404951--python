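"""Delta-delta-Ct relative quantification and sequencing concordance.

Per biological replicate, the target's Ct is normalized to a reference
gene within each sample (dCt = Ct_target - Ct_reference), the treated and
control dCt are differenced (ddCt), and the fold change is 2^(-ddCt).
Means and standard errors are computed across biological replicates on the
fold scale (matching error bars drawn on fold axes); a log2-scale summary
is available behind a flag. Direction concordance against sequencing-based
fold changes (FPKM ratios) is the per-gene agreement of fold-vs-1 signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene_id", "sample", "replicate", "ct")


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(ct["sample"]) - {"treated", "control"}
    if bad:
        raise ValueError(f"unknown sample labels: {sorted(bad)}")
    # technical replicates (duplicate rows per gene/sample/replicate) are
    # averaged before the biological-replicate statistics
    return (ct.groupby(["gene_id", "sample", "replicate"], as_index=False)
            ["ct"].mean())


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str,
                   log_scale_se: bool = False) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per target gene.

    Requires the reference gene in every (sample, replicate) a target was
    measured in. Returns a table indexed by gene_id with fold, se_fold and
    n_replicates (the reference itself yields fold 1 exactly).
    """
    ct = _validate_ct(ct)
    ref = ct[ct["gene_id"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    ref_ct = ref.set_index(["sample", "replicate"])["ct"]

    rows = []
    for gid, sub in ct.groupby("gene_id"):
        pivot = sub.set_index(["sample", "replicate"])["ct"]
        folds = []
        reps = sorted({r for (_, r) in pivot.index})
        for rep in reps:
            for sample in ("treated", "control"):
                if (sample, rep) not in pivot.index:
                    raise ValueError(
                        f"{gid}: missing {sample} Ct in replicate {rep}")
                if (sample, rep) not in ref_ct.index:
                    raise ValueError(
                        f"reference {reference_gene!r} missing {sample} Ct "
                        f"in replicate {rep}")
            dct_t = pivot[("treated", rep)] - ref_ct[("treated", rep)]
            dct_c = pivot[("control", rep)] - ref_ct[("control", rep)]
            folds.append(2.0 ** (-(dct_t - dct_c)))
        folds = np.asarray(folds)
        if log_scale_se:
            logs = np.log2(folds)
            se = float(logs.std(ddof=1) / np.sqrt(len(logs))) \
                if len(logs) > 1 else 0.0
            rows.append((gid, float(2.0 ** logs.mean()), se, len(folds)))
        else:
            se = float(folds.std(ddof=1) / np.sqrt(len(folds))) \
                if len(folds) > 1 else 0.0
            rows.append((gid, float(folds.mean()), se, len(folds)))
    out = pd.DataFrame(rows, columns=["gene_id", "fold", "se_fold",
                                      "n_replicates"])
    return out.set_index("gene_id")


def concordance(rel_expr: pd.DataFrame, pipeline_folds: pd.Series
                ) -> pd.DataFrame:
    """Direction agreement between qPCR folds and sequencing fold changes.

    Both fold sets are compared against 1; the returned table carries a
    per-gene ``agree`` flag and an ``agreement`` attribute (fraction of
    overlapping genes agreeing).
    """
    overlap = rel_expr.index.intersection(pipeline_folds.index)
    if len(overlap) == 0:
        raise ValueError("no overlapping genes between qPCR and pipeline folds")
    q = rel_expr.loc[overlap, "fold"]
    p = pipeline_folds.loc[overlap].astype(float)
    agree = np.sign(np.log2(q)) == np.sign(np.log2(p))
    out = pd.DataFrame({"qpcr_fold": q, "pipeline_fold": p, "agree": agree})
    out.attrs["agreement"] = float(agree.mean())
    return out
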