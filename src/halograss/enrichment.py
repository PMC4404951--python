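"""Gene-set over-representation of annotation terms among DE genes.

For each term the 2x2 membership table (DE vs reference, annotated vs not)
is scored with the one-sided Fisher's exact upper tail — the hypergeometric
P(X >= k) — with Bonferroni control over the tested terms. The reference
universe is the organ's expressed unigene set, and GO terms and pathway ids
form separate testing families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_upper(k: int, n: int, K: int, N_ref: int) -> float:
    """Exact hypergeometric upper tail P(X >= k).

    ``k`` annotated genes in a draw of ``n`` from a universe of ``N_ref``
    containing ``K`` annotated genes. Computed by the exact distribution,
    not a normal approximation.
    """
    if not (0 <= K <= N_ref and 0 <= n <= N_ref and 0 <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent 2x2 table: k={k}, n={n}, K={K}, N_ref={N_ref}")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N_ref, K, n))


def enrich(de_genes: set, reference: set, term_map: pd.DataFrame,
           alpha: float = 0.05) -> pd.DataFrame:
    """Test every term represented in the reference for over-representation.

    ``term_map`` has columns gene_id and term_id (multi-row per gene). Only
    annotations of reference genes are considered; the Bonferroni family
    size is the number of terms with at least one reference carrier.
    """
    offenders = set(de_genes) - set(reference)
    if offenders:
        raise ValueError(
            "DE genes outside the reference universe: "
            + ", ".join(sorted(offenders)[:10]))
    de_genes = set(de_genes)
    reference = set(reference)
    n = len(de_genes)
    N_ref = len(reference)

    in_ref = term_map[term_map["gene_id"].isin(reference)]
    rows = []
    for term, genes in in_ref.groupby("term_id")["gene_id"]:
        carriers = set(genes)
        K = len(carriers)
        k = len(carriers & de_genes)
        rows.append((term, k, n, K, N_ref, hypergeom_upper(k, n, K, N_ref)))
    df = pd.DataFrame(rows,
                      columns=["term_id", "k", "n", "K", "N_ref", "p_raw"])
    m = len(df)
    if m:
        df["p_adj"] = np.minimum(1.0, m * df["p_raw"])
        df["enriched"] = df["p_adj"] <= alpha
    else:
        df["p_adj"] = np.array([], dtype=float)
        df["enriched"] = np.array([], dtype=bool)
    return df.sort_values(["p_adj", "term_id"]).reset_index(drop=True)
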