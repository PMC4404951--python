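"""Expression quantification from alignments of short reads to a unigene catalog.

Only fragments whose alignment records all name a single unigene are counted,
so that lowly expressed transcripts are not inflated by multi-mapping reads.
FPKM (fragments per kilobase of transcript per million mapped fragments) is
computed from the unique-hit counts, the unigene lengths, and the per-sample
mapped totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

#: Canonical sample order: shoot-control, shoot-NaCl, root-control, root-NaCl.
SAMPLES = ("CS", "NS", "CR", "NR")

#: Organ -> (control sample, NaCl sample).
ORGAN_SAMPLES = {"shoot": ("CS", "NS"), "root": ("CR", "NR")}


@dataclass
class CountMatrix:
    """Unigene x sample table of uniquely mapped fragment counts.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by unigene id with one column per sample.
    lengths
        Unigene lengths in bp, indexed like ``counts``.

    The per-sample mapped totals are the column sums of ``counts``; they are
    exposed as :attr:`totals` so the FPKM denominator and the proportion-test
    library sizes always agree with the matrix itself.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
            raise ValueError(f"missing lengths for genes: {missing}")
        if (self.lengths < 1).any():
            raise ValueError("unigene lengths must be >= 1 bp")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(counts=df, lengths=lengths)


@dataclass
class ExpressionMatrix:
    """FPKM values on the same axes as the source :class:`CountMatrix`."""

    values: pd.DataFrame
    lengths: pd.Series = field(repr=False, default=None)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def count_unique_hits(sam_path, reference_ids=None):
    """Count fragments mapping to exactly one unigene in a SAM stream.

    A fragment (all records sharing a QNAME, both mates of a pair included)
    contributes one count to a unigene iff every one of its mapped records
    names that single reference. Fragments whose records name two or more
    distinct references are multi-hits and contribute nothing, as do
    unmapped records. MAPQ is ignored.

    Returns
    -------
    (counts, total)
        ``counts`` is an integer Series over all references declared in the
        SAM header (or ``reference_ids`` if given), ``total`` its sum.
    """
    MULTI = object()
    per_read: dict[str, object] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        refs = list(sam.references) if reference_ids is None else list(reference_ids)
        for rec in sam:
            if rec.is_unmapped:
                continue
            rname = rec.reference_name
            seen = per_read.get(rec.query_name)
            if seen is None:
                per_read[rec.query_name] = rname
            elif seen is not MULTI and seen != rname:
                per_read[rec.query_name] = MULTI
    counts = pd.Series(0, index=pd.Index(refs, name="gene_id"), dtype=np.int64)
    tally: dict[str, int] = {}
    for ref in per_read.values():
        if ref is not MULTI:
            tally[ref] = tally.get(ref, 0) + 1
    if tally:
        tallied = pd.Series(tally)
        counts.loc[tallied.index] = tallied
    return counts, int(counts.sum())


def counts_from_sams(sam_paths: dict, lengths: pd.Series) -> CountMatrix:
    """Build a CountMatrix from one SAM file per sample label."""
    cols = {}
    for sample, path in sam_paths.items():
        cols[sample], _ = count_unique_hits(path, reference_ids=lengths.index)
    df = pd.DataFrame(cols)
    return CountMatrix(counts=df, lengths=lengths)


def expressed_sets(cm: CountMatrix) -> dict[str, set]:
    """Per-organ expressed unigene sets.

    A unigene is expressed in an organ iff it has at least one uniquely
    mapped fragment across the organ's control and NaCl libraries. These
    sets are both the differential-expression testing universe and the
    enrichment reference.
    """
    out = {}
    for organ, (ctrl, nacl) in ORGAN_SAMPLES.items():
        for s in (ctrl, nacl):
            if s not in cm.counts.columns:
                raise ValueError(f"sample {s!r} missing from count matrix")
        mask = (cm.counts[ctrl] + cm.counts[nacl]) >= 1
        out[organ] = set(cm.counts.index[mask])
    return out


def compute_fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """FPKM(g, s) = 1e9 * C(g, s) / (N(s) * L(g))."""
    totals = cm.totals
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise ValueError(f"empty library (zero mapped fragments): {empty}")
    vals = 1e9 * cm.counts.div(totals, axis=1).div(cm.lengths, axis=0)
    return ExpressionMatrix(values=vals, lengths=cm.lengths)
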