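"""Truth-labeled synthetic data for the four-sample salinity design.

Emulates a two-organ (shoot/root), two-condition (control/500 mM NaCl)
transcriptome experiment on a de novo unigene catalog: organ-specific
expression as structural zeros, a configurable fraction of truly
salt-responsive unigenes with known direction and fold change, annotation
vocabularies with planted term enrichment, multi-mapping alignments, and
paired reads contaminated with adapters, poly(A)/poly(T) tails, low-quality
ends, ambiguous bases, and duplicate pairs. Every generator is a pure
function of (spec, seed), so identical inputs reproduce identical bytes.

The count model is gamma-Poisson (negative binomial): single-library
sequencing still carries biological overdispersion, and the Poisson limit
is recovered at dispersion 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .quantify import SAMPLES, ORGAN_SAMPLES, CountMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default 3' adapter planted in contaminated reads (Illumina TruSeq stem).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {field_name}: {msg}")


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogSpec:
    """Parameters of the unigene catalog and its annotation vocabularies.

    ``length_min`` defaults to 201 bp, the minimum assembled contig length
    of the catalog this design emulates. ``annotation_density`` is the mean
    number of terms per gene, applied per vocabulary (GO and pathway).
    """

    n_genes: int = 2000
    length_min: int = 201
    length_max: int = 1800
    n_terms_go: int = 200
    n_terms_pathway: int = 100
    annotation_density: float = 2.0
    organ_specific_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes >= 0, "n_genes", "must be >= 0")
        _require(self.length_min >= 201, "length_min", "must be >= 201 bp")
        _require(self.length_max >= self.length_min, "length_max",
                 "must be >= length_min")
        _require(self.n_terms_go >= 0, "n_terms_go", "must be >= 0")
        _require(self.n_terms_pathway >= 0, "n_terms_pathway", "must be >= 0")
        _require(self.annotation_density >= 0, "annotation_density",
                 "must be >= 0")
        _require(0 <= self.organ_specific_fraction <= 1,
                 "organ_specific_fraction", "must be in [0, 1]")


@dataclass
class Catalog:
    """A synthetic unigene catalog with annotation maps and truth skeleton."""

    spec: CatalogSpec
    sequences: dict[str, str]
    lengths: pd.Series
    go_map: pd.DataFrame        # columns: gene_id, term_id
    pathway_map: pd.DataFrame   # columns: gene_id, term_id
    truth_genes: pd.DataFrame   # index gene_id; column: organ in {both,shoot,root}

    @property
    def gene_ids(self) -> pd.Index:
        return self.lengths.index

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid in self.gene_ids:
                fh.write(f">{gid}\n{self.sequences[gid]}\n")

    def write_annotation(self, go_path, pathway_path) -> None:
        self.go_map.to_csv(go_path, sep="\t", index=False)
        self.pathway_map.to_csv(pathway_path, sep="\t", index=False)


def _annotation_map(rng, gene_ids, vocab, density) -> pd.DataFrame:
    rows_gene, rows_term = [], []
    if len(vocab):
        k = rng.poisson(density, size=len(gene_ids))
        k = np.minimum(k, len(vocab))
        for gid, n_terms in zip(gene_ids, k):
            if n_terms:
                for t in rng.choice(len(vocab), size=n_terms, replace=False):
                    rows_gene.append(gid)
                    rows_term.append(vocab[t])
    return pd.DataFrame({"gene_id": rows_gene, "term_id": rows_term})


def generate_catalog(spec: CatalogSpec) -> Catalog:
    """Generate the unigene catalog, annotation maps and truth skeleton.

    Sequence lengths are uniform in [length_min, length_max]; each gene gets
    a Poisson(annotation_density) number of distinct terms from each
    vocabulary; organ-specific genes (structural zeros in the other organ)
    are split evenly between shoot-only and root-only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = pd.Index([f"unigene{i:06d}" for i in range(n)], name="gene_id")
    lengths = pd.Series(
        rng.integers(spec.length_min, spec.length_max + 1, size=n),
        index=gene_ids, name="length",
    )
    sequences = {}
    for gid, L in lengths.items():
        seq = rng.integers(0, 4, size=int(L))
        sequences[gid] = _BASES[seq].tobytes().decode("ascii")

    go_vocab = [f"GO:{i:07d}" for i in range(spec.n_terms_go)]
    pw_vocab = [f"ko{i:05d}" for i in range(spec.n_terms_pathway)]
    go_map = _annotation_map(rng, gene_ids, go_vocab, spec.annotation_density)
    pw_map = _annotation_map(rng, gene_ids, pw_vocab, spec.annotation_density)

    organ = np.full(n, "both", dtype=object)
    n_spec = int(round(spec.organ_specific_fraction * n))
    idx = rng.choice(n, size=n_spec, replace=False)
    half = n_spec // 2
    organ[idx[:half]] = "shoot"
    organ[idx[half:]] = "root"
    truth = pd.DataFrame({"organ": organ}, index=gene_ids)

    return Catalog(spec=spec, sequences=sequences, lengths=lengths,
                   go_map=go_map, pathway_map=pw_map, truth_genes=truth)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DESpec:
    """Parameters of the salt-response signal planted in the counts.

    ``fold_change`` is the multiplicative NaCl/control effect (> 1) applied
    in a responsive gene's organ(s); ``dispersion`` is the negative-binomial
    overdispersion (variance = mu + dispersion * mu^2), with the Poisson
    model at 0; ``abundance_sigma`` is the log-normal sd of baseline
    abundances (0 gives a flat null useful for calibration);
    ``enriched_terms`` maps term ids to the odds multiplier with which genes
    carrying them are preferred when drawing the truly responsive set.
    """

    de_fraction: float = 0.05
    fold_change: float = 4.0
    up_fraction: float = 0.5
    shared_fraction: float = 0.3
    dispersion: float = 0.05
    library_sizes: dict = field(default_factory=lambda: {
        "CS": 1_000_000, "NS": 1_000_000, "CR": 1_000_000, "NR": 1_000_000})
    enriched_terms: dict = field(default_factory=dict)
    abundance_sigma: float = 1.0

    def validate(self) -> None:
        for name in ("de_fraction", "up_fraction", "shared_fraction"):
            _require(0 <= getattr(self, name) <= 1, name, "must be in [0, 1]")
        _require(self.fold_change > 1, "fold_change", "must be > 1")
        _require(self.dispersion >= 0, "dispersion", "must be >= 0")
        _require(self.abundance_sigma >= 0, "abundance_sigma", "must be >= 0")
        for s in SAMPLES:
            _require(s in self.library_sizes, "library_sizes",
                     f"missing sample {s}")
            _require(self.library_sizes[s] > 0, "library_sizes",
                     f"{s} must be positive")


@dataclass
class TruthTable:
    """Ground truth for genes (DE status, direction, fold) and terms."""

    genes: pd.DataFrame   # index gene_id
    terms: pd.DataFrame   # index term_id; columns family, enriched

    def write(self, genes_path, terms_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index_label="gene_id")
        self.terms.to_csv(terms_path, sep="\t", index_label="term_id")


def generate_counts(catalog: Catalog, de_spec: DESpec, seed: int):
    """Draw the four-sample count matrix and complete the truth table.

    Expected counts are gamma-Poisson with per-sample normalization so each
    column's expected total equals the configured library size; responsive
    genes carry the fold-change multiplier in their organ's NaCl library,
    and organ-specific genes are structural zeros elsewhere.
    """
    de_spec.validate()
    if catalog.spec.n_genes == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(seed)
    n = catalog.spec.n_genes
    gene_ids = catalog.gene_ids
    organ = catalog.truth_genes["organ"].to_numpy()

    if de_spec.abundance_sigma > 0:
        abundance = rng.lognormal(0.0, de_spec.abundance_sigma, size=n)
    else:
        abundance = np.ones(n)

    # Choose responsive genes, biased toward carriers of enriched terms.
    weights = np.ones(n)
    if de_spec.enriched_terms:
        pos = pd.Series(np.arange(n), index=gene_ids)
        for amap in (catalog.go_map, catalog.pathway_map):
            for term, mult in de_spec.enriched_terms.items():
                carriers = amap.loc[amap["term_id"] == term, "gene_id"]
                if len(carriers):
                    weights[pos[carriers].to_numpy()] *= float(mult)
    n_de = int(round(de_spec.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False, p=weights / weights.sum())
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    de_shoot = np.zeros(n, dtype=bool)
    de_root = np.zeros(n, dtype=bool)
    up = np.zeros(n, dtype=bool)
    for i in de_idx:
        up[i] = rng.random() < de_spec.up_fraction
        if organ[i] == "shoot":
            de_shoot[i] = True
        elif organ[i] == "root":
            de_root[i] = True
        elif rng.random() < de_spec.shared_fraction:
            de_shoot[i] = de_root[i] = True
        elif rng.random() < 0.5:
            de_shoot[i] = True
        else:
            de_root[i] = True

    fold = de_spec.fold_change
    mult = np.ones((n, 4))
    col = {s: j for j, s in enumerate(SAMPLES)}
    mult[organ == "shoot", col["CR"]] = 0.0
    mult[organ == "shoot", col["NR"]] = 0.0
    mult[organ == "root", col["CS"]] = 0.0
    mult[organ == "root", col["NS"]] = 0.0
    eff = np.where(up, fold, 1.0 / fold)
    mult[de_shoot, col["NS"]] *= eff[de_shoot]
    mult[de_root, col["NR"]] *= eff[de_root]

    counts = np.empty((n, 4), dtype=np.int64)
    mu = np.empty((n, 4))
    for j, s in enumerate(SAMPLES):
        w = abundance * mult[:, j]
        mu[:, j] = de_spec.library_sizes[s] * w / w.sum()
        if de_spec.dispersion > 0:
            shape = 1.0 / de_spec.dispersion
            lam = mu[:, j] * rng.gamma(shape, 1.0 / shape, size=n)
        else:
            lam = mu[:, j]
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=list(SAMPLES)),
        lengths=catalog.lengths,
    )

    genes = catalog.truth_genes.copy()
    genes["is_de"] = is_de
    genes["de_shoot"] = de_shoot
    genes["de_root"] = de_root
    direction = np.where(is_de, np.where(up, "up", "down"), "none")
    genes["direction"] = direction
    genes["fold_change"] = np.where(is_de, np.where(up, fold, 1.0 / fold), 1.0)
    genes["mu_CS"] = mu[:, col["CS"]]
    genes["mu_CR"] = mu[:, col["CR"]]

    term_rows = []
    for family, amap in (("GO", catalog.go_map), ("pathway", catalog.pathway_map)):
        for term in amap["term_id"].unique():
            term_rows.append((term, family, term in de_spec.enriched_terms))
    terms = pd.DataFrame(term_rows, columns=["term_id", "family", "enriched"])
    terms = terms.set_index("term_id")

    return cm, TruthTable(genes=genes, terms=terms)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContaminationSpec:
    """Per-pair probabilities of each read-level artifact.

    Adapter read-through and poly(A) tailing both replace the 3' end of
    mate 1 and are mutually exclusive, so their fractions may not sum
    above 1. Low-quality ends (QV 2 flanks) are trimmable; ambiguous-base
    pairs carry an internal 'N'; duplicate pairs are byte-identical copies
    of an earlier pair.
    """

    adapter_fraction: float = 0.05
    polya_fraction: float = 0.05
    n_fraction: float = 0.02
    lowq_end_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    adapter: str = DEFAULT_ADAPTER

    def validate(self) -> None:
        for name in ("adapter_fraction", "polya_fraction", "n_fraction",
                     "lowq_end_fraction", "duplicate_fraction"):
            _require(0 <= getattr(self, name) <= 1, name, "must be in [0, 1]")
        _require(self.adapter_fraction + self.polya_fraction <= 1,
                 "adapter_fraction+polya_fraction",
                 "mutually exclusive 3'-end classes must sum to <= 1")


def generate_reads(catalog: Catalog, per_gene_pairs: pd.Series, read_len: int,
                   contamination: ContaminationSpec, seed: int,
                   mean_qv: int = 36, polya_run: int = 14, lowq_qv: int = 2):
    """Generate paired reads with per-pair truth labels.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    ``(read_id, bases1, quals1, bases2, quals2)`` tuples (quals are integer
    lists, Sanger/Phred+33 on disk) and ``truth`` is a DataFrame with one
    row per pair carrying the artifact flags and the expected post-trim
    lengths of each mate (``clean_len1``/``clean_len2``).
    """
    contamination.validate()
    _require(read_len >= 1, "read_len", "must be >= 1")
    rng = np.random.default_rng(seed)
    adapter = contamination.adapter
    frag_len = min(2 * read_len, int(catalog.lengths.min()))

    def revcomp(s: str) -> str:
        return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]

    pairs = []
    truth_rows = []
    i = 0
    originals = []
    for gid, n_pairs in per_gene_pairs.items():
        seq = catalog.sequences[gid]
        n_pairs = int(n_pairs)
        # distinct fragment starts per gene so only planted duplicates are
        # byte-identical (truth is nevertheless recomputed below)
        n_starts = len(seq) - frag_len + 1
        if n_pairs <= n_starts:
            start_pool = iter(rng.choice(n_starts, size=n_pairs,
                                         replace=False))
        else:
            start_pool = iter(rng.integers(0, n_starts, size=n_pairs))
        for _ in range(n_pairs):
            rid = f"pair{i:07d}"
            dup = bool(originals and rng.random() < contamination.duplicate_fraction)
            if dup:
                src = originals[rng.integers(0, len(originals))]
                b1, q1, b2, q2, tr = src
                tr = dict(tr)
                tr["is_duplicate_pair"] = True
                pairs.append((rid, b1, list(q1), b2, list(q2)))
                truth_rows.append({"read_id": rid, **tr})
                i += 1
                continue
            start = int(next(start_pool))
            b1 = seq[start:start + read_len]
            b2 = revcomp(seq[start + frag_len - read_len:start + frag_len])
            q1 = rng.integers(mean_qv - 4, mean_qv + 4, size=read_len).tolist()
            q2 = rng.integers(mean_qv - 4, mean_qv + 4, size=read_len).tolist()
            flags = {"gene_id": gid, "has_adapter": False,
                     "has_polyA_tail": False, "has_N": False,
                     "low_quality": False, "is_duplicate_pair": False}
            clean1 = clean2 = read_len

            u = rng.random()
            if u < contamination.adapter_fraction:
                # replace the 3' tail of mate 1 with the adapter prefix
                ins = int(rng.integers(read_len // 3, read_len - 12))
                tail = (adapter * 4)[:read_len - ins]
                b1 = b1[:ins] + tail
                flags["has_adapter"] = True
                clean1 = ins
            elif u < contamination.adapter_fraction + contamination.polya_fraction:
                ins = int(rng.integers(read_len // 3, read_len - polya_run))
                head = b1[:ins]
                if head.endswith("A"):
                    head = head[:-1] + "G"
                b1 = head + "A" * (read_len - ins)
                flags["has_polyA_tail"] = True
                clean1 = ins

            if rng.random() < contamination.n_fraction:
                # plant inside the clean portion so trimming cannot remove it
                mid = max(0, clean1 // 2)
                b1 = b1[:mid] + "N" + b1[mid + 1:]
                flags["has_N"] = True

            if rng.random() < contamination.lowq_end_fraction:
                e5 = int(rng.integers(1, 8))
                e3 = int(rng.integers(1, 8))
                q2[:e5] = [lowq_qv] * e5
                q2[-e3:] = [lowq_qv] * e3
                flags["low_quality"] = True
                clean2 = read_len - e5 - e3

            pairs.append((rid, b1, q1, b2, q2))
            tr = {**flags, "clean_len1": clean1, "clean_len2": clean2}
            originals.append((b1, q1, b2, q2, tr))
            truth_rows.append({"read_id": rid, **tr})
            i += 1

    if not truth_rows:
        truth = pd.DataFrame(columns=["read_id"]).set_index("read_id")
    else:
        truth = pd.DataFrame(truth_rows).set_index("read_id")
        # duplicate truth by the byte-identity rule itself, so chance
        # collisions are labeled exactly as a deduplicator would see them
        seen: set = set()
        dup_flags = []
        for rid, b1, _, b2, _ in pairs:
            key = (b1, b2)
            dup_flags.append(key in seen)
            seen.add(key)
        truth["is_duplicate_pair"] = dup_flags
    return pairs, truth


def write_fastq_pair(pairs, path1, path2) -> None:
    """Write paired reads to two FASTQ files (Sanger/Phred+33 qualities)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, b1, q1, b2, q2 in pairs:
            f1.write(f"@{rid}/1\n{b1}\n+\n"
                     + "".join(chr(q + 33) for q in q1) + "\n")
            f2.write(f"@{rid}/2\n{b2}\n+\n"
                     + "".join(chr(q + 33) for q in q2) + "\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def generate_alignments(catalog: Catalog, per_gene_reads: pd.Series,
                        multimap_fraction: float, seed: int, sam_path):
    """Emit SAM records for one sample with multi-mapping truth labels.

    Each read of ``per_gene_reads`` (total reads per gene) is flagged
    multi-mapped with probability ``multimap_fraction``; multi reads emit
    two records naming distinct references (primary + secondary), unique
    reads exactly one. Returns a truth DataFrame (read_id, gene_id,
    is_unique).
    """
    _require(0 <= multimap_fraction < 1, "multimap_fraction",
             "must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = list(catalog.gene_ids)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g, "LN": int(catalog.lengths[g])} for g in gene_ids],
    }
    ref_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    i = 0
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for gid, n_reads in per_gene_reads.items():
            for _ in range(int(n_reads)):
                rid = f"read{i:08d}"
                multi = bool(len(gene_ids) > 1
                             and rng.random() < multimap_fraction)
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = rid
                rec.flag = 0
                rec.reference_id = ref_pos[gid]
                rec.reference_start = int(
                    rng.integers(0, max(1, catalog.lengths[gid] - 50)))
                rec.mapping_quality = 0 if multi else 60
                rec.cigarstring = "50M"
                sam.write(rec)
                if multi:
                    other = int(rng.integers(0, len(gene_ids) - 1))
                    if other >= ref_pos[gid]:
                        other += 1
                    rec2 = pysam.AlignedSegment(sam.header)
                    rec2.query_name = rid
                    rec2.flag = 256
                    rec2.reference_id = other
                    rec2.reference_start = 0
                    rec2.mapping_quality = 0
                    rec2.cigarstring = "50M"
                    sam.write(rec2)
                rows.append((rid, gid, not multi))
                i += 1
    truth = pd.DataFrame(rows, columns=["read_id", "gene_id", "is_unique"])
    return truth.set_index("read_id")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(folds: dict, reference_gene: str, n_replicates: int = 3,
                  ct_noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate a Ct table from true treated/control expression folds.

    The target Ct drops by log2(fold) under treatment (Ct = baseline -
    log2(expression) + Gaussian noise); the reference gene's fold is pinned
    at 1. Returns a tidy table (gene_id, sample, replicate, ct).
    """
    _require(n_replicates >= 1, "n_replicates", "must be >= 1")
    _require(ct_noise_sd >= 0, "ct_noise_sd", "must be >= 0")
    if reference_gene not in folds:
        raise ValueError(
            f"reference gene {reference_gene!r} absent from the truth folds")
    if not math.isclose(float(folds[reference_gene]), 1.0):
        raise ValueError("reference gene fold must be 1")
    rng = np.random.default_rng(seed)
    rows = []
    for gid, fold in folds.items():
        _require(fold > 0, "folds", f"{gid} fold must be > 0")
        baseline = float(rng.uniform(20.0, 30.0))
        for rep in range(1, n_replicates + 1):
            for sample, f in (("control", 1.0), ("treated", float(fold))):
                ct = baseline - math.log2(f)
                if ct_noise_sd > 0:
                    ct += float(rng.normal(0.0, ct_noise_sd))
                rows.append((gid, sample, rep, ct))
    return pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "ct"])
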