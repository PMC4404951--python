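"""Read pre-processing for paired short-read libraries.

The pipeline mirrors a de novo transcriptome QC path: optional removal of
byte-identical duplicate pairs, adapter and poly(A)/poly(T) tail trimming,
stripping of low-quality (QV < 10) bases from both ends, and a four-part
screen that discards a read when

1. its average QV is <= 17,
2. its length is <= 20 bp (16 bp for the tag-sequencing profile),
3. the fraction of bases with QV < 10 reaches 10%, or
4. it contains an ambiguous 'N'.

Criteria (3) and (4) are printed as keep-conditions ("<10%", "no N") in the
source procedure; the screen discards their complement, with the 10%
boundary itself a discard. A pair is dropped whenever either mate fails.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict

#: Bases removed per trimming rule, reads discarded per screening rule.
TRIM_RULES = ("adapter", "homopolymer", "quality")
SCREEN_RULES = ("avg_qv", "length", "lowq_fraction", "ambiguous")


@dataclass
class QCRead:
    """One sequencing read with per-base Phred quality values."""

    read_id: str
    mate: int
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}/{self.mate}: bases and quals differ in length")
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"{self.read_id}/{self.mate}: QV outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCConfig:
    """Trimming and screening thresholds.

    ``min_len`` is a discard-inclusive bound (length <= min_len discards);
    the default 20 bp suits 100 bp paired reads, 16 bp the short-tag
    profile. ``min_avg_qv`` likewise discards at equality. A read is also
    discarded when its fraction of bases below ``end_trim_qv`` is at least
    ``max_lowq_fraction``.
    """

    adapter_seqs: tuple = ("AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC",)
    min_adapter_overlap: int = 3
    adapter_max_error_rate: float = 0.1
    homopolymer_min_run: int = 10
    end_trim_qv: int = 10
    min_avg_qv: float = 17.0
    min_len: int = 20
    max_lowq_fraction: float = 0.10
    forbid_n: bool = True
    dedup: bool = True

    def __post_init__(self) -> None:
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")
        if not (0 <= self.adapter_max_error_rate < 1):
            raise ValueError("adapter_max_error_rate must be in [0, 1)")
        if self.homopolymer_min_run < 1:
            raise ValueError("homopolymer_min_run must be >= 1")
        if min(self.end_trim_qv, self.min_avg_qv, self.min_len) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 < self.max_lowq_fraction <= 1):
            raise ValueError("max_lowq_fraction must be in (0, 1]")

    @classmethod
    def turf(cls, **kw) -> "QCConfig":
        """Default profile for 100 bp paired RNA-seq reads (min_len 20)."""
        return cls(**kw)

    @classmethod
    def rice(cls, **kw) -> "QCConfig":
        """Short-tag (MPSS-style) profile: min_len 16, no adapter list."""
        kw.setdefault("min_len", 16)
        return cls(**kw)


@dataclass
class QCReport:
    """Pair-level accounting of the QC run; balances exactly."""

    input_pairs: int = 0
    duplicate_pairs_removed: int = 0
    blacklisted_pairs: int = 0
    bases_trimmed: dict = field(
        default_factory=lambda: {r: 0 for r in TRIM_RULES})
    pairs_discarded: dict = field(
        default_factory=lambda: {r: 0 for r in SCREEN_RULES})
    pairs_discarded_total: int = 0
    pairs_surviving: int = 0

    def balances(self) -> bool:
        return (self.input_pairs
                == self.duplicate_pairs_removed + self.blacklisted_pairs
                + self.pairs_discarded_total + self.pairs_surviving)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("counter\tvalue\n")
            for key, val in asdict(self).items():
                if isinstance(val, dict):
                    for sub, v in val.items():
                        fh.write(f"{key}.{sub}\t{v}\n")
                else:
                    fh.write(f"{key}\t{val}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def deduplicate_pairs(pair_stream):
    """Drop pairs whose two base strings both match a previously seen pair.

    First occurrence is kept, survivor order preserved. Returns
    ``(survivors, removed_count)``.
    """
    seen = set()
    survivors = []
    removed = 0
    for r1, r2 in pair_stream:
        if r1.read_id.split("/")[0] != r2.read_id.split("/")[0]:
            raise ValueError(f"orphan mate: {r1.read_id} vs {r2.read_id}")
        key = (r1.bases, r2.bases)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            survivors.append((r1, r2))
    return survivors, removed


def _find_adapter(bases: str, adapter: str, min_overlap: int,
                  max_error_rate: float) -> int | None:
    """Leftmost cut position of a read-suffix / adapter-prefix match.

    Scanning from the 5' end finds the longest qualifying overlap first;
    the mismatch rate over the overlap must not exceed ``max_error_rate``.
    """
    n = len(bases)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        mism = sum(1 for a, b in zip(bases[i:i + overlap], adapter[:overlap])
                   if a != b)
        if mism <= max_error_rate * overlap:
            return i
    return None


def trim_read(read: QCRead, cfg: QCConfig, _tally: dict | None = None) -> QCRead:
    """Adapter removal, then poly(A)/(T) tail removal, then end trimming.

    The adapter cut removes the matched suffix and everything 3' of it;
    poly(A) runs of >= homopolymer_min_run are cut at the 3' end and
    poly(T) runs at the 5' end; finally bases with QV < end_trim_qv are
    stripped from both ends. Qualities are trimmed in lockstep. May return
    an empty read.
    """
    bases, quals = read.bases, list(read.quals)

    best = None
    for adapter in cfg.adapter_seqs:
        cut = _find_adapter(bases, adapter, cfg.min_adapter_overlap,
                            cfg.adapter_max_error_rate)
        if cut is not None and (best is None or cut < best):
            best = cut
    if best is not None:
        if _tally is not None:
            _tally["adapter"] += len(bases) - best
        bases, quals = bases[:best], quals[:best]

    run = len(bases) - len(bases.rstrip("A"))
    if run >= cfg.homopolymer_min_run:
        if _tally is not None:
            _tally["homopolymer"] += run
        bases, quals = bases[:len(bases) - run], quals[:len(bases) - run]
    run = len(bases) - len(bases.lstrip("T"))
    if run >= cfg.homopolymer_min_run:
        if _tally is not None:
            _tally["homopolymer"] += run
        bases, quals = bases[run:], quals[run:]

    lo, hi = 0, len(bases)
    while lo < hi and quals[lo] < cfg.end_trim_qv:
        lo += 1
    while hi > lo and quals[hi - 1] < cfg.end_trim_qv:
        hi -= 1
    if _tally is not None:
        _tally["quality"] += lo + (len(bases) - hi)
    bases, quals = bases[lo:hi], quals[lo:hi]

    return QCRead(read.read_id, read.mate, bases, quals)


def screen_read(read: QCRead, cfg: QCConfig):
    """Apply the four-criterion screen to an already-trimmed read.

    Returns ``(keep, reasons)`` with every triggered failure reason listed.
    """
    reasons = []
    n = len(read)
    avg = sum(read.quals) / n if n else 0.0
    if avg <= cfg.min_avg_qv:
        reasons.append("avg_qv")
    if n <= cfg.min_len:
        reasons.append("length")
    lowq = sum(1 for q in read.quals if q < cfg.end_trim_qv)
    if n and lowq / n >= cfg.max_lowq_fraction:
        reasons.append("lowq_fraction")
    if cfg.forbid_n and "N" in read.bases:
        reasons.append("ambiguous")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# FASTQ I/O (line-number aware)
# ---------------------------------------------------------------------------

def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, mate: int):
    """Yield QCRead records from a FASTQ file, reporting malformed records
    with their line number."""
    with _open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(
                    f"{path}:{lineno}: FASTQ header must start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(
                    f"{path}:{lineno - 1}: expected '+' separator line")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}:{lineno}: sequence and quality lengths differ")
            rid = header[1:].split()[0]
            yield QCRead(rid, mate, seq,
                         [ord(c) - 33 for c in qual])


def write_fastq(reads, path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n"
                     + "".join(chr(q + 33) for q in r.quals) + "\n")


def run_qc(fastq_in1, fastq_in2, fastq_out1, fastq_out2, cfg: QCConfig,
           blacklist: set | None = None) -> QCReport:
    """Deduplicate, trim and screen a FASTQ pair; write survivors.

    ``blacklist`` is an optional set of read ids to drop up front (the
    configurable surrogate for tRNA/rRNA exclusion). The returned
    :class:`QCReport` accounting balances exactly at pair level.
    """
    report = QCReport()
    pairs = list(zip(read_fastq(fastq_in1, 1), read_fastq(fastq_in2, 2)))
    report.input_pairs = len(pairs)

    if blacklist:
        kept = []
        for r1, r2 in pairs:
            rid = r1.read_id.split("/")[0]
            if rid in blacklist or r1.read_id in blacklist:
                report.blacklisted_pairs += 1
            else:
                kept.append((r1, r2))
        pairs = kept

    if cfg.dedup:
        pairs, report.duplicate_pairs_removed = deduplicate_pairs(pairs)

    out1, out2 = [], []
    for r1, r2 in pairs:
        t1 = trim_read(r1, cfg, report.bases_trimmed)
        t2 = trim_read(r2, cfg, report.bases_trimmed)
        keep1, reasons1 = screen_read(t1, cfg)
        keep2, reasons2 = screen_read(t2, cfg)
        if keep1 and keep2:
            report.pairs_surviving += 1
            out1.append(t1)
            out2.append(t2)
        else:
            report.pairs_discarded_total += 1
            for reason in dict.fromkeys(reasons1 + reasons2):
                report.pairs_discarded[reason] += 1

    write_fastq(out1, fastq_out1)
    write_fastq(out2, fastq_out2)
    assert report.balances(), "QC accounting failed to balance"
    return report
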