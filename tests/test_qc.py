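"""Read QC: dedup, trimming, four-criterion screen, accounting."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import halograss as hg
from halograss.qc import QCRead, QCConfig, read_fastq


def mk(bases, quals=None, rid="r", mate=1):
    if quals is None:
        quals = [30] * len(bases)
    return QCRead(rid, mate, bases, quals)


class TestDeduplicate:
    def test_identical_pair_removed_once(self):
        p = (mk("ACGT", rid="a/1"), mk("TTTT", rid="a/2", mate=2))
        q = (mk("ACGT", rid="b/1"), mk("TTTT", rid="b/2", mate=2))
        survivors, removed = hg.deduplicate_pairs([p, q])
        assert removed == 1 and len(survivors) == 1
        assert survivors[0][0].read_id == "a/1"

    def test_one_mate_identical_keeps_both(self):
        p = (mk("ACGT", rid="a/1"), mk("TTTT", rid="a/2", mate=2))
        q = (mk("ACGT", rid="b/1"), mk("GGGG", rid="b/2", mate=2))
        survivors, removed = hg.deduplicate_pairs([p, q])
        assert removed == 0 and len(survivors) == 2

    def test_multiple_copies_counted_by_brute_force(self, rng):
        distinct = [(mk(s, rid=f"p{i}/1"), mk(s[::-1], rid=f"p{i}/2", mate=2))
                    for i, s in enumerate(
                        "".join(rng.choice(list("ACGT"), 20)) for _ in range(100))]
        stream = distinct + [
            (mk(distinct[0][0].bases, rid=f"d{j}/1"),
             mk(distinct[0][1].bases, rid=f"d{j}/2", mate=2))
            for j in range(9)]
        seen = set()
        expected_removed = 0
        for r1, r2 in stream:
            key = (r1.bases, r2.bases)
            expected_removed += key in seen
            seen.add(key)
        _, removed = hg.deduplicate_pairs(stream)
        assert removed == expected_removed == 9

    def test_orphan_mate_errors_with_id(self):
        p = (mk("ACGT", rid="a/1"), mk("TTTT", rid="zzz/2", mate=2))
        with pytest.raises(ValueError, match="a/1"):
            hg.deduplicate_pairs([p])


class TestTrim:
    CFG = QCConfig(adapter_seqs=("AGATCGGAAGAGC",), min_adapter_overlap=3)

    def test_clean_read_unchanged(self):
        r = mk("ACGTACGTACGTACGTACGTACGTACGT")
        t = hg.trim_read(r, self.CFG)
        assert t.bases == r.bases and t.quals == r.quals

    def test_polya_tail_cut(self):
        r = mk("ACGT" + "A" * 12)
        t = hg.trim_read(r, QCConfig(adapter_seqs=(), homopolymer_min_run=10))
        assert t.bases == "ACGT"

    def test_polyt_head_cut(self):
        r = mk("T" * 11 + "GCGC")
        t = hg.trim_read(r, QCConfig(adapter_seqs=(), homopolymer_min_run=10))
        assert t.bases == "GCGC"

    def test_short_homopolymer_kept(self):
        r = mk("ACGT" + "A" * 9)
        t = hg.trim_read(r, QCConfig(adapter_seqs=(), homopolymer_min_run=10))
        assert t.bases == r.bases

    def test_end_trim_matches_brute_force_scan(self):
        quals = [2, 2, 30, 30, 30, 2]
        r = mk("ACGTAC", quals)
        t = hg.trim_read(r, QCConfig(adapter_seqs=(), end_trim_qv=10))
        # brute-force: strip from both ends until QV >= 10
        lo, hi = 0, len(quals)
        while lo < hi and quals[lo] < 10:
            lo += 1
        while hi > lo and quals[hi - 1] < 10:
            hi -= 1
        assert t.bases == r.bases[lo:hi] == "GTA"
        assert t.quals == [30, 30, 30]

    def test_adapter_suffix_cut_with_mismatch(self):
        insert = "CCGTTGCAACGTTAAGCACCA"
        read = insert + "AGATCGGAAGTGC"  # one mismatch in 13 bases (<10%... )
        r = mk(read)
        cfg = QCConfig(adapter_seqs=("AGATCGGAAGAGC",), min_adapter_overlap=5,
                       adapter_max_error_rate=0.1)
        t = hg.trim_read(r, cfg)
        assert t.bases == insert

    def test_trim_is_idempotent(self):
        r = mk("GGCA" + "A" * 15, [2, 2, 30, 30] + [30] * 15)
        cfg = QCConfig(adapter_seqs=(), homopolymer_min_run=10)
        once = hg.trim_read(r, cfg)
        twice = hg.trim_read(once, cfg)
        assert once.bases == twice.bases and once.quals == twice.quals


class TestScreen:
    def test_length_boundary_is_discard_inclusive(self):
        r = mk("A" * 20)
        keep, reasons = hg.screen_read(r, QCConfig())
        assert not keep and "length" in reasons
        keep, _ = hg.screen_read(mk("A" * 21), QCConfig())
        assert keep

    def test_ambiguous_base_discards(self):
        keep, reasons = hg.screen_read(mk("ACGTN" + "ACGT" * 5), QCConfig())
        assert not keep and reasons == ["ambiguous"]

    def test_lowq_fraction_boundary_discards_at_exactly_ten_percent(self):
        quals = [5] * 10 + [30] * 90
        keep, reasons = hg.screen_read(mk("A" * 25 + "C" * 75, quals),
                                       QCConfig())
        assert not keep and "lowq_fraction" in reasons
        quals = [5] * 9 + [30] * 91
        keep, _ = hg.screen_read(mk("A" * 25 + "C" * 75, quals), QCConfig())
        assert keep

    def test_average_qv_boundary_inclusive(self):
        keep, reasons = hg.screen_read(mk("ACGT" * 8, [17] * 32), QCConfig())
        assert not keep and "avg_qv" in reasons

    def test_rice_profile_keeps_seventeen_mers(self):
        r = mk("ACGTACGTACGTACGTA")  # 17 bases
        keep, _ = hg.screen_read(r, QCConfig.rice())
        assert keep
        assert not hg.screen_read(r, QCConfig.turf())[0]

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=40))
    def test_raising_min_avg_qv_never_increases_survivors(self, thr):
        reads = [mk("ACGT" * 10, [q] * 40) for q in range(0, 41, 4)]
        survive = sum(hg.screen_read(r, QCConfig(min_avg_qv=thr))[0]
                      for r in reads)
        survive_stricter = sum(
            hg.screen_read(r, QCConfig(min_avg_qv=min(thr + 5, 60)))[0]
            for r in reads)
        assert survive_stricter <= survive


class TestRunQC:
    def test_empty_input(self, tmp_path):
        for name in ("i1.fq", "i2.fq"):
            (tmp_path / name).write_text("")
        rep = hg.run_qc(tmp_path / "i1.fq", tmp_path / "i2.fq",
                        tmp_path / "o1.fq", tmp_path / "o2.fq", QCConfig())
        assert rep.input_pairs == 0 and rep.pairs_surviving == 0
        assert rep.balances()

    def test_malformed_fastq_reports_line_number(self, tmp_path):
        (tmp_path / "bad.fq").write_text("@r1\nACGT\nJUNK\nIIII\n")
        with pytest.raises(ValueError, match="bad.fq:3"):
            list(read_fastq(tmp_path / "bad.fq", 1))

    def test_survivor_count_matches_recount_and_balances(self, small_catalog,
                                                         tmp_path):
        per_gene = pd.Series(10, index=small_catalog.gene_ids)
        pairs, truth = hg.generate_reads(
            small_catalog, per_gene, 100, hg.ContaminationSpec(), seed=9)
        hg.write_fastq_pair(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        rep = hg.run_qc(tmp_path / "r1.fq", tmp_path / "r2.fq",
                        tmp_path / "c1.fq", tmp_path / "c2.fq", QCConfig())
        assert rep.balances()
        recount = sum(1 for _ in read_fastq(tmp_path / "c1.fq", 1))
        assert recount == rep.pairs_surviving

    def test_qc_idempotent_on_own_output(self, small_catalog, tmp_path):
        per_gene = pd.Series(10, index=small_catalog.gene_ids)
        pairs, _ = hg.generate_reads(
            small_catalog, per_gene, 100, hg.ContaminationSpec(), seed=10)
        hg.write_fastq_pair(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        cfg = QCConfig(min_adapter_overlap=8)
        hg.run_qc(tmp_path / "r1.fq", tmp_path / "r2.fq",
                  tmp_path / "c1.fq", tmp_path / "c2.fq", cfg)
        rep2 = hg.run_qc(tmp_path / "c1.fq", tmp_path / "c2.fq",
                         tmp_path / "d1.fq", tmp_path / "d2.fq", cfg)
        assert rep2.pairs_surviving == rep2.input_pairs
        assert (tmp_path / "d1.fq").read_bytes() == \
            (tmp_path / "c1.fq").read_bytes()

    def test_blacklist_filter_counts_separately(self, small_catalog, tmp_path):
        per_gene = pd.Series(5, index=small_catalog.gene_ids)
        zero = hg.ContaminationSpec(adapter_fraction=0, polya_fraction=0,
                                    n_fraction=0, lowq_end_fraction=0,
                                    duplicate_fraction=0)
        pairs, _ = hg.generate_reads(small_catalog, per_gene, 100, zero, 11)
        hg.write_fastq_pair(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        blacklist = {pairs[0][0], pairs[1][0]}
        rep = hg.run_qc(tmp_path / "r1.fq", tmp_path / "r2.fq",
                        tmp_path / "c1.fq", tmp_path / "c2.fq", QCConfig(),
                        blacklist=blacklist)
        assert rep.blacklisted_pairs == 2
        assert rep.balances()
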