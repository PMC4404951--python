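"""Generator correctness: determinism, truth consistency, planted effects."""

import numpy as np
import pandas as pd
import pytest

import halograss as hg
from halograss.simulate import ContaminationSpec


class TestCatalog:
    def test_empty_catalog(self):
        cat = hg.generate_catalog(hg.CatalogSpec(n_genes=0))
        assert len(cat.gene_ids) == 0
        assert len(cat.go_map) == 0 and len(cat.pathway_map) == 0

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = hg.CatalogSpec(n_genes=200, seed=7)
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        hg.generate_catalog(spec).write_fasta(f1)
        hg.generate_catalog(spec).write_fasta(f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_lengths_within_bounds(self, small_catalog):
        spec = small_catalog.spec
        assert (small_catalog.lengths >= spec.length_min).all()
        assert (small_catalog.lengths <= spec.length_max).all()

    def test_mean_annotation_density_matches_poisson_rate(self):
        cat = hg.generate_catalog(
            hg.CatalogSpec(n_genes=10_000, annotation_density=2.0, seed=5))
        mean_terms = len(cat.go_map) / 10_000
        assert 1.9 <= mean_terms <= 2.1

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="length_min"):
            hg.generate_catalog(hg.CatalogSpec(length_min=100))
        with pytest.raises(ValueError, match="organ_specific_fraction"):
            hg.generate_catalog(hg.CatalogSpec(organ_specific_fraction=1.5))


class TestCounts:
    def test_null_configuration_marks_no_de(self, small_catalog):
        spec = hg.DESpec(de_fraction=0.0,
                         library_sizes={s: 10_000 for s in hg.SAMPLES})
        _, truth = hg.generate_counts(small_catalog, spec, seed=1)
        assert truth.genes["is_de"].sum() == 0

    def test_fold_change_must_exceed_one(self, small_catalog):
        with pytest.raises(ValueError, match="fold_change"):
            hg.generate_counts(small_catalog, hg.DESpec(fold_change=0.5), 1)

    def test_library_size_conservation(self, counts_with_signal):
        _, cm, _ = counts_with_signal
        for s in hg.SAMPLES:
            assert abs(cm.totals[s] - 300_000) / 300_000 < 0.02

    def test_poisson_limit_variance_matches_mean(self):
        cat = hg.generate_catalog(
            hg.CatalogSpec(n_genes=60, organ_specific_fraction=0.0, seed=33))
        spec = hg.DESpec(de_fraction=0.0, dispersion=0.0, abundance_sigma=0.0,
                         library_sizes={s: 60_000 for s in hg.SAMPLES})
        draws = np.array([
            hg.generate_counts(cat, spec, seed=s)[0]
            .counts["CS"].to_numpy() for s in range(40)])
        mean = draws.mean(axis=0)
        var = draws.var(axis=0, ddof=1)
        # variance/mean ratio ~ 1 for Poisson, averaged over genes
        assert abs((var / mean).mean() - 1.0) < 0.15

    def test_planted_fold_recovered_in_high_abundance_stratum(self):
        cat = hg.generate_catalog(
            hg.CatalogSpec(n_genes=20_000, organ_specific_fraction=0.0,
                           seed=31))
        spec = hg.DESpec(de_fraction=0.1, fold_change=4.0, up_fraction=0.5,
                         shared_fraction=0.0, dispersion=0.0,
                         library_sizes={s: 4_000_000 for s in hg.SAMPLES})
        cm, truth = hg.generate_counts(cat, spec, seed=32)
        tg = truth.genes
        up = tg.index[tg["de_shoot"] & (tg["direction"] == "up")
                      & (tg["mu_CS"] >= 100)]
        assert len(up) >= 250
        ratio = (cm.counts.loc[up, "NS"].sum() / cm.counts.loc[up, "CS"].sum())
        assert 3.5 <= ratio <= 4.5

    def test_organ_specific_genes_are_structural_zeros(self, counts_with_signal):
        _, cm, truth = counts_with_signal
        shoot_only = truth.genes.index[truth.genes["organ"] == "shoot"]
        assert (cm.counts.loc[shoot_only, ["CR", "NR"]].to_numpy() == 0).all()

    def test_truth_fraction_matches_spec_within_binomial_error(self):
        cat = hg.generate_catalog(hg.CatalogSpec(n_genes=10_000, seed=41))
        spec = hg.DESpec(de_fraction=0.05)
        _, truth = hg.generate_counts(cat, spec, seed=42)
        n_de = truth.genes["is_de"].sum()
        sd = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(n_de - 500) <= 3 * sd


class TestReads:
    def test_no_contamination_means_no_flags(self, small_catalog):
        per_gene = pd.Series(5, index=small_catalog.gene_ids)
        zero = ContaminationSpec(adapter_fraction=0, polya_fraction=0,
                                 n_fraction=0, lowq_end_fraction=0,
                                 duplicate_fraction=0)
        _, truth = hg.generate_reads(small_catalog, per_gene, 100, zero, 1)
        flag_cols = ["has_adapter", "has_polyA_tail", "has_N", "low_quality",
                     "is_duplicate_pair"]
        assert not truth[flag_cols].any().any()

    def test_duplicate_fraction_binomial(self):
        # long genes so fragment starts are distinct and only planted
        # duplicates are byte-identical
        cat = hg.generate_catalog(
            hg.CatalogSpec(n_genes=100, length_min=1500, length_max=1800,
                           seed=34))
        per_gene = pd.Series(100, index=cat.gene_ids)
        spec = ContaminationSpec(adapter_fraction=0, polya_fraction=0,
                                 n_fraction=0, lowq_end_fraction=0,
                                 duplicate_fraction=0.1)
        _, truth = hg.generate_reads(cat, per_gene, 100, spec, 2)
        n = len(truth)
        n_dup = truth["is_duplicate_pair"].sum()
        assert abs(n_dup - 0.1 * n) <= 3 * np.sqrt(n * 0.1 * 0.9)

    def test_flagged_n_reads_contain_n(self, small_catalog):
        per_gene = pd.Series(20, index=small_catalog.gene_ids)
        spec = ContaminationSpec(n_fraction=0.3)
        pairs, truth = hg.generate_reads(small_catalog, per_gene, 100, spec, 3)
        bases1 = {rid: b1 for rid, b1, _, _, _ in pairs}
        flagged = truth.index[truth["has_N"]]
        assert len(flagged) > 0
        assert all("N" in bases1[rid] for rid in flagged)

    def test_incoherent_exclusive_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ContaminationSpec(adapter_fraction=0.7,
                              polya_fraction=0.6).validate()


class TestAlignments:
    def test_zero_multimap_single_records(self, small_catalog, tmp_path):
        per_gene = pd.Series(10, index=small_catalog.gene_ids)
        sam = tmp_path / "u.sam"
        truth = hg.generate_alignments(small_catalog, per_gene, 0.0, 1, sam)
        assert truth["is_unique"].all()
        counts, total = hg.count_unique_hits(sam)
        assert total == len(truth)

    def test_multimap_fraction_binomial(self, small_catalog, tmp_path):
        per_gene = pd.Series(10_000 // 60 + 1, index=small_catalog.gene_ids)
        truth = hg.generate_alignments(small_catalog, per_gene, 0.5, 2,
                                       tmp_path / "m.sam")
        n = len(truth)
        n_unique = truth["is_unique"].sum()
        assert abs(n_unique - 0.5 * n) <= 150 * (n / 10_000)

    def test_multi_records_share_name_distinct_refs(self, small_catalog,
                                                    tmp_path):
        import pysam
        per_gene = pd.Series(5, index=small_catalog.gene_ids[:10])
        sam = tmp_path / "m2.sam"
        truth = hg.generate_alignments(small_catalog, per_gene, 0.5, 3, sam)
        refs_by_read: dict = {}
        with pysam.AlignmentFile(str(sam), "r") as fh:
            for rec in fh:
                refs_by_read.setdefault(rec.query_name, set()).add(
                    rec.reference_name)
        for rid, row in truth.iterrows():
            assert len(refs_by_read[rid]) == (1 if row["is_unique"] else 2)


class TestQpcr:
    def test_noise_free_fold_one_gives_equal_dct(self):
        ct = hg.generate_qpcr({"g": 1.0, "ref": 1.0}, "ref", 3, 0.0, 1)
        piv = ct[ct["gene_id"] == "g"].pivot_table(
            index="replicate", columns="sample", values="ct")
        assert np.allclose(piv["treated"], piv["control"])

    def test_noise_free_fold_four_gives_ddct_minus_two(self):
        ct = hg.generate_qpcr({"g": 4.0, "ref": 1.0}, "ref", 1, 0.0, 1)
        t = ct.set_index(["gene_id", "sample"])["ct"]
        ddct = ((t[("g", "treated")] - t[("ref", "treated")])
                - (t[("g", "control")] - t[("ref", "control")]))
        assert ddct == pytest.approx(-2.0, abs=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            hg.generate_qpcr({"g": 2.0}, "ref")

    def test_noisy_fold_recovered_within_band(self):
        folds = []
        for seed in range(40):
            ct = hg.generate_qpcr({"g": 4.0, "ref": 1.0}, "ref", 3, 0.2, seed)
            folds.append(hg.delta_delta_ct(ct, "ref").loc["g", "fold"])
        folds = np.asarray(folds)
        # band derived by propagating N(0, 0.2) Ct noise through 2^-ddCt
        assert np.mean((folds >= 3.0) & (folds <= 5.3)) >= 0.75
        assert 3.5 <= folds.mean() <= 4.5
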