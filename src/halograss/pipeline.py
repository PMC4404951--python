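"""End-to-end orchestration: simulate -> qc -> quantify -> DE -> enrichment
-> correspondence analysis -> cross-species comparison -> qPCR concordance.

A single declarative configuration (YAML or dict) with one master seed
drives every stage; per-stage seeds are spawned deterministically from it,
so re-running the same config produces byte-identical output tables. Each
stage logs record counts into the provenance block, enabling conservation
checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from . import qc as qcmod
from . import quantify as qt
from . import diffexp as de
from . import enrichment as en
from . import ca as camod
from . import setcompare as sc
from . import qpcr as qp

DEFAULT_CONFIG = {
    "seed": 0,
    "catalog": {},            # CatalogSpec overrides
    "de_spec": {},            # DESpec overrides
    "reads": {"n_pairs": 4000, "read_len": 100, "contamination": {}},
    "alignments": {"multimap_fraction": 0.6, "reads_per_sample": 50000},
    "qc": {"profile": "turf"},
    "de": {"alpha": 0.05},
    "enrichment": {"alpha": 0.05},
    "ca": {"theta_summit": 0.25, "theta_edge": 0.15, "linkage_cut": 0.5},
    "qpcr": {"n_genes": 6, "n_replicates": 3, "ct_noise_sd": 0.0},
    "rice": {"enabled": True},  # second synthetic experiment for the
                                # cross-species pathway comparison
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run plus provenance."""

    outdir: Path
    qc_report: qcmod.QCReport
    counts: qt.CountMatrix
    fpkm: qt.ExpressionMatrix
    de_tables: dict
    de_venn: de.DEVenn
    enrichment_tables: dict
    embedding: camod.CAEmbedding
    descriptors: pd.DataFrame
    comparison: dict
    qpcr_table: pd.DataFrame
    qpcr_concordance: pd.DataFrame
    truth: sim.TruthTable
    provenance: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """SHA-256 over the bundle's written TSV outputs, in sorted order."""
        h = hashlib.sha256()
        for p in sorted(self.outdir.rglob("*.tsv")):
            h.update(p.name.encode())
            h.update(p.read_bytes())
        return h.hexdigest()


def _enrich_by_direction(de_table, reference, catalog, alpha):
    out = {}
    for direction in ("up", "down"):
        genes = set(de_table.index[(de_table["is_de"])
                                   & (de_table["direction"] == direction)])
        for family, amap in (("GO", catalog.go_map),
                             ("pathway", catalog.pathway_map)):
            out[(direction, family)] = en.enrich(
                genes, reference, amap, alpha=alpha)
    return out


def run_pipeline(config: dict, outdir) -> ReportBundle:
    """Run every stage on synthetic data defined by ``config``.

    Writes all tables under ``outdir`` and returns the in-memory bundle.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config["seed"]).spawn(8)
    stage_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]
    log = {}

    # --- simulate ---------------------------------------------------------
    cat_kwargs = dict(config["catalog"])
    cat_kwargs.setdefault("seed", stage_seed[0])
    catalog = sim.generate_catalog(sim.CatalogSpec(**cat_kwargs))
    catalog.write_fasta(outdir / "catalog.fasta")
    catalog.write_annotation(outdir / "go_map.tsv", outdir / "pathway_map.tsv")
    de_spec = sim.DESpec(**config["de_spec"])
    counts_true, truth = sim.generate_counts(catalog, de_spec, stage_seed[1])
    truth.write(outdir / "truth_genes.tsv", outdir / "truth_terms.tsv")
    log["n_genes"] = catalog.spec.n_genes

    # --- reads + QC -------------------------------------------------------
    reads_cfg = config["reads"]
    rng = np.random.default_rng(stage_seed[2])
    n_pairs = int(reads_cfg["n_pairs"])
    weights = counts_true.counts["CS"].to_numpy().astype(float) + 1.0
    per_gene = pd.Series(
        rng.multinomial(n_pairs, weights / weights.sum()),
        index=catalog.gene_ids)
    contamination = sim.ContaminationSpec(**reads_cfg.get("contamination", {}))
    pairs, read_truth = sim.generate_reads(
        catalog, per_gene, int(reads_cfg["read_len"]), contamination,
        stage_seed[2])
    sim.write_fastq_pair(pairs, outdir / "reads_R1.fastq",
                         outdir / "reads_R2.fastq")
    profile = config["qc"]["profile"]
    cfg = qcmod.QCConfig.rice() if profile == "rice" else qcmod.QCConfig.turf()
    qc_report = qcmod.run_qc(
        outdir / "reads_R1.fastq", outdir / "reads_R2.fastq",
        outdir / "clean_R1.fastq", outdir / "clean_R2.fastq", cfg)
    qc_report.to_tsv(outdir / "qc_report.tsv")
    log["read_pairs_in"] = qc_report.input_pairs
    log["read_pairs_out"] = qc_report.pairs_surviving

    # --- alignments + quantification -------------------------------------
    aln_cfg = config["alignments"]
    mm = float(aln_cfg["multimap_fraction"])
    cap = int(aln_cfg["reads_per_sample"])
    sam_paths = {}
    for j, sample in enumerate(qt.SAMPLES):
        col = counts_true.counts[sample]
        total = int(col.sum())
        if total > cap:  # downsample the emitted SAM, keep proportions
            p = col.to_numpy() / total
            col = pd.Series(
                np.random.default_rng(stage_seed[3] + j).multinomial(cap, p),
                index=col.index)
        # inflate so that the unique fraction approximates the true counts
        sam_paths[sample] = outdir / f"aln_{sample}.sam"
        sim.generate_alignments(catalog, col, mm, stage_seed[3] + j,
                                sam_paths[sample])
    counts = qt.counts_from_sams(sam_paths, catalog.lengths)
    counts.to_tsv(outdir / "counts.tsv")
    fpkm = qt.compute_fpkm(counts)
    fpkm.to_tsv(outdir / "fpkm.tsv")
    expressed = qt.expressed_sets(counts)
    log["mapped_fragments"] = {s: int(t) for s, t in counts.totals.items()}

    # --- differential expression ------------------------------------------
    alpha = float(config["de"]["alpha"])
    de_tables = {organ: de.call_de(counts, organ, alpha=alpha)
                 for organ in ("shoot", "root")}
    for organ, tab in de_tables.items():
        tab.to_csv(outdir / f"de_{organ}.tsv", sep="\t")
    venn = de.de_venn(de_tables["shoot"], de_tables["root"])
    venn.to_tsv(outdir / "de_venn.tsv")
    log["de_calls"] = {o: int(t["is_de"].sum()) for o, t in de_tables.items()}

    # --- enrichment -------------------------------------------------------
    e_alpha = float(config["enrichment"]["alpha"])
    enrichment_tables = {}
    for organ in ("shoot", "root"):
        per = _enrich_by_direction(de_tables[organ], expressed[organ],
                                   catalog, e_alpha)
        for (direction, family), tab in per.items():
            enrichment_tables[(organ, direction, family)] = tab
            tab.to_csv(outdir / f"enrich_{organ}_{direction}_{family}.tsv",
                       sep="\t", index=False)

    # --- correspondence analysis ------------------------------------------
    ca_cfg = config["ca"]
    augmented = camod.add_guide_genes(fpkm.values)
    emb = camod.correspondence_analysis(augmented)
    de_union = sorted(venn.all_de())
    subset = de_union if de_union else None
    descriptors = camod.describe_positions(
        emb, subset, theta_summit=float(ca_cfg["theta_summit"]),
        theta_edge=float(ca_cfg["theta_edge"]))
    emb.to_tsv(outdir / "ca_coordinates.tsv")
    descriptors.to_csv(outdir / "ca_positions.tsv", sep="\t")
    if len(de_union) >= 2:
        labels, summary = camod.cluster_subset(
            emb, de_union, linkage_cut=float(ca_cfg["linkage_cut"]))
        labels.to_csv(outdir / "ca_clusters.tsv", sep="\t")
        summary.to_csv(outdir / "ca_cluster_summary.tsv", sep="\t")

    # --- cross-species comparison -----------------------------------------
    comparison = {}
    if config["rice"]["enabled"]:
        rice_cat_kwargs = dict(config["catalog"])
        rice_cat_kwargs["seed"] = stage_seed[4]
        rice_catalog = sim.generate_catalog(sim.CatalogSpec(**rice_cat_kwargs))
        rice_counts, _ = sim.generate_counts(rice_catalog, de_spec,
                                             stage_seed[5])
        rice_expressed = qt.expressed_sets(rice_counts)
        rice_de = {organ: de.call_de(rice_counts, organ, alpha=alpha)
                   for organ in ("shoot", "root")}
        for direction in ("up", "down"):
            def enriched_ids(tab, ref, amap):
                genes = set(tab.index[(tab["is_de"])
                                      & (tab["direction"] == direction)])
                res = en.enrich(genes, ref, amap, alpha=e_alpha)
                return set(res.loc[res["enriched"], "term_id"])

            turf_shoot = enriched_ids(de_tables["shoot"], expressed["shoot"],
                                      catalog.pathway_map)
            turf_root = enriched_ids(de_tables["root"], expressed["root"],
                                     catalog.pathway_map)
            rice_leaf = enriched_ids(rice_de["shoot"], rice_expressed["shoot"],
                                     rice_catalog.pathway_map)
            rice_root = enriched_ids(rice_de["root"], rice_expressed["root"],
                                     rice_catalog.pathway_map)
            part = sc.venn_partition({
                "turf_shoot": turf_shoot, "turf_root": turf_root,
                "rice_leaf": rice_leaf, "rice_root": rice_root,
            }) if (turf_shoot | turf_root | rice_leaf | rice_root) else None
            comp = sc.species_compare(turf_shoot, turf_root, rice_leaf,
                                      rice_root, direction=direction)
            comp.to_tsv(outdir / f"pathway_compare_{direction}.tsv")
            if part is not None:
                part.to_tsv(outdir / f"pathway_venn_{direction}.tsv")
            comparison[direction] = comp

    # --- qPCR -------------------------------------------------------------
    qcfg = config["qpcr"]
    de_called = de_tables["root"][de_tables["root"]["is_de"]]
    strong = de_called[(de_called["x1"] >= 50) | (de_called["x2"] >= 50)]
    # verification panel: called genes that are truly root-responsive
    true_root = set(truth.genes.index[truth.genes["de_root"]])
    targets = [g for g in strong.index if g in true_root]
    targets = targets[: int(qcfg["n_genes"])]
    ref_candidates = [g for g in counts.gene_ids
                      if g not in set(truth.genes.index[truth.genes["is_de"]])
                      and counts.counts.loc[g, "CR"] > 0]
    reference = ref_candidates[0]
    folds = {g: float(truth.genes.loc[g, "fold_change"]) for g in targets}
    folds[reference] = 1.0
    ct = sim.generate_qpcr(folds, reference,
                           n_replicates=int(qcfg["n_replicates"]),
                           ct_noise_sd=float(qcfg["ct_noise_sd"]),
                           seed=stage_seed[6])
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    rel = qp.delta_delta_ct(ct, reference)
    rel.to_csv(outdir / "qpcr_folds.tsv", sep="\t")
    seq_folds = pd.Series({
        g: (counts.counts.loc[g, "NR"] / counts.totals["NR"] + 1e-12)
           / (counts.counts.loc[g, "CR"] / counts.totals["CR"] + 1e-12)
        for g in targets}, name="pipeline_fold")
    conc = qp.concordance(rel.drop(index=reference), seq_folds) \
        if targets else pd.DataFrame()
    if targets:
        conc.to_csv(outdir / "qpcr_concordance.tsv", sep="\t")

    provenance = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seed": config["seed"],
        "record_counts": log,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True))

    return ReportBundle(
        outdir=outdir, qc_report=qc_report, counts=counts, fpkm=fpkm,
        de_tables=de_tables, de_venn=venn,
        enrichment_tables=enrichment_tables, embedding=emb,
        descriptors=descriptors, comparison=comparison, qpcr_table=ct,
        qpcr_concordance=conc, truth=truth, provenance=provenance)
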