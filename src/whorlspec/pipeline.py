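"""End-to-end pipeline wiring: simulate -> QC -> DEG -> enrichment ->
whorl specificity -> degradome -> phylogeny -> qPCR.

A single global seed fans out to per-stage seeds; rerunning with the same
configuration and seed reproduces byte-identical outputs, recorded in a
manifest with per-file SHA-256 checksums.  Configuration is a nested
mapping mirroring each stage's parameters; unknown keys are rejected
before any stage runs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deg, degradome, enrich, io, phylo, qpcr, quantnorm, whorl
from .containers import ExpressionMatrix
from .synth import SimConfig, simulate_degradome, simulate_expression, \
    simulate_go_annotation, simulate_protein_families

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "sim": {
        "n_genes": 800,
        "organs": ["sepal", "petal", "stamen"],
        "cultivars": ["wild", "formal", "anemone"],
        "n_replicates": 3,
        "baseline_mean": 100.0,
        "dispersion": 0.1,
        "frac_specific": 0.1,
        "specificity_fold": 20.0,
        "fading": {"wild": 0.0, "formal": 0.75, "anemone": 0.5},
        "gene_length_range": [200, 3000],
    },
    "qc": {"within_threshold": 0.73, "outlier_threshold": 0.2},
    "cluster": {"highlight_below": 20000.0, "log_transform": True},
    "deg": {"log2fc": 1.0, "pval": 0.05, "fdr": 0.001},
    "enrich": {"alpha": 0.05, "min_genes": 5, "n_terms": 40, "n_enriched": 5,
               "enrichment_odds": 10.0, "highly_enriched_cutoff": 1e-5},
    "whorl": {"factor": 10.0, "floor": 0.1},
    "degradome": {"n_mirnas": 6, "n_targets": 3, "n_transcripts": 20,
                  "transcript_length": 300, "score_cutoff": 5.0,
                  "n_shuffles": 39, "pval": 0.05},
    "phylo": {"n_families": 8, "seq_length": 120, "mutation_rate": 0.05},
    "qpcr": {"n_genes": 5, "alpha": 0.05},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Demo defaults, optionally updated from a YAML file and a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage on synthetic data; returns the output manifest."""
    config = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config["log_level"])
    seed = int(config["seed"])
    stage_seeds = {name: seed + off for off, name in enumerate(
        ["sim", "annotation", "degradome", "phylo", "qpcr"], start=0)}
    manifest: dict = {"seed": seed, "config": config, "outputs": {}}

    def record(stage: str, name: str, path: Path):
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path.relative_to(outdir)), "sha256": _sha256(path)}

    # -- simulate -------------------------------------------------------------
    simc = config["sim"]
    sim_config = SimConfig(
        n_genes=int(simc["n_genes"]), organs=tuple(simc["organs"]),
        cultivars=tuple(simc["cultivars"]), n_replicates=int(simc["n_replicates"]),
        baseline_mean=float(simc["baseline_mean"]),
        dispersion=float(simc["dispersion"]),
        frac_specific=float(simc["frac_specific"]),
        specificity_fold=float(simc["specificity_fold"]),
        fading=simc["fading"], seed=stage_seeds["sim"],
        gene_length_range=tuple(simc["gene_length_range"]))
    counts, truth = simulate_expression(sim_config)
    annotation = simulate_go_annotation(
        sim_config, truth, n_terms=int(config["enrich"]["n_terms"]),
        n_enriched=int(config["enrich"]["n_enriched"]),
        enrichment_odds=float(config["enrich"]["enrichment_odds"]),
        seed=stage_seeds["annotation"])
    sim_dir = outdir / "synth"
    sim_dir.mkdir(exist_ok=True)
    io.write_counts(counts, sim_dir / "counts.tsv", sim_dir / "samples.tsv")
    io.write_annotation(annotation, sim_dir / "annotation.tsv")
    io.write_truth(truth, sim_dir / "truth.json")
    for name in ["counts.tsv", "samples.tsv", "annotation.tsv", "truth.json"]:
        record("synth", name, sim_dir / name)

    # -- QC and organ clustering ---------------------------------------------
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    report = quantnorm.replicate_qc(
        counts, within_threshold=float(config["qc"]["within_threshold"]),
        outlier_threshold=float(config["qc"]["outlier_threshold"]))
    report.correlations.to_csv(qc_dir / "correlations.tsv", sep="\t")
    report.flagged.to_csv(qc_dir / "flagged.tsv", sep="\t", index=False)
    kept = [s for s in counts.sample_ids if s not in report.removed]
    counts_qc = counts.subset_samples(kept)
    dendro = quantnorm.organ_dendrogram(
        counts_qc, highlight_below=float(config["cluster"]["highlight_below"]),
        log_transform=bool(config["cluster"]["log_transform"]))
    (qc_dir / "organ_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    for name in ["correlations.tsv", "flagged.tsv", "organ_dendrogram.nwk"]:
        record("qc", name, qc_dir / name)

    # -- differential expression ----------------------------------------------
    deg_dir = outdir / "deg"
    deg_dir.mkdir(exist_ok=True)
    thresholds = deg.Thresholds(log2fc=float(config["deg"]["log2fc"]),
                                pval=float(config["deg"]["pval"]),
                                fdr=float(config["deg"]["fdr"]))
    groups = counts_qc.group_key()
    comparisons: list[tuple[str, str, str]] = []
    for cultivar in sim_config.cultivars:
        organs = list(sim_config.organs)
        for i in range(len(organs)):
            for j in range(i + 1, len(organs)):
                comparisons.append((f"{cultivar}:{organs[i]}_vs_{organs[j]}",
                                    f"{organs[i]}|{cultivar}",
                                    f"{organs[j]}|{cultivar}"))
    deg_tables: dict[str, pd.DataFrame] = {}
    for comp_id, ga, gb in comparisons:
        sa = list(groups.index[groups == ga])
        sb = list(groups.index[groups == gb])
        table = deg.call_degs(counts_qc, sa, sb, thresholds=thresholds,
                              comparison=comp_id)
        deg_tables[comp_id] = table
        fname = f"deg_{comp_id.replace(':', '_')}.tsv"
        table.to_csv(deg_dir / fname, sep="\t")
        record("deg", fname, deg_dir / fname)
    first_two = list(deg_tables)[:2]
    overlap = deg.overlap_analysis(deg_tables[first_two[0]],
                                   deg_tables[first_two[1]])
    io.write_json({"shared": overlap.shared, "private_x": overlap.private_x,
                   "private_y": overlap.private_y,
                   "concordance": overlap.concordance,
                   "partition": {f"{a}/{b}": n
                                 for (a, b), n in overlap.partition.items()}},
                  deg_dir / "overlap.json")
    record("deg", "overlap.json", deg_dir / "overlap.json")

    # -- GO enrichment and resemblance ----------------------------------------
    enr_dir = outdir / "enrich"
    enr_dir.mkdir(exist_ok=True)
    results = [enrich.ks_enrichment(deg_tables[c]["pvalue"], annotation,
                                    min_genes=int(config["enrich"]["min_genes"]),
                                    comparison=c)
               for c in deg_tables]
    alpha = float(config["enrich"]["alpha"])
    matrix = enrich.build_comparison_matrix(results, alpha=alpha)
    matrix.to_csv(enr_dir / "comparison_matrix.tsv", sep="\t")
    resemblance = enrich.cluster_comparisons(matrix)
    (enr_dir / "resemblance.nwk").write_text(resemblance.to_newick() + "\n")
    screen = enrich.highly_enriched_screen(
        results, cutoff=float(config["enrich"]["highly_enriched_cutoff"]))
    screen.to_csv(enr_dir / "highly_enriched.tsv", sep="\t")
    for name in ["comparison_matrix.tsv", "resemblance.nwk", "highly_enriched.tsv"]:
        record("enrich", name, enr_dir / name)

    # -- whorl specificity and collapse ---------------------------------------
    whorl_dir = outdir / "whorl"
    whorl_dir.mkdir(exist_ok=True)
    rp = quantnorm.rpkm(counts_qc)
    organ_means = {}
    for cultivar in sim_config.cultivars:
        cols = rp.samples.index[rp.samples["cultivar"] == cultivar]
        sub = rp.subset_samples(list(cols))
        organ_means[cultivar] = sub.group_means(by=("organ",))
    wild = sim_config.cultivars[0]
    wild_table = whorl.whorl_specific_genes(
        organ_means[wild], factor=float(config["whorl"]["factor"]),
        floor=float(config["whorl"]["floor"]))
    wild_table.to_csv(whorl_dir / "wild_specific.tsv", sep="\t")
    record("whorl", "wild_specific.tsv", whorl_dir / "wild_specific.tsv")
    collapse_summary = {}
    for cultivar in sim_config.cultivars[1:]:
        rep = whorl.specificity_collapse(
            wild_table, organ_means[cultivar],
            factor=float(config["whorl"]["factor"]),
            floor=float(config["whorl"]["floor"]))
        rep.per_gene.to_csv(whorl_dir / f"collapse_{cultivar}.tsv", sep="\t")
        rep.heatmap.to_csv(whorl_dir / f"heatmap_{cultivar}.tsv", sep="\t")
        record("whorl", f"collapse_{cultivar}.tsv",
               whorl_dir / f"collapse_{cultivar}.tsv")
        record("whorl", f"heatmap_{cultivar}.tsv",
               whorl_dir / f"heatmap_{cultivar}.tsv")
        collapse_summary[cultivar] = {
            "overall_retention": rep.overall_retention(),
            "retention": rep.retention.to_dict(),
            "mean_delta_tau": float((rep.per_gene["tau_wild"]
                                     - rep.per_gene["tau_cultivar"]).mean()),
        }
    io.write_json(collapse_summary, whorl_dir / "collapse_summary.json")
    record("whorl", "collapse_summary.json", whorl_dir / "collapse_summary.json")

    # -- degradome -------------------------------------------------------------
    dg_dir = outdir / "degradome"
    dg_dir.mkdir(exist_ok=True)
    dgc = config["degradome"]
    dg_sim = simulate_degradome(
        sim_config, n_mirnas=int(dgc["n_mirnas"]), n_targets=int(dgc["n_targets"]),
        n_transcripts=int(dgc["n_transcripts"]),
        transcript_length=int(dgc["transcript_length"]),
        libraries=("shoot", "floral_bud"), seed=stage_seeds["degradome"])
    io.write_fasta(dg_sim.mirnas, dg_dir / "mirnas.fa")
    io.write_fasta(dg_sim.transcripts, dg_dir / "transcripts.fa")
    for lib, prof in dg_sim.profiles.items():
        io.write_pileup(prof, dg_dir / f"pileup_{lib}.tsv")
        record("degradome", f"pileup_{lib}.tsv", dg_dir / f"pileup_{lib}.tsv")
    merged_profile = degradome.merge_profiles(dg_sim.profiles)
    hits = degradome.scan_targets(dg_sim.mirnas, dg_sim.transcripts,
                                  score_cutoff=float(dgc["score_cutoff"]))
    hits = degradome.categorize_hits(hits, merged_profile)
    supported = [h for h in hits if h.category is not None]
    supported = degradome.annotate_pvalues(
        supported, dg_sim.mirnas, dg_sim.transcripts, merged_profile,
        n_shuffles=int(dgc["n_shuffles"]), seed=stage_seeds["degradome"])
    hit_rows = [{"mirna": h.mirna_id, "transcript": h.transcript_id,
                 "slice_pos": h.slice_pos, "score": h.score,
                 "category": h.category, "pvalue": h.pvalue}
                for h in supported]
    pd.DataFrame(hit_rows).to_csv(dg_dir / "hits.tsv", sep="\t", index=False)
    confident = [h for h in supported
                 if h.pvalue is not None and h.pvalue < float(dgc["pval"])]
    for h in confident:
        tab = degradome.tplot_table(h.transcript_id, merged_profile, [h])
        fname = f"tplot_{h.mirna_id}_{h.transcript_id}.tsv"
        tab.to_csv(dg_dir / fname, sep="\t", index=False)
        record("degradome", fname, dg_dir / fname)
    for name in ["mirnas.fa", "transcripts.fa", "hits.tsv"]:
        record("degradome", name, dg_dir / name)

    # -- phylogeny / orthology -------------------------------------------------
    ph_dir = outdir / "phylo"
    ph_dir.mkdir(exist_ok=True)
    phc = config["phylo"]
    prot = simulate_protein_families(
        sim_config, n_families=int(phc["n_families"]),
        seq_length=int(phc["seq_length"]),
        mutation_rate=float(phc["mutation_rate"]), seed=stage_seeds["phylo"])
    io.write_fasta(prot.proteome_a, ph_dir / "proteome_a.fa")
    io.write_fasta(prot.proteome_b, ph_dir / "proteome_b.fa")
    io.write_similarity(prot.scores_ab, ph_dir / "scores_ab.tsv")
    io.write_similarity(prot.scores_ba, ph_dir / "scores_ba.tsv")
    pairs = phylo.rbh_orthologs(prot.scores_ab, prot.scores_ba)
    pd.DataFrame(pairs, columns=["protein_a", "protein_b"]).to_csv(
        ph_dir / "orthologs.tsv", sep="\t", index=False)
    tree = phylo.nj_tree(prot.distances)
    (ph_dir / "nj_tree.nwk").write_text(tree + "\n")
    prot.distances.to_csv(ph_dir / "distances.tsv", sep="\t")
    for name in ["proteome_a.fa", "proteome_b.fa", "scores_ab.tsv",
                 "scores_ba.tsv", "orthologs.tsv", "nj_tree.nwk", "distances.tsv"]:
        record("phylo", name, ph_dir / name)

    # -- qPCR validation -------------------------------------------------------
    qp_dir = outdir / "qpcr"
    qp_dir.mkdir(exist_ok=True)
    rngq = np.random.default_rng(stage_seeds["qpcr"])
    rp_means = organ_means[wild]
    picked = list(rp_means.index[:int(config["qpcr"]["n_genes"])])
    samples = list(rp_means.columns)
    rows = []
    for gene in picked:
        for sample in samples:
            # Ct declines by one cycle per doubling of abundance
            ct_t = 30.0 - np.log2(rp_means.loc[gene, sample] + 1.0)
            for rep in range(3):
                rows.append((gene, sample,
                             float(ct_t + rngq.normal(0.0, 0.15)),
                             float(20.0 + rngq.normal(0.0, 0.1))))
    ct = pd.DataFrame(rows, columns=["gene", "sample", "ct_target",
                                     "ct_reference"])
    rq_table = qpcr.ddct(ct, calibrator=samples[0])
    rq = rq_table.pivot(index="gene", columns="sample", values="rq")
    corr = qpcr.platform_correlation(rq, rp_means.loc[picked],
                                     alpha=float(config["qpcr"]["alpha"]))
    ct.to_csv(qp_dir / "ct_table.tsv", sep="\t", index=False)
    rq_table.to_csv(qp_dir / "relative_quantities.tsv", sep="\t", index=False)
    corr.to_csv(qp_dir / "platform_correlation.tsv", sep="\t")
    for name in ["ct_table.tsv", "relative_quantities.tsv",
                 "platform_correlation.tsv"]:
        record("qpcr", name, qp_dir / name)

    manifest_path = outdir / "manifest.json"
    io.write_json(manifest, manifest_path)
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
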