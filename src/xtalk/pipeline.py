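"""End-to-end orchestration: simulate -> cluster -> dmr -> annotate -> scan -> network.

The pipeline is driven by a flat configuration mapping (YAML on disk); every
stage can be toggled, all randomness flows from a single ``seed``, and the
run produces a machine-readable summary report (JSON + TSV) along with the
intermediate TSV/BED artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation, dmr, expression, io, network, nrbs, simulate
from .clustering import TriadCall, round_half_up, summarize_categories

log = logging.getLogger("xtalk.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "xtalk_out",
    # stage toggles
    "run_simulate": True,
    "run_cluster": True,
    "run_dmr": True,
    "run_annotate": True,
    "run_scan_nrbs": True,
    "run_network": True,
    "use_paper_fixture": False,
    # expression simulation
    "n_genes": 2000,
    "effect_size": 2.0,
    "nb_dispersion": 0.05,
    "n_reps": 3,
    # genome / methylome simulation
    "genome_len": 100_000,
    "n_dmr_regions": 8,
    "dmr_region_len": 800,
    "methylation_effect": -0.8,
    "depth": 100_000,
    "fragment_len": 50,
    "dmr_cpg_enrichment": 3.0,
    "n_planted_motifs": 30,
    "n_genome_genes": 20,
    "n_genome_tes": 30,
    # DMR caller
    "window": 10,
    "iterations": 100,
    "extend": 0,
    "retention_rule": "and",
    # NRBS scan
    "min_score": 3.0,
    "p_enter": 0.05,
    "mismatch": 0.05,
    "max_spacer": 8,
    # network
    "hub_degree": 20,
    # inputs when simulation is disabled
    "counts_explant": None,
    "counts_whole": None,
}


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Merge defaults, an optional YAML file, and keyword overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        config.update(user)
    config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def _planted_methylation_truth(config: Mapping[str, Any], genome: simulate.GenomeFixture):
    """Plant a mix of triad responses on the genome fixture's DMR intervals."""
    codes = ("d_n_d", "d_d_d", "n_n_d", "d_n_n", "d_n_u", "n_d_d")
    e = abs(float(config["methylation_effect"]))
    sign = {"d": -e, "u": e, "n": 0.0}
    truth = []
    for i, row in enumerate(genome.dmr_intervals.itertuples(index=False)):
        code = codes[i % len(codes)]
        effects = tuple(sign[c] for c in code.split("_"))
        truth.append(
            simulate.MethylationTruth(
                seq_id=row.seq_id, start=int(row.start), end=int(row.end),
                effect_fraction=effects,
            )
        )
    return truth


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Execute the enabled stages in dependency order and write a report.

    Identical configurations (including seed) produce identical artifacts.
    Fails fast if a required input path is missing.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {"parameters": {k: v for k, v in cfg.items()}, "stages": {}}

    for key in ("counts_explant", "counts_whole"):
        if cfg[key] is not None and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"configured input does not exist: {cfg[key]}")

    if cfg["use_paper_fixture"]:
        log.info("stage report: published worked-example tables")
        gene_table, dmr_table = simulate.paper_counts_fixture()
        gene_calls = [
            TriadCall(r.gene_id, r.code, r.category) for r in gene_table.itertuples(index=False)
        ]
        dmr_calls = [
            TriadCall(r.dmr_id, r.code, r.category) for r in dmr_table.itertuples(index=False)
        ]
        gene_summary = summarize_categories(gene_calls)
        dmr_summary = summarize_categories(dmr_calls)
        gene_summary.to_csv(outdir / "gene_categories.tsv", sep="\t", index=False)
        dmr_summary.to_csv(outdir / "dmr_categories.tsv", sep="\t", index=False)
        overlap_pct = round_half_up(
            100.0 * float((dmr_table["nearest_gene_distance"] == 0).mean())
        )
        report["stages"]["fixture"] = {
            "n_genes": len(gene_table),
            "n_dmrs": len(dmr_table),
            "gene_categories": _summary_dict(gene_summary),
            "dmr_categories": _summary_dict(dmr_summary),
            "dmr_gene_overlap_pct": overlap_pct,
        }
        _write_report(report, outdir)
        return report

    genome = None
    methylome_truth = None
    reads = None
    explant = whole = truth = None

    if cfg["run_simulate"]:
        log.info("stage simulate: seed=%d n_genes=%d", seed, cfg["n_genes"])
        explant, whole, truth = simulate.simulate_expression(
            n_genes=int(cfg["n_genes"]),
            effect_size=float(cfg["effect_size"]),
            nb_dispersion=float(cfg["nb_dispersion"]),
            n_reps=int(cfg["n_reps"]),
            seed=seed,
        )
        io.write_counts(explant, outdir / "counts_explant.tsv")
        io.write_counts(whole, outdir / "counts_whole.tsv")
        truth.to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)

        rng = np.random.default_rng(seed + 1)
        motif_specs = []
        topologies = ("DR", "IR", "ER")
        # non-overlapping 40 bp slots so planted motifs never clobber each other
        slots = rng.choice(int(cfg["genome_len"]) // 40 - 1,
                           size=int(cfg["n_planted_motifs"]), replace=False)
        for k, s in enumerate(sorted(slots)):
            motif_specs.append(
                ("chr1", int(s) * 40, topologies[k % 3],
                 int(rng.integers(0, int(cfg["max_spacer"]) + 1)))
            )
        genome = simulate.simulate_genome(
            seq_len=int(cfg["genome_len"]),
            n_genes=int(cfg["n_genome_genes"]),
            n_tes=int(cfg["n_genome_tes"]),
            dmr_cpg_enrichment=float(cfg["dmr_cpg_enrichment"]),
            dmr_len=int(cfg["dmr_region_len"]),
            n_dmr_intervals=int(cfg["n_dmr_regions"]),
            planted_motifs=motif_specs,
            seed=seed + 1,
        )
        io.write_fasta(genome.sequences, outdir / "genome.fa")
        io.write_gff3(genome.genes, outdir / "genes.gff3")
        io.write_bed(genome.tes, outdir / "tes.bed")

        methylome_truth = _planted_methylation_truth(cfg, genome)
        reads = simulate.simulate_methylome(
            genome_len=int(cfg["genome_len"]),
            truth=methylome_truth,
            depth=int(cfg["depth"]),
            fragment_len=int(cfg["fragment_len"]),
            seed=seed + 2,
        )
        io.write_reads_bed(reads, "chr1", outdir / "methylcap_reads.bed")
        report["stages"]["simulate"] = {
            "n_genes": int(cfg["n_genes"]),
            "n_truth_genes": len(truth),
            "n_methylation_regions": len(methylome_truth),
            "n_planted_motifs": len(genome.planted_motifs),
        }
    elif cfg["counts_explant"] and cfg["counts_whole"]:
        explant = io.read_counts(cfg["counts_explant"])
        whole = io.read_counts(cfg["counts_whole"])

    if cfg["run_cluster"]:
        if explant is None or whole is None:
            raise ValueError("clustering requires count matrices (simulate or configure paths)")
        log.info("stage cluster: %d genes", len(explant))
        result = expression.classify_counts(explant, whole)
        io.write_calls(result["calls"], outdir / "gene_calls.tsv")
        stage = {
            "n_de": result["n_de"],
            "n_retained": result["n_retained"],
            "threshold_explant": result["threshold_explant"],
            "threshold_whole": result["threshold_whole"],
        }
        if result["calls"]:
            summary = summarize_categories(result["calls"])
            summary.to_csv(outdir / "gene_categories.tsv", sep="\t", index=False)
            stage["categories"] = _summary_dict(summary)
        report["stages"]["cluster"] = stage

    dmr_result = None
    if cfg["run_dmr"]:
        if reads is None:
            raise ValueError("DMR stage requires simulated methylome reads")
        log.info("stage dmr: %d reads/sample", int(cfg["depth"]))
        dmr_result = dmr.detect_dmrs(
            reads,
            seq_len=int(cfg["genome_len"]),
            window=int(cfg["window"]),
            iterations=int(cfg["iterations"]),
            extend=int(cfg["extend"]),
            seed=seed + 3,
            rule=str(cfg["retention_rule"]),
        )
        _write_dmrs(dmr_result, outdir / "dmrs.bed")
        stage = {
            "n_dmrs": len(dmr_result.dmrs),
            "per_treatment": dmr_result.per_treatment_counts,
            "thresholds": {
                t: {"w_max": th.w_max, "h_max": th.h_max}
                for t, th in dmr_result.thresholds.items()
            },
        }
        calls = [
            TriadCall(f"dmr{i:04d}", d.code, d.category)
            for i, d in enumerate(dmr_result.dmrs)
        ]
        if calls:
            summary = summarize_categories(calls)
            summary.to_csv(outdir / "dmr_categories.tsv", sep="\t", index=False)
            stage["categories"] = _summary_dict(summary)
        report["stages"]["dmr"] = stage

    if cfg["run_annotate"] and dmr_result is not None and genome is not None:
        log.info("stage annotate: %d DMRs", len(dmr_result.dmrs))
        dmr_df = pd.DataFrame(
            [{"seq_id": "chr1", "start": d.start, "end": d.end} for d in dmr_result.dmrs]
        )
        stage: dict[str, Any] = {}
        if len(dmr_df):
            annotated = annotation.annotate_distances(dmr_df, genome.genes)
            annotated.to_csv(outdir / "dmrs_annotated.tsv", sep="\t", index=False)
            te_frac, families = annotation.overlap_fraction(
                [(d.start, d.end) for d in dmr_result.dmrs],
                [
                    (int(r.start), int(r.end), str(r.family))
                    for r in genome.tes.itertuples(index=False)
                ],
            )
            dmr_seqs = annotation.extract_sequences(genome.sequences, dmr_df)
            exon_seqs = annotation.extract_sequences(
                genome.sequences, genome.exons[["seq_id", "start", "end"]]
            )
            cpg = annotation.cpg_enrichment(
                annotation.dinucleotide_profile(dmr_seqs),
                annotation.dinucleotide_profile(exon_seqs),
            )
            stage = {
                "gene_overlap_fraction": float((annotated["nearest_gene_distance"] == 0).mean()),
                "te_overlap_fraction": te_frac,
                "te_families": families,
                "cpg": cpg,
            }
        report["stages"]["annotate"] = stage

    if cfg["run_scan_nrbs"] and genome is not None:
        log.info("stage scan-nrbs")
        model = nrbs.build_nrbs_model(
            mismatch=float(cfg["mismatch"]),
            max_spacer=int(cfg["max_spacer"]),
            p_enter=float(cfg["p_enter"]),
        )
        hits = []
        for seq_id, seq in genome.sequences.items():
            hits.extend(
                (seq_id, h) for h in nrbs.viterbi_scan(seq, model, float(cfg["min_score"]))
            )
        with open(outdir / "nrbs_hits.bed", "w") as fh:
            for seq_id, h in hits:
                fh.write(
                    f"{seq_id}\t{h.start}\t{h.end}\t{h.label}\t{h.score:.3f}\t{h.strand}\t{h.spacer}\n"
                )
        planted = {(sid, pos) for sid, pos, _, _ in genome.planted_motifs}
        recovered = sum(
            1
            for sid, pos, topo, spacer in genome.planted_motifs
            if any(
                s == sid and h.start == pos and h.topology == topo and h.spacer == spacer
                for s, h in hits
            )
        )
        report["stages"]["scan_nrbs"] = {
            "n_hits": len(hits),
            "n_planted": len(planted),
            "n_recovered": recovered,
            "labels": dict(pd.Series([h.label for _, h in hits]).value_counts())
            if hits
            else {},
        }

    if cfg["run_network"]:
        log.info("stage network")
        pathways, nodes = simulate.simulate_pathways(seed=seed + 4)
        rng = np.random.default_rng(seed + 5)
        de_genes = list(rng.choice(nodes, size=40, replace=False))
        graph = network.merge_pathway_graphs(pathways, de_genes)
        metrics = network.node_metrics(graph, hub_degree=int(cfg["hub_degree"]))
        metrics.to_csv(outdir / "network_metrics.tsv", sep="\t")
        exponent, r2 = (None, None)
        try:
            exponent, r2 = network.powerlaw_check(list(metrics["degree"]))
        except ValueError:
            pass
        report["stages"]["network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_hubs": int(metrics["is_hub"].sum()),
            "powerlaw_exponent": exponent,
            "powerlaw_r2": r2,
        }

    _write_report(report, outdir)
    return report


def _summary_dict(summary: pd.DataFrame) -> dict[str, dict[str, float]]:
    cats = summary[summary["level"] == "category"]
    return {
        str(row["name"]): {"count": int(row["count"]), "percent": float(row["percent"])}
        for _, row in cats.iterrows()
    }


def _write_dmrs(result: dmr.DMRResult, path: Path) -> None:
    with open(path, "w") as fh:
        for d in result.dmrs:
            sign = "+" if d.sign > 0 else "-"
            fh.write(
                f"chr1\t{d.start}\t{d.end}\t{d.code}\t{d.height:.3f}\t{sign}\t{d.category}\n"
            )


def _write_report(report: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    rows = []
    for stage, payload in report["stages"].items():
        for key, value in payload.items():
            if isinstance(value, (int, float, str)) or value is None:
                rows.append({"stage": stage, "metric": key, "value": value})
    pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
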