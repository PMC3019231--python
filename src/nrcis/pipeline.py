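"""End-to-end orchestration: simulate (or load) inputs, then run every
analysis stage and write a machine-readable report bundle.

The stages mirror a complete downstream ChIP-seq analysis: replicate
overlap accounting, genomic-location classification and TSS-centric
summaries, target-gene assignment, repeat-element / ETS motif scanning
with co-occurrence classification, and expression + gene-set enrichment
integration. Given a fixed seed and inputs the run is fully
deterministic; rerunning produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation, expression_enrichment as ee, interval_core, io_formats, motif_scan
from .synthetic_data import (
    SimulationConfig,
    generate_expression_table,
    generate_gene_annotation,
    generate_peak_set,
    generate_replicate_pair,
    generate_sequences_with_planted_motifs,
    generate_spaced_peaks,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Windows and tolerances are in bp and must be non-negative: target
    window ±1 kb, replicate tolerance 0, histone co-occupancy tolerance
    200 bp, 100 bp TSS bins and 50 bp co-occupancy bins by default.
    Input paths left as ``None`` are generated synthetically from
    ``sim`` (which defaults to ``SimulationConfig(seed=seed)``).
    """

    seed: int = 0
    out_dir: str | Path = "nrcis_run"
    window: int = 1_000
    tolerance: int = 0
    histone_tolerance: int = 200
    tss_bin: int = 100
    tss_span: int = 10_000
    cooccupancy_bin: int = 50
    motif_spec: motif_scan.RepeatElementSpec = field(
        default_factory=motif_scan.RepeatElementSpec
    )
    ets_mode: str = "extended"
    peaks_path: str | None = None
    genes_path: str | None = None
    fasta_path: str | None = None
    expression_path: str | None = None
    gmt_path: str | None = None
    sim: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("window", "tolerance", "histone_tolerance", "tss_bin", "cooccupancy_bin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_inputs(sim: SimulationConfig, out_dir: Path) -> dict[str, Path]:
    """Write a full synthetic input bundle plus its ground truth."""
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = generate_gene_annotation(sim)
    peaks, peak_truth = generate_peak_set(sim, genes)
    base = generate_spaced_peaks(sim, min(len(peaks), 1_000))
    rep1, rep2, rep_truth = generate_replicate_pair(sim, base)
    seqs, seq_truth = generate_sequences_with_planted_motifs(sim, min(len(peaks), 1_000))
    targets = {t.gene_id for t in annotation.assign_target_genes(peaks, genes)}
    expr = generate_expression_table(sim, genes, targets)
    paths = {
        "genes": out_dir / "genes.tsv",
        "peaks": out_dir / "peaks.bed",
        "rep1": out_dir / "rep1.bed",
        "rep2": out_dir / "rep2.bed",
        "fasta": out_dir / "peak_sequences.fa",
        "expression": out_dir / "expression.tsv",
        "truth": out_dir / "ground_truth.json",
    }
    io_formats.write_gene_models(paths["genes"], genes)
    io_formats.write_peaks(paths["peaks"], peaks)
    io_formats.write_peaks(paths["rep1"], rep1)
    io_formats.write_peaks(paths["rep2"], rep2)
    io_formats.write_fasta(paths["fasta"], seqs)
    io_formats.write_expression(paths["expression"], expr)
    paths["truth"].write_text(
        json.dumps(
            {"peaks": peak_truth, "replicates": rep_truth, "sequences": seq_truth},
            indent=1,
        )
        + "\n",
        encoding="utf-8",
    )
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write per-stage TSVs plus ``summary.json``.

    Returns the summary dict (integer percentages exactly as reported,
    raw fractions alongside).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimulationConfig(seed=config.seed)

    if config.peaks_path and config.genes_path:
        genes = io_formats.read_gene_models(config.genes_path)
        peaks = io_formats.read_peaks(config.peaks_path)
        rep1 = rep2 = None
    else:
        sim_paths = simulate_inputs(sim, out_dir / "inputs")
        genes = io_formats.read_gene_models(sim_paths["genes"])
        peaks = io_formats.read_peaks(sim_paths["peaks"])
        rep1 = io_formats.read_peaks(sim_paths["rep1"])
        rep2 = io_formats.read_peaks(sim_paths["rep2"])
    seqs = (
        io_formats.read_fasta(config.fasta_path)
        if config.fasta_path
        else generate_sequences_with_planted_motifs(sim, min(len(peaks), 1_000))[0]
    )

    summary: dict = {"parameters": {
        "seed": config.seed,
        "window": config.window,
        "tolerance": config.tolerance,
        "histone_tolerance": config.histone_tolerance,
        "tss_bin": config.tss_bin,
        "cooccupancy_bin": config.cooccupancy_bin,
        "motif": config.motif_spec.name,
        "ets_mode": config.ets_mode,
    }}

    # --- replicate overlap -------------------------------------------------
    if rep1 is not None and rep2 is not None:
        ov = interval_core.set_overlap(rep1, rep2, config.tolerance)
        summary["replicate_overlap"] = {
            "n_rep1": ov.n_a,
            "n_rep2": ov.n_b,
            "n_rep1_shared": ov.n_a_hit,
            "pct_rep1_shared": ov.pct_a_hit,
            "frac_rep1_shared": ov.frac_a_hit,
        }

    # --- annotation --------------------------------------------------------
    annos = annotation.annotate_peaks(peaks, genes)
    with open(out_dir / "peak_annotation.tsv", "w", encoding="utf-8") as fh:
        fh.write("peak\tchrom\tstart\tend\theight\tcategory\tsub_category\tgene\ttss_distance\n")
        for a in annos:
            p = a.peak
            fh.write(
                f"{p.name}\t{p.chrom}\t{p.start}\t{p.end}\t{p.height:g}\t"
                f"{a.category.value}\t{'' if a.sub_category is None else a.sub_category.value}\t"
                f"{a.gene_id or ''}\t{'' if a.tss_distance is None else a.tss_distance}\n"
            )
    summary["location"] = annotation.location_summary(peaks, genes)
    edges, counts = annotation.tss_histogram(peaks, genes, config.tss_bin, config.tss_span)
    summary["tss_histogram"] = {
        "bin_bp": config.tss_bin,
        "edges": edges.tolist(),
        "counts": counts.tolist(),
    }
    assignments = annotation.assign_target_genes(peaks, genes, config.window)
    med_in, med_out = annotation.median_height_split(peaks, genes, config.window)
    summary["targets"] = {
        "n_peaks": len(peaks),
        "n_assignments": len(assignments),
        "n_target_genes": len({a.gene_id for a in assignments}),
        "pct_peaks_within_window": round(100 * len(assignments) / len(peaks)) if peaks else 0,
        "median_height_within": med_in,
        "median_height_outside": med_out,
    }
    with open(out_dir / "target_genes.tsv", "w", encoding="utf-8") as fh:
        fh.write("peak\tgene\ttss_distance\n")
        for t in assignments:
            fh.write(f"{t.peak_name}\t{t.gene_id}\t{t.tss_distance}\n")

    # --- motifs ------------------------------------------------------------
    per_peak, motif_summary = motif_scan.classify_peak_motifs(
        seqs, config.motif_spec, config.ets_mode
    )
    repeat_hits = [
        h for name, s in seqs.items()
        for h in motif_scan.scan_repeat_elements(s, config.motif_spec, seq_name=name)
    ]
    m_edges, m_counts = motif_scan.motif_offset_histogram(repeat_hits, bin_bp=10, span_bp=250)
    summary["motifs"] = {
        "classes": motif_summary,
        "spacer_composition": motif_scan.spacer_composition(repeat_hits),
        "offset_histogram": {"edges": m_edges.tolist(), "counts": m_counts.tolist()},
    }
    with open(out_dir / "motif_classes.tsv", "w", encoding="utf-8") as fh:
        fh.write("sequence\tclass\n")
        for name, cls in per_peak.items():
            fh.write(f"{name}\t{cls}\n")

    # --- expression + enrichment ------------------------------------------
    expr = (
        io_formats.read_expression(config.expression_path)
        if config.expression_path
        else generate_expression_table(sim, genes, {a.gene_id for a in assignments})
    )
    target_ids = {a.gene_id for a in assignments} & set(expr)
    if target_ids:
        t_sum = ee.summarize_expression(target_ids, expr)
        a_sum = ee.summarize_expression(expr.keys(), expr)
        bg = ee.sample_random_background(expr, n=min(3_000, len(expr)), seed=config.seed)
        b_sum = ee.summarize_expression(bg, expr)
        summary["expression"] = {
            "targets": {"n": t_sum.n, "median": t_sum.median, "q1": t_sum.q1, "q3": t_sum.q3},
            "all_genes": {"n": a_sum.n, "median": a_sum.median},
            "random_background": {"n": b_sum.n, "median": b_sum.median},
        }
        if config.gmt_path:
            gene_sets = io_formats.read_gmt(config.gmt_path)
            results = ee.hypergeometric_enrichment(target_ids, gene_sets, expr.keys())
            summary["enrichment"] = [
                {"set": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p}
                for r in results
            ]

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
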