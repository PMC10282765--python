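"""End-to-end orchestration of the analysis stages.

Runs, in order: DEG integration (filter + progressive elimination) ->
co-expression network (soft threshold + TOM) on the shared genes ->
module detection, merging and trait statistics -> hub scoring on the
interaction network restricted to the top module's genes -> G-quadruplex
scanning and summary -> gene-set cross-referencing of the shared genes
with the G4-containing genes.  A machine-readable JSON report and a
plain-text summary are written to the output directory, stamped with the
seed and a hash of the configuration.  ``--demo`` mode generates every
input from :mod:`n4.synthio` first, so the full pipeline runs with no
external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from n4 import coexpression, deg_integration, g4scan, genesets, hubnet, modules, synthio

log = logging.getLogger("n4.pipeline")


@dataclass
class PipelineConfig:
    # input paths (ignored under demo mode, which generates them)
    deg_dir: str | None = None
    expression: str | None = None
    traits: str | None = None
    edges: str | None = None
    fasta: str | None = None
    genes_bed: str | None = None
    outdir: str = "n4_out"
    seed: int = 0
    # stage parameters
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_datasets: int = 8
    candidate_betas: list[int] = field(default_factory=lambda: list(range(1, 11)))
    r2_target: float = 0.9
    network_type: str = "unsigned"
    min_module_size: int = 20
    merge_threshold: float = 0.25
    mtr_r2_cut: float = 0.5
    mtr_p_cut: float = 0.05
    hub_top_k: int = 10
    score_threshold: float = 0.4
    g4_subtype: str = "both"
    g4_min_loop: int = 1
    g4_max_loop: int = 7
    promoter_len: int = 1000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    _PATH_FIELDS = ("deg_dir", "expression", "traits", "edges", "fasta", "genes_bed", "outdir")

    def hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        params = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


REPORT_SCHEMA: dict[str, type] = {
    "config_hash": str,
    "seed": int,
    "elimination": dict,
    "soft_threshold": dict,
    "module_sizes": dict,
    "significant_modules": list,
    "hubs": dict,
    "g4": dict,
    "genesets": dict,
}


def validate_report(report: dict) -> None:
    """Structural check of the pipeline report (keys and types)."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )


def _demo_inputs(config: PipelineConfig, outdir: Path) -> synthio.SynthConfig:
    scfg = synthio.SynthConfig(seed=config.seed)
    synthio.write_all(scfg, outdir / "inputs")
    config.deg_dir = str(outdir / "inputs" / "deg")
    config.expression = str(outdir / "inputs" / "expression.tsv")
    config.traits = str(outdir / "inputs" / "traits.tsv")
    config.fasta = str(outdir / "inputs" / "sequences.fa")
    config.genes_bed = str(outdir / "inputs" / "genes.bed")
    return scfg


def run(config: PipelineConfig, demo: bool = False) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = _demo_inputs(config, outdir) if demo else None
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=str)

    report: dict = {"config_hash": config.hash(), "seed": int(config.seed)}
    t0 = time.time()

    # --- stage 1: DEG integration -------------------------------------
    stage = "deg_integration"
    try:
        deg_dir = Path(config.deg_dir)
        tables = [deg_integration.read_deg_table(p) for p in sorted(deg_dir.glob("*.tsv"))]
        if len(tables) < 2:
            raise ValueError(f"need >= 2 DEG tables in {deg_dir}")
        min_ds = min(config.min_datasets, len(tables))
        trace, _ = deg_integration.integrate(
            tables, min_ds, config.fc_threshold, config.p_threshold
        )
        deg_integration.write_trace(trace, outdir / "elimination_trace.tsv")
        deg_integration.write_gene_list(trace.final_genes, outdir / "shared_genes.txt")
        shared = trace.final_genes
        report["elimination"] = {
            "n_datasets_in": len(tables),
            "n_datasets_final": len(trace.final_datasets),
            "steps": [list(s) for s in trace.steps],
            "n_shared_genes": len(shared),
        }
        log.info("%s: %d shared genes from %d datasets (%.1fs)",
                 stage, len(shared), len(trace.final_datasets), time.time() - t0)

        # --- stage 2: co-expression network ---------------------------
        stage = "coexpression"
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        keep = [g for g in expr.index if g in shared]
        expr_net = expr.loc[keep] if len(keep) >= 3 * config.min_module_size else expr
        net, screen = coexpression.build_network(
            expr_net,
            network_type=config.network_type,
            r2_target=config.r2_target,
            candidate_betas=config.candidate_betas,
        )
        if screen is not None:
            screen.to_csv(outdir / "soft_threshold_screen.tsv", sep="\t", index=False)
        sel = screen[screen["selected"] != ""].iloc[0] if screen is not None else None
        report["soft_threshold"] = {
            "beta": int(net.beta),
            "r2": float(sel["r2"]) if sel is not None else None,
            "slope": float(sel["slope"]) if sel is not None else None,
        }

        # --- stage 3: modules -----------------------------------------
        stage = "modules"
        traits = pd.read_csv(config.traits, sep="\t", index_col=0)
        assignment = modules.detect_modules(
            net.dissimilarity(), net.gene_ids, min_module_size=config.min_module_size
        )
        assignment, _ = modules.merge_modules(expr_net, assignment, config.merge_threshold)
        assignment = modules.relabel_by_size(assignment)
        eg = modules.module_eigengenes(expr_net, assignment)
        mtr = modules.module_trait_relationships(eg, traits)
        gene_stats = modules.gene_module_stats(expr_net, assignment, eg, traits)
        sig = modules.significant_modules(
            mtr, gene_stats, r2_cut=config.mtr_r2_cut, p_cut=config.mtr_p_cut
        )
        pd.Series(assignment.labels, name="module").rename_axis("gene_id").to_csv(
            outdir / "module_assignment.tsv", sep="\t"
        )
        mtr.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        sizes = assignment.module_sizes()
        report["module_sizes"] = {m: sizes[m] for m in assignment.non_grey()}
        report["n_unassigned"] = sizes.get(modules.GREY, 0)
        report["significant_modules"] = sig["module"].tolist()
        top_module = (
            sig["module"].iloc[0] if len(sig) else (assignment.non_grey() or [None])[0]
        )
        report["top_module"] = top_module
        log.info("modules: %d (top: %s)", len(assignment.non_grey()), top_module)

        # --- stage 4: hub genes ---------------------------------------
        stage = "hubnet"
        top_genes = assignment.members(top_module) if top_module else []
        if demo:
            edges_df, _ = synthio.make_network(scfg, node_ids=sorted(top_genes))
            edges_df.to_csv(outdir / "inputs" / "network.tsv", sep="\t", index=False)
            config.edges = str(outdir / "inputs" / "network.tsv")
        g = hubnet.load_network(config.edges, score_threshold=config.score_threshold)
        if top_genes and not demo:
            g = g.subgraph([v for v in g.nodes if v in set(top_genes)]).copy()
        hubs = hubnet.mcc_scores(g, top_k=config.hub_top_k)
        clusters = hubnet.dense_clusters(g)
        hubnet.write_hub_table(hubs, outdir / "hub_genes.tsv")
        hubnet.write_clusters(clusters, outdir / "dense_clusters.tsv")
        report["hubs"] = {
            "top": hubs.top_k,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "n_dense_clusters": len(clusters),
        }

        # --- stage 5: G-quadruplex scan -------------------------------
        stage = "g4scan"
        sequences = g4scan.read_fasta(config.fasta)
        models = g4scan.read_bed12(config.genes_bed)
        hits, dropped = g4scan.scan_genome(
            sequences, models,
            subtype=config.g4_subtype,
            min_loop=config.g4_min_loop,
            max_loop=config.g4_max_loop,
            promoter_len=config.promoter_len,
        )
        summary = g4scan.summarize(hits, module_assignment=assignment.labels)
        g4scan.write_hits_bed(hits, outdir / "g4_hits.bed")
        summary.frame().to_csv(outdir / "g4_summary.tsv", sep="\t", index=False)
        report["g4"] = {
            "n_hits": len(hits),
            "n_genes": summary.genes_with_hits,
            "genes_per_region": summary.genes_per_region,
            "strand_bias_pct": summary.strand_bias_pct,
            "subtype_counts": summary.subtype_counts,
            "dropped_hits": dropped,
        }

        # --- stage 6: gene-set cross-referencing ----------------------
        stage = "genesets"
        g4_genes = genesets.GeneSet("g4", {h.gene_id for h in hits})
        shared_set = genesets.GeneSet("shared", shared)
        regions = genesets.venn([shared_set, g4_genes])
        genesets.write_venn(regions, outdir / "venn_shared_g4.tsv")
        enr = genesets.enrichment(
            shared_set, g4_genes, universe=shared | g4_genes.members | set(expr.index)
        )
        report["genesets"] = {
            "venn": {sig_: len(g_) for sig_, g_ in regions.items()},
            "enrichment": {
                "table": [enr.a, enr.b, enr.c, enr.d],
                "odds_ratio": enr.odds_ratio,
                "p": enr.p_two_sided,
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["elapsed_s"] = round(time.time() - t0, 2)
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(_human_summary(report))
    return report


def _human_summary(report: dict) -> str:
    lines = [
        f"n4 pipeline report (seed {report['seed']}, config {report['config_hash']})",
        f"shared genes after elimination: {report['elimination']['n_shared_genes']} "
        f"from {report['elimination']['n_datasets_final']} datasets",
        f"soft threshold beta = {report['soft_threshold']['beta']} "
        f"(scale-free R^2 = {report['soft_threshold']['r2']})",
        "module sizes: "
        + ", ".join(f"{m}={n}" for m, n in report["module_sizes"].items()),
        f"significant modules: {', '.join(report['significant_modules']) or 'none'}",
        f"top hub genes: {', '.join(report['hubs']['top'])}",
        f"G4: {report['g4']['n_hits']} hits in {report['g4']['n_genes']} genes; "
        f"per region {report['g4']['genes_per_region']}",
        f"shared-genes x G4 venn: {report['genesets']['venn']}",
        f"elapsed: {report['elapsed_s']} s",
    ]
    return "\n".join(lines) + "\n"
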