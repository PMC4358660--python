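"""End-to-end mechanism-of-action workflow.

ingest -> expression-filtered weighted network -> restart-walk diffusion from
spectral-count seeds -> permutation node significance -> gene-set scores with
BH selection -> leave-one-target-out impact matrix -> TSV reports plus a
provenance manifest.  Deterministic given the config: one root seed fans out
to per-stage child seeds at fixed offsets so stages can be re-run
individually against cached intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, diffusion, go_scoring, io, network

logger = logging.getLogger(__name__)

# per-stage child-seed offsets from the root seed
SEED_OFFSET_NODE_NULL = 1
SEED_OFFSET_GO = 2


class PipelineError(RuntimeError):
    """Stage-attributed pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters for a full run; defaults follow the published analysis."""

    network_path: str
    expression_path: str
    targets_path: str
    genesets_path: str
    outdir: str = "moa_run"
    fpkm_min: float = 0.1
    alpha: float = 0.3
    n_random_nodes: int = 100
    n_random_go: int = 1000
    percentile: float = 95.0
    fdr: float = 0.05
    top_fraction: float = 0.05
    p_cut: float = 0.005
    rng_seed: int = 0
    weight_function: str = "min_abs_log2"
    impact_all_terms: bool = False

    def __post_init__(self) -> None:
        checks = [
            0 < self.alpha <= 1,
            0 <= self.percentile <= 100,
            0 < self.fdr < 1,
            0 < self.top_fraction < 1,
            0 < self.p_cut <= 1,
            self.n_random_nodes >= 1,
            self.n_random_go >= 1,
        ]
        if not all(checks):
            raise ValueError("RunConfig parameter out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls(**yaml.safe_load(handle))


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_moa(config: RunConfig) -> Path:
    """Run the whole workflow; returns the run directory.

    Any stage error aborts with the stage name and the underlying cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        graph = io.read_edge_list(config.network_path)
        profile = io.read_expression(config.expression_path)
        counts = io.read_spectral_counts(config.targets_path)
        collection = io.read_gmt(config.genesets_path)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "build_network"
    try:
        filtered = network.filter_expressed(graph, profile, config.fpkm_min)
        fc = network.fold_changes(profile)
        wnet = network.weight_edges(filtered, fc, config.weight_function)
        io.write_weighted_edge_list(wnet, outdir / "weighted_network.tsv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "diffuse"
    try:
        if "strength" in counts.columns:
            seeds = counts[["strength"]].copy()
            seeds["p0"] = seeds["strength"] / seeds["strength"].sum()
        else:
            seeds = diffusion.seeds_from_counts(counts)
        result = diffusion.rwr(wnet, seeds, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "node_significance"
    try:
        null = diffusion.node_null(
            wnet,
            seeds,
            n_random=config.n_random_nodes,
            rng_seed=config.rng_seed + SEED_OFFSET_NODE_NULL,
            alpha=config.alpha,
        )
        significance = diffusion.node_significance(
            result, null, top_fraction=config.top_fraction, p_cut=config.p_cut
        )
        significance.to_csv(outdir / "node_significance.tsv", sep="\t", index_label="gene_id")
        sub = diffusion.extract_perturbed_subnetwork(wnet, significance, seeds, config.p_cut)
        with open(outdir / "perturbed_subnetwork.tsv", "w") as handle:
            handle.write("gene_a\tgene_b\tweight\tinteraction\n")
            for (a, b), data in sorted(
                ((tuple(sorted((u, v))), d) for u, v, d in sub.edges(data=True))
            ):
                handle.write(
                    f"{a}\t{b}\t{data.get('weight', 1.0):.10g}\t{data['interaction']}\n"
                )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "go_scores"
    try:
        go_table = go_scoring.go_pvalues(
            result,
            collection,
            n_random=config.n_random_go,
            percentile=config.percentile,
            rng_seed=config.rng_seed + SEED_OFFSET_GO,
            fdr=config.fdr,
        )
        go_table.to_csv(outdir / "go_scores.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "target_impact"
    try:
        selected = list(go_table.index[go_table["selected"]])
        terms = list(collection) if (config.impact_all_terms or not selected) else selected
        impact = go_scoring.target_impact(
            wnet, seeds, collection, terms,
            alpha=config.alpha, percentile=config.percentile,
        )
        impact.to_csv(outdir / "impact_matrix.tsv", sep="\t", index_label="target")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "manifest"
    try:
        manifest = {
            "version": __version__,
            "parameters": dataclasses.asdict(config),
            "inputs": {
                name: _digest(getattr(config, f"{name}_path"))
                for name in ("network", "expression", "targets", "genesets")
            },
            "network": {
                "nodes": wnet.number_of_nodes(),
                "edges": wnet.number_of_edges(),
            },
            "diffusion": {
                "iterations": result.iterations,
                "residual": result.residual,
            },
            "selected_terms": selected,
            "outputs": {
                p.name: _digest(p)
                for p in sorted(outdir.glob("*.tsv"))
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    logger.info("run complete: %s", outdir)
    return outdir
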