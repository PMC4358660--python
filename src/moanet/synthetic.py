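"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic given its integer seed and returns ground
truth alongside the data so recovery can be tested: a scale-free interaction
network, log-normal FPKM expression with a co-regulated module planted
around designated anchor genes, spectral-count target tables, gene-set
collections containing the planted module as one term, Hill-curve
dose–response matrices with an optional additive interaction on top of the
Bliss expectation, duplicate screening plates with controls and planted
hits, and binary fingerprints with planted structural clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .assay import DoseResponseMatrix
from .screen import NEG, POS


@dataclass
class SyntheticTruth:
    """Ground-truth labels attached to generated data."""

    planted_module: set = field(default_factory=set)
    planted_term_id: str | None = None
    module_anchors: list = field(default_factory=list)
    true_hits: set = field(default_factory=set)
    true_clusters: dict = field(default_factory=dict)  # compound_id -> cluster idx
    synergy_flag: bool | None = None


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def gen_ppi_network(n_nodes: int, mean_degree: float, rng_seed: int) -> nx.Graph:
    """Scale-free interaction network by preferential attachment.

    ``mean_degree`` sets the attachment parameter m ~ mean_degree / 2; the
    largest connected component is kept (preferential attachment already
    yields a connected simple graph).  Node ids are gene identifiers.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes for a network with an edge")
    if not 0 < mean_degree <= n_nodes - 1:
        raise ValueError(
            f"mean degree {mean_degree} infeasible for {n_nodes} nodes"
        )
    m = max(1, int(round(mean_degree / 2)))
    graph = nx.barabasi_albert_graph(n_nodes, m, seed=rng_seed)
    largest = max(nx.connected_components(graph), key=len)
    graph = graph.subgraph(largest).copy()
    return nx.relabel_nodes(graph, {i: _gene_id(i) for i in graph.nodes})


def gen_expression(
    network: nx.Graph,
    module_size: int,
    logfc_effect: float,
    noise_sd: float,
    rng_seed: int,
    n_anchors: int = 1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Log-normal FPKM profile with a co-regulated module planted near anchors.

    All genes get control FPKM above the 0.1 expression floor.  A
    breadth-first neighborhood of ``module_size`` genes grown from
    ``n_anchors`` randomly chosen anchor genes (the future drug-target
    seeds) receives |log2 fold change| centered at ``logfc_effect`` with a
    random sign per gene; every other gene's log2 fold change is
    Normal(0, noise_sd).  The exact fold change is recorded in a
    ``fold_change`` column (treated FPKM is derived from it and floored at 0,
    so downstream code should prefer the column, as the readers do).
    """
    nodes = sorted(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    if module_size > len(nodes):
        raise ValueError("module larger than the network")
    rng = np.random.default_rng(rng_seed)
    truth = SyntheticTruth()
    if module_size > 0:
        anchors = list(rng.choice(nodes, size=min(n_anchors, module_size), replace=False))
        truth.module_anchors = anchors
        truth.planted_module = _bfs_neighborhood(network, anchors, module_size)
    fpkm_control = 0.1 + rng.lognormal(mean=1.0, sigma=1.2, size=len(nodes))
    lfc = rng.normal(0.0, noise_sd, size=len(nodes)) if noise_sd > 0 else np.zeros(len(nodes))
    in_module = np.array([n in truth.planted_module for n in nodes])
    if in_module.any():
        magnitude = logfc_effect + (
            rng.normal(0.0, noise_sd, size=int(in_module.sum())) if noise_sd > 0 else 0.0
        )
        sign = rng.choice([-1.0, 1.0], size=int(in_module.sum()))
        lfc[in_module] = sign * magnitude
    fold_change = np.exp2(lfc)
    fpkm_treated = np.maximum((fpkm_control + 0.1) * fold_change - 0.1, 0.0)
    profile = pd.DataFrame(
        {
            "fpkm_control": fpkm_control,
            "fpkm_treated": fpkm_treated,
            "fold_change": fold_change,
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    return profile, truth


def _bfs_neighborhood(network: nx.Graph, anchors: list, size: int) -> set:
    """First ``size`` genes reached by multi-source BFS from the anchors."""
    module: list = []
    seen = set()
    frontier = list(anchors)
    while frontier and len(module) < size:
        nxt = []
        for node in frontier:
            if node in seen:
                continue
            seen.add(node)
            module.append(node)
            if len(module) >= size:
                break
            nxt.extend(sorted(network.neighbors(node)))
        frontier = nxt
    return set(module[:size])


def gen_targets(
    network: nx.Graph,
    n_targets: int,
    ratio_range: tuple[float, float],
    rng_seed: int,
    candidate_genes: list | None = None,
) -> pd.DataFrame:
    """Spectral-count table for drug targets.

    Each target gets integer counts (immobilized-compound pulldown,
    free-drug competition) whose ratio lies in ``ratio_range``; the
    immobilized-vs-competition ratio proxies binding strength.
    ``candidate_genes`` restricts where targets are drawn (used by fixtures
    to place a target inside the planted module); default is all nodes.
    """
    low, high = ratio_range
    if low < 1 or high < low:
        raise ValueError(f"invalid ratio range {ratio_range}")
    pool = sorted(candidate_genes) if candidate_genes is not None else sorted(network.nodes)
    if n_targets > len(pool):
        raise ValueError(f"cannot draw {n_targets} targets from {len(pool)} genes")
    rng = np.random.default_rng(rng_seed)
    genes = list(rng.choice(pool, size=n_targets, replace=False))
    rows = []
    for gene in genes:
        ratio = rng.uniform(low, high)
        competition = int(rng.integers(5, 21))
        for _ in range(1000):
            lo_i = int(np.ceil(low * competition - 1e-9))
            hi_i = int(np.floor(high * competition + 1e-9))
            if lo_i <= hi_i:
                break
            competition += 1
        else:  # pragma: no cover - unreachable for sane ranges
            raise ValueError(f"no integer counts realize a ratio in {ratio_range}")
        immobilized = int(np.clip(round(ratio * competition), lo_i, hi_i))
        rows.append((gene, immobilized, competition))
    return pd.DataFrame(
        rows, columns=["gene_id", "sc_immobilized", "sc_competition"]
    ).set_index("gene_id")


PLANTED_TERM_ID = "PLANTED_MODULE"


def gen_genesets(
    network: nx.Graph,
    n_terms: int,
    size_range: tuple[int, int],
    truth: SyntheticTruth,
    rng_seed: int,
) -> dict[str, set]:
    """Random gene sets plus one term equal to the planted module.

    Returns term_id -> member set; the planted term id is recorded on the
    truth object.
    """
    nodes = sorted(network.nodes)
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size range {size_range}")
    hi = min(hi, len(nodes))
    lo = min(lo, hi)
    rng = np.random.default_rng(rng_seed)
    collection: dict[str, set] = {}
    for k in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        collection[f"T{k:04d}"] = set(rng.choice(nodes, size=size, replace=False))
    if truth.planted_module:
        if truth.planted_term_id is None:
            truth.planted_term_id = PLANTED_TERM_ID
        collection[truth.planted_term_id] = set(truth.planted_module)
    return collection


_DEFAULT_HILL = {
    "ec50_x": 1.0, "hill_x": 1.5, "emax_x": 0.5,
    "ec50_y": 1.0, "hill_y": 1.5, "emax_y": 0.5,
}


def _hill_effect(dose: np.ndarray, ec50: float, hill: float, emax: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        ratio = (dose / ec50) ** hill
    return emax * ratio / (1.0 + ratio)


def gen_dose_response(
    n_doses_x: int = 6,
    n_doses_y: int = 6,
    hill_params: dict | None = None,
    bliss_interaction: float = 0.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[DoseResponseMatrix, SyntheticTruth]:
    """Dose–response matrix with Hill single agents and a Bliss-based interior.

    Doses are 2-fold dilution series centered on each drug's EC50 (plus the
    dose-0 single-agent row/column).  Interior effects are the Bliss
    expectation plus ``bliss_interaction`` plus Gaussian noise, clamped to
    [0, 1]; the default Hill maxima are low enough that an interaction up to
    0.2 never saturates, keeping the planted deviation exact when noise is
    zero.
    """
    if n_doses_x < 1 or n_doses_y < 1:
        raise ValueError("need at least one nonzero dose per drug")
    hp = dict(_DEFAULT_HILL, **(hill_params or {}))
    rng = np.random.default_rng(rng_seed)
    doses_x = hp["ec50_x"] * 2.0 ** (np.arange(n_doses_x) - n_doses_x // 2)
    doses_y = hp["ec50_y"] * 2.0 ** (np.arange(n_doses_y) - n_doses_y // 2)
    ex = _hill_effect(doses_x, hp["ec50_x"], hp["hill_x"], hp["emax_x"])
    ey = _hill_effect(doses_y, hp["ec50_y"], hp["hill_y"], hp["emax_y"])
    effect = np.zeros((n_doses_x + 1, n_doses_y + 1))
    effect[1:, 0] = ex
    effect[0, 1:] = ey
    bliss = ex[:, None] + ey[None, :] - ex[:, None] * ey[None, :]
    effect[1:, 1:] = bliss + bliss_interaction
    if noise_sd > 0:
        # noise on combination wells only: the single-agent rows are the
        # reference curves the Bliss expectation is computed from, so the
        # interior deviation is exactly interaction + Normal(0, noise_sd)
        effect[1:, 1:] += rng.normal(0.0, noise_sd, size=(n_doses_x, n_doses_y))
    effect[0, 0] = 0.0
    viability = pd.DataFrame(
        1.0 - np.clip(effect, 0.0, 1.0),
        index=pd.Index(np.concatenate([[0.0], doses_x]), name="dose_x"),
        columns=pd.Index(np.concatenate([[0.0], doses_y]), name="dose_y"),
    )
    truth = SyntheticTruth(synergy_flag=bool(bliss_interaction != 0.0))
    return DoseResponseMatrix(viability), truth


def gen_screen(
    n_plates: int = 2,
    wells_per_plate: int = 384,
    n_pos_ctrl: int = 8,
    n_neg_ctrl: int = 16,
    hit_fraction: float = 0.02,
    hit_effect: float = 6.0,
    rng_seed: int = 0,
    n_replicates: int = 2,
    mu: float = 1000.0,
    cv: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Viability screen: replicate plates with controls and planted hits.

    Each plate layout is screened ``n_replicates`` times (duplicate by
    default).  Negative controls and inactive compounds share
    Normal(mu, cv*mu) signals, positive controls sit near zero, and a
    ``hit_fraction`` of compounds is shifted down by ``hit_effect`` negative-
    control standard deviations.  Returns a long well table
    (plate_id, well_id, compound_id, replicate, signal) plus truth.
    """
    sigma = cv * mu
    n_samples = wells_per_plate - n_pos_ctrl - n_neg_ctrl
    if n_samples < 1:
        raise ValueError("no sample wells left after controls")
    rng = np.random.default_rng(rng_seed)
    n_compounds = n_plates * n_samples
    compounds = [f"C{i:05d}" for i in range(n_compounds)]
    n_hits = int(round(hit_fraction * n_compounds))
    hits = set(rng.choice(compounds, size=n_hits, replace=False)) if n_hits else set()
    records = []
    for plate in range(n_plates):
        plate_compounds = compounds[plate * n_samples : (plate + 1) * n_samples]
        for rep in range(1, n_replicates + 1):
            plate_id = f"P{plate:03d}_r{rep}"
            well = 0
            for _ in range(n_neg_ctrl):
                records.append(
                    (plate_id, f"W{well:03d}", NEG, rep, max(rng.normal(mu, sigma), 0.0))
                )
                well += 1
            for _ in range(n_pos_ctrl):
                records.append(
                    (plate_id, f"W{well:03d}", POS, rep, abs(rng.normal(0.02 * mu, 0.2 * sigma)))
                )
                well += 1
            for comp in plate_compounds:
                center = mu - hit_effect * sigma if comp in hits else mu
                records.append(
                    (plate_id, f"W{well:03d}", comp, rep, max(rng.normal(center, sigma), 0.0))
                )
                well += 1
    plates = pd.DataFrame(
        records, columns=["plate_id", "well_id", "compound_id", "replicate", "signal"]
    )
    return plates, SyntheticTruth(true_hits=hits)


def gen_fingerprints(
    n_compounds: int,
    n_bits: int = 128,
    n_clusters: int = 8,
    flip_prob: float = 0.05,
    rng_seed: int = 0,
    prototype_density: float = 0.3,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Binary fingerprints with planted structural clusters.

    Each cluster has a random prototype bit vector; members are the
    prototype with independent bit flips at ``flip_prob``.  Every compound
    keeps at least one set bit so Jaccard similarity stays defined.
    """
    if n_compounds < 1 or n_bits < 1 or not 1 <= n_clusters <= n_compounds:
        raise ValueError("invalid fingerprint generator parameters")
    rng = np.random.default_rng(rng_seed)
    assignment = np.sort(np.arange(n_compounds) % n_clusters)
    prototypes = rng.random((n_clusters, n_bits)) < prototype_density
    for proto in prototypes:  # guarantee a non-empty prototype
        if not proto.any():
            proto[rng.integers(n_bits)] = True
    fps = np.empty((n_compounds, n_bits), dtype=int)
    ids = [f"C{i:05d}" for i in range(n_compounds)]
    for i, cluster in enumerate(assignment):
        flips = rng.random(n_bits) < flip_prob
        fp = prototypes[cluster] ^ flips
        if not fp.any():
            fp[rng.integers(n_bits)] = True
        fps[i] = fp
    frame = pd.DataFrame(
        fps, index=pd.Index(ids, name="compound_id"),
        columns=[f"bit{j}" for j in range(n_bits)],
    )
    truth = SyntheticTruth(true_clusters=dict(zip(ids, (int(c) for c in assignment))))
    return frame, truth


# ---------------------------------------------------------------------------
# Complete propagation fixture

FIXTURE_DEFAULTS = dict(
    n_nodes=500,
    mean_degree=10.0,
    module_size=50,
    logfc_effect=2.0,
    noise_sd=0.3,
    n_targets=11,
    ratio_range=(2.0, 20.0),
    n_terms=200,
    size_range=(10, 200),
    n_anchors=3,
)


def make_fixture(rng_seed: int = 0, **overrides) -> dict:
    """Full synthetic input set for the propagation pipeline.

    Builds network, expression, targets, and gene sets with consistent
    truth.  The planted module is grown from ``n_anchors`` anchor genes that
    become drug targets with high binding ratios, so the module is genuinely
    seed-proximal; the remaining targets are drawn from outside the module.
    Defaults follow :data:`FIXTURE_DEFAULTS`.
    """
    params = dict(FIXTURE_DEFAULTS, **overrides)
    network = gen_ppi_network(params["n_nodes"], params["mean_degree"], rng_seed)
    profile, truth = gen_expression(
        network,
        params["module_size"],
        params["logfc_effect"],
        params["noise_sd"],
        rng_seed + 1,
        n_anchors=params["n_anchors"],
    )
    low, high = params["ratio_range"]
    anchor_targets = gen_targets(
        network, len(truth.module_anchors), (max(low, high * 0.75), high),
        rng_seed + 2, candidate_genes=truth.module_anchors,
    )
    outside = sorted(set(network.nodes) - truth.planted_module)
    other_targets = gen_targets(
        network, params["n_targets"] - len(anchor_targets), (low, high),
        rng_seed + 3, candidate_genes=outside,
    )
    targets = pd.concat([anchor_targets, other_targets])
    genesets = gen_genesets(
        network, params["n_terms"], params["size_range"], truth, rng_seed + 4
    )
    return {
        "network": network,
        "expression": profile,
        "targets": targets,
        "genesets": genesets,
        "truth": truth,
        "params": params,
    }
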