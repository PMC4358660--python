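"""Gene-set scoring on the thresholded diffusion landscape.

A gene set's score is the sum of asymptotic walk probabilities over its
member genes, after probabilities below the 95th percentile are zeroed to
limit noise.  Significance comes from rescoring random node sets of the same
size; Benjamini–Hochberg selection is applied at FDR 5%.  The leave-one-
target-out impact matrix quantifies how much each drug target contributes to
each selected term's score.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diffusion import DEFAULT_ALPHA, DiffusionResult, rwr
from .network import transition_operator

DEFAULT_PERCENTILE = 95.0
DEFAULT_N_RANDOM = 1000
DEFAULT_FDR = 0.05


def threshold_probabilities(
    result: DiffusionResult | pd.Series, percentile: float = DEFAULT_PERCENTILE
) -> pd.Series:
    """Zero node probabilities strictly below the given percentile (ties kept)."""
    probs = result.probabilities if isinstance(result, DiffusionResult) else result
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    cut = np.percentile(probs.to_numpy(), percentile)
    return probs.where(probs >= cut, 0.0)


def go_score(thresholded: pd.Series, members: Iterable) -> float:
    """Sum of thresholded probabilities over member genes present in the network."""
    members = set(members)
    present = thresholded.index.intersection(members)
    return float(thresholded.loc[present].sum())


def _null_scores(
    thresholded: np.ndarray, size: int, n_random: int, rng: np.random.Generator
) -> np.ndarray:
    """Scores of ``n_random`` uniform node sets of ``size`` nodes."""
    n = thresholded.size
    keys = rng.random((n_random, n))
    draws = np.argpartition(keys, size - 1, axis=1)[:, :size] if size < n else (
        np.broadcast_to(np.arange(n), (n_random, n))
    )
    return thresholded[draws].sum(axis=1)


def go_pvalues(
    result: DiffusionResult | pd.Series,
    collection: Mapping[str, set],
    n_random: int = DEFAULT_N_RANDOM,
    percentile: float = DEFAULT_PERCENTILE,
    rng_seed: int = 0,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Permutation p-values, BH q-values and FDR selection for each gene set.

    For every term, ``n_random`` node sets of the same size are drawn
    uniformly without replacement from the network and scored on the same
    thresholded probability vector; p = #{null >= observed} / n_random, the
    plain permutation estimator.  A term whose observed score beats every
    resample gets p = 0: with a term collection much larger than the number
    of affordable resamples, the conservative (1 + k)/(1 + n) estimator
    would floor every q-value above any usable FDR cutoff and no term could
    ever be selected, so the unbiased estimator is used here (the node-level
    empirical p-values keep the +1 correction).
    """
    thresholded = threshold_probabilities(result, percentile)
    values = thresholded.to_numpy()
    node_index = {g: i for i, g in enumerate(thresholded.index)}
    n_nodes = len(node_index)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for term_id, members in collection.items():
        in_net = [node_index[g] for g in members if g in node_index]
        size = len(in_net)
        if len(members) > n_nodes:
            raise ValueError(
                f"term {term_id!r} has {len(members)} members but the network "
                f"has only {n_nodes} nodes"
            )
        observed = float(values[in_net].sum()) if in_net else 0.0
        if size == 0:
            p = 1.0
        else:
            null = _null_scores(values, size, n_random, rng)
            p = np.count_nonzero(null >= observed) / n_random
        rows.append((term_id, size, observed, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "n_members", "score", "p_value"]
    ).set_index("term_id")
    q, selected = bh_adjust(table["p_value"], fdr=fdr)
    table["q_value"] = q
    table["selected"] = selected
    return table


def bh_adjust(
    p_values: pd.Series | np.ndarray, fdr: float = DEFAULT_FDR
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and selection at the given FDR."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= fdr


def target_impact(
    wnet: nx.Graph,
    seeds: pd.DataFrame,
    collection: Mapping[str, set],
    terms: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    percentile: float = DEFAULT_PERCENTILE,
    epsilon: float = 1e-12,
) -> pd.DataFrame:
    """Leave-one-target-out log10 score ratios (targets x terms).

    Each target is removed in turn, the remaining restart probabilities are
    renormalized to sum to 1, the walk and thresholded term scores are
    recomputed, and the entry is ``log10((score_without + eps) /
    (score_full + eps))``.  Negative entries mark terms whose association
    with the drug depends on that target — potentially essential targets.
    Entries where both scores fall below ``epsilon`` are set to 0.
    """
    if len(seeds) < 2:
        raise ValueError("leave-one-out needs at least 2 targets")
    term_ids = list(terms) if terms is not None else list(collection)
    operator = transition_operator(wnet)
    full = threshold_probabilities(rwr(wnet, seeds, alpha=alpha, operator=operator), percentile)
    full_scores = np.array([go_score(full, collection[t]) for t in term_ids])
    matrix = np.zeros((len(seeds), len(term_ids)))
    for i, target in enumerate(seeds.index):
        remaining = seeds.drop(index=target).copy()
        if remaining["strength"].sum() <= 0:
            raise ValueError(f"removing {target!r} leaves no seed strength")
        remaining["p0"] = remaining["strength"] / remaining["strength"].sum()
        loo = threshold_probabilities(
            rwr(wnet, remaining, alpha=alpha, operator=operator), percentile
        )
        loo_scores = np.array([go_score(loo, collection[t]) for t in term_ids])
        ratios = np.log10((loo_scores + epsilon) / (full_scores + epsilon))
        ratios[(loo_scores < epsilon) & (full_scores < epsilon)] = 0.0
        matrix[i] = ratios
    return pd.DataFrame(matrix, index=list(seeds.index), columns=term_ids)
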