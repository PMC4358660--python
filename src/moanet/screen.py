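"""Viability-screen triage: plate normalization, z-score hit calling, and
Jaccard/Tanimoto clustering of hit fingerprints.

Raw per-well signals are normalized to the median of each plate's
negative-control (vehicle) wells; compound replicates are averaged and
z-scored against the pooled normalized negative controls.  Hits fall below
a z threshold (default -2.12).  Structural families among the hits are found
by average-linkage hierarchical clustering of Jaccard distances between
binary fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

Z_THRESHOLD = -2.12

NEG = "NEG"
POS = "POS"
_PLATE_COLUMNS = ["plate_id", "well_id", "compound_id", "replicate", "signal"]


def _check_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in _PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    if (plate["signal"] < 0).any():
        raise ValueError("negative raw signals")


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Divide every well by the median of the plate's negative-control wells."""
    _check_plate(plate)
    out = plate.copy()
    for plate_id, group in plate.groupby("plate_id"):
        neg = group.loc[group["compound_id"] == NEG, "signal"]
        if len(neg) < 2:
            raise ValueError(f"plate {plate_id!r} has fewer than 2 negative controls")
        med = float(neg.median())
        if med <= 0:
            raise ValueError(f"plate {plate_id!r} negative-control median is not positive")
        out.loc[group.index, "normalized"] = group["signal"] / med
    return out


def control_separation(plates: pd.DataFrame) -> float:
    """Z'-factor-style separation between positive and negative controls.

    1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| on pooled normalized
    controls; informational plate-QC only.
    """
    norm = plates if "normalized" in plates.columns else normalize_plate(plates)
    neg = norm.loc[norm["compound_id"] == NEG, "normalized"]
    pos = norm.loc[norm["compound_id"] == POS, "normalized"]
    if pos.empty:
        return float("nan")
    gap = abs(pos.mean() - neg.mean())
    if gap == 0:
        return float("-inf")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / gap)


def zscore_hits(plates: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Compound z-scores against pooled normalized negative controls.

    Replicates of a compound (duplicate plates) are averaged after
    normalization; z = (mean normalized signal - mu_neg) / sigma_neg and a
    compound is a hit when z < ``threshold``.
    """
    norm = plates if "normalized" in plates.columns else normalize_plate(plates)
    neg = norm.loc[norm["compound_id"] == NEG, "normalized"]
    mu, sigma = float(neg.mean()), float(neg.std(ddof=1))
    if sigma == 0:
        raise ValueError("negative controls have zero variance; z-scores undefined")
    samples = norm[~norm["compound_id"].isin([NEG, POS])]
    mean_signal = samples.groupby("compound_id")["normalized"].mean()
    z = (mean_signal - mu) / sigma
    return pd.DataFrame(
        {
            "mean_normalized": mean_signal,
            "z_score": z,
            "is_hit": z < threshold,
        }
    ).sort_index()


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for binary fingerprints; errors if both are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints have different lengths")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both fingerprints are all-zero; similarity undefined")
    return np.count_nonzero(a & b) / union


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - jaccard_similarity(a, b)


@dataclass
class ClusterResult:
    """Flat clusters from the cut dendrogram.

    ``families`` are clusters with two or more members (candidate scaffold
    families); ``singletons`` the rest.
    """

    labels: pd.Series
    families: list[list[str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    linkage: np.ndarray | None = None


def cluster_hits(
    fingerprints: pd.DataFrame, cut_distance: float, method: str = "average"
) -> ClusterResult:
    """Hierarchical clustering of fingerprints on Jaccard distance.

    ``fingerprints`` is a compounds x bits 0/1 table.  The dendrogram
    (average linkage by default) is cut at ``cut_distance``; compounds are
    processed in sorted-id order so the labelling is independent of input
    order.
    """
    if len(fingerprints) < 2:
        raise ValueError("clustering needs at least 2 compounds")
    fps = fingerprints.sort_index()
    matrix = fps.to_numpy(bool)
    if (~matrix.any(axis=1)).any():
        raise ValueError("all-zero fingerprint(s) present")
    distances = pdist(matrix, metric="jaccard")
    linkage = sch.linkage(distances, method=method)
    labels = sch.fcluster(linkage, t=cut_distance, criterion="distance")
    series = pd.Series(labels, index=fps.index, name="cluster")
    families, singletons = [], []
    for _, members in series.groupby(series):
        ids = list(members.index)
        if len(ids) >= 2:
            families.append(ids)
        else:
            singletons.extend(ids)
    return ClusterResult(
        labels=series, families=families, singletons=singletons, linkage=linkage
    )
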