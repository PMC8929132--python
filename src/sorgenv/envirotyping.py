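"""Stress-pattern discovery and environment classification.

Daily relative-transpiration (RT) and heat (GT) indices from the season
simulator are averaged into fixed-length thermal-time bins (100 °Cd from
emergence), pooled across site × year × sowing × management × cultivar
combinations, and clustered with k-means to discover water stress patterns
(WSP) and heat stress patterns (HSP).  Water and heat trajectories are
always clustered independently.  New seasons are classified by minimum sum
of squared differences to the stored centroids, and the WSP × HSP pair is
regrouped into four yield-relevant environment categories (ECG): no stress,
heat, water, and combined heat-and-water stress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "EcgLabel",
    "ClusterModel",
    "bin_trajectory",
    "build_trajectory_matrix",
    "fit_kmeans",
    "select_k",
    "cluster_frequencies",
    "classify_trajectory",
    "regroup_ecg",
]

DEFAULT_BIN_WIDTH = 100.0  # °Cd


class EcgLabel(str, Enum):
    """Four-way yield-relevant environment category."""

    NO_STRESS = "no_stress"
    HEAT = "heat"
    WATER = "water"
    HEAT_AND_WATER = "heat_and_water"


def bin_trajectory(
    daily_index: np.ndarray,
    daily_tt: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int | None = None,
) -> np.ndarray:
    """Average a daily stress index into thermal-time bins.

    Bin *b* (1-based) holds the unweighted mean of daily values whose
    cumulative thermal time falls in ``((b−1)·width, b·width]``.  The output
    is truncated, or right-padded with the final bin's value, to exactly
    ``n_bins`` so trajectories of different season lengths are comparable;
    a bin with no days (possible only through irregular thermal-time input)
    inherits the previous bin's value.
    """
    daily_index = np.asarray(daily_index, dtype=float)
    daily_tt = np.asarray(daily_tt, dtype=float)
    if daily_index.size == 0:
        raise ValueError("daily series is empty")
    if daily_index.shape != daily_tt.shape:
        raise ValueError("daily_index and daily_tt must align")
    cum_tt = np.cumsum(daily_tt)
    if cum_tt[-1] <= 0:
        raise ValueError("cumulative thermal time must be positive")
    if n_bins is None:
        n_bins = int(np.floor(cum_tt[-1] / bin_width))
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")

    bin_of_day = np.maximum(np.ceil(cum_tt / bin_width).astype(int), 1)
    n_avail = int(bin_of_day.max())
    means = np.full(n_avail, np.nan)
    for b in range(1, n_avail + 1):
        mask = bin_of_day == b
        if mask.any():
            means[b - 1] = daily_index[mask].mean()
        elif b > 1:
            means[b - 1] = means[b - 2]
    if np.isnan(means[0]):
        means[0] = daily_index[0]

    out = np.empty(n_bins)
    take = min(n_bins, n_avail)
    out[:take] = means[:take]
    if n_bins > n_avail:
        out[n_avail:] = means[-1]
    return out


def build_trajectory_matrix(
    seasons: Iterable[tuple[dict, pd.DataFrame]],
    index_col: str,
    n_bins: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Assemble binned trajectories into an environments × bins table.

    ``seasons`` yields ``(meta, daily)`` pairs where ``daily`` is the
    per-day table of a season result with ``tt`` and the requested index
    column (``"rt"`` or ``"gt"``).  Metadata keys become leading columns;
    bins become ``bin_01 .. bin_NN``, all values in [0, 1].
    """
    rows = []
    for meta, daily in seasons:
        vec = bin_trajectory(
            daily[index_col].to_numpy(), daily["tt"].to_numpy(), bin_width, n_bins
        )
        row = dict(meta)
        row.update({f"bin_{b + 1:02d}": vec[b] for b in range(n_bins)})
        rows.append(row)
    if not rows:
        raise ValueError("no seasons supplied")
    return pd.DataFrame(rows)


def trajectory_values(matrix: pd.DataFrame) -> np.ndarray:
    """Extract the numeric bin block of a trajectory table."""
    bin_cols = [c for c in matrix.columns if c.startswith("bin_")]
    if not bin_cols:
        raise ValueError("matrix has no bin_* columns")
    return matrix[bin_cols].to_numpy(dtype=float)


@dataclass
class ClusterModel:
    """Fitted k-means stress-pattern model.

    Cluster labels are 1..k and ordered by descending membership, so
    pattern 1 is always the most frequent one in the training set.
    ``variance_explained`` is 1 − within-cluster SS / total SS about the
    grand mean (0 when the total SS is itself 0).
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    variance_explained: float
    seed: int
    index_votes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": int(self.k),
            "centroids": self.centroids.tolist(),
            "labels": self.labels.tolist(),
            "inertia": float(self.inertia),
            "variance_explained": float(self.variance_explained),
            "seed": int(self.seed),
            "index_votes": self.index_votes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"], dtype=float),
            labels=np.asarray(payload["labels"], dtype=int),
            inertia=payload["inertia"],
            variance_explained=payload["variance_explained"],
            seed=payload["seed"],
            index_votes=payload.get("index_votes", {}),
        )


def fit_kmeans(
    X: np.ndarray | pd.DataFrame, k: int, seed: int, n_init: int = 25
) -> ClusterModel:
    """Euclidean k-means with best-of-``n_init`` k-means++ restarts.

    Deterministic for a fixed seed.  Trajectory bins share units ([0, 1]
    stress index), so no standardization is applied.
    """
    if isinstance(X, pd.DataFrame):
        X = trajectory_values(X)
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    if np.isnan(X).any():
        raise ValueError("trajectory matrix contains missing values")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)

    # Relabel clusters 1..k by descending membership for reporting stability.
    counts = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    centroids = km.cluster_centers_[order]

    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    degenerate = total_ss <= 1e-12 * X.size  # all rows identical up to rounding
    var_explained = 0.0 if degenerate else 1.0 - km.inertia_ / total_ss
    return ClusterModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=float(km.inertia_),
        variance_explained=float(var_explained),
        seed=seed,
    )


def select_k(
    X: np.ndarray | pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 25,
) -> tuple[int, dict]:
    """Choose the cluster count by majority vote of internal validity indices.

    Fits every k in ``k_range`` and scores each partition with the
    silhouette, Calinski–Harabasz (both higher-better) and Davies–Bouldin
    (lower-better) indices; each index votes for its best k and the
    majority wins, with ties broken toward the smaller k.  When every index
    votes differently the smallest candidate is chosen (no common
    structure, prefer parsimony).  Returns the chosen k and a vote record.
    """
    if isinstance(X, pd.DataFrame):
        X = trajectory_values(X)
    X = np.asarray(X, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if X.shape[0] <= max(ks):
        raise ValueError("need more rows than the largest candidate k")

    scores: dict[int, dict[str, float]] = {}
    for k in ks:
        labels = fit_kmeans(X, k, seed, n_init=n_init).labels
        scores[k] = {
            "silhouette": silhouette_score(X, labels),
            "calinski_harabasz": calinski_harabasz_score(X, labels),
            "davies_bouldin": davies_bouldin_score(X, labels),
        }

    votes = {
        "silhouette": max(ks, key=lambda k: (scores[k]["silhouette"], -k)),
        "calinski_harabasz": max(ks, key=lambda k: (scores[k]["calinski_harabasz"], -k)),
        "davies_bouldin": min(ks, key=lambda k: (scores[k]["davies_bouldin"], k)),
    }
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = max(tally.values())
    if best < 2:
        # No majority: the indices see no common structure; prefer the
        # most parsimonious candidate.
        chosen = min(ks)
    else:
        chosen = min(k for k, v in tally.items() if v == best)
    return chosen, {"votes": votes, "tally": tally, "scores": scores}


def cluster_frequencies(
    labels: np.ndarray, meta: pd.DataFrame, group_by: str, prefix: str = "C"
) -> pd.DataFrame:
    """Per-group cluster frequency table (tidy: group, cluster, count, frequency).

    Every (group, cluster) pair appears, including zero counts, and
    frequencies sum to 1 within each group.
    """
    if group_by not in meta.columns:
        raise KeyError(f"unknown group key {group_by!r}")
    labels = np.asarray(labels)
    if len(labels) != len(meta):
        raise ValueError("labels and meta must align")
    df = meta[[group_by]].copy()
    df["cluster"] = labels
    all_clusters = np.unique(labels)
    rows = []
    for group, sub in df.groupby(group_by, sort=True):
        n = len(sub)
        counts = sub["cluster"].value_counts()
        for c in all_clusters:
            cnt = int(counts.get(c, 0))
            rows.append(
                {
                    "group": group,
                    "cluster": f"{prefix}{c}",
                    "count": cnt,
                    "frequency": cnt / n,
                }
            )
    return pd.DataFrame(rows)


def classify_trajectory(traj: np.ndarray, model: ClusterModel) -> int:
    """Assign a binned trajectory to the nearest centroid (min SSD).

    Ties are broken toward the lowest cluster label.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.shape != (model.centroids.shape[1],):
        raise ValueError("trajectory length does not match the centroids")
    ssd = ((model.centroids - traj[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(ssd)) + 1  # argmin returns the first (lowest) minimum


def regroup_ecg(
    wsp: int,
    hsp: int,
    nonstress_wsp: frozenset[int] | set[int] = frozenset({2}),
    low_hsp: frozenset[int] | set[int] = frozenset({1}),
) -> EcgLabel:
    """Map a (WSP, HSP) pair to one of the four environment categories.

    ``nonstress_wsp`` holds the water patterns regarded as unstressed and
    ``low_hsp`` the heat patterns regarded as low heat; both sets are
    data-driven in principle (chosen from simulated-yield contrasts) and
    default to water pattern 2 and heat pattern 1.
    """
    if wsp < 1 or hsp < 1:
        raise ValueError("cluster labels are 1-based")
    water_ok = wsp in nonstress_wsp
    heat_ok = hsp in low_hsp
    if water_ok and heat_ok:
        return EcgLabel.NO_STRESS
    if water_ok:
        return EcgLabel.HEAT
    if heat_ok:
        return EcgLabel.WATER
    return EcgLabel.HEAT_AND_WATER
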