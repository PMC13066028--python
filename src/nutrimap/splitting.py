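"""Spatially representative train/test splitting of survey clusters.

The split operates at the primary-sampling-unit (cluster) level so that no
cluster's children straddle both partitions.  A Delaunay triangulation of the
cluster sites identifies interior vertices (non-hull), and test clusters are
chosen among them by farthest-point sampling, spreading the held-out data
across the surveyed region while keeping every test cluster inside the convex
hull of the training clusters (interpolation rather than extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError


@dataclass
class SplitResult:
    """Cluster-level train/test assignment."""

    train_clusters: np.ndarray
    test_clusters: np.ndarray
    train_ids: np.ndarray
    test_ids: np.ndarray
    simplices: np.ndarray | None
    method: str

    @property
    def test_fraction(self) -> float:
        n = len(self.train_ids) + len(self.test_ids)
        return len(self.test_ids) / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "train_clusters": np.asarray(self.train_clusters).tolist(),
            "test_clusters": np.asarray(self.test_clusters).tolist(),
        }


def _cluster_table(table: pd.DataFrame) -> pd.DataFrame:
    agg = table.groupby("cluster_id").agg(
        lon=("lon", "first"), lat=("lat", "first"), size=("cluster_id", "size")
    )
    return agg.reset_index()


def _farthest_point_order(coords: np.ndarray, start: int) -> list[int]:
    """Greedy ordering maximizing the minimum distance to already-picked sites."""
    n = len(coords)
    picked = [start]
    mind = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))
        picked.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(coords - coords[nxt], axis=1))
    return picked


def delaunay_split(table: pd.DataFrame, frac_train: float = 0.8, seed: int = 0) -> SplitResult:
    """Split child observations 80/20 (by default) on whole clusters.

    Parameters
    ----------
    table
        Child-level table with ``cluster_id``, ``lon``, ``lat`` columns (all
        children in a cluster share coordinates).  A cluster-level table works
        too, in which case each row is its own observation.
    frac_train
        Target training share of observations, strictly between 0 and 1.
    seed
        Controls the farthest-point starting cluster and all tie-breaks.

    Test clusters are drawn from interior (non-convex-hull) Delaunay vertices
    when enough exist, by farthest-point sampling; degenerate geometry falls
    back to a seeded random split with a warning.
    """
    if not 0.0 < frac_train < 1.0:
        raise ValueError("frac_train must be strictly between 0 and 1")
    clusters = _cluster_table(table) if "cluster_id" in table.columns else None
    if clusters is None:
        table = table.copy()
        table["cluster_id"] = np.arange(len(table))
        clusters = _cluster_table(table)
    coords = clusters[["lon", "lat"]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    simplices = None
    method = "delaunay"
    try:
        if len(coords) < 4:
            raise QhullError("need at least 4 sites for a triangulation")
        tri = Delaunay(coords)
        simplices = tri.simplices
        hull = set(np.unique(tri.convex_hull).tolist())
        interior = [i for i in range(len(coords)) if i not in hull]
    except QhullError:
        warnings.warn(
            "degenerate cluster geometry; falling back to a seeded random split",
            UserWarning,
            stacklevel=2,
        )
        method = "random_fallback"
        interior = []

    sizes = clusters["size"].to_numpy()
    n_obs = int(sizes.sum())
    target_test = (1.0 - frac_train) * n_obs

    if method == "delaunay":
        # candidate order: interior vertices by farthest-point sampling, then
        # (only if interior runs out) hull vertices, also spread out.
        if interior:
            start = interior[int(rng.integers(len(interior)))]
            order_all = _farthest_point_order(coords, start)
            candidates = [i for i in order_all if i in set(interior)]
            candidates += [i for i in order_all if i not in set(interior)]
        else:
            candidates = _farthest_point_order(coords, int(rng.integers(len(coords))))
    else:
        candidates = list(rng.permutation(len(coords)))

    test_idx: list[int] = []
    test_count = 0
    for i in candidates:
        if abs(test_count + sizes[i] - target_test) < abs(test_count - target_test):
            test_idx.append(i)
            test_count += sizes[i]
        elif test_count > 0:
            break
    if not test_idx:  # target smaller than every cluster: take the best single one
        test_idx = [int(candidates[0])]

    test_mask = np.zeros(len(coords), dtype=bool)
    test_mask[test_idx] = True
    test_clusters = clusters.loc[test_mask, "cluster_id"].to_numpy()
    train_clusters = clusters.loc[~test_mask, "cluster_id"].to_numpy()
    in_test = table["cluster_id"].isin(test_clusters).to_numpy()
    ids = table.index.to_numpy()
    return SplitResult(
        train_clusters=train_clusters,
        test_clusters=test_clusters,
        train_ids=ids[~in_test],
        test_ids=ids[in_test],
        simplices=simplices,
        method=method,
    )


def spatial_folds(table: pd.DataFrame, k_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Partition clusters into k spatially spread folds.

    Clusters are ordered by farthest-point sampling and dealt round-robin into
    folds, so each fold covers the whole region rather than one contiguous
    block.  Returns per-fold arrays of cluster ids (an exact partition).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    clusters = _cluster_table(table)
    if len(clusters) < k_folds:
        raise ValueError("fewer clusters than folds")
    coords = clusters[["lon", "lat"]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    order = _farthest_point_order(coords, int(rng.integers(len(coords))))
    ids = clusters["cluster_id"].to_numpy()
    return [ids[np.asarray(order[f::k_folds], dtype=int)] for f in range(k_folds)]
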