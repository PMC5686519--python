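"""Density-based clustering of BGC distance submatrices.

DBSCAN is implemented directly against its standard definition on a
precomputed distance matrix: a point is *core* when at least ``min_pts``
points (itself included) lie within radius ``eps``; clusters are the
density-connected components of core points; a non-core point with a core
neighbor is a *border* point and joins the cluster of its lowest-index core
neighbor (a fixed tie-break — the textbook definition leaves border
assignment order-dependent); everything else is noise.

Parameter selection runs the full (eps × min_pts) grid — by default eps
0.01..0.98 in steps of 0.01 and min_pts 2..15, i.e. 1,372 combinations —
and picks the parameterization maximizing a noise-penalized mean
silhouette among runs with at least two clusters and a bounded noise
fraction.  The silhouette coefficient s = (b - a) / max(a, b) itself is
reported with noise excluded and size-1 clusters scoring 0; for *selection*
the mean instead counts each noise point as 0, because with a discrete
similarity score a parameterization can otherwise reach a perfect
noise-excluded silhouette simply by discarding every within-family variant
as noise, which is exactly the degenerate solution the sweep exists to
avoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

NOISE = -1


def default_eps_values() -> np.ndarray:
    """eps 0.01 .. 0.98 in steps of 0.01 (98 values)."""
    return np.round(np.arange(1, 99) * 0.01, 2)


def default_minpts_values() -> np.ndarray:
    """min_pts 2 .. 15 (14 values)."""
    return np.arange(2, 16)


@dataclass
class SweepGrid:
    """The (eps, min_pts) parameter grid."""

    eps_values: np.ndarray = field(default_factory=default_eps_values)
    minpts_values: np.ndarray = field(default_factory=default_minpts_values)

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_values, dtype=float)
        if eps.size == 0 or (np.diff(eps) <= 0).any():
            raise ValueError("eps_values must be non-empty and strictly increasing")
        if (eps <= 0).any() or (eps >= 1).any():
            raise ValueError("eps_values must lie in (0,1)")
        mp = np.asarray(self.minpts_values, dtype=int)
        if mp.size == 0 or (mp < 2).any():
            raise ValueError("minpts_values must be >= 2")
        self.eps_values = eps
        self.minpts_values = mp

    @property
    def size(self) -> int:
        return len(self.eps_values) * len(self.minpts_values)


@dataclass
class ClusterAssignment:
    """Labels for one distance submatrix at one (eps, min_pts) setting."""

    ids: list[str]
    labels: np.ndarray
    eps: float
    min_pts: int
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != self.labels.size:
            raise ValueError("ids and labels must have equal length")

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for bgc_id, label in zip(self.ids, self.labels):
            if label >= 0:
                out.setdefault(int(label), []).append(bgc_id)
        return out


@dataclass
class SilhouetteReport:
    """Per-sample silhouette values; noise points are excluded."""

    ids: list[str]
    values: np.ndarray
    n_excluded: int

    @property
    def mean(self) -> float:
        """Mean silhouette, or NaN when fewer than two clusters exist."""
        return float(np.mean(self.values)) if self.values.size else float("nan")

    @property
    def defined(self) -> bool:
        return self.values.size > 0


def _validate_distance(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def dbscan(
    dist: pd.DataFrame | np.ndarray,
    eps: float,
    min_pts: int,
    ids: Sequence[str] | None = None,
    class_label: str | None = None,
) -> ClusterAssignment:
    """DBSCAN on a precomputed symmetric distance matrix.

    Cluster ids are contiguous from 0, ordered by each cluster's lowest
    member index, which makes the labeling invariant (up to relabeling)
    under input permutation.
    """
    if not 0.0 < eps <= 1.0:
        raise ValueError(f"eps must lie in (0,1], got {eps}")
    if min_pts < 2:
        raise ValueError(f"min_pts must be >= 2, got {min_pts}")
    if ids is None:
        ids = list(dist.index) if isinstance(dist, pd.DataFrame) else [str(i) for i in range(len(dist))]
    D = _validate_distance(dist)
    n = D.shape[0]

    adjacency = D <= eps  # diagonal is 0, so each point neighbors itself
    n_neighbors = adjacency.sum(axis=1)
    core = n_neighbors >= min_pts
    labels = np.full(n, NOISE, dtype=int)

    core_idx = np.flatnonzero(core)
    if core_idx.size:
        sub = adjacency[np.ix_(core_idx, core_idx)]
        _, comp = connected_components(csr_matrix(sub), directed=False)
        labels[core_idx] = comp
        # border points join the cluster of their lowest-index core neighbor
        for i in np.flatnonzero(~core):
            core_nb = core_idx[adjacency[i, core_idx]]
            if core_nb.size:
                labels[i] = labels[core_nb.min()]
        # canonical relabeling: clusters ordered by lowest member index
        order: dict[int, int] = {}
        for lab in labels:
            if lab >= 0 and lab not in order:
                order[lab] = len(order)
        labels = np.array([order[lab] if lab >= 0 else NOISE for lab in labels])

    return ClusterAssignment(list(ids), labels, float(eps), int(min_pts), class_label)


def silhouette(dist: pd.DataFrame | np.ndarray, labels: Sequence[int]) -> SilhouetteReport:
    """Per-sample silhouette s = (b - a)/max(a, b) on a distance matrix.

    a: mean distance to own-cluster co-members; b: minimum over other
    clusters of the mean distance to that cluster.  Samples in size-1
    clusters score 0; noise is excluded.  With fewer than two clusters the
    report's mean is NaN (an explicit sentinel, not an exception).
    """
    if isinstance(dist, pd.DataFrame):
        all_ids = list(dist.index)
    else:
        all_ids = [str(i) for i in range(len(dist))]
    D = _validate_distance(dist)
    labels = np.asarray(labels, dtype=int)
    if labels.size != D.shape[0]:
        raise ValueError("labels length must match the distance matrix")

    keep = labels >= 0
    cluster_ids = sorted(set(labels[keep].tolist()))
    if len(cluster_ids) < 2:
        return SilhouetteReport([], np.array([]), n_excluded=int((~keep).sum()))

    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    ids_out: list[str] = []
    values: list[float] = []
    for i in np.flatnonzero(keep):
        own = members[labels[i]]
        if own.size == 1:
            ids_out.append(all_ids[i])
            values.append(0.0)
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, members[c]].mean() for c in cluster_ids if c != labels[i])
        denom = max(a, b)
        s = 0.0 if denom == 0 else (b - a) / denom
        ids_out.append(all_ids[i])
        values.append(float(s))
    return SilhouetteReport(ids_out, np.asarray(values), n_excluded=int((~keep).sum()))


def sweep(
    dist: pd.DataFrame | np.ndarray,
    grid: SweepGrid | None = None,
    noise_cap: float = 0.5,
    ids: Sequence[str] | None = None,
    class_label: str | None = None,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Evaluate every (eps, min_pts) combination; return the best assignment.

    Best = maximal noise-penalized mean silhouette (noise points count as
    0) among parameterizations with >= 2 clusters and noise fraction <=
    ``noise_cap``; ties break toward smaller eps, then smaller min_pts.
    When no parameterization yields two clusters, an all-noise assignment
    is returned with a warning.
    """
    grid = grid or SweepGrid()
    if ids is None:
        ids = list(dist.index) if isinstance(dist, pd.DataFrame) else [str(i) for i in range(len(dist))]
    D = _validate_distance(dist)
    n = D.shape[0]

    rows = []
    best: ClusterAssignment | None = None
    best_score = -np.inf
    for eps in grid.eps_values:
        for min_pts in grid.minpts_values:
            asg = dbscan(D, float(eps), int(min_pts), ids=ids, class_label=class_label)
            rep = silhouette(D, asg.labels)
            mean_s = rep.mean if rep.defined else float("nan")
            # selection objective: noise points count as silhouette 0
            penalized = float(rep.values.sum()) / n if rep.defined and n else float("nan")
            rows.append(
                {
                    "class": class_label or "all",
                    "eps": float(eps),
                    "minpts": int(min_pts),
                    "n_clusters": asg.n_clusters,
                    "n_noise": asg.n_noise,
                    "mean_silhouette": mean_s,
                }
            )
            if (
                asg.n_clusters >= 2
                and (n == 0 or asg.n_noise / n <= noise_cap)
                and np.isfinite(penalized)
                and penalized > best_score
            ):
                best, best_score = asg, penalized
    table = pd.DataFrame(rows, columns=["class", "eps", "minpts", "n_clusters", "n_noise", "mean_silhouette"])
    if best is None:
        warnings.warn(
            f"sweep ({class_label or 'all'}): no parameterization produced >= 2 clusters; "
            "returning an all-noise assignment"
        )
        best = ClusterAssignment(
            list(ids), np.full(n, NOISE), float(grid.eps_values[0]), int(grid.minpts_values[0]), class_label
        )
    return best, table


def find_singletons(assignments: Iterable[ClusterAssignment]) -> set[str]:
    """BGCs that cluster with nothing: noise points and size-1 clusters."""
    singles: set[str] = set()
    for asg in assignments:
        sizes: dict[int, int] = {}
        for lab in asg.labels:
            if lab >= 0:
                sizes[int(lab)] = sizes.get(int(lab), 0) + 1
        for bgc_id, lab in zip(asg.ids, asg.labels):
            if lab == NOISE or sizes.get(int(lab), 0) == 1:
                singles.add(bgc_id)
    return singles


def combined_labels(assignments: Iterable[ClusterAssignment]) -> dict[str, int]:
    """One global integer label per BGC; each noise point gets its own label."""
    out: dict[str, int] = {}
    nxt = 0
    for asg in assignments:
        offset = nxt
        used = set()
        for bgc_id, lab in zip(asg.ids, asg.labels):
            if lab >= 0:
                out[bgc_id] = offset + int(lab)
                used.add(offset + int(lab))
        nxt = (max(used) + 1) if used else nxt
        for bgc_id, lab in zip(asg.ids, asg.labels):
            if lab == NOISE:
                out[bgc_id] = nxt
                nxt += 1
    return out


def write_sweep_table(tables: Iterable[pd.DataFrame], path) -> None:
    pd.concat(list(tables), ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )


def write_assignments(assignments: Iterable[ClusterAssignment], path) -> None:
    rows = []
    for asg in assignments:
        for bgc_id, lab in zip(asg.ids, asg.labels):
            rows.append(
                {
                    "bgc_id": bgc_id,
                    "class": asg.class_label or "all",
                    "cluster_id": "NOISE" if lab == NOISE else int(lab),
                }
            )
    pd.DataFrame(rows, columns=["bgc_id", "class", "cluster_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


class SweepDBSCAN(ClusterMixin, BaseEstimator):
    """DBSCAN with built-in grid search on a precomputed distance matrix.

    ``fit(X)`` expects a square symmetric distance matrix.  Fitted
    attributes: ``labels_``, ``best_eps_``, ``best_min_pts_``,
    ``sweep_table_`` (the full grid diagnostics) and
    ``silhouette_report_`` for the selected labeling.
    """

    def __init__(
        self,
        eps_values: Sequence[float] | None = None,
        minpts_values: Sequence[int] | None = None,
        noise_cap: float = 0.5,
    ):
        self.eps_values = eps_values
        self.minpts_values = minpts_values
        self.noise_cap = noise_cap

    def _grid(self) -> SweepGrid:
        return SweepGrid(
            np.asarray(self.eps_values, dtype=float) if self.eps_values is not None else default_eps_values(),
            np.asarray(self.minpts_values, dtype=int)
            if self.minpts_values is not None
            else default_minpts_values(),
        )

    def fit(self, X, y=None):
        best, table = sweep(X, grid=self._grid(), noise_cap=self.noise_cap)
        self.labels_ = best.labels
        self.best_eps_ = best.eps
        self.best_min_pts_ = best.min_pts
        self.sweep_table_ = table
        self.silhouette_report_ = silhouette(X, best.labels)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self
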