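"""Spatiotemporal cluster-mass permutation correction.

Suprathreshold channel x time cells are grouped into connected clusters
(same channel at adjacent timepoints, or neighboring channels at the same
timepoint — no diagonal moves), each scored by the sum of its F values.
Family-wise corrected p-values come from the permutation distribution of
the maximum cluster mass, using the Freedman–Lane scheme so nuisance
covariates (age and, when testing group, the D score) are respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import DesignMatrix, contrasts_to_matrix
from .montage import Montage
from .preprocess import SubjectContrast

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "form_clusters",
    "max_cluster_mass",
    "permutation_null",
    "report_clusters",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, irreflexive sensor neighbor relation with positions."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    distance_threshold_mm: float
    pairs: tuple[tuple[int, int], ...]  # index pairs, a < b
    region: tuple[str, ...] | None = None  # per-channel region label

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_channels, dtype=int)
        for a, b in self.pairs:
            counts[a] += 1
            counts[b] += 1
        return counts


def build_adjacency(
    montage: Montage,
    distance_threshold_mm: float = 40.0,
    region: dict[str, str] | None = None,
) -> AdjacencyGraph:
    """Neighbor pairs = sensor pairs within a Euclidean distance threshold.

    With a ``region`` partition (channel label -> region label), pairs
    crossing region boundaries are excluded, so clusters can never span
    two regions. Isolated channels are permitted (they can still form
    purely temporal clusters).
    """
    if len(set(montage.labels)) != len(montage.labels):
        raise ValueError("duplicate channel labels")
    if montage.n_channels < 2:
        raise ValueError("need at least 2 channels")
    region_tuple = None
    if region is not None:
        missing = [lab for lab in montage.labels if lab not in region]
        if missing:
            raise ValueError(f"channels without region assignment: {missing}")
        region_tuple = tuple(region[lab] for lab in montage.labels)
    d = montage.distances()
    pairs = []
    for a in range(montage.n_channels):
        for b in range(a + 1, montage.n_channels):
            if d[a, b] <= distance_threshold_mm:
                if region_tuple is not None and region_tuple[a] != region_tuple[b]:
                    continue
                pairs.append((a, b))
    return AdjacencyGraph(
        labels=montage.labels,
        positions=montage.positions,
        distance_threshold_mm=float(distance_threshold_mm),
        pairs=tuple(pairs),
        region=region_tuple,
    )


@dataclass
class Cluster:
    cells: list[tuple[int, int]]  # (channel index, time index)
    mass: float
    p_corrected: float | None = None

    @property
    def channel_indices(self) -> list[int]:
        return sorted({c for c, _ in self.cells})

    @property
    def time_indices(self) -> list[int]:
        return sorted({t for _, t in self.cells})


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _suprathreshold_components(mask: np.ndarray, pairs) -> list[list[tuple[int, int]]]:
    cells = np.argwhere(mask)
    if cells.size == 0:
        return []
    idx = {(int(c), int(t)): k for k, (c, t) in enumerate(cells)}
    uf = _UnionFind(len(cells))
    # temporal adjacency within each channel
    both = mask[:, :-1] & mask[:, 1:]
    for c, t in np.argwhere(both):
        uf.union(idx[(int(c), int(t))], idx[(int(c), int(t) + 1)])
    # spatial adjacency at identical timepoints
    for a, b in pairs:
        for t in np.flatnonzero(mask[a] & mask[b]):
            uf.union(idx[(a, int(t))], idx[(b, int(t))])
    comps: dict[int, list[tuple[int, int]]] = {}
    for (c, t), k in idx.items():
        comps.setdefault(uf.find(k), []).append((c, t))
    return list(comps.values())


def form_clusters(
    F: np.ndarray, threshold_F: float, graph: AdjacencyGraph
) -> list[Cluster]:
    """Connected components of cells with F > threshold, scored by mass."""
    if threshold_F <= 0:
        raise ValueError("threshold_F must be > 0")
    F = np.asarray(F, float)
    if F.shape[0] != graph.n_channels:
        raise ValueError("field rows do not match graph channels")
    clusters = [
        Cluster(cells=sorted(cells), mass=float(sum(F[c, t] for c, t in cells)))
        for cells in _suprathreshold_components(F > threshold_F, graph.pairs)
    ]
    clusters.sort(key=lambda cl: -cl.mass)
    return clusters


def max_cluster_mass(F: np.ndarray, threshold_F: float, graph: AdjacencyGraph) -> float:
    comps = _suprathreshold_components(np.asarray(F) > threshold_F, graph.pairs)
    if not comps:
        return 0.0
    F = np.asarray(F)
    return max(float(sum(F[c, t] for c, t in cells)) for cells in comps)


@dataclass
class ClusterResult:
    regressor: str
    clusters: list[Cluster]
    null_distribution: np.ndarray
    n_permutations: int
    seed: int
    cluster_forming_p: float
    threshold_F: float
    channel_names: tuple[str, ...]
    times_ms: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected is not None and c.p_corrected <= alpha]


def _f_single_regressor(Y, X, pinvX, cjj, j, dfr):
    """F field for one regressor, vectorized over cells."""
    B = pinvX @ Y
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dfr
    return B[j] ** 2 / np.maximum(sigma2 * cjj, 1e-300)


def permutation_null(
    contrasts: list[SubjectContrast],
    design: DesignMatrix,
    regressor: str,
    graph: AdjacencyGraph,
    n_permutations: int = 1000,
    seed: int = 0,
    cluster_forming_p: float = 0.05,
) -> ClusterResult:
    """Freedman–Lane cluster-mass permutation test for one regressor.

    The reduced model (all regressors except the tested one) is fitted;
    its residuals are row-permuted, added back to the reduced fit, and the
    full model refitted per permutation. The maximum cluster mass over the
    grid per permutation forms the null; observed clusters get
    ``p = (1 + #{null >= mass}) / (1 + n_permutations)`` (ties counted as
    exceeding — conservative; the add-one estimator floors p at 1/(n+1)).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for stable p-values")
    pids = [c.participant_id for c in contrasts]
    design = design.reorder(pids)
    j = design.column_index(regressor)
    Y, shape = contrasts_to_matrix(contrasts)
    X = design.X
    n, p = X.shape
    dfr = n - p
    pinvX = np.linalg.pinv(X)
    cjj = float(np.diag(np.linalg.inv(X.T @ X))[j])
    threshold_F = float(stats.f.ppf(1.0 - cluster_forming_p, 1, dfr))

    F_obs = _f_single_regressor(Y, X, pinvX, cjj, j, dfr).reshape(shape)
    clusters = form_clusters(F_obs, threshold_F, graph)

    # reduced model without the tested regressor
    Z = np.delete(X, j, axis=1)
    Hz = Z @ np.linalg.pinv(Z)
    fitted = Hz @ Y
    R = Y - fitted

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        Ystar = fitted + R[rng.permutation(n)]
        Fb = _f_single_regressor(Ystar, X, pinvX, cjj, j, dfr).reshape(shape)
        null[b] = max_cluster_mass(Fb, threshold_F, graph)

    for cl in clusters:
        cl.p_corrected = float((1 + np.sum(null >= cl.mass)) / (1 + n_permutations))

    return ClusterResult(
        regressor=regressor,
        clusters=clusters,
        null_distribution=null,
        n_permutations=n_permutations,
        seed=seed,
        cluster_forming_p=cluster_forming_p,
        threshold_F=threshold_F,
        channel_names=contrasts[0].channel_names,
        times_ms=contrasts[0].times_ms,
    )


def report_clusters(result: ClusterResult) -> pd.DataFrame:
    """Human-readable cluster table: latency window (ms), channels, mass, p.

    Rows are ordered by descending cluster mass, matching the order in
    ``result.clusters``.
    """
    rows = []
    for k, cl in enumerate(result.clusters, start=1):
        tidx = cl.time_indices
        rows.append({
            "cluster": k,
            "regressor": result.regressor,
            "start_ms": float(result.times_ms[tidx[0]]),
            "end_ms": float(result.times_ms[tidx[-1]]),
            "n_cells": len(cl.cells),
            "n_channels": len(cl.channel_indices),
            "channels": ",".join(result.channel_names[c] for c in cl.channel_indices),
            "mass": cl.mass,
            "p_corrected": cl.p_corrected,
        })
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "regressor", "start_ms", "end_ms", "n_cells",
            "n_channels", "channels", "mass", "p_corrected",
        ],
    )
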