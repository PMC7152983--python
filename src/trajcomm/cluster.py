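"""Hierarchical clustering of trajectory frames on pairwise RMSD.

Average-linkage agglomeration with a merging-distance cutoff (default
2.5 Å), centroid extraction as the member with the most neighbors within
a cutoff, and population percentages — the machinery behind "most
abundant binding pose" reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import FrameSeries, Selection
from .superpose import kabsch_fit, _rmsd

logger = logging.getLogger(__name__)

DEFAULT_MERGE_CUTOFF = 2.5  # Å
DEFAULT_REPORT_THRESHOLD = 0.01  # fraction of population


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    population_percent: float
    centroid_frame: int


@dataclass
class ClusterSummary:
    clusters: list[Cluster]
    cutoff: float
    report_threshold: float = DEFAULT_REPORT_THRESHOLD

    def populations(self) -> list[float]:
        return [c.population_percent for c in self.clusters]

    @property
    def n_frames(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def pairwise_rmsd_matrix(
    series: FrameSeries,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Symmetric frame-vs-frame RMSD matrix after pairwise rigid fits.

    d(i, j) is the RMSD on the measure selection after fitting frame j's
    fit selection onto frame i's.  ``stride`` subsamples frames before
    the O(n²) computation.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    if series.n_frames < 2:
        raise ValueError("pairwise matrix needs at least 2 frames")
    fi = fit_selection.as_array()
    mi = measure_selection.as_array()
    frames = np.arange(0, series.n_frames, stride)
    n = len(frames)
    d = np.zeros((n, n))
    if np.array_equal(fi, mi):
        return _pairwise_rmsd_same(series.coords[np.ix_(frames, fi)])
    for a in range(n):
        ca_fit = series.coords[frames[a], fi]
        ca_meas = series.coords[frames[a], mi]
        for b in range(a + 1, n):
            fit = kabsch_fit(series.coords[frames[b], fi], ca_fit)
            val = _rmsd(fit.apply(series.coords[frames[b], mi]), ca_meas)
            d[a, b] = d[b, a] = val
    return d


def _pairwise_rmsd_same(x: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """All-pairs fitted RMSD when fit == measure selection.

    Uses the closed form rmsd² = (|X|² + |Y|² − 2(s₁+s₂±s₃))/N with the
    singular values of the cross-covariance, batched over frame pairs.
    """
    n, n_atoms, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.einsum("fij,fij->f", xc, xc)
    ai, bi = np.triu_indices(n, k=1)
    d = np.zeros((n, n))
    for lo in range(0, len(ai), chunk):
        a = ai[lo : lo + chunk]
        b = bi[lo : lo + chunk]
        h = np.einsum("pij,pik->pjk", xc[b], xc[a])
        s = np.linalg.svd(h, compute_uv=False)
        sign = np.sign(np.linalg.det(h))
        sign[sign == 0] = 1.0
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = np.clip((norms[a] + norms[b] - 2.0 * trace) / n_atoms, 0.0, None)
        d[a, b] = d[b, a] = np.sqrt(msd)
    return d


def average_linkage(
    matrix: np.ndarray,
    merge_cutoff: float = DEFAULT_MERGE_CUTOFF,
    neighbor_cutoff: float | None = None,
) -> ClusterSummary:
    """Agglomerative average-linkage clustering with a merge cutoff.

    Clusters merge while the minimum average inter-cluster distance is
    ≤ ``merge_cutoff``; the result is returned ordered by descending
    population.  ``neighbor_cutoff`` (for centroid picking) defaults to
    the merge cutoff.
    """
    if merge_cutoff <= 0:
        raise ValueError("merge_cutoff must be positive")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be square and symmetric")
    if neighbor_cutoff is None:
        neighbor_cutoff = merge_cutoff
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(matrix, checks=False), method="average")
        labels = fcluster(z, t=merge_cutoff, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = tuple(int(i) for i in np.nonzero(labels == lab)[0])
        clusters.append(
            Cluster(
                members=members,
                population_percent=100.0 * len(members) / n,
                centroid_frame=centroid_frame(members, matrix, neighbor_cutoff),
            )
        )
    # descending population; ties by smallest first member for determinism
    clusters.sort(key=lambda c: (-c.population_percent, c.members[0]))
    return ClusterSummary(clusters=clusters, cutoff=merge_cutoff)


def centroid_frame(members: tuple[int, ...] | list[int], matrix: np.ndarray, neighbor_cutoff: float) -> int:
    """Member with the most neighbors within ``neighbor_cutoff``; ties → smallest id."""
    members = list(members)
    if not members:
        raise ValueError("cluster is empty")
    sub = np.asarray(matrix)[np.ix_(members, members)]
    counts = (sub <= neighbor_cutoff).sum(axis=1) - 1  # exclude self
    best = int(np.argmax(counts))  # argmax takes first (= smallest id) on ties
    return members[best]


def report_major_clusters(
    summary: ClusterSummary, threshold: float = DEFAULT_REPORT_THRESHOLD
) -> ClusterSummary:
    """Retain clusters whose population fraction is strictly above ``threshold``."""
    kept = [c for c in summary.clusters if c.population_percent / 100.0 > threshold]
    if not kept:
        logger.warning("no cluster exceeds the %.1f%% reporting threshold", 100 * threshold)
    return ClusterSummary(clusters=kept, cutoff=summary.cutoff, report_threshold=threshold)
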