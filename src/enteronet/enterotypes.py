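"""Enterotype discovery: Jensen-Shannon distances, PAM, CH selection, PCoA.

The enterotyping recipe clusters samples on the Jensen-Shannon *distance*
(square root of the Jensen-Shannon divergence, natural log, bounded by
``sqrt(ln 2)``) computed from genus-level relative abundances, partitions
with PAM (k-medoids, BUILD + SWAP), and picks the number of clusters
maximizing a medoid-based Calinski-Harabasz index. Ordination is classical
scaling (PCoA) of the same distance matrix.

PAM here is fully deterministic: greedy BUILD seeding followed by
steepest-descent SWAP with ties broken by lowest sample index, so no
random restarts or seeds are involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform

from .io_tables import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "EnterotypeResult",
    "OrdinationResult",
    "jensen_shannon_distance",
    "jsd_matrix",
    "pam_cluster",
    "calinski_harabasz",
    "select_enterotypes",
    "pcoa",
    "driver_taxa",
]


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative pairwise sample distances."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class EnterotypeResult:
    assignment: pd.Series  # sample id -> cluster index
    medoids: list[str]  # one sample id per cluster
    ch_scores: dict[int, float]  # k -> CH value
    k_selected: int

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.assignment.value_counts().sort_index().to_dict()


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # descending, positive axes only
    proportion_explained: np.ndarray


def _smooth(p: np.ndarray, pseudocount: float) -> np.ndarray:
    q = p + pseudocount
    return q / q.sum()


def jensen_shannon_distance(p, q, pseudocount: float = 0.0) -> float:
    """Jensen-Shannon distance between two relative-abundance profiles.

    ``sqrt(0.5·KL(p‖m) + 0.5·KL(q‖m))`` with ``m = (p+q)/2`` in natural
    log. Zeros are handled by adding ``pseudocount`` to every entry and
    renormalizing first; with ``pseudocount=0`` the usual ``0·log 0 = 0``
    convention applies, so disjoint supports give ``sqrt(ln 2)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in a probability vector")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1")
    return float(jensenshannon(_smooth(p, pseudocount), _smooth(q, pseudocount)))


def jsd_matrix(table: AbundanceTable, pseudocount: float = 1e-6) -> DistanceMatrix:
    """Pairwise Jensen-Shannon distances between all samples of a table."""
    values = table.values + pseudocount
    values = values / values.sum(axis=1, keepdims=True)
    condensed = pdist(values, metric="jensenshannon")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


def pam_cluster(D: DistanceMatrix, k: int) -> tuple[pd.Series, list[str]]:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily seeds ``k`` medoids minimizing total distance of every
    sample to its nearest medoid; SWAP repeatedly applies the best
    strictly-improving (medoid, non-medoid) exchange until none exists.
    Deterministic: candidate loops run in ascending index order and only
    strict improvements are accepted.

    Returns the per-sample assignment (cluster indices ordered by medoid
    position) and the medoid sample ids.
    """
    n = D.n
    if not 2 <= k < n:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    d = D.values

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        cand_cost = np.minimum(nearest[:, None], d).sum(axis=0)
        cand_cost[medoids] = np.inf
        j = int(np.argmin(cand_cost))
        medoids.append(j)
        np.minimum(nearest, d[:, j], out=nearest)

    medoids = sorted(medoids)
    cost = _pam_cost(d, medoids)
    # SWAP (steepest descent)
    while True:
        best = (cost, None)
        non_medoids = [h for h in range(n) if h not in medoids]
        for m in medoids:
            rest = [x for x in medoids if x != m]
            d_rest = d[:, rest].min(axis=1)
            for h in non_medoids:
                new_cost = np.minimum(d_rest, d[:, h]).sum()
                if new_cost < best[0] - 1e-12:
                    best = (new_cost, (m, h))
        if best[1] is None:
            break
        m, h = best[1]
        medoids = sorted(set(medoids) - {m} | {h})
        cost = best[0]

    assign = _assign(d, medoids)
    ids = pd.Series(assign, index=D.ids, name="cluster")
    return ids, [D.ids[m] for m in medoids]


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _assign(d: np.ndarray, medoids: list[int]) -> np.ndarray:
    # argmin over medoids sorted ascending → nearest-medoid ties go to the
    # lowest sample index
    return np.argmin(d[:, medoids], axis=1)


def calinski_harabasz(D: DistanceMatrix, assignment) -> float:
    """Medoid-based Calinski-Harabasz index from a distance matrix.

    ``CH = [B/(k−1)] / [W/(n−k)]`` with ``W`` the sum of squared distances
    of samples to their cluster medoid and ``B`` the size-weighted sum of
    squared distances of cluster medoids to the overall medoid (the sample
    minimizing total squared distance to all samples). Medoid ties break
    to the lowest sample index. ``W = 0`` returns ``+inf``.
    """
    labels = np.asarray(
        assignment.values if isinstance(assignment, pd.Series) else assignment
    )
    d2 = D.values**2
    n = D.n
    clusters = np.unique(labels)
    k = len(clusters)
    if k < 2:
        raise ValueError("calinski_harabasz needs at least 2 clusters")
    overall = int(np.argmin(d2.sum(axis=0)))
    W = 0.0
    B = 0.0
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        med = members[int(np.argmin(d2[np.ix_(members, members)].sum(axis=0)))]
        W += d2[members, med].sum()
        B += members.size * d2[med, overall]
    if W == 0:
        return float("inf")
    return float((B / (k - 1)) / (W / (n - k)))


def select_enterotypes(
    table: AbundanceTable,
    k_range=None,
    pseudocount: float = 1e-6,
) -> EnterotypeResult:
    """Full enterotyping: JSD matrix → PAM over ``k_range`` → CH argmax.

    ``k_range`` defaults to ``2..min(10, n−1)``. CH ties select the
    smallest k. The whole CH curve is returned for audit.
    """
    D = jsd_matrix(table, pseudocount=pseudocount)
    n = D.n
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] >= n:
        raise ValueError("k_range must lie within [2, n-1]")

    ch_scores: dict[int, float] = {}
    results: dict[int, tuple[pd.Series, list[str]]] = {}
    for k in k_range:
        assignment, medoids = pam_cluster(D, k)
        results[k] = (assignment, medoids)
        ch_scores[k] = calinski_harabasz(D, assignment)
    best_k = max(k_range, key=lambda k: (ch_scores[k], -k))
    assignment, medoids = results[best_k]
    return EnterotypeResult(assignment, medoids, ch_scores, best_k)


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (classical scaling).

    Double-centers ``−0.5·J·D²·J``, eigendecomposes, and scales the
    eigenvectors of the positive eigenvalues by their square roots.
    Negative eigenvalues (non-Euclidean distances) are dropped both from
    the axes and from the proportion-explained denominator.
    """
    d2 = D.values**2
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, abs(eigval).max(initial=0.0) * 1e-10)
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_pos == 0:  # all-zero distances
        coords = pd.DataFrame(
            np.zeros((n, n_axes)),
            index=D.ids,
            columns=[f"PCo{i + 1}" for i in range(n_axes)],
        )
        return OrdinationResult(coords, np.zeros(n_axes), np.zeros(n_axes))
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    lam = eigval[:n_axes]
    coords = eigvec[:, :n_axes] * np.sqrt(lam)
    frame = pd.DataFrame(
        coords, index=D.ids, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    prop = lam / eigval[pos].sum()
    return OrdinationResult(frame, lam, prop)


def driver_taxa(table: AbundanceTable, assignment, top_n: int = 5) -> dict[int, pd.DataFrame]:
    """Rank taxa distinguishing each cluster.

    For every cluster, taxa are ordered by (mean relative abundance within
    the cluster − mean abundance in all other samples), descending; the
    top ``top_n`` are returned with both means.
    """
    labels = (
        assignment
        if isinstance(assignment, pd.Series)
        else pd.Series(assignment, index=table.sample_ids)
    )
    labels = labels.loc[table.sample_ids]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    out: dict[int, pd.DataFrame] = {}
    for c in clusters:
        inside = table.data.loc[labels == c].mean(axis=0)
        outside = table.data.loc[labels != c].mean(axis=0)
        df = pd.DataFrame(
            {"mean_in": inside, "mean_out": outside, "difference": inside - outside}
        ).sort_values("difference", ascending=False)
        out[c] = df.head(top_n)
    return out
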