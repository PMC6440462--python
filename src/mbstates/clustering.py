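"""Deterministic distance-matrix clustering: PAM (BUILD + SWAP) and UPGMA.

Both algorithms consume only a symmetric distance matrix.  All tie-breaks are
by lowest sample position (PAM) or lexicographically smallest cluster-slot
pair (UPGMA), so repeated runs on the same matrix are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beta_diversity import DistanceMatrix

__all__ = [
    "ClusteringSolution",
    "pam",
    "upgma_cluster",
    "cluster_medoid",
    "canonicalize_labels",
    "make_clusterer",
]

_EPS = 1e-12


def _as_matrix(D) -> tuple[np.ndarray, list[str] | None, str | None]:
    if isinstance(D, DistanceMatrix):
        return D.values, D.sample_ids, D.metric_id
    d = np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    return d, None, None


def canonicalize_labels(labels) -> np.ndarray:
    """Relabel clusters as 1..k by order of first appearance."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        key = lab.item() if hasattr(lab, "item") else lab
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out


@dataclass
class ClusteringSolution:
    """A k-partition of samples from one (algorithm, distance) combination.

    ``labels`` are canonical 1..k integers in sample order.  ``medoids``
    holds the k medoid sample positions (PAM only), indexed by cluster;
    ``merge_sequence`` holds (slot_a, slot_b, height, new_size) merge records
    (UPGMA only).
    """

    algorithm_id: str
    k: int
    labels: np.ndarray
    metric_id: str | None = None
    sample_ids: list[str] | None = None
    medoids: list[int] | None = None
    objective: float | None = None
    merge_sequence: list[tuple[int, int, float, int]] | None = field(
        default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) != self.k or uniq[0] != 1 or uniq[-1] != self.k:
            raise ValueError("labels must cover clusters 1..k, all non-empty")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]

    def labels_by_id(self) -> dict[str, int]:
        if self.sample_ids is None:
            raise ValueError("solution has no sample ids attached")
        return {s: int(l) for s, l in zip(self.sample_ids, self.labels)}


# ---------------------------------------------------------------------------
# PAM


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dn = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dn[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))  # argmax -> lowest index on ties
        medoids.append(c)
        dn = np.minimum(dn, d[c])
    return medoids


def pam(D, k: int) -> ClusteringSolution:
    """Partitioning Around Medoids with greedy BUILD and best-improvement SWAP.

    BUILD seeds the first medoid at the point minimizing total distance to
    all points, then greedily adds the point giving the largest objective
    decrease.  SWAP repeatedly applies the single best strictly-improving
    (medoid, non-medoid) exchange until 1-swap local optimality.  The
    objective is the sum of distances from each point to its nearest medoid.
    """
    d, sample_ids, metric_id = _as_matrix(D)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")

    medoids = sorted(_pam_build(d, k))
    while True:
        med = np.array(medoids)  # ascending sample position
        dmat = d[med]  # k x n
        order = np.argsort(dmat, axis=0, kind="stable")
        cols = np.arange(n)
        nearest = order[0]
        dn = dmat[nearest, cols]
        ds = dmat[order[1], cols]

        best_delta = -_EPS
        best_swap = None
        for mi in range(k):
            # removing medoid mi: points attached to it fall back to their
            # second-nearest medoid before the candidate is considered
            base = np.where(nearest == mi, ds, dn)
            deltas = (np.minimum(base[None, :], d) - dn[None, :]).sum(axis=1)
            deltas[med] = np.inf
            h = int(np.argmin(deltas))
            if deltas[h] < best_delta:
                best_delta = float(deltas[h])
                best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = sorted(medoids[:mi] + medoids[mi + 1:] + [h])

    med = np.array(medoids)
    dmat = d[med]
    nearest = np.argmin(dmat, axis=0)  # ties -> lowest medoid position
    nearest[med] = np.arange(k)  # a medoid anchors its own cluster
    objective = float(dmat[nearest, np.arange(n)].sum())
    labels = canonicalize_labels(nearest)
    # reorder medoids to follow canonical cluster numbering
    med_by_cluster = [0] * k
    for pos, lab in zip(nearest, labels):
        med_by_cluster[lab - 1] = int(med[pos])
    return ClusteringSolution(
        algorithm_id="pam", k=k, labels=labels, metric_id=metric_id,
        sample_ids=sample_ids, medoids=med_by_cluster, objective=objective,
    )


# ---------------------------------------------------------------------------
# UPGMA


def _upgma_merges(d: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Full merge sequence under size-weighted average linkage.

    Clusters live in "slots" indexed by their smallest member position; a
    merge folds the larger slot into the smaller one (Lance-Williams update
    of the average linkage).  Ties on merge height pick the lexicographically
    smallest (slot_a, slot_b) pair.
    """
    n = d.shape[0]
    w = d.astype(float).copy()
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    iu = np.triu_indices(n, k=1)
    merges: list[tuple[int, int, float, int]] = []
    for _ in range(n - 1):
        work = w.copy()
        work[~active, :] = np.inf
        work[:, ~active] = np.inf
        tri = np.full_like(work, np.inf)
        tri[iu] = work[iu]
        flat = int(np.argmin(tri))  # row-major -> lexicographically smallest
        a, b = divmod(flat, n)
        h = float(w[a, b])
        na, nb = sizes[a], sizes[b]
        # fold b into a (a < b by upper-triangle scan)
        w[a, :] = (na * w[a, :] + nb * w[b, :]) / (na + nb)
        w[:, a] = w[a, :]
        w[a, a] = 0.0
        sizes[a] = na + nb
        active[b] = False
        merges.append((a, b, h, int(na + nb)))
    return merges


def upgma_cluster(D, k: int) -> ClusteringSolution:
    """Agglomerative UPGMA (average linkage) cut at k clusters.

    The tree is built by n-1 greedy merges of the closest pair of clusters
    under size-weighted average inter-cluster distance; labels come from
    stopping after n-k merges.
    """
    d, sample_ids, metric_id = _as_matrix(D)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    merges = _upgma_merges(d)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, _, _ in merges[: n - k]:
        parent[find(b)] = find(a)
    roots = np.array([find(i) for i in range(n)])
    labels = canonicalize_labels(roots)
    return ClusteringSolution(
        algorithm_id="hclust", k=k, labels=labels, metric_id=metric_id,
        sample_ids=sample_ids, merge_sequence=merges,
    )


def cluster_medoid(D, member_ids) -> int:
    """Member position minimizing the summed distance to the other members."""
    d, _, _ = _as_matrix(D)
    members = np.asarray(list(member_ids), dtype=int)
    if members.size == 0:
        raise ValueError("member set is empty")
    members = np.sort(members)
    sub = d[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


# ---------------------------------------------------------------------------
# Clusterer plumbing used by the validation scores


def make_clusterer(algorithm_id: str):
    """Return ``f(matrix, k) -> (labels, medoid_positions)`` for an algorithm.

    For PAM the medoids are the algorithm's own; for UPGMA each cluster's
    medoid is derived with :func:`cluster_medoid` so hierarchical partitions
    can also classify held-out samples.
    """
    if algorithm_id == "pam":
        def _cluster(d, k):
            sol = pam(d, k)
            return sol.labels, list(sol.medoids)
    elif algorithm_id == "hclust":
        def _cluster(d, k):
            sol = upgma_cluster(d, k)
            meds = [cluster_medoid(d, sol.members(c)) for c in range(1, k + 1)]
            return sol.labels, meds
    else:
        raise KeyError(f"unknown algorithm {algorithm_id!r}")
    return _cluster
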