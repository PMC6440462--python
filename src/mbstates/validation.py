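"""Clustering assessment scores: silhouette, prediction strength, Jaccard.

Each score consumes a distance matrix plus a clustering procedure bound to
the same metric.  Prediction strength and bootstrap Jaccard stability are
randomized; both are bit-reproducible given a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .beta_diversity import DistanceMatrix
from .clustering import make_clusterer

logger = logging.getLogger(__name__)

__all__ = [
    "AssessmentRecord",
    "average_silhouette",
    "prediction_strength",
    "jaccard_stability",
    "assess_combination",
]


@dataclass
class AssessmentRecord:
    """Scores for one (algorithm, metric, k) grid combination.

    ``ps_mean`` / ``jaccard_mean`` are ``None`` when the combination has only
    been silhouette-scored (lazy grid mode); the selection step fills them in
    on demand.
    """

    algorithm_id: str
    metric_id: str
    k: int
    si: float
    labels: np.ndarray = field(repr=False)
    cluster_sizes: tuple[int, ...]
    ps_mean: float | None = None
    ps_reps: int = 0
    jaccard_per_cluster: tuple[float, ...] | None = None
    jaccard_mean: float | None = None
    boot_reps: int = 0
    error: str | None = None

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.si <= 1 + 1e-12:
            raise ValueError(f"silhouette {self.si} outside [-1, 1]")
        for name, v in (("ps_mean", self.ps_mean), ("jaccard_mean", self.jaccard_mean)):
            if v is not None and not 0 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.jaccard_per_cluster is not None and len(self.jaccard_per_cluster) != self.k:
            raise ValueError("jaccard_per_cluster length must equal k")
        if sum(self.cluster_sizes) != len(self.labels):
            raise ValueError("cluster sizes do not sum to n")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.algorithm_id, self.metric_id, self.k)


def _matrix(D) -> np.ndarray:
    return D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)


def average_silhouette(D, labels) -> float:
    """Average silhouette width of a labelled partition.

    Per sample: ``a`` is the mean distance to own-cluster co-members, ``b``
    the smallest mean distance to any other cluster; the sample score is
    ``(b - a) / max(a, b)``.  Samples in singleton clusters score 0, as do
    samples with ``a == b == 0``.
    """
    d = _matrix(D)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("labels do not match the distance matrix")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    k = len(clusters)
    sums = np.empty((n, k))
    counts = np.empty(k, dtype=int)
    for ci, c in enumerate(clusters):
        mask = labels == c
        counts[ci] = mask.sum()
        sums[:, ci] = d[:, mask].sum(axis=1)
    own = np.searchsorted(clusters, labels)
    s = np.zeros(n)
    for i in range(n):
        ci = own[i]
        if counts[ci] == 1:
            continue  # singleton convention: s = 0
        a = sums[i, ci] / (counts[ci] - 1)
        other = [sums[i, cj] / counts[cj] for cj in range(k) if cj != ci]
        b = min(other)
        denom = max(a, b)
        if denom > 0:
            s[i] = (b - a) / denom
    return float(s.mean())


def _classify(d: np.ndarray, test_idx: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Assign each test sample to the cluster of its nearest medoid (1-based).

    Ties go to the medoid at the lowest sample position.
    """
    med = np.asarray(medoids, dtype=int)
    dists = d[np.ix_(test_idx, med)]
    pos_order = np.argsort(med, kind="stable")
    sub = dists[:, pos_order]
    choice = pos_order[np.argmin(sub, axis=1)]
    return choice + 1


def _pair_match_counts(test_labels: np.ndarray, assigned: np.ndarray, k: int,
                       aggregation: str) -> float:
    """Score one classification direction of a prediction-strength split."""
    per_cluster = []
    total_match = 0
    total_pairs = 0
    for c in range(1, k + 1):
        members = np.nonzero(test_labels == c)[0]
        m = len(members)
        if m < 2:
            per_cluster.append(1.0)
            continue
        counts = np.bincount(assigned[members])
        match = int((counts * (counts - 1) // 2).sum())
        pairs = m * (m - 1) // 2
        per_cluster.append(match / pairs)
        total_match += match
        total_pairs += pairs
    if aggregation == "min":
        return float(min(per_cluster))
    if aggregation == "global":
        return 1.0 if total_pairs == 0 else total_match / total_pairs
    raise ValueError(f"unknown ps aggregation {aggregation!r}")


def prediction_strength(D, k: int, clusterer, reps: int = 100,
                        rng=None, aggregation: str = "min",
                        both_directions: bool = True,
                        counter=None) -> float:
    """Split-half prediction strength of a k-clustering.

    Each repetition splits the samples into two halves, clusters both, and
    classifies the samples of one half to their nearest medoid from the
    other half's clustering.  Each test cluster is scored by the proportion
    of its sample pairs that land in a single training cluster; a
    repetition's score aggregates over test clusters (minimum by default).
    Both classification directions are averaged.  Singleton test clusters
    count as perfectly preserved.
    """
    d = _matrix(D)
    n = d.shape[0]
    if k == 1:
        return 1.0
    if isinstance(clusterer, str):
        clusterer = make_clusterer(clusterer)
    if n < 2 * k:
        raise ValueError(f"n={n} too small to split for k={k}")
    rng = np.random.default_rng(rng)
    scores = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(n)
        half_a = np.sort(perm[: n // 2])
        half_b = np.sort(perm[n // 2:])
        rep = []
        for train, test in ((half_a, half_b), (half_b, half_a)):
            lab_tr, med_tr = clusterer(d[np.ix_(train, train)], k)
            lab_te, _ = clusterer(d[np.ix_(test, test)], k)
            if counter is not None:
                counter.add_clusterings(2)
            med_global = [int(train[m]) for m in med_tr]
            assigned = _classify(d, test, med_global)
            rep.append(_pair_match_counts(lab_te, assigned, k, aggregation))
            if not both_directions:
                break
        scores[r] = float(np.mean(rep))
    return float(scores.mean())


def jaccard_stability(D, k: int, clusterer, boot_reps: int = 100,
                      rng=None, counter=None) -> tuple[tuple[float, ...], float]:
    """Bootstrap stability of each cluster, scored by Jaccard set similarity.

    The full data is clustered once; each bootstrap resample (n draws with
    replacement, distance sub-matrix with duplicated rows) is re-clustered
    and every original cluster — restricted to the distinct samples present
    in the resample — is matched to its best-overlapping resample cluster.
    Returns per-cluster means over resamples and their grand mean.
    """
    d = _matrix(D)
    n = d.shape[0]
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    if isinstance(clusterer, str):
        clusterer = make_clusterer(clusterer)
    rng = np.random.default_rng(rng)
    full_labels, _ = clusterer(d, k)
    originals = [set(np.nonzero(full_labels == c)[0].tolist())
                 for c in range(1, k + 1)]
    acc = np.zeros(k)
    effective = 0
    for _ in range(boot_reps):
        idx = np.sort(rng.integers(0, n, size=n))
        distinct = set(idx.tolist())
        if len(distinct) < k:
            logger.warning("bootstrap resample has %d < %d distinct samples; skipped",
                           len(distinct), k)
            continue
        lab, _ = clusterer(d[np.ix_(idx, idx)], k)
        if counter is not None:
            counter.add_clusterings(1)
        resampled = [set(idx[lab == c].tolist()) for c in range(1, k + 1)]
        effective += 1
        for ci, orig in enumerate(originals):
            restricted = orig & distinct
            best = 0.0
            for res in resampled:
                inter = len(restricted & res)
                union = len(restricted | res)
                if union and inter / union > best:
                    best = inter / union
            acc[ci] += best
    if effective == 0:
        raise ValueError("all bootstrap resamples degenerate; cannot score")
    per_cluster = tuple(float(x) for x in acc / effective)
    return per_cluster, float(np.mean(per_cluster))


def assess_combination(table, metric_id: str, algorithm_id: str, k: int,
                       config, D: DistanceMatrix | None = None,
                       rng=None, counter=None) -> AssessmentRecord:
    """Full assessment (SI + PS + Jaccard) of one grid combination."""
    from .beta_diversity import distance_matrix

    if D is None:
        D = distance_matrix(table, metric_id)
    clusterer = make_clusterer(algorithm_id)
    labels, _ = clusterer(D.values, k)
    if counter is not None:
        counter.add_scored(1)  # the silhouette-scored full clustering
        counter.add_clusterings(1)
    si = average_silhouette(D, labels)
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    ps = prediction_strength(
        D, k, clusterer, reps=config.ps_reps, rng=rng,
        aggregation=config.ps_aggregation, counter=counter)
    if counter is not None:
        counter.add_scored(config.ps_reps)
    jac_pc, jac = jaccard_stability(
        D, k, clusterer, boot_reps=config.boot_reps, rng=rng, counter=counter)
    if counter is not None:
        counter.add_scored(config.boot_reps)
    sizes = tuple(int(x) for x in np.bincount(labels, minlength=k + 1)[1:])
    return AssessmentRecord(
        algorithm_id=algorithm_id, metric_id=metric_id, k=k, si=si,
        labels=labels, cluster_sizes=sizes,
        ps_mean=ps, ps_reps=config.ps_reps,
        jaccard_per_cluster=jac_pc, jaccard_mean=jac, boot_reps=config.boot_reps,
    )
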