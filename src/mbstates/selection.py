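"""Assessment grid and the three-criterion robust-state decision algorithm.

The grid evaluates every (algorithm, distance, k) combination; selection then
scans metric pairs ranked by average silhouette and accepts the first
candidate whose prediction strength or bootstrap Jaccard stability clears its
threshold, subject to a minimum-cluster-size gate.  An explicit ``none``
outcome with the full decision trail is a first-class result.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .beta_diversity import METRICS, DistanceMatrix, distance_matrix
from .clustering import make_clusterer
from .validation import (
    AssessmentRecord,
    assess_combination,
    average_silhouette,
    jaccard_stability,
    prediction_strength,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "RobustStates",
    "ExecutionCounter",
    "GridResult",
    "evaluate_grid",
    "select_states",
    "run_pipeline",
    "records_to_dataframe",
]

DEFAULT_METRICS = ("jsd", "rjsd", "braycurtis", "morisitahorn", "kulczynski")
DEFAULT_ALGORITHMS = ("pam", "hclust")


@dataclass
class SelectionConfig:
    """Tunable constants of the grid and the decision algorithm."""

    k_min: int = 2
    k_max: int = 10
    metrics: tuple[str, ...] = DEFAULT_METRICS
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    si_threshold: float = 0.25
    ps_threshold: float = 0.80
    jaccard_threshold: float = 0.75
    ps_reps: int = 100
    boot_reps: int = 100
    min_cluster_size: int = 5
    rng_seed: int = 0
    ps_aggregation: str = "min"          # "min" | "global"
    jaccard_aggregation: str = "mean"    # "mean" | "min"
    si_both_members: bool = True         # both pair members must clear SI
    gate_both_members: bool = False      # gate PS/Jaccard on both members

    def __post_init__(self) -> None:
        for name in ("si_threshold", "ps_threshold", "jaccard_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.ps_reps < 1 or self.boot_reps < 1:
            raise ValueError("repetition counts must be >= 1")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        unknown = set(self.algorithms) - set(DEFAULT_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    @property
    def k_values(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class RobustStates:
    """Outcome of the decision algorithm for one clustering algorithm."""

    outcome: str  # "selected" | "none"
    algorithm_id: str
    chosen_metric: str | None = None
    partner_metric: str | None = None
    k: int | None = None
    labels: np.ndarray | None = None
    sample_ids: list[str] | None = None
    si_pair_average: float | None = None
    ps_value: float | None = None
    jaccard_value: float | None = None
    decision_trail: list[dict] = field(default_factory=list)

    def trail_json(self) -> str:
        doc = {
            "outcome": self.outcome,
            "algorithm": self.algorithm_id,
            "chosen_metric": self.chosen_metric,
            "partner_metric": self.partner_metric,
            "k": self.k,
            "si_pair_average": self.si_pair_average,
            "ps_value": self.ps_value,
            "jaccard_value": self.jaccard_value,
            "decision_trail": self.decision_trail,
        }
        return json.dumps(doc, indent=2)


class ExecutionCounter:
    """Counts scored assessments and underlying clustering runs.

    ``scored`` follows the grid's accounting (one silhouette + one per
    PS repetition + one per bootstrap resample for each combination);
    ``clusterings`` counts every actual clustering call, which is larger
    because each PS repetition clusters four half-matrices.
    """

    def __init__(self) -> None:
        self.scored = 0
        self.clusterings = 0
        self.combinations = 0

    def add_scored(self, n: int) -> None:
        self.scored += n

    def add_clusterings(self, n: int) -> None:
        self.clusterings += n

    def add_combination(self) -> None:
        self.combinations += 1

    def as_dict(self) -> dict:
        return {"scored": self.scored, "clusterings": self.clusterings,
                "combinations": self.combinations}


class GridResult(list):
    """List of :class:`AssessmentRecord` with the counter and shared matrices."""

    def __init__(self, records, counter: ExecutionCounter,
                 distance_matrices: dict[str, DistanceMatrix]):
        super().__init__(records)
        self.counter = counter
        self.distance_matrices = distance_matrices

    @property
    def execution_count(self) -> int:
        return self.counter.scored


def _combo_rng(config: SelectionConfig, algorithm_id: str, metric_id: str,
               k: int) -> np.random.Generator:
    """Seed stream unique to one grid coordinate, independent of visit order."""
    alg = DEFAULT_ALGORITHMS.index(algorithm_id)
    met = DEFAULT_METRICS.index(metric_id)
    ss = np.random.SeedSequence([int(config.rng_seed), alg, met, k])
    return np.random.default_rng(ss)


def evaluate_grid(table, config: SelectionConfig | None = None,
                  eager: bool = True) -> GridResult:
    """Assess every (algorithm, metric, k) combination of the configured grid.

    With ``eager=True`` (the full procedure) every combination receives all
    three scores; with ``eager=False`` only the silhouette is computed and
    PS/Jaccard are left for lazy, on-demand scoring during selection.
    Distance matrices are computed once per metric and shared.  A failed
    combination yields a record with ``error`` set instead of being dropped.
    """
    config = config or SelectionConfig()
    if not table.normalized:
        raise ValueError("evaluate_grid requires a normalized table")
    if table.n_samples <= config.k_max:
        raise ValueError(
            f"n={table.n_samples} must exceed k_max={config.k_max}")
    counter = ExecutionCounter()
    dms = {m: distance_matrix(table, m) for m in config.metrics}
    records: list[AssessmentRecord] = []
    for algorithm_id in config.algorithms:
        clusterer = make_clusterer(algorithm_id)
        for metric_id in config.metrics:
            D = dms[metric_id]
            for k in config.k_values:
                counter.add_combination()
                try:
                    if eager:
                        rng = _combo_rng(config, algorithm_id, metric_id, k)
                        rec = assess_combination(
                            table, metric_id, algorithm_id, k, config,
                            D=D, rng=rng, counter=counter)
                    else:
                        labels, _ = clusterer(D.values, k)
                        counter.add_scored(1)
                        counter.add_clusterings(1)
                        si = average_silhouette(D, labels)
                        sizes = tuple(int(x) for x in
                                      np.bincount(labels, minlength=k + 1)[1:])
                        rec = AssessmentRecord(
                            algorithm_id=algorithm_id, metric_id=metric_id,
                            k=k, si=si, labels=labels, cluster_sizes=sizes)
                except Exception as exc:  # record, never silently drop
                    logger.warning("combination (%s, %s, k=%d) failed: %s",
                                   algorithm_id, metric_id, k, exc)
                    rec = AssessmentRecord(
                        algorithm_id=algorithm_id, metric_id=metric_id, k=k,
                        si=0.0, labels=np.ones(table.n_samples, dtype=int),
                        cluster_sizes=(table.n_samples,), error=str(exc))
                records.append(rec)
    return GridResult(records, counter, dms)


def _fill_scores(rec: AssessmentRecord, config: SelectionConfig,
                 D: DistanceMatrix, counter: ExecutionCounter | None) -> None:
    """Lazily compute PS and Jaccard for a silhouette-only record."""
    clusterer = make_clusterer(rec.algorithm_id)
    rng = _combo_rng(config, rec.algorithm_id, rec.metric_id, rec.k)
    # same per-combination stream order as the eager path: PS, then bootstrap
    rec.ps_mean = prediction_strength(
        D, rec.k, clusterer, reps=config.ps_reps, rng=rng,
        aggregation=config.ps_aggregation, counter=counter)
    rec.ps_reps = config.ps_reps
    if counter is not None:
        counter.add_scored(config.ps_reps)
    jac_pc, jac = jaccard_stability(
        D, rec.k, clusterer, boot_reps=config.boot_reps, rng=rng,
        counter=counter)
    rec.jaccard_per_cluster = jac_pc
    rec.jaccard_mean = jac
    rec.boot_reps = config.boot_reps
    if counter is not None:
        counter.add_scored(config.boot_reps)


def _jaccard_value(rec: AssessmentRecord, config: SelectionConfig) -> float:
    if config.jaccard_aggregation == "min":
        return float(min(rec.jaccard_per_cluster))
    return float(rec.jaccard_mean)


def select_states(records, config: SelectionConfig, algorithm_id: str,
                  distance_matrices: dict[str, DistanceMatrix] | None = None,
                  counter: ExecutionCounter | None = None) -> RobustStates:
    """Apply the three-criterion decision rule to one algorithm's records.

    Candidates are (unordered metric pair, k) tuples whose members both clear
    the silhouette threshold; they are ranked by pair-average silhouette
    (ties: smaller k, then lexicographic pair).  Scanning in rank order, the
    first candidate whose gating member passes the prediction-strength OR
    Jaccard threshold — and whose full-data partition has no cluster smaller
    than ``min_cluster_size`` — supplies the final labels.
    """
    recs = [r for r in records if r.algorithm_id == algorithm_id and r.error is None]
    if not recs:
        raise ValueError(f"no records for algorithm {algorithm_id!r}")
    by_key: dict[tuple[str, int], AssessmentRecord] = {
        (r.metric_id, r.k): r for r in recs}
    metrics_present = sorted({r.metric_id for r in recs})
    if len(metrics_present) < 2:
        raise ValueError("selection needs records for at least 2 metrics")

    candidates = []
    for k in sorted({r.k for r in recs}):
        for m1, m2 in itertools.combinations(metrics_present, 2):
            r1, r2 = by_key.get((m1, k)), by_key.get((m2, k))
            if r1 is None or r2 is None:
                continue
            avg = 0.5 * (r1.si + r2.si)
            if config.si_both_members:
                ok = r1.si > config.si_threshold and r2.si > config.si_threshold
            else:
                ok = avg > config.si_threshold
            if ok:
                candidates.append((avg, k, (m1, m2)))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    trail: list[dict] = []
    if not candidates:
        best = max(recs, key=lambda r: r.si)
        trail.append({
            "accepted": False,
            "reason": "no metric pair cleared the silhouette threshold",
            "si_threshold": config.si_threshold,
            "best_si": best.si,
            "best_combination": [best.metric_id, best.k],
        })
    for avg, k, (m1, m2) in candidates:
        r1, r2 = by_key[(m1, k)], by_key[(m2, k)]
        if r1.si != r2.si:
            lead, partner = (r1, r2) if r1.si > r2.si else (r2, r1)
        else:  # tie: lexicographically smaller metric leads
            lead, partner = (r1, r2) if r1.metric_id < r2.metric_id else (r2, r1)
        gated = [lead, partner] if config.gate_both_members else [lead]
        entry = {
            "pair": [m1, m2], "k": k, "si_average": avg,
            "si": {m1: r1.si, m2: r2.si}, "lead_metric": lead.metric_id,
        }
        accept = True
        for rec in gated:
            if rec.ps_mean is None:
                if distance_matrices is None:
                    raise ValueError(
                        "record lacks PS/Jaccard scores and no distance "
                        "matrices were provided for lazy scoring")
                _fill_scores(rec, config, distance_matrices[rec.metric_id], counter)
            jval = _jaccard_value(rec, config)
            ps_ok = rec.ps_mean > config.ps_threshold
            jac_ok = jval >= config.jaccard_threshold
            entry.setdefault("gates", {})[rec.metric_id] = {
                "ps": rec.ps_mean, "ps_pass": ps_ok,
                "jaccard": jval, "jaccard_pass": jac_ok,
            }
            if not (ps_ok or jac_ok):
                accept = False
                entry["reason"] = (
                    f"{rec.metric_id}: PS {rec.ps_mean:.3f} <= "
                    f"{config.ps_threshold} and Jaccard {jval:.3f} < "
                    f"{config.jaccard_threshold}")
                break
        if accept and min(lead.cluster_sizes) < config.min_cluster_size:
            accept = False
            entry["reason"] = (
                f"cluster of size {min(lead.cluster_sizes)} < "
                f"min_cluster_size {config.min_cluster_size}")
        entry["accepted"] = accept
        trail.append(entry)
        if accept:
            entry["reason"] = "all gates passed"
            return RobustStates(
                outcome="selected", algorithm_id=algorithm_id,
                chosen_metric=lead.metric_id, partner_metric=partner.metric_id,
                k=k, labels=lead.labels.copy(),
                sample_ids=None, si_pair_average=avg,
                ps_value=lead.ps_mean, jaccard_value=_jaccard_value(lead, config),
                decision_trail=trail)
    return RobustStates(outcome="none", algorithm_id=algorithm_id,
                        decision_trail=trail)


class PipelineResult(dict):
    """Mapping algorithm_id -> RobustStates, with grid records attached."""

    def __init__(self, states: dict, grid: GridResult):
        super().__init__(states)
        self.grid = grid

    @property
    def counter(self) -> ExecutionCounter:
        return self.grid.counter


def run_pipeline(table, config: SelectionConfig | None = None,
                 eager: bool = False) -> PipelineResult:
    """Evaluate the grid and select robust states for each algorithm.

    ``eager=True`` scores PS/Jaccard for every combination up front (the
    complete procedure, needed for full assessment graphics); the default
    lazy mode scores them only for candidates reached during the selection
    scan, which is much faster and decision-equivalent because each
    combination draws from its own coordinate-keyed random stream.
    """
    config = config or SelectionConfig()
    grid = evaluate_grid(table, config, eager=eager)
    states: dict[str, RobustStates] = {}
    for algorithm_id in config.algorithms:
        result = select_states(grid, config, algorithm_id,
                               distance_matrices=grid.distance_matrices,
                               counter=grid.counter)
        if result.outcome == "selected":
            result.sample_ids = list(table.sample_ids)
        states[algorithm_id] = result
    return PipelineResult(states, grid)


def records_to_dataframe(records):
    """Tidy table of assessment records (one row per combination)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "algorithm": r.algorithm_id, "metric": r.metric_id, "k": r.k,
            "si": r.si, "ps_mean": r.ps_mean, "ps_reps": r.ps_reps,
            "jaccard_mean": r.jaccard_mean, "boot_reps": r.boot_reps,
            "cluster_sizes": ";".join(map(str, r.cluster_sizes)),
            "error": r.error,
        })
    return pd.DataFrame(rows)
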