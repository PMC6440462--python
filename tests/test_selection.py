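import numpy as np
import pytest

from mbstates import SelectionConfig, generate_states_dataset, run_pipeline
from mbstates.selection import (
    DEFAULT_METRICS,
    evaluate_grid,
    select_states,
)
from mbstates.synthetic import SyntheticSpec
from mbstates.validation import AssessmentRecord


def make_record(metric, k, si, ps=0.0, jaccard=0.0, n=30, sizes=None,
                algorithm="pam"):
    """Hand-built assessment record with a balanced partition by default."""
    if sizes is None:
        base = n // k
        sizes = [base + (1 if i < n % k else 0) for i in range(k)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    return AssessmentRecord(
        algorithm_id=algorithm, metric_id=metric, k=k, si=si,
        labels=labels, cluster_sizes=tuple(sizes),
        ps_mean=ps, ps_reps=100,
        jaccard_per_cluster=tuple([jaccard] * k), jaccard_mean=jaccard,
        boot_reps=100)


def full_record_set(si_map, ps_map=None, jaccard_map=None, sizes_map=None):
    """Records for all 5 metrics x k=2..10; unspecified SI default 0.1."""
    ps_map = ps_map or {}
    jaccard_map = jaccard_map or {}
    sizes_map = sizes_map or {}
    records = []
    for metric in DEFAULT_METRICS:
        for k in range(2, 11):
            records.append(make_record(
                metric, k,
                si=si_map.get((metric, k), 0.10),
                ps=ps_map.get((metric, k), 0.0),
                jaccard=jaccard_map.get((metric, k), 0.0),
                sizes=sizes_map.get((metric, k)),
            ))
    return records


CONFIG = SelectionConfig(rng_seed=0)


class TestSelectStates:
    def test_fig1_narrative(self):
        """Top SI pair at k=3 is {jsd, rjsd}; jsd leads and passes PS."""
        records = full_record_set(
            si_map={("jsd", 3): 0.60, ("rjsd", 3): 0.58,
                    ("braycurtis", 3): 0.20, ("morisitahorn", 3): 0.20,
                    ("kulczynski", 3): 0.20},
            ps_map={("jsd", 3): 0.95},
        )
        out = select_states(records, CONFIG, "pam")
        assert out.outcome == "selected"
        assert out.k == 3
        assert out.chosen_metric == "jsd"
        assert out.partner_metric == "rjsd"
        assert out.si_pair_average == pytest.approx(0.59)
        assert out.ps_value == pytest.approx(0.95)
        # labels come from the jsd record
        assert np.array_equal(out.labels, records[1].labels)

    def test_all_si_below_threshold_gives_none(self):
        records = full_record_set(si_map={})  # everything at 0.10
        out = select_states(records, CONFIG, "pam")
        assert out.outcome == "none"
        assert len(out.decision_trail) == 1
        assert "silhouette" in out.decision_trail[0]["reason"]

    def test_fallback_to_next_candidate(self):
        """Top pair fails both gates; second pair passes via Jaccard."""
        records = full_record_set(
            si_map={("jsd", 3): 0.60, ("rjsd", 3): 0.58,
                    ("braycurtis", 4): 0.50, ("morisitahorn", 4): 0.45},
            ps_map={("jsd", 3): 0.50},
            jaccard_map={("jsd", 3): 0.60, ("braycurtis", 4): 0.80},
        )
        out = select_states(records, CONFIG, "pam")
        assert out.outcome == "selected"
        assert out.k == 4
        assert out.chosen_metric == "braycurtis"
        # first scanned candidate is recorded as rejected
        first = out.decision_trail[0]
        assert first["accepted"] is False
        assert first["k"] == 3 and set(first["pair"]) == {"jsd", "rjsd"}
        assert out.decision_trail[-1]["accepted"] is True

    def test_min_cluster_size_gate(self):
        records = full_record_set(
            si_map={("jsd", 3): 0.60, ("rjsd", 3): 0.58},
            ps_map={("jsd", 3): 0.95},
            sizes_map={("jsd", 3): [24, 3, 3]},
        )
        out = select_states(records, CONFIG, "pam")
        assert out.outcome == "none"
        assert "min_cluster_size" in out.decision_trail[0]["reason"]

    def test_jaccard_threshold_inclusive_ps_exclusive(self):
        records = full_record_set(
            si_map={("jsd", 2): 0.60, ("rjsd", 2): 0.58},
            ps_map={("jsd", 2): 0.80},       # not strictly above
            jaccard_map={("jsd", 2): 0.75},  # exactly at threshold: passes
        )
        out = select_states(records, CONFIG, "pam")
        assert out.outcome == "selected"
        gates = out.decision_trail[0]["gates"]["jsd"]
        assert gates["ps_pass"] is False
        assert gates["jaccard_pass"] is True

    def test_rank_tie_prefers_smaller_k(self):
        records = full_record_set(
            si_map={("jsd", 5): 0.60, ("rjsd", 5): 0.60,
                    ("jsd", 2): 0.60, ("rjsd", 2): 0.60},
            ps_map={("jsd", 2): 0.9, ("jsd", 5): 0.9},
        )
        out = select_states(records, CONFIG, "pam")
        assert out.k == 2

    def test_si_average_rule_configurable(self):
        # pair average 0.30 but one member below 0.25
        records = full_record_set(
            si_map={("jsd", 2): 0.45, ("rjsd", 2): 0.15},
            ps_map={("jsd", 2): 0.9},
        )
        assert select_states(records, CONFIG, "pam").outcome == "none"
        loose = SelectionConfig(si_both_members=False)
        assert select_states(records, loose, "pam").outcome == "selected"

    def test_gate_both_members_configurable(self):
        records = full_record_set(
            si_map={("jsd", 2): 0.60, ("rjsd", 2): 0.58},
            ps_map={("jsd", 2): 0.95},  # partner rjsd fails both gates
        )
        assert select_states(records, CONFIG, "pam").outcome == "selected"
        strict = SelectionConfig(gate_both_members=True)
        assert select_states(records, strict, "pam").outcome == "none"

    def test_monotone_in_si_threshold(self):
        """Lowering the SI threshold never shrinks the candidate set."""
        rng = np.random.default_rng(0)
        si_map = {(m, k): float(rng.uniform(0, 0.6))
                  for m in DEFAULT_METRICS for k in range(2, 11)}
        records = full_record_set(si_map=si_map)  # all gates fail -> full scan
        lo = select_states(records, SelectionConfig(si_threshold=0.10), "pam")
        hi = select_states(records, SelectionConfig(si_threshold=0.40), "pam")
        lo_cands = {(tuple(e["pair"]), e["k"]) for e in lo.decision_trail if "pair" in e}
        hi_cands = {(tuple(e["pair"]), e["k"]) for e in hi.decision_trail if "pair" in e}
        assert hi_cands <= lo_cands

    def test_raising_gates_never_creates_selection(self):
        records = full_record_set(
            si_map={("jsd", 3): 0.60, ("rjsd", 3): 0.58},
            ps_map={("jsd", 3): 0.85},
            jaccard_map={("jsd", 3): 0.80},
        )
        assert select_states(records, CONFIG, "pam").outcome == "selected"
        strict = SelectionConfig(ps_threshold=0.99, jaccard_threshold=0.99)
        assert select_states(records, strict, "pam").outcome == "none"

    def test_deterministic(self):
        records = full_record_set(
            si_map={("jsd", 3): 0.60, ("rjsd", 3): 0.58},
            ps_map={("jsd", 3): 0.95})
        a = select_states(records, CONFIG, "pam")
        b = select_states(records, CONFIG, "pam")
        assert a.decision_trail == b.decision_trail

    def test_empty_records_error(self):
        with pytest.raises(ValueError, match="no records"):
            select_states([], CONFIG, "pam")

    def test_needs_two_metrics(self):
        records = [make_record("jsd", k, 0.5) for k in range(2, 5)]
        with pytest.raises(ValueError, match="2 metrics"):
            select_states(records, CONFIG, "pam")


class TestSelectionConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SelectionConfig(si_threshold=1.5)

    def test_k_range(self):
        with pytest.raises(ValueError):
            SelectionConfig(k_min=1)
        with pytest.raises(ValueError):
            SelectionConfig(k_min=5, k_max=3)

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="unknown metrics"):
            SelectionConfig(metrics=("jsd", "unifrac"))

    def test_reps_positive(self):
        with pytest.raises(ValueError):
            SelectionConfig(ps_reps=0)


@pytest.fixture(scope="module")
def small_planted():
    spec = SyntheticSpec(n_states=2, samples_per_state=8, n_taxa=40,
                         separation=50.0, depth=5000, seed=5)
    return generate_states_dataset(spec)


class TestEvaluateGrid:
    def test_restricted_cardinality(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd",), algorithms=("pam",),
                                 k_min=2, k_max=3, ps_reps=2, boot_reps=2)
        grid = evaluate_grid(table, config)
        assert len(grid) == 2
        assert {(r.metric_id, r.k) for r in grid} == {("jsd", 2), ("jsd", 3)}

    def test_counter_accounting(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd", "braycurtis"),
                                 algorithms=("pam",), k_min=2, k_max=4,
                                 ps_reps=3, boot_reps=2)
        grid = evaluate_grid(table, config)
        assert len(grid) == 6
        assert grid.execution_count == 6 * (1 + 3 + 2)

    def test_lazy_mode_scores_si_only(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd", "rjsd"), algorithms=("pam",),
                                 k_min=2, k_max=3, ps_reps=2, boot_reps=2)
        grid = evaluate_grid(table, config, eager=False)
        assert all(r.ps_mean is None for r in grid)
        assert grid.execution_count == 4

    def test_requires_enough_samples(self, small_planted):
        table, _ = small_planted
        with pytest.raises(ValueError, match="must exceed"):
            evaluate_grid(table, SelectionConfig(k_max=table.n_samples))

    def test_config_passthrough(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd", "rjsd"), algorithms=("pam",),
                                 k_min=2, k_max=2, ps_reps=5, boot_reps=4)
        grid = evaluate_grid(table, config)
        assert all(r.ps_reps == 5 and r.boot_reps == 4 for r in grid)


class TestRunPipeline:
    def test_planted_recovery(self, small_planted):
        table, truth = small_planted
        config = SelectionConfig(ps_reps=10, boot_reps=10, rng_seed=3,
                                 k_max=5)
        result = run_pipeline(table, config)
        states = result["pam"]
        assert states.outcome == "selected"
        assert states.k == 2
        assert states.sample_ids == table.sample_ids
        # labels agree with truth as a partition
        canon = {}
        for t, l in zip(truth, states.labels):
            canon.setdefault(t, l)
            assert canon[t] == l

    def test_lazy_and_eager_agree(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd", "braycurtis"), k_max=4,
                                 algorithms=("pam",), ps_reps=5, boot_reps=5,
                                 rng_seed=9)
        lazy = run_pipeline(table, config, eager=False)["pam"]
        eager = run_pipeline(table, config, eager=True)["pam"]
        assert lazy.outcome == eager.outcome
        assert lazy.k == eager.k
        assert lazy.chosen_metric == eager.chosen_metric
        assert lazy.ps_value == eager.ps_value
        assert lazy.jaccard_value == eager.jaccard_value

    def test_null_data_gives_none(self):
        spec = SyntheticSpec(n_states=1, samples_per_state=40, n_taxa=60,
                             separation=0.0, depth=5000, seed=11)
        table, _ = generate_states_dataset(spec)
        config = SelectionConfig(ps_reps=5, boot_reps=5, rng_seed=11)
        result = run_pipeline(table, config)
        assert result["pam"].outcome == "none"
        assert result["hclust"].outcome == "none"

    def test_per_algorithm_results(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(ps_reps=3, boot_reps=3, k_max=4, rng_seed=1)
        result = run_pipeline(table, config)
        assert set(result) == {"pam", "hclust"}
        for alg, states in result.items():
            assert states.algorithm_id == alg

    def test_trail_restricted_to_configured_grid(self, small_planted):
        table, _ = small_planted
        config = SelectionConfig(metrics=("jsd", "rjsd"), algorithms=("pam",),
                                 k_min=2, k_max=2, ps_reps=2, boot_reps=2)
        result = run_pipeline(table, config)
        trail = result["pam"].decision_trail
        assert all(e.get("k") == 2 for e in trail if "k" in e)
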