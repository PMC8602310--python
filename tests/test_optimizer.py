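"""Two-stage optimizer: LHS, NSGA-II, incumbent selection, SQP refinement.

Mock evaluators with known optima exercise the optimization machinery
without finite-element solves; the end-to-end inverse-crime recovery lives
in the experiments and acceptance suites.
"""

import numpy as np
import pytest

from plaquemech.constitutive import pack
from plaquemech.objective import InterfaceError, ObjectiveValue
from plaquemech.optimizer import (
    OptimizerConfig,
    RunTrace,
    _nondominated_sort,
    diverse_runner_ups,
    lhs_sample,
    nsga2_stage,
    select_incumbent,
    sqp_refine,
)


def make_objective(values: np.ndarray) -> ObjectiveValue:
    return ObjectiveValue(
        errors=tuple(
            InterfaceError(pair=(f"e{i}",), value=float(v), n_target=1, n_deformed=1)
            for i, v in enumerate(values)
        )
    )


class QuadraticEvaluator:
    """Smooth two-component objective with minimum at a known point."""

    n_objectives = 2

    def __init__(self, x_true):
        self.x_true = np.asarray(x_true)

    def __call__(self, pv):
        d = pv.to_scaled() - self.x_true
        half = len(d) // 2 or 1
        return make_objective(
            np.array([np.sum(d[:half] ** 2), np.sum(d[half:] ** 2)])
        )


class ConeEvaluator:
    """Norm-like objective resembling the interface error near its optimum."""

    n_objectives = 3

    def __init__(self, x_true, seed=0):
        self.x_true = np.asarray(x_true)
        rng = np.random.default_rng(seed)
        self.A = [rng.normal(size=(4, len(x_true))) for _ in range(3)]

    def __call__(self, pv):
        d = pv.to_scaled() - self.x_true
        return make_objective(np.array([np.linalg.norm(a @ d) for a in self.A]))


@pytest.fixture
def template(bounds):
    return pack(bounds, "linear")


class TestLHS:
    def test_single_sample_in_bounds(self, template):
        (pv,) = lhs_sample(template, 1, seed=0)
        assert np.all((0 <= pv.to_scaled()) & (pv.to_scaled() <= 1))

    def test_stratification_per_dimension(self, template):
        n = 24
        X = np.array([p.to_scaled() for p in lhs_sample(template, n, seed=7)])
        for d in range(template.n_free):
            strata = np.floor(X[:, d] * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_deterministic_for_fixed_seed(self, template):
        a = lhs_sample(template, 8, seed=3)
        b = lhs_sample(template, 8, seed=3)
        assert all(
            np.array_equal(x.free_values(), y.free_values()) for x, y in zip(a, b)
        )

    def test_invalid_count_rejected(self, template):
        with pytest.raises(ValueError):
            lhs_sample(template, 0, seed=0)


class TestNSGA2:
    def test_trace_length_is_population_times_generations_plus_initial(self, template):
        cfg = OptimizerConfig(population=10, generations=4, seed=0)
        trace = nsga2_stage(QuadraticEvaluator([0.4, 0.6, 0.5, 0.5]), template, cfg)
        assert len(trace) == 10 * (4 + 1)

    def test_best_total_nonincreasing_over_generations(self, template):
        cfg = OptimizerConfig(population=12, generations=6, seed=1)
        trace = nsga2_stage(QuadraticEvaluator([0.3, 0.3, 0.7, 0.7]), template, cfg)
        best_by_gen = []
        for g in range(7):
            recs = [r for r in trace.records if r.stage == f"nsga2-g{g}"]
            best_by_gen.append(min(r.total for r in recs))
        running = np.minimum.accumulate(best_by_gen)
        assert running[-1] <= running[0]
        assert running[-1] < 0.05  # the search actually closes in

    def test_final_population_mutually_nondominated(self, template):
        """Exhaustive pairwise domination check on the last generation's
        survivors (reconstructed as the best-ranked of the final pool)."""
        cfg = OptimizerConfig(population=12, generations=5, seed=2)
        ev = ConeEvaluator([0.5, 0.5, 0.5, 0.5])
        trace = nsga2_stage(ev, template, cfg)
        F = np.array([r.objectives for r in trace.records])
        fronts = _nondominated_sort(F)
        first = F[fronts[0]]
        for i in range(len(first)):
            for j in range(len(first)):
                if i != j:
                    dominates = np.all(first[i] <= first[j]) and np.any(
                        first[i] < first[j]
                    )
                    assert not dominates

    def test_all_evaluations_within_bounds(self, template):
        cfg = OptimizerConfig(population=10, generations=5, seed=3)
        trace = nsga2_stage(QuadraticEvaluator([0.2, 0.8, 0.5, 0.1]), template, cfg)
        X = np.array([r.x_scaled for r in trace.records])
        assert np.all((0 <= X) & (X <= 1))
        for r in trace.records:
            pv = template.with_scaled(r.x_scaled)
            for e in pv.free_entries:
                assert e.bounds[0] <= e.value <= e.bounds[1]

    def test_deterministic_trace_for_fixed_seed(self, template):
        cfg = OptimizerConfig(population=8, generations=3, seed=11)
        t1 = nsga2_stage(QuadraticEvaluator([0.5] * 4), template, cfg)
        t2 = nsga2_stage(QuadraticEvaluator([0.5] * 4), template, cfg)
        assert all(
            np.array_equal(a.x_scaled, b.x_scaled)
            and np.array_equal(a.objectives, b.objectives)
            for a, b in zip(t1.records, t2.records)
        )

    def test_failed_evaluations_get_infinite_fitness(self, template):
        class Flaky:
            n_objectives = 2
            count = 0

            def __call__(self, pv):
                self.count += 1
                if self.count % 5 == 0:
                    raise ValueError("synthetic failure")
                return make_objective(np.array([1.0, 2.0]))

        cfg = OptimizerConfig(population=6, generations=2, seed=4)
        trace = nsga2_stage(Flaky(), template, cfg)
        infs = [r for r in trace.records if not np.isfinite(r.total)]
        assert len(infs) > 0
        assert all(np.all(np.isinf(r.objectives)) for r in infs)


class TestIncumbent:
    def test_minimum_row_selected(self, template):
        trace = RunTrace()
        totals = [3.0, 1.0, 2.0]
        for i, t in enumerate(totals):
            from plaquemech.optimizer import TraceRecord

            trace.append(
                TraceRecord(
                    stage="nsga2-g0",
                    index=i,
                    x_scaled=np.full(4, 0.1 * (i + 1)),
                    values=np.zeros(4),
                    objectives=np.array([t / 2, t / 2]),
                )
            )
        inc = select_incumbent(trace, template)
        assert np.allclose(inc.to_scaled(), 0.2)

    def test_tie_goes_to_earliest_evaluation(self, template):
        from plaquemech.optimizer import TraceRecord

        trace = RunTrace()
        for i in range(3):
            trace.append(
                TraceRecord(
                    stage="s",
                    index=i,
                    x_scaled=np.full(4, 0.1 * (i + 1)),
                    values=np.zeros(4),
                    objectives=np.array([1.0]),
                )
            )
        assert trace.best_index() == 0

    def test_incumbent_not_worse_than_final_front(self, template):
        cfg = OptimizerConfig(population=10, generations=4, seed=5)
        trace = nsga2_stage(ConeEvaluator([0.4] * 4), template, cfg)
        inc_total = trace.records[trace.best_index()].total
        last_gen = [r.total for r in trace.records if r.stage == "nsga2-g4"]
        assert inc_total <= min(last_gen)


class TestSQPRefine:
    def test_immediate_stop_at_optimum_of_quadratic(self, template):
        x_true = np.array([0.3, 0.7, 0.5, 0.2])
        ev = QuadraticEvaluator(x_true)
        start = template.with_scaled(x_true)
        cfg = OptimizerConfig(sqp_max_evals=40, seed=0)
        y, info = sqp_refine(ev, start, cfg)
        assert np.allclose(y.to_scaled(), x_true, atol=1e-6)
        assert info["n_simulations"] < cfg.sqp_max_evals * 5

    def test_recovers_quadratic_minimum(self, template):
        # squared-distance residuals halve per Gauss-Newton step (linear
        # rate), so the budget covers enough iterations to converge
        x_true = np.array([0.31, 0.62, 0.55, 0.18])
        ev = QuadraticEvaluator(x_true)
        start = template.with_scaled(np.array([0.9, 0.1, 0.2, 0.9]))
        cfg = OptimizerConfig(sqp_max_evals=120, seed=0)
        y, _ = sqp_refine(ev, start, cfg)
        assert np.allclose(y.to_scaled(), x_true, atol=1e-4)

    def test_bound_active_minimum_lands_on_bound(self, template):
        class OutsideBox:
            n_objectives = 1

            def __call__(self, pv):
                d = pv.to_scaled() - np.array([1.3, 0.5, 0.5, 0.5])
                return make_objective(np.array([np.sum(d**2)]))

        start = template.with_scaled(np.full(4, 0.5))
        y, _ = sqp_refine(OutsideBox(), start, OptimizerConfig(seed=0))
        x = y.to_scaled()
        assert x[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(x[1:], 0.5, atol=1e-6)

    def test_monotone_decrease_and_budget(self, template):
        x_true = np.full(4, 0.42)
        ev = ConeEvaluator(x_true)
        start = template.with_scaled(np.array([0.9, 0.15, 0.6, 0.3]))
        cfg = OptimizerConfig(sqp_max_evals=15, seed=0)
        trace = RunTrace()
        y, info = sqp_refine(ev, start, cfg, trace=trace)
        n = template.n_free
        assert info["n_simulations"] <= cfg.sqp_max_evals * (n + 1)
        assert ev(y).total <= ev(start).total
        X = np.array([r.x_scaled for r in trace.records])
        assert np.all((0 <= X) & (X <= 1))

    def test_cone_objective_converges(self, template):
        """The norm-like objective characteristic of interface matching is
        driven to its exact zero."""
        x_true = np.array([0.37, 0.63, 0.51, 0.44])
        ev = ConeEvaluator(x_true, seed=1)
        start = template.with_scaled(np.full(4, 0.8))
        y, _ = sqp_refine(ev, start, OptimizerConfig(sqp_max_evals=40, seed=0))
        assert np.allclose(y.to_scaled(), x_true, atol=1e-4)

    def test_deterministic_from_fixed_start(self, template):
        ev = ConeEvaluator(np.full(4, 0.42))
        start = template.with_scaled(np.array([0.9, 0.15, 0.6, 0.3]))
        cfg = OptimizerConfig(seed=0)
        y1, _ = sqp_refine(ev, start, cfg)
        y2, _ = sqp_refine(ev, start, cfg)
        assert np.array_equal(y1.free_values(), y2.free_values())


class TestRunnerUps:
    def test_runner_ups_are_distant_from_incumbent(self, template):
        cfg = OptimizerConfig(population=16, generations=4, seed=6)
        trace = nsga2_stage(ConeEvaluator([0.5] * 4), template, cfg)
        inc = trace.records[trace.best_index()].x_scaled
        extras = diverse_runner_ups(trace, k=2, min_dist=0.25)
        assert len(extras) == 2
        for e in extras:
            assert np.linalg.norm(e - inc) >= 0.25
        assert np.linalg.norm(extras[0] - extras[1]) >= 0.25
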