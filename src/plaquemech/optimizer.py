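"""Two-stage material-parameter optimization.

Stage 1 is a global multi-objective search with NSGA-II (elitist
non-dominated sorting genetic algorithm) over the vector of interface
errors, initialized by Latin hypercube sampling in the log-scaled parameter
box. The individual with the minimum *sum* of interface errors across all
generations — not just the final front — seeds stage 2, a bound-constrained
sequential-quadratic-programming refinement of the scalar objective using
forward finite-difference gradients (each function evaluation thus costs
n + 1 simulations for n free parameters).

All stochastic steps are driven by a single seed; the complete evaluation
history is recorded in a :class:`RunTrace` from which the incumbent and the
final answer are reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .constitutive import BoundsTable, ParameterVector, pack
from .forward_fe import (
    ForwardEvaluator,
    LoadCase,
    SimulationError,
    SolverSettings,
)
from .geometry import LabeledMesh
from .objective import ObjectiveMode, ObjectiveValue


@dataclass(frozen=True)
class OptimizerConfig:
    """Budgets and operator constants of the two optimization stages.

    Defaults mirror the verification protocol: a population of 24 propagated
    over 7 generations (linear mode; 24 for the Yeoh mode), then SQP with at
    most 40 function evaluations and a termination residual of 1e-9.
    Crossover/mutation constants are the canonical NSGA-II choices
    (simulated binary crossover, polynomial mutation) applied in scaled
    space.
    """

    population: int = 24
    generations: int = 7
    sqp_max_evals: int = 40
    sqp_residual: float = 1e-9
    fd_step: float = 3e-4
    seed: int = 0
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0

    def __post_init__(self) -> None:
        if self.population < 1 or self.generations < 1 or self.sqp_max_evals < 1:
            raise ValueError("optimizer budgets must be >= 1")
        if self.sqp_residual <= 0 or self.fd_step <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class TraceRecord:
    """One evaluated parameter vector."""

    stage: str
    index: int
    x_scaled: np.ndarray
    values: np.ndarray
    objectives: np.ndarray  # interface-error vector (inf on failure)

    @property
    def total(self) -> float:
        return float(self.objectives.sum())


class RunTrace:
    """Append-only log of every evaluation of a recovery run."""

    def __init__(self, seed: int | None = None):
        self.records: list[TraceRecord] = []
        self.seed = seed

    def append(self, rec: TraceRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def best_index(self) -> int:
        """Index of the evaluation with minimum objective sum (earliest on
        ties)."""
        if not self.records:
            raise ValueError("empty trace")
        totals = np.array([r.total for r in self.records])
        return int(np.argmin(totals))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            row = {"eval": i, "stage": r.stage, "index": r.index, "total": r.total}
            row.update({f"x{j}": v for j, v in enumerate(r.x_scaled)})
            row.update({f"p{j}": v for j, v in enumerate(r.values)})
            row.update({f"err{j}": v for j, v in enumerate(r.objectives)})
            rows.append(row)
        return pd.DataFrame(rows)

    def simulation_count(self) -> int:
        return len(self.records)


class _TracedEvaluator:
    """Wraps the user evaluator: records every call, maps failures to +inf
    objectives, and enforces a consistent objective-vector length."""

    def __init__(self, evaluator, template: ParameterVector, trace: RunTrace):
        self.evaluator = evaluator
        self.template = template
        self.trace = trace
        self.n_obj: int | None = getattr(evaluator, "n_objectives", None)

    def __call__(self, x_scaled: np.ndarray, stage: str, index: int) -> np.ndarray:
        pv = self.template.with_scaled(x_scaled)
        try:
            value: ObjectiveValue = self.evaluator(pv)
            objs = value.vector
            if self.n_obj is None:
                self.n_obj = len(objs)
        except (SimulationError, FloatingPointError, ValueError):
            objs = np.full(self.n_obj or 1, np.inf)
        self.trace.append(
            TraceRecord(
                stage=stage,
                index=index,
                x_scaled=np.array(x_scaled, dtype=float),
                values=pv.free_values(),
                objectives=np.asarray(objs, dtype=float),
            )
        )
        return np.asarray(objs, dtype=float)


# --------------------------------------------------------------------------
# Latin hypercube sampling
# --------------------------------------------------------------------------


def lhs_sample(template: ParameterVector, n: int, seed: int) -> list[ParameterVector]:
    """Space-filling Latin hypercube sample of ``n`` parameter vectors.

    Stratification holds per dimension in scaled (log) space: exactly one
    sample falls in each of the n equal-probability strata.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = template.n_free
    if d == 0:
        raise ValueError("parameter vector has no free entries")
    x = qmc.LatinHypercube(d=d, seed=seed).random(n)
    return [template.with_scaled(row) for row in x]


# --------------------------------------------------------------------------
# NSGA-II
# --------------------------------------------------------------------------


def _nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sort (minimization); returns fronts as index
    arrays, best first."""
    n = len(F)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(F[i] <= F[j]) and np.any(F[i] < F[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif np.all(F[j] <= F[i]) and np.any(F[j] < F[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.where(dom_count == 0)[0]
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=int)
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        dist[order[0]] = dist[order[-1]] = np.inf
        # skip degenerate spans (identical or non-finite objective columns)
        if n > 2 and np.isfinite(fk[0]) and np.isfinite(fk[-1]) and fk[-1] > fk[0]:
            finite_mid = np.where(np.isfinite(fk[2:]), fk[2:], fk[-1])
            dist[order[1:-1]] += (finite_mid - fk[:-2]) / (fk[-1] - fk[0])
    return dist


def _sbx_crossover(
    p1: np.ndarray, p2: np.ndarray, eta: float, prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0, 1] variables."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for k in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[k] - p2[k]) < 1e-14:
            continue
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (
            1 / (2 * (1 - u))
        ) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        c2[k] = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _polynomial_mutation(
    x: np.ndarray, eta: float, prob: float, rng: np.random.Generator
) -> np.ndarray:
    y = x.copy()
    for k in range(len(x)):
        if rng.random() >= prob:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u + (1 - 2 * u) * (1 - y[k]) ** (eta + 1)) ** (
                1 / (eta + 1)
            ) - 1
        else:
            delta = 1 - (
                2 * (1 - u) + 2 * (u - 0.5) * y[k] ** (eta + 1)
            ) ** (1 / (eta + 1))
        y[k] = y[k] + delta
    return np.clip(y, 0, 1)


def _rank_and_crowding(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(_nondominated_sort(F)):
        rank[front] = r
        crowd[front] = _crowding_distance(F[front])
    return rank, crowd


def nsga2_stage(
    evaluator,
    template: ParameterVector,
    config: OptimizerConfig,
    trace: RunTrace | None = None,
) -> RunTrace:
    """Global NSGA-II search on the interface-error vector.

    The trace accumulates ``population * generations`` evaluations plus the
    initial Latin-hypercube population; the final population is mutually
    non-dominated (first fronts of the last environmental selection).
    """
    trace = trace if trace is not None else RunTrace(seed=config.seed)
    traced = evaluator if isinstance(evaluator, _TracedEvaluator) else _TracedEvaluator(
        evaluator, template, trace
    )
    rng = np.random.default_rng(config.seed)
    d = template.n_free
    pop = config.population
    X = qmc.LatinHypercube(d=d, seed=config.seed).random(pop)
    F = np.array([traced(x, "nsga2-g0", i) for i, x in enumerate(X)])
    # replace failures so domination comparisons stay meaningful
    F = np.nan_to_num(F, nan=np.inf)
    mut_prob = 1.0 / d
    for g in range(1, config.generations + 1):
        rank, crowd = _rank_and_crowding(F)

        def tourney() -> int:
            i, j = rng.integers(0, pop, size=2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < pop:
            a, b = X[tourney()], X[tourney()]
            c1, c2 = _sbx_crossover(a, b, config.crossover_eta, config.crossover_prob, rng)
            children.append(_polynomial_mutation(c1, config.mutation_eta, mut_prob, rng))
            if len(children) < pop:
                children.append(
                    _polynomial_mutation(c2, config.mutation_eta, mut_prob, rng)
                )
        CX = np.array(children)
        CF = np.array(
            [traced(x, f"nsga2-g{g}", i) for i, x in enumerate(CX)]
        )
        allX = np.vstack([X, CX])
        allF = np.vstack([F, CF])
        rank, crowd = _rank_and_crowding(allF)
        order = np.lexsort((-crowd, rank))
        keep = order[:pop]
        X, F = allX[keep], allF[keep]
    return trace


def select_incumbent(trace: RunTrace, template: ParameterVector) -> ParameterVector:
    """The evaluated individual with the minimum interface-error sum across
    the entire trace (earliest evaluation wins ties)."""
    rec = trace.records[trace.best_index()]
    return template.with_scaled(rec.x_scaled)


def diverse_runner_ups(
    trace: RunTrace, k: int = 2, min_dist: float = 0.25
) -> list[np.ndarray]:
    """Low-objective trace points separated from the incumbent and from
    each other — restart candidates covering distinct basins.

    Distances are weighted per dimension by the spread of the best trace
    points: directions along which good individuals scatter widely are the
    poorly determined ones, and that is exactly where restart diversity
    pays off (the weakly identifiable stiffening coefficients form long
    shallow valleys with secondary basins). The incumbent is excluded.
    """
    recs = sorted(
        (r for r in trace.records if np.isfinite(r.total)), key=lambda r: r.total
    )
    chosen: list[np.ndarray] = []
    if not recs:
        return chosen
    top = np.array([r.x_scaled for r in recs[: max(10, len(recs) // 10)]])
    w = top.std(axis=0)
    w = w / (w.max() + 1e-12)
    anchor = [recs[0].x_scaled]
    for r in recs[1:]:
        if all(
            np.linalg.norm((r.x_scaled - s) * w) >= min_dist for s in anchor + chosen
        ):
            chosen.append(r.x_scaled.copy())
        if len(chosen) == k:
            break
    return chosen


# --------------------------------------------------------------------------
# SQP refinement
# --------------------------------------------------------------------------


def _lm_descend(
    fvec,
    x0: np.ndarray,
    e0: np.ndarray,
    cap: int,
    counter: list[int],
    fd_rounds: tuple[float, ...],
    residual: float,
) -> tuple[np.ndarray, np.ndarray, str]:
    """One damped Gauss-Newton (Levenberg-Marquardt) descent.

    The model is least-squares in the interface-error vector; a trial step
    is accepted only when the error *sum* strictly decreases, so the scalar
    objective is monotone over the stage. The forward-difference step
    shrinks over ``fd_rounds`` as the iterate approaches the optimum (the
    nearest-node objective is norm-like, so the useful difference step
    tracks the distance to the minimizer). Stops on the residual rule
    (successive objective decrease below ``residual`` at the final
    difference step), on a stall, or on the simulation cap.
    """
    n = len(x0)
    x, e = x0.copy(), np.asarray(e0, dtype=float).copy()
    total = float(e.sum())
    lam = 1e-3
    fdi = 0
    fd = fd_rounds[0]
    while counter[0] < cap - (n + 2):
        J = np.empty((len(e), n))
        for k in range(n):
            xk = x.copy()
            h = fd if xk[k] + fd <= 1.0 else -fd
            xk[k] += h
            J[:, k] = (fvec(xk) - e) / h
        A = J.T @ J
        g = J.T @ e
        # damping scale: Marquardt diagonal floored at a fraction of its
        # maximum, so near-insensitive directions (whose finite-difference
        # column is curvature noise) stay bounded as the damping grows
        d0 = np.diag(A)
        diag = np.diag(np.maximum(d0, max(1e-3 * d0.max(), 1e-12)))
        improved = False
        while counter[0] < cap and lam < 1e9:
            try:
                v = np.linalg.solve(A + lam * diag, -g)
            except np.linalg.LinAlgError:
                break
            dx = v
            # geodesic acceleration: a second-order correction along the
            # step, invaluable in the curved narrow valleys produced by
            # stiffness-coefficient compensation (one extra simulation)
            if np.linalg.norm(v) > 1e-12 and counter[0] < cap:
                h2 = 0.1
                rv = fvec(np.clip(x + h2 * v, 0.0, 1.0))
                acc = (2.0 / h2) * ((rv - e) / h2 - J @ v)
                try:
                    a = np.linalg.solve(A + lam * diag, -(J.T @ acc) / 2.0)
                    if np.linalg.norm(a) < 0.75 * np.linalg.norm(v):
                        dx = v + 0.5 * a
                except np.linalg.LinAlgError:
                    pass
            if counter[0] >= cap:
                break
            xt = np.clip(x + dx, 0.0, 1.0)
            et = fvec(xt)
            tt = float(et.sum())
            if tt < total:
                gain = total - tt
                x, e, total = xt, et, tt
                lam = max(lam / 10.0, 1e-12)
                improved = True
                if gain < residual:
                    if fdi + 1 < len(fd_rounds):
                        fdi += 1
                        fd = fd_rounds[fdi]
                        lam = 1e-3
                    else:
                        return x, e, "residual"
                break
            lam *= 10.0
        if not improved:
            if fdi + 1 < len(fd_rounds):
                fdi += 1
                fd = fd_rounds[fdi]
                lam = 1e-3
            else:
                return x, e, "stalled"
    return x, e, "budget"


def sqp_refine(
    evaluator,
    start: ParameterVector,
    config: OptimizerConfig,
    trace: RunTrace | None = None,
    extra_starts: tuple[np.ndarray, ...] = (),
) -> tuple[ParameterVector, dict]:
    """Local refinement of the interface objective from the incumbent.

    The refinement is a sequential quadratic descent of Gauss-Newton type:
    the quadratic model is built from a forward finite-difference Jacobian
    of the interface-error vector (n simulations per model build, n + 1
    per accepted point — the least-squares structure of the error vector is
    what the quadratic model exploits), with Levenberg-Marquardt damping,
    projection onto the search bounds, and acceptance only on strict
    decrease of the scalar objective δ_SO. Stop rules: successive-objective
    residual below ``config.sqp_residual``, or the total simulation budget
    ``sqp_max_evals * (n + 1)``.

    ``extra_starts`` (scaled points, typically diverse runner-ups from the
    global stage) trigger additional descents within the same budget — a
    restart policy that guards against the secondary basins of the
    nearest-node objective; the best point over all descents is returned,
    so δ_SO never increases over the stage.
    """
    trace = trace if trace is not None else RunTrace(seed=config.seed)
    traced = evaluator if isinstance(evaluator, _TracedEvaluator) else _TracedEvaluator(
        evaluator, start, trace
    )
    n = start.n_free
    budget = config.sqp_max_evals * (n + 1)
    counter = [0]

    def fvec(x: np.ndarray) -> np.ndarray:
        counter[0] += 1
        v = traced(np.clip(x, 0.0, 1.0), "sqp", counter[0] - 1)
        return np.where(np.isfinite(v), v, 1e12)

    fd = config.fd_step
    fd_rounds = (fd, fd / 30.0, fd / 300.0)
    starts = [start.to_scaled()] + [np.asarray(s, dtype=float) for s in extra_starts]
    best: tuple[float, np.ndarray] | None = None
    stop = "budget"
    for idx, x0 in enumerate(starts):
        if counter[0] >= budget - (n + 2):
            break
        cap = counter[0] + (budget - counter[0]) // (len(starts) - idx)
        e0 = fvec(x0)
        x, e, stop = _lm_descend(
            fvec, x0, e0, cap, counter, fd_rounds, config.sqp_residual
        )
        tot = float(e.sum())
        if best is None or tot < best[0]:
            best = (tot, x)
    # polish from the overall best with any leftover budget
    if best is not None and counter[0] < budget - (n + 2):
        x, e, _ = _lm_descend(
            fvec,
            best[1],
            fvec(best[1]),
            budget,
            counter,
            fd_rounds[1:],
            config.sqp_residual,
        )
        if float(e.sum()) < best[0]:
            best = (float(e.sum()), x)
    assert best is not None
    info = {
        "stop": stop,
        "n_simulations": counter[0],
        "n_simulations_max": budget,
        "n_starts": len(starts),
    }
    return start.with_scaled(best[1]), info


# --------------------------------------------------------------------------
# End-to-end recovery
# --------------------------------------------------------------------------


def recover_materials(
    base: LabeledMesh,
    target: LabeledMesh,
    load: LoadCase,
    bounds: BoundsTable,
    config: OptimizerConfig,
    mode: ObjectiveMode | str = ObjectiveMode.INTERFACE,
    model: str = "linear",
    settings: SolverSettings | None = None,
    evaluator=None,
) -> tuple[ParameterVector, RunTrace]:
    """Recover the free material parameters that deform ``base`` into
    ``target`` under ``load``: NSGA-II global stage, incumbent selection by
    the interface-error sum across all generations, SQP refinement.

    ``model`` selects the packing mode (``linear``, ``yeoh`` or
    ``yeoh-calcium``); ``mode`` the objective (interface / surface /
    diameter). A custom ``evaluator`` may replace the forward-FE one (used
    by tests with mock objectives).
    """
    template = pack(bounds, model)
    if evaluator is None:
        evaluator = ForwardEvaluator(
            base, target, load, settings=settings, mode=ObjectiveMode(mode)
        )
    trace = RunTrace(seed=config.seed)
    traced = _TracedEvaluator(evaluator, template, trace)
    nsga2_stage(traced, template, config, trace=trace)
    incumbent = select_incumbent(trace, template)
    extra = tuple(diverse_runner_ups(trace))
    y_star, _ = sqp_refine(traced, incumbent, config, trace=trace, extra_starts=extra)
    return y_star, trace
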