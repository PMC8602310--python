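"""Verification studies: target generation, noise injection, repeated-run
recovery, and objective-mode comparison.

The in-silico verification loop is an "inverse crime" by construction: the
target geometry is produced by the same forward solver used in the
recovery, so the assigned parameters are the exact optimum and percent
recovery errors measure the method, not model mismatch. Noise studies
perturb the nodal displacement field between base and target with
multiplicative Gaussian noise whose standard deviation is a fraction of the
maximum displacement magnitude; pressure studies perturb the loading used
to *generate* the target while the recovery still assumes the nominal
pressure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import BoundsTable, ParameterVector, default_bounds, pack
from .forward_fe import (
    DisplacementField,
    FEModel,
    LoadCase,
    SolverSettings,
    apply_displacement,
    simulate,
)
from .geometry import (
    Inclusion,
    LabeledMesh,
    SynthVesselSpec,
    generate_synthetic_vessel,
    tissue_volume_fractions,
)
from .objective import ObjectiveMode
from .optimizer import OptimizerConfig, RunTrace, recover_materials
from .tissues import Tissue


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian displacement noise.

    Every displacement component u is replaced by u * (1 + z) with
    z ~ N(0, n * max|u|), where max|u| is the largest absolute displacement
    component in the field — the literal elementwise reading of the noise
    model (the per-node-vector alternative is rejected; see methods note).
    """

    n: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("noise fraction must be >= 0")


def make_target(
    base: LabeledMesh,
    load: LoadCase,
    y_assigned: ParameterVector,
    settings: SolverSettings | None = None,
    model: FEModel | None = None,
) -> tuple[LabeledMesh, DisplacementField]:
    """Simulate the target geometry from the base under the pressure
    differential with assigned materials; the displacement field is kept
    for noise studies."""
    return simulate(base, load, y_assigned, settings=settings, model=model)


def add_noise(u: DisplacementField | np.ndarray, spec: NoiseSpec) -> DisplacementField:
    """Apply the multiplicative Gaussian noise model to a displacement
    field, componentwise, seeded."""
    vals = u.values if isinstance(u, DisplacementField) else np.asarray(u, dtype=float)
    if spec.n == 0:
        return DisplacementField(vals.copy())
    umax = np.abs(vals).max()
    if umax == 0:
        raise ValueError("cannot scale noise on an identically zero field")
    rng = np.random.default_rng(spec.seed)
    z = rng.normal(0.0, spec.n * umax, size=vals.shape)
    return DisplacementField(vals * (1.0 + z))


def noisy_target(
    base: LabeledMesh, u: DisplacementField, spec: NoiseSpec
) -> LabeledMesh:
    """Noisy target geometry: base coordinates plus the noisy displacements."""
    return apply_displacement(base, add_noise(u, spec))


def perturb_pressure(load: LoadCase, fraction: float) -> LoadCase:
    """Scale the pressure differential by (1 + fraction), e.g. +-5% or
    +-10%, keeping the base acquisition pressure."""
    return LoadCase(
        p_base_mmhg=load.p_base_mmhg,
        p_target_mmhg=load.p_base_mmhg + load.delta_p_mmhg * (1.0 + fraction),
    )


# --------------------------------------------------------------------------
# Study configuration and report
# --------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """One verification study: geometry, constitutive and objective mode,
    optimizer budgets, noise/pressure perturbations, and the seed list
    (one recovery run per seed)."""

    spec: SynthVesselSpec = field(default_factory=SynthVesselSpec)
    model: str = "linear"  # linear | yeoh | yeoh-calcium
    objective_mode: ObjectiveMode | str = ObjectiveMode.INTERFACE
    load: LoadCase = field(default_factory=LoadCase)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    solver: SolverSettings | None = None
    noise: NoiseSpec | None = None
    pressure_perturbation: float = 0.0
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    bounds: BoundsTable | None = None
    outdir: str | None = None


@dataclass
class RecoveryReport:
    """Per-parameter recovery errors with per-run and aggregate statistics.

    ``runs`` has one row per (seed, free parameter) with the assigned value,
    the recovered value and the percent error
    100 * |recovered - assigned| / assigned.
    """

    runs: pd.DataFrame
    metadata: dict

    def per_run(self) -> pd.DataFrame:
        g = self.runs.groupby("seed")["pct_error"]
        return g.agg(["mean", "median", "std"])

    def per_parameter(self) -> pd.DataFrame:
        g = self.runs.groupby(["tissue", "param"])["pct_error"]
        return g.agg(["mean", "median", "std"])

    def aggregate(self) -> dict:
        """Mean +- SD and median percent error over all free parameters and
        runs (the reporting convention of the verification studies)."""
        e = self.runs["pct_error"]
        return {
            "mean": float(e.mean()),
            "sd": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            "median": float(e.median()),
            "max": float(e.max()),
            "n_runs": int(self.runs["seed"].nunique()),
            "n_parameters": int(len(e) / max(self.runs["seed"].nunique(), 1)),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "aggregate": self.aggregate(),
            "runs": self.runs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RecoveryReport":
        payload = json.loads(Path(path).read_text())
        return cls(runs=pd.DataFrame(payload["runs"]), metadata=payload["metadata"])


def percent_errors(
    recovered: ParameterVector, assigned: ParameterVector, seed: int
) -> pd.DataFrame:
    rows = []
    for (tissue, param), rec, asg in zip(
        assigned.free_names(), recovered.free_values(), assigned.free_values()
    ):
        rows.append(
            {
                "seed": seed,
                "tissue": tissue.label,
                "param": param,
                "assigned": float(asg),
                "recovered": float(rec),
                "pct_error": 100.0 * abs(rec - asg) / asg,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> RecoveryReport:
    """Run one recovery per seed and consolidate the percent errors.

    The target is generated once (noise, when requested, is re-drawn per
    seed, so each run sees an independent noisy realization). Failed runs
    are recorded in the metadata and excluded from the aggregates with a
    warning.
    """
    bounds = config.bounds if config.bounds is not None else default_bounds()
    base = generate_synthetic_vessel(config.spec)
    assigned = pack(bounds, config.model)
    gen_load = perturb_pressure(config.load, config.pressure_perturbation)
    target_clean, u_clean = make_target(
        base, gen_load, assigned, settings=config.solver
    )
    frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        from . import io as mesh_io

        mesh_io.write_mesh(base, str(outdir / "base.vtu"))
        mesh_io.write_mesh(target_clean, str(outdir / "target.vtu"))
    for seed in config.seeds:
        if config.noise is not None and config.noise.n > 0:
            target = noisy_target(
                base, u_clean, replace(config.noise, seed=seed)
            )
        else:
            target = target_clean
        opt = replace(config.optimizer, seed=seed)
        try:
            y_star, trace = recover_materials(
                base,
                target,
                config.load,
                bounds,
                opt,
                mode=config.objective_mode,
                model=config.model,
                settings=config.solver,
            )
        except Exception as exc:  # noqa: BLE001 - a failed run is data
            import warnings

            warnings.warn(f"recovery run seed={seed} failed: {exc}", stacklevel=2)
            failures.append({"seed": seed, "error": str(exc)})
            continue
        frames.append(percent_errors(y_star, assigned, seed))
        if outdir:
            trace.to_dataframe().to_csv(outdir / f"trace_seed{seed}.csv", index=False)
    if not frames:
        raise RuntimeError("every recovery run failed")
    runs = pd.concat(frames, ignore_index=True)
    meta = {
        "model": config.model,
        "objective_mode": str(ObjectiveMode(config.objective_mode).value),
        "noise": None if config.noise is None else config.noise.n,
        "pressure_perturbation": config.pressure_perturbation,
        "delta_p_mmhg": config.load.delta_p_mmhg,
        "seeds": list(config.seeds),
        "population": config.optimizer.population,
        "generations": config.optimizer.generations,
        "sqp_max_evals": config.optimizer.sqp_max_evals,
        "mesh": {
            "dim": config.spec.dim,
            "n_nodes": int(base.n_nodes),
            "n_elements": int(base.n_elements),
        },
        "volume_fractions": {
            t.label: round(v, 3) for t, v in tissue_volume_fractions(base).items()
        },
        "failures": failures,
    }
    report = RecoveryReport(runs=runs, metadata=meta)
    if outdir:
        report.to_json(outdir / "report.json")
    return report


def compare_objective_modes(
    config: StudyConfig,
    modes: tuple[ObjectiveMode | str, ...] = (
        ObjectiveMode.INTERFACE,
        ObjectiveMode.SURFACE,
        ObjectiveMode.DIAMETER,
    ),
) -> dict[str, RecoveryReport]:
    """Run the same study (identical geometry, targets, and seeds) once per
    objective mode — the paired comparison between full interface matching
    and the two macro-morphological baselines."""
    out: dict[str, RecoveryReport] = {}
    for mode in modes:
        mode = ObjectiveMode(mode)
        sub = replace(
            config,
            objective_mode=mode,
            outdir=str(Path(config.outdir) / mode.value) if config.outdir else None,
        )
        out[mode.value] = run_study(sub)
    return out


# --------------------------------------------------------------------------
# Phenotype presets
# --------------------------------------------------------------------------


def phenotype_spec(name: str, dim: int = 2) -> SynthVesselSpec:
    """Synthetic lesion phenotypes.

    ``A`` is the default layout (sparse calcium < 1%, excluded from
    recovery). ``B`` and ``C`` are additional phenotypes with differing
    inclusion layouts and calcium above 1% volume, used by the
    9-parameter reproducibility mode.
    """
    if name == "A":
        return SynthVesselSpec(dim=dim)
    if name == "B":
        # calcific lesion: large calcium arc, smaller lipid pool
        inclusions = (
            Inclusion(Tissue.FIBROUS, theta=(10.0, 95.0)),
            Inclusion(Tissue.LIPID, theta=(120.0, 185.0), radial=(0.3, 0.7)),
            Inclusion(Tissue.MIXED, theta=(200.0, 240.0), radial=(0.2, 0.8)),
            Inclusion(Tissue.CALCIUM, theta=(260.0, 300.0), radial=(0.25, 0.65)),
        )
        return SynthVesselSpec(dim=dim, inclusions=inclusions)
    if name == "C":
        # fibro-calcific lesion: two fibrous arcs, deep calcium nodule
        inclusions = (
            Inclusion(Tissue.FIBROUS, theta=(0.0, 60.0)),
            Inclusion(Tissue.FIBROUS, theta=(150.0, 200.0), radial=(0.0, 0.6)),
            Inclusion(Tissue.LIPID, theta=(70.0, 140.0), radial=(0.25, 0.75)),
            Inclusion(Tissue.MIXED, theta=(210.0, 250.0), radial=(0.3, 0.7)),
            Inclusion(Tissue.CALCIUM, theta=(300.0, 330.0), radial=(0.3, 0.8)),
        )
        return SynthVesselSpec(dim=dim, inclusions=inclusions)
    raise ValueError(f"unknown phenotype {name!r} (expected A, B or C)")


def c30_sensitivity_check(
    base: LabeledMesh,
    load: LoadCase,
    y: ParameterVector,
    settings: SolverSettings | None = None,
) -> dict:
    """Diagnostic behind holding C30 fixed: reports the peak principal
    stretch of the forward solve and warns when it exceeds 20% strain (the
    regime where the cubic coefficient starts to matter)."""
    fem = FEModel(base, settings)
    _, u = simulate(base, load, y, model=fem)
    peak = fem.max_stretch(u.values.reshape(-1))
    result = {"max_stretch": peak, "max_strain_pct": 100.0 * (peak - 1.0)}
    if peak > 1.2:
        import warnings

        warnings.warn(
            f"peak stretch {peak:.3f} exceeds 20% strain: the objective may "
            "be sensitive to C30, which is held fixed",
            stacklevel=2,
        )
    return result
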