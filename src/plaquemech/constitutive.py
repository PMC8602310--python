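"""Constitutive models and material parameter vectors.

Two models are supported:

* **Linear elastic** (Hooke's law, sigma = E * eps) for nearly
  incompressible tissue, with a fixed Poisson ratio of 0.49.
* **Yeoh hyperelastic**: an isotropic strain-energy density that is a cubic
  polynomial in the first deviatoric strain invariant,

      W = C10 (I1 - 3) + C20 (I1 - 3)^2 + C30 (I1 - 3)^3,

  where I1 is the first invariant of the deviatoric right Cauchy-Green
  tensor (the standard stretch-based Yeoh invariant). Near
  incompressibility is enforced with a volumetric penalty
  U_vol = kappa/2 (J - 1)^2 with kappa = 1000 * mu0 = 2000 * C10 per
  material, keeping the finite-element formulation displacement-only.

The free parameters of a recovery are packed into a
:class:`ParameterVector` whose entries carry per-parameter bounds and a
fixed mask. Three packing modes mirror the verification studies: ``linear``
(4 free moduli), ``yeoh`` (8 free coefficients, all C30 fixed, calcium
excluded), and ``yeoh-calcium`` (adds the calcium C10, 9 free).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .tissues import SOFT_TISSUES, Tissue

#: Poisson ratio of the nearly incompressible linear model.
NU_LINEAR = 0.49

#: Volumetric penalty multiple of the initial shear modulus (Yeoh model).
KAPPA_FACTOR = 1000.0


@dataclass(frozen=True)
class LinearElasticParams:
    """Linear elastic material: Young's modulus E (kPa), Poisson ratio nu."""

    E: float
    nu: float = NU_LINEAR

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass(frozen=True)
class YeohParams:
    """Yeoh coefficients C10, C20, C30 (kPa) and volumetric penalty kappa.

    ``kappa`` defaults to ``KAPPA_FACTOR * mu0`` with mu0 = 2 C10.
    """

    c10: float
    c20: float = 0.0
    c30: float = 0.0
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.c10 <= 0:
            raise ValueError("C10 must be positive")
        if self.c20 < 0 or self.c30 < 0:
            raise ValueError("C20 and C30 must be non-negative")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 2.0 * KAPPA_FACTOR * self.c10)
        elif self.kappa <= 0:
            raise ValueError("kappa must be positive")


def yeoh_strain_energy(i1_dev: np.ndarray | float, p: YeohParams) -> np.ndarray | float:
    """Isochoric Yeoh strain-energy density (kPa) at deviatoric invariant
    ``i1_dev`` (>= 3; the undeformed state gives W = 0)."""
    x = np.asarray(i1_dev, dtype=float) - 3.0
    if np.any(x < -1e-12):
        raise ValueError("the deviatoric invariant I1 cannot fall below 3")
    x = np.maximum(x, 0.0)
    w = p.c10 * x + p.c20 * x**2 + p.c30 * x**3
    return w if w.ndim else float(w)


def yeoh_uniaxial_stress(stretch: np.ndarray | float, p: YeohParams) -> np.ndarray | float:
    """Closed-form incompressible uniaxial Cauchy stress (kPa) at stretch
    ``lambda``: sigma = 2 (lambda^2 - 1/lambda) dW/dI1 with
    I1 = lambda^2 + 2/lambda."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    i1 = lam**2 + 2.0 / lam
    x = i1 - 3.0
    dw = p.c10 + 2.0 * p.c20 * x + 3.0 * p.c30 * x**2
    s = 2.0 * (lam**2 - 1.0 / lam) * dw
    return s if s.ndim else float(s)


def initial_shear_modulus(p: YeohParams) -> float:
    """Small-strain shear modulus mu0 = 2 C10 (kPa)."""
    return 2.0 * p.c10


# --------------------------------------------------------------------------
# Bounds table (assigned ground truths and search ranges)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundsTable:
    """Assigned parameter values and search ranges per tissue and parameter.

    ``assigned[tissue][param]`` -> float; ``ranges[tissue][param]`` ->
    (lo, hi) or absent when the parameter is never free.
    """

    assigned: dict[Tissue, dict[str, float]]
    ranges: dict[Tissue, dict[str, tuple[float, float]]]
    volume_pct: dict[Tissue, float]

    def __post_init__(self) -> None:
        for t, params in self.ranges.items():
            for name, (lo, hi) in params.items():
                if not 0 < lo < hi:
                    raise ValueError(f"bad range for {t.label}.{name}: ({lo}, {hi})")
                v = self.assigned[t].get(name)
                if v is not None and not lo <= v <= hi:
                    raise ValueError(
                        f"assigned {t.label}.{name}={v} outside range ({lo}, {hi})"
                    )


def default_bounds() -> BoundsTable:
    """The packaged ground-truth / search-range table."""
    text = (
        importlib.resources.files("plaquemech") / "data" / "material_table.yaml"
    ).read_text()
    return bounds_from_dict(yaml.safe_load(text))


def bounds_from_dict(raw: dict) -> BoundsTable:
    assigned: dict[Tissue, dict[str, float]] = {}
    ranges: dict[Tissue, dict[str, tuple[float, float]]] = {}
    volume: dict[Tissue, float] = {}
    for name, block in raw.items():
        t = Tissue.from_label(name)
        assigned[t] = {}
        ranges[t] = {}
        for key, val in block.items():
            if key == "volume_pct":
                volume[t] = float(val)
                continue
            assigned[t][key] = float(val["assigned"])
            if "range" in val:
                lo, hi = val["range"]
                ranges[t][key] = (float(lo), float(hi))
    return BoundsTable(assigned=assigned, ranges=ranges, volume_pct=volume)


# --------------------------------------------------------------------------
# Parameter vector
# --------------------------------------------------------------------------

#: Recovery modes and the (tissue, parameter) entries that are free in each.
PACK_MODES = ("linear", "yeoh", "yeoh-calcium")


@dataclass(frozen=True)
class ParameterEntry:
    tissue: Tissue
    param: str
    value: float
    bounds: tuple[float, float] | None
    fixed: bool


@dataclass(frozen=True)
class ParameterVector:
    """Ordered material parameters with bounds and a fixed mask.

    Free entries are exposed both on their physical scale and on a
    log10 scale mapped to [0, 1] over the search range — the space in which
    the optimizer works, since ranges span one to two orders of magnitude.
    """

    entries: tuple[ParameterEntry, ...]
    model: str

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.fixed:
                if e.bounds is None:
                    raise ValueError(f"free entry {e.tissue.label}.{e.param} lacks bounds")
                lo, hi = e.bounds
                if not lo <= e.value <= hi:
                    raise ValueError(
                        f"free entry {e.tissue.label}.{e.param}={e.value} "
                        f"outside bounds ({lo}, {hi})"
                    )

    # -- free-parameter views ------------------------------------------------

    @property
    def free_entries(self) -> tuple[ParameterEntry, ...]:
        return tuple(e for e in self.entries if not e.fixed)

    @property
    def n_free(self) -> int:
        return sum(not e.fixed for e in self.entries)

    def free_values(self) -> np.ndarray:
        return np.array([e.value for e in self.free_entries])

    def free_names(self) -> list[tuple[Tissue, str]]:
        return [(e.tissue, e.param) for e in self.free_entries]

    def with_free_values(self, values: np.ndarray) -> "ParameterVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_free,):
            raise ValueError("wrong number of free values")
        it = iter(values)
        new = tuple(
            e if e.fixed else replace(e, value=float(next(it))) for e in self.entries
        )
        return ParameterVector(new, self.model)

    def to_scaled(self) -> np.ndarray:
        """Free values mapped to [0, 1] via log10 over their search range."""
        out = []
        for e in self.free_entries:
            lo, hi = e.bounds
            out.append(np.log10(e.value / lo) / np.log10(hi / lo))
        return np.array(out)

    def with_scaled(self, x: np.ndarray) -> "ParameterVector":
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        vals = []
        for xi, e in zip(x, self.free_entries, strict=True):
            lo, hi = e.bounds
            vals.append(lo * (hi / lo) ** xi)
        return self.with_free_values(np.array(vals))

    # -- full-assignment views ------------------------------------------------

    def unpack(self) -> dict[Tissue, dict[str, float]]:
        out: dict[Tissue, dict[str, float]] = {}
        for e in self.entries:
            out.setdefault(e.tissue, {})[e.param] = e.value
        return out

    def materials(self) -> dict[Tissue, LinearElasticParams | YeohParams]:
        """Per-tissue constitutive parameter objects for the forward solver."""
        full = self.unpack()
        mats: dict[Tissue, LinearElasticParams | YeohParams] = {}
        for t, params in full.items():
            if self.model == "linear":
                mats[t] = LinearElasticParams(E=params["E"])
            else:
                mats[t] = YeohParams(
                    c10=params["C10"], c20=params["C20"], c30=params["C30"]
                )
        return mats


def pack(
    bounds: BoundsTable,
    model: str,
    values: dict[Tissue, dict[str, float]] | None = None,
) -> ParameterVector:
    """Build a :class:`ParameterVector` for a recovery mode.

    ``linear`` frees E for the four soft tissues (calcium E fixed);
    ``yeoh`` frees C10 and C20 for the four soft tissues with every C30 and
    all calcium parameters held at their assigned values; ``yeoh-calcium``
    additionally frees the calcium C10 (used when the calcium volume
    fraction exceeds one percent). ``values`` overrides assigned values.
    """
    if model not in PACK_MODES:
        raise ValueError(f"unknown model {model!r}; expected one of {PACK_MODES}")
    params = ("E",) if model == "linear" else ("C10", "C20", "C30")
    entries: list[ParameterEntry] = []
    for t in Tissue:
        for name in params:
            value = bounds.assigned[t][name]
            if values is not None:
                value = values.get(t, {}).get(name, value)
            free = False
            if name == "E" and t in SOFT_TISSUES:
                free = True
            elif name in ("C10", "C20") and t in SOFT_TISSUES:
                free = True
            elif name == "C10" and t is Tissue.CALCIUM and model == "yeoh-calcium":
                free = True
            rng = bounds.ranges[t].get(name)
            entries.append(
                ParameterEntry(
                    tissue=t, param=name, value=value, bounds=rng, fixed=not free
                )
            )
    mdl = "linear" if model == "linear" else "yeoh"
    return ParameterVector(tuple(entries), mdl)
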