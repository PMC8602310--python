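"""Geometry-difference objectives for the inverse method.

The primary objective matches *tissue interfaces*: for every interface (the
common nodes of two node sets) the error is the mean, over interface nodes
of the target geometry, of the Euclidean distance to the nearest node of
the corresponding interface in the deformed geometry. The error is
directional (target -> deformed) and deliberately not symmetrized. The
vector of all interface errors is the multi-objective fitness; their sum is
the single-objective scalar.

Two macro-morphological baselines are provided for comparison studies:
``surface`` matches only the inner and outer wall surfaces, and
``diameter`` compares minimum/maximum luminal diameters on evenly spaced
cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Interface, LabeledMesh, NodeSetArray


class ObjectiveMode(str, Enum):
    INTERFACE = "interface"
    SURFACE = "surface"
    DIAMETER = "diameter"


@dataclass(frozen=True)
class InterfaceError:
    """Mean nearest-node distance (mm) between two corresponding interfaces."""

    pair: tuple[str, ...]
    value: float
    n_target: int
    n_deformed: int


@dataclass(frozen=True)
class ObjectiveValue:
    """The vector of interface errors (multi-objective fitness) and their
    sum (single-objective fitness)."""

    errors: tuple[InterfaceError, ...]
    iteration: int | None = None

    @property
    def vector(self) -> np.ndarray:
        return np.array([e.value for e in self.errors])

    @property
    def total(self) -> float:
        return float(sum(e.value for e in self.errors))


def interface_error(
    target_nodes: np.ndarray,
    deformed_nodes: np.ndarray,
    pair: tuple[str, ...] = ("", ""),
) -> InterfaceError:
    """Mean distance from each target-interface node to the nearest
    deformed-interface node (spatial-index search, identical to exhaustive
    search up to ties, which carry equal distance)."""
    t = np.asarray(target_nodes, dtype=float)
    d = np.asarray(deformed_nodes, dtype=float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError(f"empty node set in interface comparison {pair}")
    dist, _ = cKDTree(d).query(t)
    return InterfaceError(
        pair=pair, value=float(dist.mean()), n_target=len(t), n_deformed=len(d)
    )


def evaluate(
    deformed: LabeledMesh,
    target: LabeledMesh,
    nsets: NodeSetArray,
    mode: ObjectiveMode | str = ObjectiveMode.INTERFACE,
    interfaces: list[Interface] | None = None,
    n_slices: int = 10,
    iteration: int | None = None,
) -> ObjectiveValue:
    """Quantify the discrepancy between a simulated deformed geometry and
    the target geometry.

    Both meshes must share the base topology (node sets and interfaces are
    defined on node indices of the common base mesh). In ``interface`` mode
    one error per tissue/surface interface is produced; ``surface`` mode
    compares only the inner and outer surface node sets; ``diameter`` mode
    compares min/max luminal diameters on ``n_slices`` cross sections.
    """
    mode = ObjectiveMode(mode)
    if mode is ObjectiveMode.INTERFACE:
        if interfaces is None:
            from .geometry import extract_interfaces

            interfaces = extract_interfaces(nsets)
        if not interfaces:
            raise ValueError("no interfaces available for the interface objective")
        errs = tuple(
            interface_error(
                target.coords[i.nodes], deformed.coords[i.nodes], pair=i.pair
            )
            for i in interfaces
        )
        return ObjectiveValue(errors=errs, iteration=iteration)
    if mode is ObjectiveMode.SURFACE:
        errs = tuple(
            interface_error(
                target.coords[nsets[name]], deformed.coords[nsets[name]], pair=(name,)
            )
            for name in ("inner", "outer")
        )
        return ObjectiveValue(errors=errs, iteration=iteration)
    return diameter_objective(
        deformed, target, n_slices=n_slices, inner_nodes=nsets["inner"], iteration=iteration
    )


def feret_diameters(points_2d: np.ndarray, n_directions: int = 180) -> tuple[float, float]:
    """Minimum and maximum Feret (caliper) diameter of a planar point set,
    sampled over ``n_directions`` evenly spaced directions."""
    pts = np.asarray(points_2d, dtype=float)
    phi = np.pi * np.arange(n_directions) / n_directions
    dirs = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    proj = pts @ dirs.T  # (n_pts, n_dirs)
    extent = proj.max(axis=0) - proj.min(axis=0)
    return float(extent.min()), float(extent.max())


def diameter_objective(
    deformed: LabeledMesh,
    target: LabeledMesh,
    n_slices: int = 10,
    inner_nodes: np.ndarray | None = None,
    iteration: int | None = None,
) -> ObjectiveValue:
    """Macro-morphological baseline: mean absolute discrepancy of the
    minimum and maximum luminal diameters over cross-section slices.

    In 3D, slices are planes at ``n_slices`` evenly spaced axial stations;
    the luminal contour of a slice collects inner-surface nodes within half
    the axial node spacing of the plane. The 2D plane-strain mode has a
    single slice — the section itself.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if inner_nodes is None:
        from .geometry import extract_node_sets

        inner_nodes = extract_node_sets(deformed)["inner"]
    slices: list[np.ndarray]
    if deformed.dim == 2:
        slices = [inner_nodes]
    else:
        z = target.coords[inner_nodes][:, 2]
        zu = np.unique(np.round(z, 9))
        half_dz = 0.5 * np.median(np.diff(zu)) if len(zu) > 1 else np.inf
        stations = np.linspace(z.min(), z.max(), n_slices + 2)[1:-1]
        slices = [
            inner_nodes[np.abs(z - zs) <= half_dz + 1e-12] for zs in stations
        ]
        slices = [s for s in slices if len(s) >= 3]
        if not slices:
            raise ValueError("no luminal contour nodes found near the slice planes")
    dmin_err, dmax_err = [], []
    for nodes in slices:
        tmin, tmax = feret_diameters(target.coords[nodes][:, :2])
        smin, smax = feret_diameters(deformed.coords[nodes][:, :2])
        dmin_err.append(abs(tmin - smin))
        dmax_err.append(abs(tmax - smax))
    errs = (
        InterfaceError(
            pair=("min_diameter",),
            value=float(np.mean(dmin_err)),
            n_target=len(slices),
            n_deformed=len(slices),
        ),
        InterfaceError(
            pair=("max_diameter",),
            value=float(np.mean(dmax_err)),
            n_target=len(slices),
            n_deformed=len(slices),
        ),
    )
    return ObjectiveValue(errors=errs, iteration=iteration)
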