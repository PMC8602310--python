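"""Labeled vessel meshes: generation, labeling, node sets, and interfaces.

The central container is :class:`LabeledMesh` — a quadratic simplex mesh
(6-node triangles in the 2D plane-strain mode, 10-node tetrahedra in 3D)
with one tissue label per element. :func:`generate_synthetic_vessel` builds
a straight thick-walled annular vessel with parametric intramural
inclusions, standing in for an image-derived geometry: deterministic,
analytically checkable, and with controllable tissue volume fractions.

Node sets (one per tissue class present, plus the inner and outer wall
surfaces) and their pairwise intersections — the tissue interfaces — are the
geometric primitives consumed by the interface-matching objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import elements as el
from .tissues import SET_ORDER, Tissue


class MeshError(ValueError):
    """Raised for invalid mesh topology or degenerate geometry."""


class SpecError(ValueError):
    """Raised for a degenerate synthetic-vessel specification."""


# --------------------------------------------------------------------------
# Mesh container
# --------------------------------------------------------------------------


@dataclass
class LabeledMesh:
    """Quadratic simplex mesh with per-element tissue labels.

    Parameters
    ----------
    coords:
        Node coordinates in mm, shape ``(n_nodes, dim)`` with dim 2 or 3.
    elements:
        Connectivity, shape ``(n_el, 6)`` for triangles or ``(n_el, 10)``
        for tetrahedra, VTK node ordering.
    labels:
        Integer :class:`~plaquemech.tissues.Tissue` code per element.
    """

    coords: np.ndarray
    elements: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        self.elements = np.ascontiguousarray(np.asarray(self.elements, dtype=np.int64))
        self.labels = np.ascontiguousarray(np.asarray(self.labels, dtype=np.int64))
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise MeshError("coords must be (n_nodes, 2) or (n_nodes, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (6, 10):
            raise MeshError("elements must be 6-node triangles or 10-node tets")
        if (self.dim == 2) != (self.elements.shape[1] == 6):
            raise MeshError("element type inconsistent with coordinate dimension")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.coords)
        ):
            raise MeshError("element connectivity indexes nonexistent nodes")
        if self.labels.shape != (len(self.elements),):
            raise MeshError("one tissue label required per element")
        valid = {int(t) for t in Tissue}
        if self.labels.size and not set(np.unique(self.labels)).issubset(valid):
            raise MeshError("labels must be Tissue codes 1..5")

    # -- basic queries ------------------------------------------------------

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_corners(self) -> int:
        return 3 if self.dim == 2 else 4

    def element_centroids(self) -> np.ndarray:
        """Centroid of each element (mean of its corner nodes)."""
        return self.coords[self.elements[:, : self.n_corners]].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Element areas (2D) / volumes (3D), by quadrature on the curved
        isoparametric geometry. All values must be strictly positive."""
        if self.dim == 2:
            pts, w = el.tri_quadrature()
            _, dN = el.tri6_shape(pts)
        else:
            pts, w = el.tet_quadrature()
            _, dN = el.tet10_shape(pts)
        X = self.coords[self.elements]  # (nel, nn, dim)
        J = np.einsum("end,qna->eqda", X, dN)
        det = np.linalg.det(J)
        if np.any(det <= 0):
            raise MeshError("non-positive element Jacobian encountered")
        return det @ w

    def section_axis(self) -> np.ndarray:
        """In-plane centroid of the cross section (rigid-mode pin reference)."""
        return self.coords[:, :2].mean(axis=0)

    # -- boundary topology ---------------------------------------------------

    def boundary_facets(self) -> np.ndarray:
        """Boundary facets as node-index rows (3-node edges / 6-node faces).

        A facet is on the boundary when it belongs to exactly one element;
        a facet shared by more than two elements marks a non-manifold mesh.
        """
        facets = self._all_facets()
        corners = np.sort(facets[:, : self.dim], axis=1)
        _, inv, counts = np.unique(
            corners, axis=0, return_inverse=True, return_counts=True
        )
        if np.any(counts > 2):
            bad = facets[np.isin(inv, np.where(counts > 2)[0])]
            raise MeshError(f"non-manifold facets (shared by >2 elements): {bad[:5]}")
        return facets[counts[inv] == 1]

    def _all_facets(self) -> np.ndarray:
        conn = self.elements
        if self.dim == 2:
            local = el.TRI6_EDGES
        else:
            local = el.TET10_FACES
        return np.concatenate([conn[:, list(loc)] for loc in local], axis=0)

    @property
    def end_caps(self) -> tuple[np.ndarray, np.ndarray]:
        """Node sets at the two longitudinal extremes (3D; empty in 2D).

        Identified by axial coordinate within ``1e-6 * length`` of either
        extreme.
        """
        if self.dim == 2:
            e = np.empty(0, dtype=np.int64)
            return e, e
        z = self.coords[:, 2]
        tol = 1e-6 * max(z.max() - z.min(), 1.0)
        lo = np.where(z <= z.min() + tol)[0]
        hi = np.where(z >= z.max() - tol)[0]
        return lo, hi

    def classified_boundary(self) -> dict[str, np.ndarray]:
        """Boundary facets grouped as inner surface, outer surface, end caps.

        End-cap facets are those whose nodes all lie on an end cap; the
        remaining boundary facets are split into connected components, with
        the component of smaller mean radius (about the section axis) taken
        as the inner (luminal) surface. Raises :class:`MeshError` if the
        leftover facets do not form exactly two closed sheets.
        """
        facets = self.boundary_facets()
        out: dict[str, np.ndarray] = {}
        mask_wall = np.ones(len(facets), dtype=bool)
        if self.dim == 3:
            lo, hi = self.end_caps
            for name, cap in (("cap_lo", lo), ("cap_hi", hi)):
                on_cap = np.isin(facets, cap).all(axis=1)
                out[name] = facets[on_cap]
                mask_wall &= ~on_cap
        wall = facets[mask_wall]
        comp = _facet_components(wall)
        n_comp = comp.max() + 1 if len(comp) else 0
        if n_comp != 2:
            raise MeshError(
                f"expected 2 lateral boundary sheets (inner/outer), found {n_comp}; "
                f"orphan facets: {wall[:5]}"
            )
        axis = self.section_axis()
        radii = [
            np.linalg.norm(
                self.coords[np.unique(wall[comp == c])][:, :2] - axis, axis=1
            ).mean()
            for c in range(2)
        ]
        inner_c = int(np.argmin(radii))
        out["inner"] = wall[comp == inner_c]
        out["outer"] = wall[comp == 1 - inner_c]
        return out


def _facet_components(facets: np.ndarray) -> np.ndarray:
    """Connected components of facets linked through shared nodes."""
    n = len(facets)
    if n == 0:
        return np.empty(0, dtype=int)
    node_to_facets: dict[int, list[int]] = {}
    for i, f in enumerate(facets):
        for node in f:
            node_to_facets.setdefault(int(node), []).append(i)
    comp = np.full(n, -1, dtype=int)
    current = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = current
        while stack:
            i = stack.pop()
            for node in facets[i]:
                for j in node_to_facets[int(node)]:
                    if comp[j] < 0:
                        comp[j] = current
                        stack.append(j)
        current += 1
    return comp


# --------------------------------------------------------------------------
# Node sets and interfaces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSetArray:
    """Named node-index sets: one per tissue class present, plus the inner
    (luminal) and outer wall surfaces."""

    sets: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.sets[name]

    def names(self) -> list[str]:
        order = {n: i for i, n in enumerate(SET_ORDER)}
        return sorted(self.sets, key=lambda n: order.get(n, len(order)))


@dataclass(frozen=True)
class Interface:
    """Common nodes of two named node sets (a tissue-tissue or
    tissue-surface interface)."""

    pair: tuple[str, str]
    nodes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=np.int64))


def extract_node_sets(mesh: LabeledMesh) -> NodeSetArray:
    """Build the node-set array: material sets are the union of nodes of
    elements carrying that label; inner/outer sets come from the classified
    boundary."""
    sets: dict[str, np.ndarray] = {}
    for code in np.unique(mesh.labels):
        t = Tissue(int(code))
        nodes = np.unique(mesh.elements[mesh.labels == code])
        sets[t.label] = nodes
    boundary = mesh.classified_boundary()
    for name in ("inner", "outer"):
        sets[name] = np.unique(boundary[name])
    if not len(sets["inner"]) or not len(sets["outer"]):
        raise MeshError("inner or outer surface node set is empty")
    return NodeSetArray(sets)


def extract_interfaces(nsets: NodeSetArray, min_nodes: int = 3) -> list[Interface]:
    """All unordered pairs of node sets with a non-empty intersection.

    Pairs with fewer than ``min_nodes`` common nodes are dropped with a
    warning: a one- or two-node "interface" makes the mean-distance error
    degenerate.
    """
    names = nsets.names()
    out: list[Interface] = []
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            common = np.intersect1d(nsets[x], nsets[y])
            if len(common) == 0:
                continue
            if len(common) < min_nodes:
                warnings.warn(
                    f"interface {x}-{y} has only {len(common)} node(s); dropped",
                    stacklevel=2,
                )
                continue
            out.append(Interface(pair=(x, y), nodes=common))
    return out


def tissue_volume_fractions(mesh: LabeledMesh) -> dict[Tissue, float]:
    """Volume (3D) / area (2D) percentage per tissue class present."""
    vols = mesh.element_volumes()
    total = vols.sum()
    return {
        Tissue(int(code)): 100.0 * vols[mesh.labels == code].sum() / total
        for code in np.unique(mesh.labels)
    }


def label_elements(
    mesh: LabeledMesh, points: np.ndarray, point_labels: np.ndarray
) -> LabeledMesh:
    """Assign each element the label of the annotated point nearest its
    centroid. Exact distance ties are broken toward the lowest point index."""
    points = np.asarray(points, dtype=float)
    point_labels = np.asarray(point_labels, dtype=np.int64)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("annotated point cloud must be a non-empty (n, dim) array")
    if len(point_labels) != len(points):
        raise ValueError("one label required per annotated point")
    cent = mesh.element_centroids()
    tree = cKDTree(points)
    d, idx = tree.query(cent)
    # enforce the lowest-index tie rule exactly
    for i in range(len(cent)):
        cand = tree.query_ball_point(cent[i], d[i] * (1 + 1e-12) + 1e-300)
        if cand:
            idx[i] = min(cand)
    return replace(mesh, labels=point_labels[idx])


# --------------------------------------------------------------------------
# Synthetic vessel generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Inclusion:
    """An intramural inclusion: an angular wedge spanning a radial band of
    the wall (and an axial band in 3D), overriding the background label.

    Angles in degrees; radial/axial ranges as fractions of wall thickness /
    vessel length. ``theta`` ranges may wrap past 360.
    """

    tissue: Tissue
    theta: tuple[float, float]
    radial: tuple[float, float] = (0.0, 1.0)
    axial: tuple[float, float] = (0.0, 1.0)


#: Default inclusion layout. The angular and radial extents are chosen so
#: the resulting area fractions approximate the tissue prevalence of the
#: reference lesion model: artery ~64.5%, fibrous ~19.4%, lipid ~13.0%,
#: mixed ~2.9%, calcium ~0.3%. Lipid and mixed are intramural (they do not
#: touch the wall surfaces); calcium is a sparse mid-wall speck.
DEFAULT_INCLUSIONS = (
    Inclusion(Tissue.FIBROUS, theta=(0.0, 70.0)),
    Inclusion(Tissue.LIPID, theta=(90.0, 183.6), radial=(0.25, 0.75)),
    Inclusion(Tissue.MIXED, theta=(210.0, 231.0), radial=(0.25, 0.75)),
    Inclusion(Tissue.CALCIUM, theta=(240.0, 247.5), radial=(1 / 3, 1 / 2)),
)


@dataclass(frozen=True)
class SynthVesselSpec:
    """Specification of a synthetic straight vessel segment.

    Lengths in mm. ``dim=2`` gives a plane-strain annular cross section,
    ``dim=3`` a tube of tetrahedra extruded over ``length``.
    """

    inner_radius: float = 1.5
    wall_thickness: float = 1.0
    length: float = 4.0
    n_circ: int = 48
    n_rad: int = 6
    n_axial: int = 8
    dim: int = 2
    inclusions: tuple[Inclusion, ...] = DEFAULT_INCLUSIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius <= 0 or self.wall_thickness <= 0:
            raise SpecError("inner radius and wall thickness must be positive")
        if self.dim not in (2, 3):
            raise SpecError("dim must be 2 or 3")
        if self.dim == 3 and self.length <= 0:
            raise SpecError("length must be positive in 3D")
        if self.n_circ < 8 or self.n_rad < 2 or (self.dim == 3 and self.n_axial < 2):
            raise SpecError("mesh resolution below the minimum for shaped elements")
        for inc in self.inclusions:
            r0, r1 = inc.radial
            z0, z1 = inc.axial
            if not (0.0 <= r0 < r1 <= 1.0):
                raise SpecError(f"inclusion {inc.tissue.label} radial band outside the wall")
            if not (0.0 <= z0 < z1 <= 1.0):
                raise SpecError(f"inclusion {inc.tissue.label} axial band outside the segment")
            if inc.theta[1] <= inc.theta[0]:
                raise SpecError(f"inclusion {inc.tissue.label} has empty angular extent")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness


def _kuhn_tets() -> list[list[tuple[int, int, int]]]:
    """Six-tetrahedron Kuhn decomposition of a hex cell, as index offsets."""
    import itertools

    steps = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
    tets = []
    for perm in itertools.permutations((0, 1, 2)):
        v = [(0, 0, 0)]
        cur = (0, 0, 0)
        for axis in perm:
            cur = tuple(c + s for c, s in zip(cur, steps[axis]))
            v.append(cur)
        tets.append(v)
    return tets


def generate_synthetic_vessel(spec: SynthVesselSpec) -> LabeledMesh:
    """Generate a labeled annular vessel mesh from a spec.

    The mesh is a structured polar (2D) or polar-extruded (3D) grid of
    quadratic simplices whose midside nodes sit on the polar mid-surfaces,
    so the luminal and outer boundaries are curved isoparametric circles.
    The background label is artery; inclusions override it by centroid
    region membership, in declaration order. Deterministic for a fixed spec.
    """
    if spec.dim == 2:
        mesh = _annulus_mesh_2d(spec)
    else:
        mesh = _tube_mesh_3d(spec)
    labels = _labels_from_regions(mesh, spec)
    return replace(mesh, labels=labels)


def _polar_coords(spec: SynthVesselSpec) -> tuple[np.ndarray, np.ndarray]:
    nc, nr = 2 * spec.n_circ, 2 * spec.n_rad
    theta = 2 * np.pi * np.arange(nc) / nc
    r = spec.inner_radius + spec.wall_thickness * np.arange(nr + 1) / nr
    return theta, r


def _annulus_mesh_2d(spec: SynthVesselSpec) -> LabeledMesh:
    theta, r = _polar_coords(spec)
    nc, nr = len(theta), len(r)
    # fine grid node ids: id = i * nr + j  (i circumferential, j radial)
    tt, rr = np.meshgrid(theta, r, indexing="ij")
    coords = np.stack([rr * np.cos(tt), rr * np.sin(tt)], axis=-1).reshape(-1, 2)

    def nid(i: int | np.ndarray, j: int | np.ndarray) -> np.ndarray:
        return (np.asarray(i) % nc) * nr + np.asarray(j)

    tris = []
    for ci in range(spec.n_circ):
        for cj in range(spec.n_rad):
            i0, j0 = 2 * ci, 2 * cj
            # corner fine-indices of the quad cell
            c = {
                (0, 0): (i0, j0),
                (1, 0): (i0 + 2, j0),
                (1, 1): (i0 + 2, j0 + 2),
                (0, 1): (i0, j0 + 2),
            }
            for tri in (((0, 0), (1, 0), (1, 1)), ((0, 0), (1, 1), (0, 1))):
                corner_idx = [c[v] for v in tri]
                mids = [
                    (
                        (corner_idx[a][0] + corner_idx[b][0]) // 2,
                        (corner_idx[a][1] + corner_idx[b][1]) // 2,
                    )
                    for a, b in el.TRI6_EDGE_PAIRS
                ]
                nodes = [nid(i, j) for i, j in corner_idx + mids]
                tris.append(nodes)
    elements = np.array(tris, dtype=np.int64)
    # ensure positive orientation
    v0 = coords[elements[:, 1]] - coords[elements[:, 0]]
    v1 = coords[elements[:, 2]] - coords[elements[:, 0]]
    flip = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0] < 0
    if np.any(flip):
        elements[flip] = elements[flip][:, [0, 2, 1, 5, 4, 3]]
    labels = np.full(len(elements), int(Tissue.ARTERY), dtype=np.int64)
    return LabeledMesh(coords, elements, labels)


def _tube_mesh_3d(spec: SynthVesselSpec) -> LabeledMesh:
    theta, r = _polar_coords(spec)
    nz = 2 * spec.n_axial
    z = spec.length * np.arange(nz + 1) / nz
    nc, nr = len(theta), len(r)
    tt, rr, zz = np.meshgrid(theta, r, z, indexing="ij")
    coords = np.stack(
        [rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1
    ).reshape(-1, 3)

    def nid(idx: np.ndarray) -> np.ndarray:
        i, j, k = idx[..., 0] % nc, idx[..., 1], idx[..., 2]
        return (i * nr + j) * (nz + 1) + k

    kuhn = _kuhn_tets()
    tets = []
    for ci in range(spec.n_circ):
        for cj in range(spec.n_rad):
            for ck in range(spec.n_axial):
                base = np.array([2 * ci, 2 * cj, 2 * ck])
                for tet in kuhn:
                    corners = [base + 2 * np.array(v) for v in tet]
                    mids = [
                        (corners[a] + corners[b]) // 2
                        for a, b in el.TET10_EDGE_PAIRS
                    ]
                    nodes = [nid(np.asarray(ix)) for ix in corners + mids]
                    tets.append(nodes)
    elements = np.array(tets, dtype=np.int64)
    # fix orientation: swap corners 1,2 (and midside nodes accordingly)
    p = coords[elements[:, :4]]
    det = np.linalg.det(p[:, 1:] - p[:, [0]])
    flip = det < 0
    if np.any(flip):
        elements[flip] = elements[flip][:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]]
    labels = np.full(len(elements), int(Tissue.ARTERY), dtype=np.int64)
    return LabeledMesh(coords, elements, labels)


def _labels_from_regions(mesh: LabeledMesh, spec: SynthVesselSpec) -> np.ndarray:
    cent = mesh.element_centroids()
    r = np.linalg.norm(cent[:, :2], axis=1)
    theta = np.degrees(np.arctan2(cent[:, 1], cent[:, 0])) % 360.0
    rfrac = (r - spec.inner_radius) / spec.wall_thickness
    zfrac = cent[:, 2] / spec.length if mesh.dim == 3 else np.full(len(cent), 0.5)
    labels = np.full(len(cent), int(Tissue.ARTERY), dtype=np.int64)
    for inc in spec.inclusions:
        t0, t1 = inc.theta
        span = (t1 - t0) % 360.0 or 360.0
        in_theta = (theta - t0) % 360.0 <= span
        in_rad = (rfrac >= inc.radial[0]) & (rfrac <= inc.radial[1])
        in_ax = (zfrac >= inc.axial[0]) & (zfrac <= inc.axial[1])
        labels[in_theta & in_rad & in_ax] = int(inc.tissue)
    return labels
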