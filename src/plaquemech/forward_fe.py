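"""Forward finite-element simulation of a pressurized labeled vessel.

The forward operator deforms a labeled mesh under a luminal pressure
differential with both ends constrained longitudinally. Two kinematic
regimes are supported, matching the two constitutive models:

* **linear** — infinitesimal strain, pressure applied on the reference
  inner surface, single sparse solve;
* **yeoh** — total-Lagrangian finite strain with Newton-Raphson over load
  steps and a follower pressure evaluated on the deformed inner surface.

Elements are quadratic simplices (6-node triangles / 10-node tetrahedra),
which mitigates volumetric locking at near-incompressibility. In addition
to the longitudinal end constraints, three tangential (circumferential)
point constraints on the outer surface remove the in-plane rigid-body
modes; they are compatible with an axisymmetric response and rotate with
the geometry. The Newton tangent omits the (unsymmetric) follower-load
stiffness; convergence is retained through load stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements as el
from . import objective as obj
from .constitutive import LinearElasticParams, ParameterVector, YeohParams
from .geometry import Interface, LabeledMesh, NodeSetArray, extract_interfaces, extract_node_sets
from .tissues import Tissue

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322


def mmhg_to_kpa(p_mmhg: float | np.ndarray) -> float | np.ndarray:
    """Convert a pressure from mmHg to kPa (1 mmHg = 0.133322 kPa)."""
    return p_mmhg * MMHG_TO_KPA


class SimulationError(RuntimeError):
    """Raised when the forward solve fails (non-convergence, singular
    system, inverted elements)."""


@dataclass(frozen=True)
class LoadCase:
    """Luminal pressure differential between the two imaged states.

    ``p_base_mmhg`` and ``p_target_mmhg`` are the acquisition pressures;
    the solver consumes their difference, converted to kPa.
    """

    p_base_mmhg: float = 0.0
    p_target_mmhg: float = 60.0

    @property
    def delta_p_mmhg(self) -> float:
        return self.p_target_mmhg - self.p_base_mmhg

    @property
    def delta_p_kpa(self) -> float:
        return mmhg_to_kpa(self.delta_p_mmhg)


@dataclass(frozen=True)
class SolverSettings:
    """Forward-solver controls.

    ``n_steps`` load steps are used in the finite-strain mode (the linear
    mode is a single solve); Newton iterates until the constrained residual
    drops below ``newton_tol`` relative to the external load norm.
    ``pin_nodes`` optionally overrides the automatically selected
    tangential-constraint nodes (useful for objectivity checks).
    """

    n_steps: int = 4
    newton_tol: float = 1e-8
    max_newton: int = 30
    pin_nodes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.max_newton < 1 or self.newton_tol <= 0:
            raise ValueError("solver settings must be positive")


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement vectors (mm), shape (n_nodes, dim)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.ascontiguousarray(np.asarray(self.values, dtype=float))
        )


def apply_displacement(mesh: LabeledMesh, u: DisplacementField | np.ndarray) -> LabeledMesh:
    """Add nodal displacements to the coordinates; labels and connectivity
    are untouched."""
    vals = u.values if isinstance(u, DisplacementField) else np.asarray(u, dtype=float)
    if vals.shape != mesh.coords.shape:
        raise ValueError("displacement shape does not match the mesh")
    return replace(mesh, coords=mesh.coords + vals)


# --------------------------------------------------------------------------
# Constraints
# --------------------------------------------------------------------------

Constraint = tuple[int, np.ndarray, float]  # (node, unit direction, value)


def default_constraints(
    mesh: LabeledMesh, pin_nodes: tuple[int, ...] | None = None
) -> list[Constraint]:
    """Longitudinal end constraints plus three tangential point constraints.

    In 3D the axial displacement of every end-cap node is fixed. The
    remaining in-plane rigid modes (two translations and the rotation about
    the vessel axis) are removed by zeroing the circumferential displacement
    component at three outer-surface nodes roughly 120 degrees apart.
    """
    cons: list[Constraint] = []
    if mesh.dim == 3:
        ez = np.array([0.0, 0.0, 1.0])
        lo, hi = mesh.end_caps
        for n in np.concatenate([lo, hi]):
            cons.append((int(n), ez, 0.0))
    outer = np.unique(mesh.classified_boundary()["outer"])
    axis = mesh.section_axis()
    xy = mesh.coords[outer][:, :2] - axis
    if pin_nodes is None:
        theta = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
        if mesh.dim == 3:
            z = mesh.coords[outer][:, 2]
            zmid = 0.5 * (z.min() + z.max())
        chosen = []
        for target in (0.0, 120.0, 240.0):
            d = np.abs((theta - target + 180.0) % 360.0 - 180.0)
            if mesh.dim == 3:
                d = d + np.abs(z - zmid)
            chosen.append(int(outer[np.argmin(d)]))
        pin_nodes = tuple(chosen)
    for n in pin_nodes:
        v = mesh.coords[n][:2] - axis
        t = np.array([-v[1], v[0]])
        t /= np.linalg.norm(t)
        d = t if mesh.dim == 2 else np.array([t[0], t[1], 0.0])
        cons.append((int(n), d, 0.0))
    return cons


def _constraint_basis(
    mesh: LabeledMesh, constraints: list[Constraint]
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Build the orthonormal reduction map T and particular solution u_p.

    Displacements are represented as u = T uhat + u_p, where T has
    orthonormal columns spanning the constraint-free subspace.
    """
    dim = mesh.dim
    ndof = mesh.n_nodes * dim
    per_node: dict[int, list[tuple[np.ndarray, float]]] = {}
    for n, d, v in constraints:
        per_node.setdefault(n, []).append((np.asarray(d, dtype=float), v))

    rows, cols, data = [], [], []
    u_p = np.zeros(ndof)
    col = 0
    for n in range(mesh.n_nodes):
        if n not in per_node:
            for i in range(dim):
                rows.append(n * dim + i)
                cols.append(col)
                data.append(1.0)
                col += 1
            continue
        D = np.stack([d for d, _ in per_node[n]], axis=1)  # (dim, k)
        vals = np.array([v for _, v in per_node[n]])
        q, r = np.linalg.qr(D, mode="complete")
        k = D.shape[1]
        if np.linalg.matrix_rank(D, tol=1e-10) < k:
            raise SimulationError(f"redundant constraints at node {n}")
        free = q[:, k:]  # (dim, dim-k) orthonormal complement
        for j in range(free.shape[1]):
            for i in range(dim):
                rows.append(n * dim + i)
                cols.append(col)
                data.append(free[i, j])
            col += 1
        if np.any(vals):
            u_p[n * dim : (n + 1) * dim] = D @ np.linalg.solve(D.T @ D, vals)
    T = sp.csr_matrix((data, (rows, cols)), shape=(ndof, col))
    return T, u_p


# --------------------------------------------------------------------------
# FE model: precomputation and assembly
# --------------------------------------------------------------------------


class FEModel:
    """Precomputed assembly data for one labeled mesh.

    Holds reference shape-function gradients at quadrature points, the
    boundary (luminal) surface quadrature, the constraint reduction, and a
    cache of per-tissue unit-modulus stiffness matrices for the linear mode.
    Instances are reused across the many forward solves of a recovery.
    """

    def __init__(
        self,
        mesh: LabeledMesh,
        settings: SolverSettings | None = None,
        constraints: list[Constraint] | None = None,
    ):
        self.mesh = mesh
        self.settings = settings or SolverSettings()
        dim = mesh.dim
        if dim == 2:
            qp, qw = el.tri_quadrature()
            _, dN = el.tri6_shape(qp)
        else:
            qp, qw = el.tet_quadrature()
            _, dN = el.tet10_shape(qp)
        X = mesh.coords[mesh.elements]  # (nel, nn, dim)
        J = np.einsum("end,qna->eqda", X, dN)
        det = np.linalg.det(J)
        if np.any(det <= 0):
            raise SimulationError("mesh contains non-positive Jacobians")
        invJ = np.linalg.inv(J)
        #: gradient of shape function n w.r.t. reference coords: (nel,nq,nn,dim)
        self.G = np.einsum("qna,eqad->eqnd", dN, invJ)
        self.wdet = det * qw[None, :]
        nn = mesh.elements.shape[1]
        edof = (mesh.elements[:, :, None] * dim + np.arange(dim)).reshape(
            len(mesh.elements), nn * dim
        )
        self.edof = edof
        self._rows = np.repeat(edof, nn * dim, axis=1).ravel()
        self._cols = np.tile(edof, (1, nn * dim)).ravel()
        self.ndof = mesh.n_nodes * dim

        if constraints is None:
            constraints = default_constraints(mesh, self.settings.pin_nodes)
        self.constraints = constraints
        self.T, self.u_p = _constraint_basis(mesh, constraints)

        # luminal surface quadrature is built on first use: meshes driven
        # purely by prescribed displacements need no inner/outer surfaces
        self._surf = None
        self._surf_sign = None
        self._unit_K: dict[int, sp.csr_matrix] = {}
        self._B = None

    # -- luminal surface quadrature -------------------------------------------

    def _setup_surface(self) -> None:
        mesh = self.mesh
        inner = mesh.classified_boundary()["inner"]
        axis = mesh.section_axis()
        if mesh.dim == 2:
            xi, w = el.gauss1d(3)
            N, dN = el.edge3_shape(xi)
            self._surf = (inner, N, dN, w)
            x = mesh.coords[inner]  # (ne, 3, 2)
            t = np.einsum("qn,end->eqd", dN, x)
            n_raw = np.stack([t[..., 1], -t[..., 0]], axis=-1)
            mid = np.einsum("qn,end->eqd", N, x) - axis
        else:
            qp, w = el.tri_quadrature()
            N, dN = el.tri6_shape(qp)
            self._surf = (inner, N, dN, w)
            x = mesh.coords[inner]  # (nf, 6, 3)
            tu = np.einsum("qna,end->eqad", dN, x)
            n_raw = np.cross(tu[:, :, 0, :], tu[:, :, 1, :])
            mid = np.einsum("qn,end->eqd", N, x)
            mid = mid - np.concatenate(
                [np.broadcast_to(axis, mid[..., :2].shape), mid[..., 2:]], axis=-1
            )
        # orient the load outward from the vessel axis (inflating traction)
        s = np.sign(np.einsum("eqd,eqd->eq", n_raw[..., : mesh.dim][..., :2], mid[..., :2]))
        self._surf_sign = np.where(s.mean(axis=1) >= 0, 1.0, -1.0)

    def pressure_load(self, p_kpa: float, coords: np.ndarray | None = None) -> np.ndarray:
        """Consistent nodal forces of a luminal pressure; evaluated on the
        reference surface by default or on deformed ``coords`` (follower)."""
        mesh = self.mesh
        if p_kpa == 0.0:
            return np.zeros(self.ndof)
        if self._surf is None:
            self._setup_surface()
        inner, N, dN, w = self._surf
        xc = (coords if coords is not None else mesh.coords)[inner]
        if mesh.dim == 2:
            t = np.einsum("qn,end->eqd", dN, xc)
            n_raw = np.stack([t[..., 1], -t[..., 0]], axis=-1)
        else:
            tu = np.einsum("qna,end->eqad", dN, xc)
            n_raw = np.cross(tu[:, :, 0, :], tu[:, :, 1, :])
        n_or = n_raw * self._surf_sign[:, None, None]
        fe = p_kpa * np.einsum("q,qn,eqd->end", w, N, n_or)
        f = np.zeros(self.ndof)
        np.add.at(f, (inner[:, :, None] * mesh.dim + np.arange(mesh.dim)).ravel(), fe.ravel())
        return f

    # -- linear mode -----------------------------------------------------------

    def _voigt_B(self) -> np.ndarray:
        if self._B is not None:
            return self._B
        G = self.G
        nel, nq, nn, dim = G.shape
        nv = 3 if dim == 2 else 6
        B = np.zeros((nel, nq, nv, nn * dim))
        a = np.arange(nn)
        if dim == 2:
            B[:, :, 0, a * 2] = G[..., 0]
            B[:, :, 1, a * 2 + 1] = G[..., 1]
            B[:, :, 2, a * 2] = G[..., 1]
            B[:, :, 2, a * 2 + 1] = G[..., 0]
        else:
            B[:, :, 0, a * 3] = G[..., 0]
            B[:, :, 1, a * 3 + 1] = G[..., 1]
            B[:, :, 2, a * 3 + 2] = G[..., 2]
            B[:, :, 3, a * 3 + 1] = G[..., 2]
            B[:, :, 3, a * 3 + 2] = G[..., 1]
            B[:, :, 4, a * 3] = G[..., 2]
            B[:, :, 4, a * 3 + 2] = G[..., 0]
            B[:, :, 5, a * 3] = G[..., 1]
            B[:, :, 5, a * 3 + 1] = G[..., 0]
        self._B = B
        return B

    @staticmethod
    def _D_unit(dim: int, nu: float) -> np.ndarray:
        f = 1.0 / ((1 + nu) * (1 - 2 * nu))
        if dim == 2:
            return f * np.array(
                [[1 - nu, nu, 0], [nu, 1 - nu, 0], [0, 0, (1 - 2 * nu) / 2]]
            )
        D = np.zeros((6, 6))
        D[:3, :3] = nu
        np.fill_diagonal(D[:3, :3], 1 - nu)
        D[3:, 3:] = np.eye(3) * (1 - 2 * nu) / 2
        return f * D

    def unit_stiffness(self, tissue: Tissue, nu: float) -> sp.csr_matrix:
        """Stiffness of the elements carrying ``tissue`` at unit Young's
        modulus (cached; the full matrix is a modulus-weighted sum)."""
        key = int(tissue)
        if key not in self._unit_K:
            mask = self.mesh.labels == key
            B = self._voigt_B()[mask]
            D = self._D_unit(self.mesh.dim, nu)
            Ke = np.einsum("eqva,vw,eqwb,eq->eab", B, D, B, self.wdet[mask])
            nn_dim = B.shape[-1]
            rows = self._rows.reshape(-1, nn_dim * nn_dim)[mask].ravel()
            cols = self._cols.reshape(-1, nn_dim * nn_dim)[mask].ravel()
            K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof))
            self._unit_K[key] = K.tocsr()
        return self._unit_K[key]

    def solve_linear(
        self, materials: dict[Tissue, LinearElasticParams], p_kpa: float
    ) -> np.ndarray:
        present = [Tissue(int(c)) for c in np.unique(self.mesh.labels)]
        missing = [t.label for t in present if t not in materials]
        if missing:
            raise SimulationError(f"materials missing for tissues: {missing}")
        nu = materials[present[0]].nu
        K = sum(materials[t].E * self.unit_stiffness(t, nu) for t in present)
        f = self.pressure_load(p_kpa)
        T, u_p = self.T, self.u_p
        K_red = (T.T @ K @ T).tocsc()
        f_red = T.T @ (f - K @ u_p)
        try:
            x = spla.spsolve(K_red, f_red)
        except Exception as exc:  # singular factorization
            raise SimulationError(f"linear solve failed: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise SimulationError("singular system: insufficient constraints")
        return T @ x + u_p

    # -- finite-strain Yeoh mode ----------------------------------------------

    def _yeoh_coeff_arrays(
        self, materials: dict[Tissue, YeohParams]
    ) -> tuple[np.ndarray, ...]:
        labels = self.mesh.labels
        out = []
        for attr in ("c10", "c20", "c30", "kappa"):
            arr = np.empty(len(labels))
            for code in np.unique(labels):
                t = Tissue(int(code))
                if t not in materials:
                    raise SimulationError(f"materials missing for tissue {t.label}")
                arr[labels == code] = getattr(materials[t], attr)
            out.append(arr[:, None])  # broadcast over quadrature points
        return tuple(out)

    def _yeoh_stress_tangent(
        self, u: np.ndarray, coeffs: tuple[np.ndarray, ...], need_tangent: bool
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """First Piola-Kirchhoff stress (and material+geometric tangent) at
        every quadrature point, sliced to the mesh dimension."""
        mesh, G = self.mesh, self.G
        dim = mesh.dim
        U = u.reshape(-1, dim)[mesh.elements]  # (nel, nn, dim)
        gradu = np.einsum("eai,eqaj->eqij", U, G)
        nel, nq = gradu.shape[:2]
        F = np.zeros((nel, nq, 3, 3))
        F[..., :dim, :dim] = gradu
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        Jdet = np.linalg.det(F)
        if np.any(Jdet <= 0):
            raise SimulationError("inverted element detected (det F <= 0)")
        C = np.einsum("eqki,eqkj->eqij", F, F)
        iC = np.linalg.inv(C)
        I1 = np.einsum("eqii->eq", C)
        J23 = Jdet ** (-2.0 / 3.0)
        Ib1 = J23 * I1
        x = Ib1 - 3.0
        c10, c20, c30, kap = coeffs
        psi1 = c10 + 2 * c20 * x + 3 * c30 * x**2
        psi2 = 2 * c20 + 6 * c30 * x
        I3 = np.eye(3)
        A = J23[..., None, None] * I3 - (Ib1 / 3.0)[..., None, None] * iC
        S = 2 * psi1[..., None, None] * A + (kap * (Jdet - 1) * Jdet)[..., None, None] * iC
        P = np.einsum("eqik,eqkj->eqij", F, S)
        if not need_tangent:
            return P[..., :dim, :dim], None
        iCiC = np.einsum("eqab,eqcd->eqabcd", iC, iC)
        sym = 0.5 * (
            np.einsum("eqac,eqbd->eqabcd", iC, iC)
            + np.einsum("eqad,eqbc->eqabcd", iC, iC)
        )
        IiC = np.einsum("ab,eqcd->eqabcd", I3, iC)
        iCI = np.einsum("eqab,cd->eqabcd", iC, I3)
        H = (
            -(J23 / 3.0)[..., None, None, None, None] * (IiC + iCI)
            + (Ib1 / 9.0)[..., None, None, None, None] * iCiC
            + (Ib1 / 3.0)[..., None, None, None, None] * sym
        )
        AA = np.einsum("eqab,eqcd->eqabcd", A, A)
        CC = 4.0 * (psi2[..., None, None, None, None] * AA
                    + psi1[..., None, None, None, None] * H)
        CC += (kap * Jdet * (2 * Jdet - 1))[..., None, None, None, None] * iCiC
        CC -= (2 * kap * Jdet * (Jdet - 1))[..., None, None, None, None] * sym
        Atan = np.einsum("eqiA,eqAJBL,eqkB->eqiJkL", F, CC, F, optimize=True)
        d = np.arange(3)
        Atan[:, :, d, :, d, :] += S
        return P[..., :dim, :dim], Atan[..., :dim, :dim, :dim, :dim]

    def _internal_force(self, P: np.ndarray) -> np.ndarray:
        fe = np.einsum("eq,eqaJ,eqiJ->eai", self.wdet, self.G, P)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.ravel(), fe.reshape(len(fe), -1).ravel())
        return f

    def _tangent_matrix(self, Atan: np.ndarray) -> sp.csr_matrix:
        Ke = np.einsum(
            "eq,eqaJ,eqiJkL,eqbL->eaibk", self.wdet, self.G, Atan, self.G,
            optimize=True,
        )
        nel = Ke.shape[0]
        nn_dim = Ke.shape[1] * Ke.shape[2]
        data = Ke.reshape(nel, nn_dim, nn_dim).ravel()
        return sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.ndof, self.ndof)
        ).tocsr()

    def _follower_load_stiffness(self, p_kpa: float) -> sp.csr_matrix:
        """Exact derivative of the 2D follower pressure load w.r.t. the
        nodal displacements (the load is linear in the deformed edge
        tangent). Restores quadratic Newton convergence in the plane-strain
        mode; in 3D the load stiffness is omitted and convergence relies on
        load stepping."""
        if self._surf is None:
            self._setup_surface()
        inner, N, dN, w = self._surf
        rot = np.array([[0.0, 1.0], [-1.0, 0.0]])  # d perp(t) / d t
        # dK[a i, b k] = p s sum_q w_q N[q,a] rot[i,k] dN[q,b]
        coef = p_kpa * np.einsum("q,qa,ik,qb->aibk", w, N, rot, dN)
        Ke = self._surf_sign[:, None, None, None, None] * coef[None]
        edof = (inner[:, :, None] * 2 + np.arange(2)).reshape(len(inner), 6)
        rows = np.repeat(edof, 6, axis=1).ravel()
        cols = np.tile(edof, (1, 6)).ravel()
        return sp.coo_matrix(
            (Ke.reshape(len(inner), 6, 6).ravel(), (rows, cols)),
            shape=(self.ndof, self.ndof),
        ).tocsr()

    def solve_yeoh(
        self,
        materials: dict[Tissue, YeohParams],
        p_kpa: float,
        u0: np.ndarray | None = None,
    ) -> np.ndarray:
        """Total-Lagrangian Newton solve with load stepping, a consistent
        tangent, and a backtracking line search on the residual norm (the
        strongly stiffening Yeoh response makes undamped Newton overshoot
        on the first iterations of a load step)."""
        coeffs = self._yeoh_coeff_arrays(materials)
        st = self.settings
        T, u_p = self.T, self.u_p
        proj = T @ T.T
        coords = self.mesh.coords

        def residual(u: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
            f_ext = self.pressure_load(
                lam * p_kpa, (coords.reshape(-1) + u).reshape(coords.shape)
            )
            P, _ = self._yeoh_stress_tangent(u, coeffs, need_tangent=False)
            f_int = self._internal_force(P)
            r = T.T @ (f_ext - f_int)
            # reference force scale: external load, or the internal-force
            # magnitude when loading is purely through prescribed motion
            ref = max(np.linalg.norm(T.T @ f_ext), np.linalg.norm(f_int), 1e-12)
            return r, ref

        def newton(u0: np.ndarray, lam: float) -> np.ndarray | None:
            """Full-step Newton at load fraction ``lam``. The follower-load
            stiffness (unsymmetric) is added only once the residual is
            within 5% of the load norm: far from the solution it degrades
            the nonmonotone global convergence, near it it restores the
            quadratic rate. Returns None when the iteration diverges."""
            u = u0.copy()
            try:
                r, ref = residual(u, lam)
            except SimulationError:
                return None
            guard = 1e8 * max(np.linalg.norm(r), ref)
            prev = np.inf
            for _ in range(st.max_newton):
                rnorm = np.linalg.norm(r)
                if rnorm <= st.newton_tol * ref:
                    return u
                # roundoff floor: the residual stagnates near machine
                # precision of the penalized system well below any useful
                # tolerance — accept
                if rnorm > 0.5 * prev and rnorm <= 1e-6 * ref:
                    return u
                if not np.isfinite(rnorm) or rnorm > guard:
                    return None
                prev = rnorm
                _, Atan = self._yeoh_stress_tangent(u, coeffs, need_tangent=True)
                K = self._tangent_matrix(Atan)
                if self.mesh.dim == 2 and rnorm < 0.05 * ref:
                    K = K - self._follower_load_stiffness(lam * p_kpa)
                K_red = (T.T @ K @ T).tocsc()
                try:
                    du = spla.spsolve(K_red, r)
                except Exception as exc:
                    raise SimulationError(f"tangent solve failed: {exc}") from exc
                if not np.all(np.isfinite(du)):
                    raise SimulationError("singular tangent system")
                u = u + T @ du
                try:
                    r, ref = residual(u, lam)
                except SimulationError:
                    return None  # inverted trial state
            return None

        # warm start: attempt a single full-load Newton from a previous
        # converged state (very effective for the small parameter moves of
        # gradient evaluations); fall back to incremental loading
        if u0 is not None and u0.shape == (self.ndof,):
            u_try = newton(proj @ u0 + u_p, 1.0)
            if u_try is not None:
                return u_try

        # incremental loading with adaptive substep halving
        u = np.zeros(self.ndof)
        lam_done = 0.0
        dlam = 1.0 / st.n_steps
        dlam_min = dlam / 64.0
        while lam_done < 1.0 - 1e-12:
            lam = min(1.0, lam_done + dlam)
            u_try = newton(proj @ u + lam * u_p, lam)
            if u_try is None:
                dlam *= 0.5
                if dlam < dlam_min:
                    raise SimulationError(
                        f"Newton did not converge past load fraction {lam_done:.3f} "
                        f"(minimum substep reached)"
                    )
                continue
            u = u_try
            lam_done = lam
            dlam = min(2.0 * dlam, 1.0 / st.n_steps)
        return u

    def internal_forces(
        self, u: np.ndarray, materials: dict[Tissue, LinearElasticParams | YeohParams]
    ) -> np.ndarray:
        """Nodal internal-force vector at displacement state ``u`` — the
        reactions on constrained degrees of freedom balance the applied
        load through this vector."""
        first = next(iter(materials.values()))
        if isinstance(first, LinearElasticParams):
            present = [Tissue(int(c)) for c in np.unique(self.mesh.labels)]
            K = sum(materials[t].E * self.unit_stiffness(t, first.nu) for t in present)
            return K @ u
        coeffs = self._yeoh_coeff_arrays(materials)
        P, _ = self._yeoh_stress_tangent(u, coeffs, need_tangent=False)
        return self._internal_force(P)

    def max_stretch(self, u: np.ndarray) -> float:
        """Largest principal stretch over all quadrature points — the
        diagnostic behind holding C30 fixed (its influence needs >20% strain)."""
        mesh, G = self.mesh, self.G
        dim = mesh.dim
        U = u.reshape(-1, dim)[mesh.elements]
        gradu = np.einsum("eai,eqaj->eqij", U, G)
        F = np.zeros((*gradu.shape[:2], 3, 3))
        F[..., :dim, :dim] = gradu
        for i in range(3):
            F[..., i, i] += 1.0
        C = np.einsum("eqki,eqkj->eqij", F, F)
        return float(np.sqrt(np.linalg.eigvalsh(C)[..., -1].max()))


# --------------------------------------------------------------------------
# Public forward operator
# --------------------------------------------------------------------------


def simulate(
    base: LabeledMesh,
    load: LoadCase,
    Y: ParameterVector,
    settings: SolverSettings | None = None,
    model: FEModel | None = None,
    u0: np.ndarray | None = None,
) -> tuple[LabeledMesh, DisplacementField]:
    """Deform ``base`` under the luminal pressure differential of ``load``
    with material parameters ``Y``; returns the deformed mesh and the nodal
    displacement field. ``u0`` optionally warm-starts the finite-strain
    Newton iteration from a previously converged state."""
    fem = model if model is not None else FEModel(base, settings)
    mats = Y.materials()
    p = load.delta_p_kpa
    if Y.model == "linear":
        u = fem.solve_linear(mats, p)
    else:
        u = fem.solve_yeoh(mats, p, u0=u0)
    U = DisplacementField(u.reshape(base.coords.shape))
    return apply_displacement(base, U), U


class ForwardEvaluator:
    """The evaluator contract consumed by the optimizer: maps a
    :class:`~plaquemech.constitutive.ParameterVector` to an
    :class:`~plaquemech.objective.ObjectiveValue` by running one forward
    simulation and comparing against the fixed target geometry.

    Assembly data (shape-function gradients, surface quadrature, the
    per-tissue unit stiffness matrices of the linear mode) is precomputed
    once and shared across the hundreds of evaluations of a recovery.
    """

    def __init__(
        self,
        base: LabeledMesh,
        target: LabeledMesh,
        load: LoadCase,
        settings: SolverSettings | None = None,
        mode: "obj.ObjectiveMode | str" = "interface",
        nsets: NodeSetArray | None = None,
        interfaces: list[Interface] | None = None,
        n_slices: int = 10,
    ):
        self.base = base
        self.target = target
        self.load = load
        self.fem = FEModel(base, settings)
        self.mode = obj.ObjectiveMode(mode)
        self.nsets = nsets if nsets is not None else extract_node_sets(base)
        self.interfaces = (
            interfaces if interfaces is not None else extract_interfaces(self.nsets)
        )
        self.n_slices = n_slices
        self.n_simulations = 0
        self._last_u: np.ndarray | None = None

    @property
    def n_objectives(self) -> int:
        return len(self.interfaces) if self.mode is obj.ObjectiveMode.INTERFACE else 2

    def __call__(self, Y: ParameterVector) -> "obj.ObjectiveValue":
        self.n_simulations += 1
        deformed, U = simulate(
            self.base, self.load, Y, model=self.fem, u0=self._last_u
        )
        self._last_u = U.values.reshape(-1)
        return obj.evaluate(
            deformed,
            self.target,
            self.nsets,
            mode=self.mode,
            interfaces=self.interfaces,
            n_slices=self.n_slices,
        )
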