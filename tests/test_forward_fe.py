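"""Forward solver verification: closed-form benchmarks and invariants.

The main oracles are the plane-strain thick-walled-cylinder (Lamé) solution
for the linear mode and the closed-form incompressible uniaxial response
for the Yeoh mode (checked on a small cube of tetrahedra under prescribed
stretch with free lateral faces).
"""

import numpy as np
import pytest

from plaquemech.constitutive import (
    NU_LINEAR,
    LinearElasticParams,
    YeohParams,
    pack,
    yeoh_uniaxial_stress,
)
from plaquemech.forward_fe import (
    FEModel,
    LoadCase,
    SolverSettings,
    apply_displacement,
    default_constraints,
    mmhg_to_kpa,
    simulate,
)
from plaquemech.geometry import LabeledMesh, SynthVesselSpec, generate_synthetic_vessel
from plaquemech.tissues import Tissue

from conftest import LOAD


def lame_radial_displacement(r, p, E, nu, r_in, r_out):
    """Plane-strain thick-walled cylinder under internal pressure."""
    return (
        (1 + nu) / E * p * r_in**2 / (r_out**2 - r_in**2)
        * ((1 - 2 * nu) * r + r_out**2 / r)
    )


def quadratic_tet_cube(nx: int = 1) -> LabeledMesh:
    """Unit cube meshed with 10-node tetrahedra (Kuhn decomposition)."""
    from plaquemech.geometry import _kuhn_tets
    from plaquemech.elements import TET10_EDGE_PAIRS

    n = 2 * nx + 1
    axis = np.linspace(0.0, 1.0, n)
    grid = {}
    coords = []

    def nid(i, j, k):
        key = (i, j, k)
        if key not in grid:
            grid[key] = len(coords)
            coords.append([axis[i], axis[j], axis[k]])
        return grid[key]

    tets = []
    for cx in range(nx):
        for cy in range(nx):
            for cz in range(nx):
                base = np.array([2 * cx, 2 * cy, 2 * cz])
                for tet in _kuhn_tets():
                    corners = [base + 2 * np.array(v) for v in tet]
                    mids = [
                        (corners[a] + corners[b]) // 2 for a, b in TET10_EDGE_PAIRS
                    ]
                    tets.append([nid(*ix) for ix in corners + mids])
    elements = np.array(tets)
    coords = np.array(coords)
    p = coords[elements[:, :4]]
    det = np.linalg.det(p[:, 1:] - p[:, [0]])
    flip = det < 0
    elements[flip] = elements[flip][:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]]
    labels = np.full(len(elements), int(Tissue.ARTERY))
    return LabeledMesh(coords, elements, labels)


def uniaxial_constraints(mesh: LabeledMesh, stretch: float):
    """Symmetry planes at x=y=z=0, prescribed x-motion of the x=1 face."""
    tol = 1e-9
    cons = []
    ex, ey, ez = np.eye(3)
    for n, (x, y, z) in enumerate(mesh.coords):
        if abs(x) < tol:
            cons.append((n, ex, 0.0))
        if abs(y) < tol:
            cons.append((n, ey, 0.0))
        if abs(z) < tol:
            cons.append((n, ez, 0.0))
        if abs(x - 1.0) < tol:
            cons.append((n, ex, stretch - 1.0))
    return cons


class TestUnits:
    @pytest.mark.parametrize("mmhg,kpa", [(0.0, 0.0), (1.0, 0.133322), (60.0, 7.99932)])
    def test_mmhg_conversion(self, mmhg, kpa):
        assert mmhg_to_kpa(mmhg) == pytest.approx(kpa)

    def test_load_case_differential(self):
        load = LoadCase(p_base_mmhg=60.0, p_target_mmhg=120.0)
        assert load.delta_p_mmhg == 60.0
        assert load.delta_p_kpa == pytest.approx(7.99932)


class TestLinearMode:
    def test_lame_thick_walled_cylinder(self, vessel2d_homogeneous):
        spec = SynthVesselSpec(dim=2, n_circ=24, n_rad=4, inclusions=())
        fem = FEModel(vessel2d_homogeneous)
        E, p = 300.0, mmhg_to_kpa(60.0)
        u = fem.solve_linear({Tissue.ARTERY: LinearElasticParams(E)}, p).reshape(-1, 2)
        r = np.linalg.norm(vessel2d_homogeneous.coords, axis=1)
        ur = np.einsum("nd,nd->n", u, vessel2d_homogeneous.coords / r[:, None])
        exact = lame_radial_displacement(
            r, p, E, NU_LINEAR, spec.inner_radius, spec.outer_radius
        )
        assert np.max(np.abs(ur - exact) / exact) < 0.02

    def test_lame_convergence_under_refinement(self):
        errs = []
        for n_c, n_r in [(12, 2), (24, 4), (48, 8)]:
            spec = SynthVesselSpec(dim=2, n_circ=n_c, n_rad=n_r, inclusions=())
            mesh = generate_synthetic_vessel(spec)
            fem = FEModel(mesh)
            p = mmhg_to_kpa(60.0)
            u = fem.solve_linear({Tissue.ARTERY: LinearElasticParams(300.0)}, p)
            u = u.reshape(-1, 2)
            r = np.linalg.norm(mesh.coords, axis=1)
            ur = np.einsum("nd,nd->n", u, mesh.coords / r[:, None])
            exact = lame_radial_displacement(
                r, p, 300.0, NU_LINEAR, spec.inner_radius, spec.outer_radius
            )
            errs.append(np.max(np.abs(ur - exact) / exact))
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 0.02  # reference refinement

    def test_lame_3d_tube_matches_plane_strain(self, vessel3d_small):
        """With both end caps fixed axially, the straight tube is in plane
        strain and the 2D Lamé solution applies exactly."""
        spec = SynthVesselSpec(dim=3, n_circ=12, n_rad=2, n_axial=2, inclusions=())
        fem = FEModel(vessel3d_small)
        p = mmhg_to_kpa(60.0)
        u = fem.solve_linear({Tissue.ARTERY: LinearElasticParams(300.0)}, p)
        u = u.reshape(-1, 3)
        r = np.linalg.norm(vessel3d_small.coords[:, :2], axis=1)
        ur = np.einsum(
            "nd,nd->n", u[:, :2], vessel3d_small.coords[:, :2] / r[:, None]
        )
        exact = lame_radial_displacement(
            r, p, 300.0, NU_LINEAR, spec.inner_radius, spec.outer_radius
        )
        assert np.max(np.abs(ur - exact) / exact) < 0.03
        # interior axial motion is a discretization artifact and stays small
        assert np.abs(u[:, 2]).max() < 5e-3 * np.abs(ur).max()

    def test_linearity_in_modulus_and_pressure(self, vessel2d, bounds, linear_target):
        y = linear_target["assigned"]
        u1 = linear_target["u"].values
        _, u2 = simulate(vessel2d, LOAD, y.with_free_values(2 * y.free_values()))
        # calcium E is fixed; double it too through the materials path
        fem = FEModel(vessel2d)
        mats = {t: LinearElasticParams(2 * m.E) for t, m in y.materials().items()}
        u2b = fem.solve_linear(mats, LOAD.delta_p_kpa).reshape(u1.shape)
        assert np.allclose(u2b, u1 / 2, rtol=1e-9, atol=1e-14)
        dbl = LoadCase(p_base_mmhg=0.0, p_target_mmhg=120.0)
        _, u3 = simulate(vessel2d, dbl, y)
        assert np.allclose(u3.values, 2 * u1, rtol=1e-9, atol=1e-14)

    def test_zero_pressure_differential_is_identity(self, vessel2d, bounds):
        y = pack(bounds, "linear")
        deformed, u = simulate(vessel2d, LoadCase(60.0, 60.0), y)
        assert np.allclose(u.values, 0.0, atol=1e-12)
        assert np.array_equal(deformed.coords, vessel2d.coords)

    def test_equilibrium_global_force_balance(self, vessel2d, linear_target):
        """The luminal pressure on a closed section is self-equilibrated:
        internal forces balance external forces on the free DOFs and the
        net reaction vanishes."""
        fem = FEModel(vessel2d)
        y = linear_target["assigned"]
        u = linear_target["u"].values.reshape(-1)
        f_int = fem.internal_forces(u, y.materials())
        f_ext = fem.pressure_load(LOAD.delta_p_kpa)
        scale = np.linalg.norm(f_ext)
        assert np.linalg.norm(fem.T.T @ (f_int - f_ext)) < 1e-8 * scale
        net = (f_int - f_ext).reshape(-1, 2).sum(axis=0)
        assert np.linalg.norm(net) < 1e-8 * scale

    def test_objectivity_under_rotation(self, bounds):
        """Rotating the section (and keeping the constraints attached to
        the same material points) rotates the displacement field."""
        spec = SynthVesselSpec(dim=2, n_circ=16, n_rad=3)
        mesh = generate_synthetic_vessel(spec)
        y = pack(bounds, "linear")
        cons = default_constraints(mesh)
        pins = tuple(n for n, d, v in cons)
        settings = SolverSettings(pin_nodes=pins)
        _, u = simulate(mesh, LOAD, y, settings=settings)
        ang = 2 * np.pi / 16  # one coarse cell: rotated mesh reuses node angles
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        from dataclasses import replace

        rotated = replace(mesh, coords=mesh.coords @ R.T)
        _, u_rot = simulate(rotated, LOAD, y, settings=settings)
        assert np.allclose(u_rot.values, u.values @ R.T, atol=1e-10)

    def test_uniaxial_cube_matches_hooke(self):
        mesh = quadratic_tet_cube(1)
        fem = FEModel(mesh, constraints=uniaxial_constraints(mesh, 1.001))
        E = 300.0
        # prescribed-displacement solve: K (T x + u_p) balanced on free DOFs
        import scipy.sparse.linalg as spla

        T, u_p = fem.T, fem.u_p
        Kmat = E * fem.unit_stiffness(Tissue.ARTERY, NU_LINEAR)
        x = spla.spsolve((T.T @ Kmat @ T).tocsc(), T.T @ (-Kmat @ u_p))
        u = T @ x + u_p
        f = Kmat @ u
        loaded = np.abs(mesh.coords[:, 0] - 1.0) < 1e-9
        reaction = f.reshape(-1, 3)[loaded, 0].sum()
        sigma = reaction / 1.0  # unit cross-section
        assert sigma == pytest.approx(E * 0.001, rel=1e-6)


class TestYeohMode:
    def test_zero_pressure_differential_is_identity(self, vessel2d, bounds):
        y = pack(bounds, "yeoh")
        _, u = simulate(vessel2d, LoadCase(60.0, 60.0), y)
        assert np.allclose(u.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("stretch", [1.05, 1.15, 1.3])
    def test_uniaxial_cube_matches_closed_form(self, stretch):
        """Finite-strain solve of a stretched cube with free lateral faces
        reproduces the incompressible closed-form Cauchy stress within 1%."""
        mesh = quadratic_tet_cube(1)
        params = YeohParams(c10=5.64, c20=18.12, c30=1.62)
        fem = FEModel(
            mesh,
            settings=SolverSettings(n_steps=4),
            constraints=uniaxial_constraints(mesh, stretch),
        )
        u = fem.solve_yeoh({Tissue.ARTERY: params}, p_kpa=0.0)
        f = fem.internal_forces(u, {Tissue.ARTERY: params})
        loaded = np.abs(mesh.coords[:, 0] - 1.0) < 1e-9
        nominal = f.reshape(-1, 3)[loaded, 0].sum()  # P * A0, A0 = 1
        # Cauchy stress: sigma = P * lambda / J with J from the lateral motion
        corners = np.all(np.abs(mesh.coords - [1, 1, 1]) < 1e-9, axis=1)
        lam_y = 1.0 + u.reshape(-1, 3)[corners, 1][0]
        lam_z = 1.0 + u.reshape(-1, 3)[corners, 2][0]
        J = stretch * lam_y * lam_z
        sigma = nominal * stretch / J
        assert sigma == pytest.approx(yeoh_uniaxial_stress(stretch, params), rel=0.01)

    def test_small_strain_matches_linear_with_e_6c10(self, vessel2d_homogeneous):
        """At <=1% strain the Yeoh response coincides with a nearly
        incompressible linear material of E = 6 C10 within 2%."""
        fem = FEModel(vessel2d_homogeneous)
        c10 = 300.0
        p = mmhg_to_kpa(5.0)  # small load -> small strain
        u_y = fem.solve_yeoh({Tissue.ARTERY: YeohParams(c10)}, p)
        u_l = fem.solve_linear(
            {Tissue.ARTERY: LinearElasticParams(6 * c10, nu=0.4995)}, p
        )
        assert np.abs(u_y).max() < 0.01 * 1.0  # strain regime check
        denom = np.abs(u_l).max()
        assert np.max(np.abs(u_y - u_l)) / denom < 0.02

    def test_follower_vs_reference_load_softening(self, vessel2d_homogeneous):
        """The follower pressure acts on the enlarged deformed lumen, so it
        deforms the vessel more than the same dead load."""
        fem = FEModel(vessel2d_homogeneous)
        mats = {Tissue.ARTERY: YeohParams(5.64, 18.0)}
        p = mmhg_to_kpa(60.0)
        u = fem.solve_yeoh(mats, p)
        f_dead = fem.pressure_load(p)
        f_follow = fem.pressure_load(
            p, vessel2d_homogeneous.coords + u.reshape(-1, 2)
        )
        assert np.linalg.norm(f_follow) > np.linalg.norm(f_dead)

    def test_newton_reports_nonconvergence(self, vessel2d_homogeneous):
        from plaquemech.forward_fe import SimulationError

        fem = FEModel(
            vessel2d_homogeneous, settings=SolverSettings(n_steps=1, max_newton=1)
        )
        # absurd load on a very soft wall with single step and one iteration
        with pytest.raises(SimulationError):
            fem.solve_yeoh({Tissue.ARTERY: YeohParams(0.01)}, 1000.0)


class TestApplyDisplacement:
    def test_zero_displacement_is_identity(self, vessel2d):
        out = apply_displacement(vessel2d, np.zeros_like(vessel2d.coords))
        assert np.array_equal(out.coords, vessel2d.coords)
        assert out.elements is vessel2d.elements or np.array_equal(
            out.elements, vessel2d.elements
        )

    def test_additivity(self, vessel2d):
        rng = np.random.default_rng(1)
        u1 = rng.normal(size=vessel2d.coords.shape) * 0.01
        u2 = rng.normal(size=vessel2d.coords.shape) * 0.01
        a = apply_displacement(apply_displacement(vessel2d, u1), u2)
        b = apply_displacement(vessel2d, u1 + u2)
        assert np.allclose(a.coords, b.coords)

    def test_shape_mismatch_rejected(self, vessel2d):
        with pytest.raises(ValueError):
            apply_displacement(vessel2d, np.zeros((3, 2)))
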