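"""Shared fixtures: small vessel meshes, targets, and the seeded recovery
studies reused by several test modules (recoveries are the expensive part,
so they are session-scoped)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from plaquemech.constitutive import default_bounds, pack
from plaquemech.forward_fe import FEModel, LoadCase, simulate
from plaquemech.geometry import SynthVesselSpec, generate_synthetic_vessel

warnings.filterwarnings("ignore", message="interface .* dropped")

#: Desk-scale plane-strain section used by the recovery studies.
STUDY_SPEC = SynthVesselSpec(dim=2, n_circ=24, n_rad=4)

#: Acquisition pressure states: 0 -> 60 mmHg differential.
LOAD = LoadCase(p_base_mmhg=0.0, p_target_mmhg=60.0)


@pytest.fixture(scope="session")
def bounds():
    return default_bounds()


@pytest.fixture(scope="session")
def vessel2d():
    """Heterogeneous plane-strain section with the default inclusion layout."""
    return generate_synthetic_vessel(STUDY_SPEC)


@pytest.fixture(scope="session")
def vessel2d_homogeneous():
    return generate_synthetic_vessel(
        SynthVesselSpec(dim=2, n_circ=24, n_rad=4, inclusions=())
    )


@pytest.fixture(scope="session")
def vessel3d_small():
    return generate_synthetic_vessel(
        SynthVesselSpec(dim=3, n_circ=12, n_rad=2, n_axial=2, inclusions=())
    )


@pytest.fixture(scope="session")
def linear_target(vessel2d, bounds):
    """Noise-free linear-elastic target and its displacement field."""
    y = pack(bounds, "linear")
    target, u = simulate(vessel2d, LOAD, y)
    return {"assigned": y, "target": target, "u": u}


@pytest.fixture(scope="session")
def yeoh_target(vessel2d, bounds):
    """Noise-free Yeoh target and its displacement field."""
    y = pack(bounds, "yeoh")
    target, u = simulate(vessel2d, LOAD, y)
    return {"assigned": y, "target": target, "u": u}


@pytest.fixture(scope="session")
def fem2d(vessel2d):
    return FEModel(vessel2d)


@pytest.fixture(scope="session")
def noise_ladder(bounds):
    """Linear-elastic recovery studies at noise levels 0, 5% and 20%,
    four seeded runs each, at the standard linear protocol budget."""
    from plaquemech.experiments import NoiseSpec, StudyConfig, run_study
    from plaquemech.optimizer import OptimizerConfig

    out = {}
    for n in (0.0, 0.05, 0.20):
        cfg = StudyConfig(
            spec=STUDY_SPEC,
            model="linear",
            load=LOAD,
            optimizer=OptimizerConfig(population=24, generations=7, sqp_max_evals=40),
            noise=None if n == 0 else NoiseSpec(n=n),
            seeds=(1, 2, 3, 4),
            bounds=bounds,
        )
        out[n] = run_study(cfg)
    return out


@pytest.fixture(scope="session")
def mode_comparison(bounds):
    """Paired-seed linear recoveries under the three objective modes."""
    from plaquemech.experiments import StudyConfig, compare_objective_modes
    from plaquemech.optimizer import OptimizerConfig

    cfg = StudyConfig(
        spec=STUDY_SPEC,
        model="linear",
        load=LOAD,
        optimizer=OptimizerConfig(population=24, generations=7, sqp_max_evals=40),
        seeds=(1, 2),
        bounds=bounds,
    )
    return compare_objective_modes(cfg)
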