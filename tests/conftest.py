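"""Shared fixtures: canonical phantoms and their measurements.

The extrusion sweep and the acquisition-emulated pair are expensive, so they
are built once per session and shared by the unit and acceptance suites.
"""

from types import SimpleNamespace

import numpy as np
import pytest
import trimesh

from meniscus3d import (
    MeniscusSpec,
    PhantomSpec,
    fit_tibial_frame,
    make_phantom,
    measure_extrusion,
)
from meniscus3d.phantom import emulate_acquisition

E_VALUES = (0.0, 1.0, 2.0, 3.0, 4.5, 5.0, 6.0)


def _measure_phantom(spec: PhantomSpec) -> SimpleNamespace:
    tibia, meniscus, truth = make_phantom(spec)
    frame = fit_tibial_frame(tibia, notch_plane_point=[0.0, spec.notch_level_y, 0.0])
    result, section, plateau = measure_extrusion(tibia, meniscus, frame)
    return SimpleNamespace(
        spec=spec,
        tibia=tibia,
        meniscus=meniscus,
        truth=truth,
        frame=frame,
        result=result,
        section=section,
        plateau=plateau,
        meniscus_local=frame.mesh_to_frame(meniscus),
    )


@pytest.fixture(scope="session")
def phantom_sweep():
    """Full measurement chain for each construction extrusion offset."""
    return {e: _measure_phantom(PhantomSpec(meniscus=MeniscusSpec(extrusion_mm=e))) for e in E_VALUES}


@pytest.fixture(scope="session")
def phantom_default(phantom_sweep):
    return phantom_sweep[3.0]


@pytest.fixture(scope="session")
def emulated_tibia_pair(phantom_default):
    """CT-like and MRI-like reconstructions of the same clean tibia."""
    tibia = phantom_default.tibia
    return (
        emulate_acquisition(tibia, "ct", seed=11),
        emulate_acquisition(tibia, "mri", seed=12),
    )


@pytest.fixture(scope="session")
def sphere20():
    return trimesh.creation.icosphere(subdivisions=4, radius=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
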