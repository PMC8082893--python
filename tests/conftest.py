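"""Shared fixtures: all geometry is generated programmatically at test time."""

import numpy as np
import pytest
import trimesh

import guideval as gv


@pytest.fixture(scope="session")
def phantom():
    """One CT-like bone phantom reused by segmentation/registration tests."""
    return gv.generate_bone_phantom(gv.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def ground_truth(phantom):
    return phantom.ground_truth_mesh


@pytest.fixture(scope="session")
def bone_model(phantom):
    """Segmented + extracted surface model of the phantom volume."""
    mask = gv.threshold_segment(phantom.volume, lower=226)
    return gv.extract_surface(mask)


@pytest.fixture(scope="session")
def guide_design(bone_model):
    return gv.design_saw_guide(bone_model, "proximal", side="radius")


@pytest.fixture(scope="session")
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


def make_records(rng, n_guides=8, n_observers=3, sd=1.0, mean=2.0, repeat_observer=None):
    """Synthetic placement-record table with iid |N(mean, sd)| errors."""
    rows = []
    sessions = [(o, 0) for o in range(1, n_observers + 1)]
    if repeat_observer:
        sessions.append((repeat_observer, 1))
    for obs, rep in sessions:
        for g in range(n_guides):
            for mod in ("CT", "sCT"):
                vals = np.abs(rng.normal(mean, sd, 8))
                rows.append(
                    dict(observer=obs, specimen=g, bone="radius", location="distal",
                         modality=mod, repeat=rep,
                         dx=vals[0], dy=vals[1], dz=vals[2], dT=vals[3],
                         phix=vals[4], phiy=vals[5], phiz=vals[6], dR=vals[7],
                         icp_rms=0.1, converged=True)
                )
    return gv.stats.records_frame(rows)
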