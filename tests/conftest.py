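"""Shared fixtures: phantoms and fitted fields are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import rewardnet as rn


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free straight bundle, 3x3 cross-section, 20 voxels long."""
    spec = rn.PhantomSpec(grid_shape=(9, 9, 26), geometry="straight_bundle",
                          bundle_cross_section=3, bundle_length=20,
                          noise_sigma=0.0, seed=0)
    acq, parc, truth = rn.make_phantom(spec)
    return spec, acq, parc, truth


@pytest.fixture(scope="session")
def straight_field(straight_phantom):
    spec, acq, parc, truth = straight_phantom
    return rn.fit_tensors(acq, method="ols", fit_mask=acq.wm_mask | (parc > 0))


@pytest.fixture(scope="session")
def straight_streams(straight_phantom, straight_field):
    _, acq, parc, _ = straight_phantom
    return rn.track(straight_field, acq.wm_mask | (parc > 0),
                    rn.TrackingConfig(), seed_mask=acq.wm_mask)


@pytest.fixture(scope="session")
def curved_phantom():
    spec = rn.PhantomSpec(grid_shape=(32, 32, 32), geometry="curved_bundle",
                          bundle_cross_section=3, noise_sigma=0.0, seed=0)
    acq, parc, truth = rn.make_phantom(spec)
    return spec, acq, parc, truth


def make_direction_field(v1_map: dict, shape, fa_value: float = 0.8):
    """Hand-built TensorField for tracking tests: only fa / v1 / defined
    matter to the tracker."""
    fa = np.full(shape, np.nan)
    v1 = np.full(shape + (3,), np.nan)
    defined = np.zeros(shape, dtype=bool)
    for vox, v in v1_map.items():
        v = np.asarray(v, dtype=float)
        v1[vox] = v / np.linalg.norm(v)
        fa[vox] = fa_value
        defined[vox] = True
    dummy = np.full(shape + (3, 3), np.nan)
    evals = np.full(shape + (3,), np.nan)
    return rn.TensorField(tensor=dummy, eigenvalues=evals, fa=fa, v1=v1,
                          defined=defined)
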