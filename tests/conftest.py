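"""Shared fixtures: small phantoms rendered once per session."""

import math

import numpy as np
import pytest
from hypothesis import settings

import spinemorph as sm

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def five_spine():
    """Noise-free 5-spine phantom at confocal spacing, with its truth."""
    stack, truth = sm.render_phantom(sm.default_five_spine_spec(seed=0))
    return stack, truth


@pytest.fixture(scope="session")
def five_spine_state(five_spine):
    """Full pipeline state run on the noise-free 5-spine phantom."""
    stack, truth = five_spine
    state = sm.build_state(stack, truth.dendrite_model, sm.RunConfig())
    sm.detect_stage(state)
    sm.segment_stage(state)
    sm.trace_stage(state)
    sm.measure_stage(state)
    return state


@pytest.fixture(scope="session")
def mixed_phantom():
    """3 stubby + 5 necked spines (1.0 µm straight necks), noise-free."""
    from spinemorph.phantom import default_stubby_necked_spec

    stack, truth = sm.render_phantom(default_stubby_necked_spec(seed=0))
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_border_distance(mask, spacing_xyz):
    """Exhaustive nearest-border-voxel search (the oracle for the EDT)."""
    dx, dy, dz = spacing_xyz
    sp = np.array([dz, dy, dx])
    from scipy import ndimage

    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    border = np.argwhere(mask & ~eroded)
    out = np.zeros(mask.shape)
    for idx in np.ndindex(mask.shape):
        if mask[idx]:
            continue
        d = np.linalg.norm((border - np.asarray(idx)) * sp, axis=1)
        out[idx] = d.min()
    return out
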