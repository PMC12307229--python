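"""Shared synthetic scenes; session-scoped because generation dominates runtime."""

import numpy as np
import pytest

from pushscope.synth import (
    BeadSceneParams,
    NoiseModel,
    generate_bead_stack,
)


@pytest.fixture(scope="session")
def bead_scene():
    """Default pushing-force scene: 20 beads, 0.8 um amplitude, SNR 5."""
    params = BeadSceneParams(seed=1)
    stack, truth = generate_bead_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def noiseless_bead_scene():
    params = BeadSceneParams(seed=1, noise_model=NoiseModel(gaussian_sd=0.0))
    stack, truth = generate_bead_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_bead_params():
    """A small, fast scene for parameter-variation tests."""
    return dict(
        image_shape=(16, 28, 64, 96),
        n_beads=4,
        seed=7,
    )


def match_bead(record, truth):
    """Index of the ground-truth bead nearest a detected record."""
    cy, cx = record.xy_centroid_px
    d = np.hypot(truth.bead_xy_px[:, 0] - cy, truth.bead_xy_px[:, 1] - cx)
    return int(d.argmin()), float(d.min())
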