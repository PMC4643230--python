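"""Shared fixtures: small seeded synthetic scenes reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from caflux.movie_io import MovieStack, RunConfig
from caflux.synthetic import SceneConfig, generate_movie
from caflux.pipeline import analyze_stack, match_to_ground_truth


SMALL_SCENE = SceneConfig(image_size=(300, 300), n_cells=40, n_frames=600, seed=3)


@pytest.fixture(scope="session")
def small_movie():
    """A 40-cell, 300x300, 300 s movie at 2 Hz with ground truth."""
    return generate_movie(SMALL_SCENE)


@pytest.fixture(scope="session")
def small_analysis(small_movie):
    """Full pipeline products + ground-truth match for the small movie."""
    stack, gt = small_movie
    config = RunConfig()
    result = analyze_stack(stack, config)
    matched = match_to_ground_truth(result.records, result.annotations, gt, stack)
    return stack, gt, config, result, matched


@pytest.fixture(scope="session")
def noise_free_movie():
    """Small noise-free movie for exactness checks (subsampling, traces)."""
    scene = SceneConfig(
        image_size=(220, 220), n_cells=12, n_frames=400,
        noise_gaussian_sd=0.0, seed=9,
    )
    return generate_movie(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(frames: np.ndarray, interval: float = 0.5) -> MovieStack:
    return MovieStack(frames=np.asarray(frames), frame_interval=interval)
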