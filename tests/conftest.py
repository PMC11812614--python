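"""Shared fixtures: small deterministic scenes for fast unit tests."""

import numpy as np
import pytest

from uncertainscan import (
    CueNoiseSpec,
    ObjectSpec,
    SyntheticCueProvider,
    SyntheticSceneSpec,
    generate_scene,
)

NOISELESS = CueNoiseSpec(
    jitter_px=0.0, merge_prob=0.0, split_prob=0.0, prompt_jitter_px=0.0
)


def small_spec(n_frames: int = 20, size: int = 48) -> SyntheticSceneSpec:
    """Two well-separated objects, one moving, on a small frame."""
    return SyntheticSceneSpec(
        objects=[
            ObjectSpec(center=(12.0, 12.0), size=5.0, velocity=(0.5, 0.25), saliency=1.0),
            ObjectSpec(center=(34.0, 34.0), size=(12.0, 10.0), shape="rect",
                       n_parts=2, saliency=0.6),
        ],
        n_frames=n_frames,
        height=size,
        width=size,
        px_per_dva=4.0,
        scene_id="unit-small",
    )


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_spec(), seed=0)


@pytest.fixture(scope="session")
def clean_provider():
    """Noise-free cue provider for deterministic filter tests."""
    return SyntheticCueProvider(noise=NOISELESS, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
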