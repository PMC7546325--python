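"""Shared fixtures: seeded synthetic scenes and a trained classifier.

Everything is generated programmatically — there are no image files on
disk.  The session-scoped model fixture exists because quadratic-SVM
training plus hard-negative mining takes ~15 s and several test modules
want the same classifier.
"""

import numpy as np
import pytest
from hypothesis import settings

from stomapore import cli, synthgen

# property tests must behave identically on every machine and run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_single_stomate_scene():
    """One noise-free, vein-free stomate on a textured background."""
    spec = synthgen.SceneSpec(
        height=220, width=220, n_stomata=1, seed=77, polarity_mix=0.0
    ).clean()
    return synthgen.generate_scene(spec)


@pytest.fixture(scope="session")
def default_scene():
    """A full default-condition scene (blur, noise, veins, artifacts)."""
    return synthgen.generate_scene(synthgen.SceneSpec(seed=404))


@pytest.fixture(scope="session")
def trained_model():
    """Classifier + extractor trained with the standard budget."""
    specs = [synthgen.SceneSpec(seed=10_000 + i) for i in range(3)]
    return cli.train_from_scenes(specs, n_per_class=150, seed=1)
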