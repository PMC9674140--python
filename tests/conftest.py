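"""Shared fixtures: phantoms are expensive, so the canonical ones are
session-scoped and every test treats them as read-only."""

import numpy as np
import pytest

from fishct.phantom import PhantomSpec, apply_effects, generate_phantom
from fishct.segmentation import segment_tissues
from fishct.vertebrae import label_vertebrae, partition_elements

# noise tiers of the stated world (native units against a 60-unit
# adipose/soft class separation)
NOISE_LOW = 8.0
NOISE_MODERATE = 12.0


def scaled_spec(scale: float = 0.7, **overrides) -> PhantomSpec:
    """A geometrically self-similar, smaller (faster) phantom spec."""
    base = PhantomSpec(**overrides)
    return apply_effects(base, {"standard_length": scale}).replace(
        seed=overrides.get("seed", 0)
    )


@pytest.fixture(scope="session")
def clean_spec():
    return PhantomSpec(noise_sd=0, seed=0)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    """Noiseless full-size phantom: (volume, truth labels, truth)."""
    return generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def clean_seg(clean_phantom):
    volume, _, _ = clean_phantom
    return segment_tissues(volume)


@pytest.fixture(scope="session")
def clean_labeling(clean_seg):
    labeling = label_vertebrae(clean_seg)
    return partition_elements(labeling)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Low-noise full-size phantom (the default acquisition model)."""
    spec = PhantomSpec(noise_sd=NOISE_LOW, seed=5)
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_seg(noisy_phantom):
    _, volume, _, _ = noisy_phantom
    return segment_tissues(volume)


@pytest.fixture()
def rng():
    # function-scoped: every test gets the same fresh, deterministic stream
    return np.random.default_rng(12345)
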