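"""Shared fixtures: small phantoms and cached expensive pipeline runs.

Session-scoped fixtures hold the costly artifacts (trained decay model,
segmented phantoms) so unit tests and the acceptance tests reuse one
computation each.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from deadwoodct import validation
from deadwoodct.ctvolume import normalize
from deadwoodct.phantom import LogPhantomSpec, generate_phantom
from deadwoodct.tunnels import segment_log

#: seed for every deterministic fixture in the suite
SUITE_SEED = 1


@pytest.fixture(scope="session")
def small_spec() -> LogPhantomSpec:
    """Desk-scale structured phantom spec (tunnels + bark gallery + cracks)."""
    return replace(
        validation.BENCH_GEOMETRY,
        tunnel_count=3,
        bark_tunnel_count=1,
        crack_count=3,
        noise_sigma_hu=0.0,
        seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def tunnel_case(small_spec):
    """Noiseless structured phantom with its full tunnel segmentation."""
    vol, lab = generate_phantom(small_spec)
    norm = normalize(vol)
    seg = segment_log(norm)
    return {"spec": small_spec, "vol": vol, "lab": lab, "norm": norm, "seg": seg}


@pytest.fixture(scope="session")
def empty_log_case():
    """Phantom with no carved structures at all."""
    spec = replace(validation.BENCH_GEOMETRY, length_slices=12, noise_sigma_hu=0.0,
                   seed=SUITE_SEED)
    vol, lab = generate_phantom(spec)
    return {"spec": spec, "vol": vol, "lab": lab, "norm": normalize(vol)}


@pytest.fixture(scope="session")
def decay_training(request):
    """Trained decay classifier with held-out evaluation (the slow fixture)."""
    return validation.decay_training_benchmark(seed=SUITE_SEED)


class ConstantModel:
    """Stub predictor returning a constant probability everywhere."""

    def __init__(self, value: float):
        self.value = value

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(patches, dtype=float), self.value)


class IdentityModel:
    """Stub predictor echoing its input patch."""

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.asarray(patches, dtype=float)


@pytest.fixture
def constant_model():
    return ConstantModel


@pytest.fixture
def identity_model():
    return IdentityModel()
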