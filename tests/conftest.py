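from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modeconn.datatypes import MultivariateSignal, MVMDParams
from modeconn.mvmd import mvmd_decompose
from modeconn.synthetic import default_cohort_spec, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DT = 0.72
T = 1200


def make_tone(freq_hz: float, T: int = T, dt: float = DT,
              phase: float = 0.0, amp: float = 1.0) -> np.ndarray:
    t = np.arange(T) * dt
    return amp * np.cos(2 * np.pi * freq_hz * t + phase)


@pytest.fixture(scope="session")
def two_tone_signal() -> MultivariateSignal:
    """3 identical channels of 20 mHz + 100 mHz tones."""
    x = make_tone(0.02) + make_tone(0.10)
    return MultivariateSignal(np.tile(x, (3, 1)), DT)


@pytest.fixture(scope="session")
def two_tone_modeset(two_tone_signal):
    return mvmd_decompose(two_tone_signal, MVMDParams(K=2, alpha=1000))


_cohort_cache: dict = {}


def decomposed_cohort(seed: int, n_participants: int = 10):
    """Default synthetic cohort decomposed with K=6 (cached per session).

    Returns (signals, ground_truth, mode_sets).
    """
    key = (seed, n_participants)
    if key not in _cohort_cache:
        spec = default_cohort_spec(n_participants=n_participants, seed=seed)
        signals, gt = generate_cohort(spec)
        params = MVMDParams(K=6, alpha=1000)
        mode_sets = [mvmd_decompose(s, params) for s in signals]
        _cohort_cache[key] = (signals, gt, mode_sets)
    return _cohort_cache[key]


@pytest.fixture(scope="session")
def default_cohort_decomposed():
    return decomposed_cohort(seed=0)
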