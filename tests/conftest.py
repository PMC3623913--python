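"""Shared fixtures: small simulated sessions and oracle helpers.

Oracles here are deliberately naive (per-trial loops, direct FFT
algebra) and independent of the vectorized implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

import plcvrfe as P
from plcvrfe.phase_metrics import PhaseTensor


@pytest.fixture(scope="session")
def small_session() -> P.SpellerSession:
    """8-channel, 2-block simulated session (2 relevant channels)."""
    cfg = P.SimConfig(n_channels=8, n_blocks=2, relevant_channels=(0, 5),
                      seed=1234)
    return P.simulate_session(cfg)


@pytest.fixture(scope="session")
def small_phase(small_session) -> tuple:
    """(target, nontarget) phase tensors of the small session at 200 Hz."""
    sess_phase, _ = P.preprocess_session(small_session)
    phase = P.phase_from_continuous(sess_phase)
    return P.split_by_target(phase)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(98765)


def random_phase_tensor(rng, n_trials=20, n_channels=5, n_samples=50,
                        fs=200.0) -> PhaseTensor:
    phi = rng.uniform(-np.pi, np.pi, size=(n_trials, n_channels, n_samples))
    return PhaseTensor(phi=phi, fs=fs)


# ---------------------------------------------------------------------------
# loop oracles (independent of the vectorized implementations)

def oracle_itc(phi: np.ndarray, x: int) -> np.ndarray:
    n_trials, _, n_samples = phi.shape
    out = np.empty(n_samples)
    for s in range(n_samples):
        acc = 0.0 + 0.0j
        for t in range(n_trials):
            acc += complex(np.cos(phi[t, x, s]), np.sin(phi[t, x, s]))
        out[s] = abs(acc / n_trials)
    return out


def oracle_plv(phi: np.ndarray, x: int, y: int) -> np.ndarray:
    n_trials, _, n_samples = phi.shape
    out = np.empty(n_samples)
    for s in range(n_samples):
        acc = 0.0 + 0.0j
        for t in range(n_trials):
            d = phi[t, x, s] - phi[t, y, s]
            acc += complex(np.cos(d), np.sin(d))
        out[s] = abs(acc / n_trials)
    return out


def oracle_pcv(phi: np.ndarray, x: int, y: int) -> np.ndarray:
    n_trials, _, n_samples = phi.shape
    out = np.empty(n_samples)
    for s in range(n_samples):
        acc = 0.0 + 0.0j
        for t in range(n_trials):
            d = phi[t, x, s] + phi[t, y, s]
            acc += complex(np.cos(d), np.sin(d))
        out[s] = abs(acc / n_trials)
    return out


def oracle_plcv(phi: np.ndarray, x: int, y: int) -> np.ndarray:
    return oracle_pcv(phi, x, y) * (1.0 - oracle_plv(phi, x, y))


def oracle_te(phi_t: np.ndarray, phi_n: np.ndarray, x: int, y: int) -> np.ndarray:
    return oracle_plcv(phi_t, x, y) - oracle_plcv(phi_n, x, y)


def oracle_hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Analytic phase via direct FFT spectrum doubling (1-D input)."""
    n = x.shape[-1]
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    return np.angle(np.fft.ifft(spec * h))
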