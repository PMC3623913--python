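"""Circular statistics of instantaneous phase across trials.

Let ``phi_x(t)`` be the analytic (Hilbert) phase of channel ``x`` on
one trial and ``n`` the number of trials.  With unit phasors
``E_x = exp(j phi_x)`` the statistics implemented here are

* ``ITC_x(t)  = |mean_trials E_x|`` — inter-trial coherence, the phase
  concentration of a single channel relative to stimulus onset;
* ``PLV_xy(t) = |mean_trials E_x conj(E_y)|`` — phase-locking value,
  the consistency of the phase *difference*, high for homologous
  channels (shared source) regardless of task;
* ``PCV_xy(t) = |mean_trials E_x E_y|`` — phase-concentration value,
  the joint consistency of the phase *sum*, high only when both
  channels are phase-reset by the task;
* ``PLCV_xy(t) = PCV_xy(t) * (1 - PLV_xy(t))`` — high for heterologous
  pairs that are jointly concentrated; identically 0 for a self pair;
* ``TE_xy(t) = PLCV_xy^target(t) - PLCV_xy^nontarget(t)`` — the target
  effect, the pairwise task-relevance signal fed to the ranking.

All circular averaging is done on unit complex numbers, never on raw
angles, so branch cuts are irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import hilbert

from .containers import EpochSet, SpellerSession, ValidationError
from .preprocess import WINDOW_S, extract_padded_windows

METRIC_KINDS = ("PLV", "PCV", "PLCV", "ITC", "TE")


@dataclass
class PhaseTensor:
    """Per-trial instantaneous phase in radians, shape (trials, channels, samples)."""

    phi: np.ndarray
    fs: float
    amplitude: Optional[np.ndarray] = None
    events: Optional[list] = None
    channel_labels: Optional[tuple[str, ...]] = None

    @property
    def n_trials(self) -> int:
        return self.phi.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phi.shape[1]

    @property
    def n_samples(self) -> int:
        return self.phi.shape[2]

    def select_channels(self, idx) -> "PhaseTensor":
        labels = None
        if self.channel_labels is not None:
            labels = tuple(self.channel_labels[i] for i in idx)
        return PhaseTensor(
            phi=self.phi[:, idx, :],
            fs=self.fs,
            amplitude=None if self.amplitude is None else self.amplitude[:, idx, :],
            events=self.events,
            channel_labels=labels,
        )


@dataclass
class PairMetricSeries:
    """Time series of one pairwise (or single-channel) circular statistic."""

    kind: str
    pair: tuple[int, int]
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValidationError(f"unknown metric kind {self.kind!r}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[-1]) / self.fs


def _analytic(data: np.ndarray, chunk: int = 256) -> np.ndarray:
    """FFT Hilbert analytic signal along the last axis, chunked over trials."""
    out = np.empty(data.shape, dtype=complex)
    for i in range(0, data.shape[0], chunk):
        out[i:i + chunk] = hilbert(data[i:i + chunk], axis=-1)
    return out


def analytic_phase(epochs: EpochSet, keep_amplitude: bool = True) -> PhaseTensor:
    """Analytic-signal phase (and envelope) of each trial and channel.

    The Hilbert transform is taken over each epoch in isolation, so the
    first and last few samples carry edge artifacts; prefer
    :func:`phase_from_continuous` when the continuous recording is
    available.
    """
    if not np.all(np.isfinite(epochs.data)):
        raise ValidationError("epoch data contains NaN or infinite values")
    z = _analytic(epochs.data)
    return PhaseTensor(
        phi=np.angle(z),
        fs=epochs.fs,
        amplitude=np.abs(z) if keep_amplitude else None,
        events=list(epochs.events),
        channel_labels=epochs.montage.labels,
    )


def phase_from_continuous(session: SpellerSession, window_s: float = WINDOW_S,
                          pad_s: float = 1.0,
                          keep_amplitude: bool = False) -> PhaseTensor:
    """Per-trial phase with Hilbert edge artifacts suppressed.

    Windows padded by ``pad_s`` on each side are cut from the continuous
    signal, the analytic signal is computed on the padded window, and
    the result is cropped back to ``[0, window_s]`` after the stimulus.
    """
    if not np.all(np.isfinite(session.signals)):
        raise ValidationError("session signals contain NaN or infinite values")
    data, i0, i1 = extract_padded_windows(session, window_s=window_s, pad_s=pad_s)
    n_trials = data.shape[0]
    phi = np.empty((n_trials, data.shape[1], i1 - i0))
    amp = np.empty_like(phi) if keep_amplitude else None
    chunk = 256
    for s in range(0, n_trials, chunk):
        z = hilbert(data[s:s + chunk], axis=-1)[..., i0:i1]
        phi[s:s + chunk] = np.angle(z)
        if amp is not None:
            amp[s:s + chunk] = np.abs(z)
    return PhaseTensor(phi=phi, fs=session.fs, amplitude=amp,
                       events=list(session.schedule),
                       channel_labels=session.montage.labels)


def split_by_target(phase: PhaseTensor) -> tuple[PhaseTensor, PhaseTensor]:
    """(target, nontarget) sub-tensors according to the attached events."""
    if phase.events is None:
        raise ValidationError("phase tensor carries no events to split on")
    mask = np.array([e.is_target for e in phase.events], dtype=bool)
    def _take(m):
        return PhaseTensor(
            phi=phase.phi[m], fs=phase.fs,
            amplitude=None if phase.amplitude is None else phase.amplitude[m],
            events=[e for e, keep in zip(phase.events, m) if keep],
            channel_labels=phase.channel_labels,
        )
    return _take(mask), _take(~mask)


def _check_channel(phase: PhaseTensor, x: int) -> None:
    if not 0 <= x < phase.n_channels:
        raise IndexError(f"channel {x} out of range 0..{phase.n_channels - 1}")


def itc(phase: PhaseTensor, x: int) -> PairMetricSeries:
    """Inter-trial coherence of one channel: |mean exp(j phi_x)|."""
    _check_channel(phase, x)
    ex = np.exp(1j * phase.phi[:, x, :])
    vals = np.abs(ex.mean(axis=0))
    return PairMetricSeries(kind="ITC", pair=(x, x),
                            values=np.clip(vals, 0.0, 1.0), fs=phase.fs)


def plv(phase: PhaseTensor, x: int, y: int) -> PairMetricSeries:
    """Phase-locking value: |mean exp(j (phi_x - phi_y))|."""
    _check_channel(phase, x)
    _check_channel(phase, y)
    ex = np.exp(1j * phase.phi[:, x, :])
    ey = np.exp(1j * phase.phi[:, y, :])
    vals = np.abs((ex * np.conj(ey)).mean(axis=0))
    return PairMetricSeries(kind="PLV", pair=(x, y),
                            values=np.clip(vals, 0.0, 1.0), fs=phase.fs)


def pcv(phase: PhaseTensor, x: int, y: int) -> PairMetricSeries:
    """Phase-concentration value: |mean exp(j (phi_x + phi_y))|."""
    _check_channel(phase, x)
    _check_channel(phase, y)
    ex = np.exp(1j * phase.phi[:, x, :])
    ey = np.exp(1j * phase.phi[:, y, :])
    vals = np.abs((ex * ey).mean(axis=0))
    return PairMetricSeries(kind="PCV", pair=(x, y),
                            values=np.clip(vals, 0.0, 1.0), fs=phase.fs)


def plcv(phase: PhaseTensor, x: int, y: int) -> PairMetricSeries:
    """Combined statistic PCV * (1 - PLV); exactly 0 for a self pair."""
    p_lock = plv(phase, x, y).values
    p_conc = pcv(phase, x, y).values
    vals = np.clip(p_conc * (1.0 - p_lock), 0.0, 1.0)
    return PairMetricSeries(kind="PLCV", pair=(x, y), values=vals, fs=phase.fs)


def te(phase_target: PhaseTensor, phase_nontarget: PhaseTensor,
       x: int, y: int) -> PairMetricSeries:
    """Target effect: PLCV on target trials minus PLCV on nontarget trials.

    Trial counts may differ between the two conditions; sample counts
    and channel counts must match.
    """
    if phase_target.n_samples != phase_nontarget.n_samples:
        raise ValidationError("target/nontarget sample counts differ")
    if phase_target.n_channels != phase_nontarget.n_channels:
        raise ValidationError("target/nontarget channel counts differ")
    vt = plcv(phase_target, x, y).values
    vn = plcv(phase_nontarget, x, y).values
    return PairMetricSeries(kind="TE", pair=(x, y), values=vt - vn,
                            fs=phase_target.fs)


def pairwise_plcv(phase: PhaseTensor) -> np.ndarray:
    """All-pairs PLCV, shape (channels, channels, samples).

    Vectorized over pairs; identical (to floating-point reduction
    order) to calling :func:`plcv` per pair.
    """
    e = np.exp(1j * phase.phi)  # (trials, channels, samples)
    n = phase.n_trials
    m_sum = np.einsum("txs,tys->xys", e, e, optimize=True) / n
    m_diff = np.einsum("txs,tys->xys", e, np.conj(e), optimize=True) / n
    p_conc = np.clip(np.abs(m_sum), 0.0, 1.0)
    p_lock = np.clip(np.abs(m_diff), 0.0, 1.0)
    return np.clip(p_conc * (1.0 - p_lock), 0.0, 1.0)


def target_effect(phase_target: PhaseTensor,
                  phase_nontarget: PhaseTensor) -> np.ndarray:
    """All-pairs TE array, shape (channels, channels, samples)."""
    if phase_target.n_samples != phase_nontarget.n_samples:
        raise ValidationError("target/nontarget sample counts differ")
    if phase_target.n_channels != phase_nontarget.n_channels:
        raise ValidationError("target/nontarget channel counts differ")
    return pairwise_plcv(phase_target) - pairwise_plcv(phase_nontarget)
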