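"""Preprocessing chain: band-pass filtering, decimation, epoch extraction.

The standard chain for this paradigm is 0.1-40 Hz band-pass on the raw
recording, decimation to 200 Hz for phase measurement, a further
decimation to 20 Hz for classification, and extraction of the 700 ms
post-stimulus window as one trial per intensification.

All filters are zero-phase (forward-backward), so filter group delay
cannot bias the phase statistics computed downstream.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import (
    EpochSet,
    ParameterError,
    SpellerSession,
    StimulusEvent,
    ValidationError,
)

DEFAULT_BAND = (0.1, 40.0)
PHASE_FS = 200.0
CLF_FS = 20.0
WINDOW_S = 0.7


def bandpass(signals: np.ndarray, fs: float,
             low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1],
             order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The forward-backward pass squares the magnitude response, and the
    reflect padding is stretched to several time constants of the low
    cutoff so the very slow high-pass transient settles off-record.
    """
    if high_hz >= fs / 2:
        raise ParameterError(
            f"high cutoff {high_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    if not 0 < low_hz < high_hz:
        raise ParameterError("need 0 < low_hz < high_hz")
    x = np.asarray(signals, dtype=float)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    padlen = min(x.shape[-1] - 1, int(3 * fs / low_hz))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def decimate(signals: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-alias filter and subsample by an integer factor (zero-phase FIR).

    Output length is ``floor(n_samples * target_fs / fs)``.
    """
    ratio = fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ParameterError(
            f"decimation from {fs} to {target_fs} Hz is not an integer factor"
        )
    x = np.asarray(signals, dtype=float)
    if q == 1:
        return x.copy()
    out = sps.decimate(x, q, ftype="fir", zero_phase=True, axis=-1)
    n_out = int(np.floor(x.shape[-1] * target_fs / fs))
    return out[..., :n_out]


def bandpass_session(session: SpellerSession, low_hz: float = DEFAULT_BAND[0],
                     high_hz: float = DEFAULT_BAND[1]) -> SpellerSession:
    if session.signals is None:
        raise ValidationError("session has no continuous signals to filter")
    return replace(session, signals=bandpass(session.signals, session.fs,
                                             low_hz, high_hz))


def decimate_session(session: SpellerSession, target_fs: float) -> SpellerSession:
    if session.signals is None:
        raise ValidationError("session has no continuous signals to decimate")
    return replace(session,
                   signals=decimate(session.signals, session.fs, target_fs),
                   fs=target_fs)


def extract_epochs(session: SpellerSession, window_s: float = WINDOW_S) -> EpochSet:
    """Cut one post-stimulus window per scheduled event.

    Windows may overlap (stimulus-onset asynchrony 175 ms is shorter
    than the 700 ms response window); no overlap correction is applied.
    """
    if session.signals is None:
        raise ValidationError("session has no continuous signals to epoch")
    fs = session.fs
    n_samp = int(round(window_s * fs))
    if n_samp < 1:
        raise ParameterError("window too short for sampling rate")
    total = session.signals.shape[1]
    starts = np.array([int(round(ev.onset_time * fs)) for ev in session.schedule])
    bad = np.flatnonzero((starts < 0) | (starts + n_samp > total))
    if bad.size:
        i = int(bad[0])
        ev = session.schedule[i]
        raise ValidationError(
            f"event {i} (onset {ev.onset_time:.3f}s, block {ev.block_index})"
            f" needs samples beyond the recording end"
        )
    data = np.empty((len(starts), session.signals.shape[0], n_samp))
    for i, s0 in enumerate(starts):
        data[i] = session.signals[:, s0:s0 + n_samp]
    return EpochSet(data=data, fs=fs, events=list(session.schedule),
                    montage=session.montage, t0=0.0)


def extract_padded_windows(session: SpellerSession, window_s: float = WINDOW_S,
                           pad_s: float = 1.0) -> tuple[np.ndarray, int, int]:
    """Cut windows padded by ``pad_s`` on both sides.

    Returns ``(data, crop_start, crop_stop)`` where
    ``data[:, :, crop_start:crop_stop]`` is the unpadded window.  Used
    to compute analytic signals away from epoch edges.
    """
    if session.signals is None:
        raise ValidationError("session has no continuous signals to epoch")
    fs = session.fs
    n_pad = int(round(pad_s * fs))
    n_win = int(round(window_s * fs))
    total = session.signals.shape[1]
    starts = np.array([int(round(ev.onset_time * fs)) for ev in session.schedule])
    bad = np.flatnonzero((starts - n_pad < 0) | (starts + n_win + n_pad > total))
    if bad.size:
        i = int(bad[0])
        ev = session.schedule[i]
        raise ValidationError(
            f"event {i} (onset {ev.onset_time:.3f}s) padded window"
            f" [{-pad_s:.2f}, {window_s + pad_s:.2f}]s leaves the recording"
        )
    data = np.empty((len(starts), session.signals.shape[0], n_win + 2 * n_pad))
    for i, s0 in enumerate(starts):
        data[i] = session.signals[:, s0 - n_pad:s0 + n_win + n_pad]
    return data, n_pad, n_pad + n_win


def preprocess_session(session: SpellerSession,
                       band: tuple[float, float] = DEFAULT_BAND,
                       phase_fs: float = PHASE_FS,
                       clf_fs: float = CLF_FS,
                       ) -> tuple[SpellerSession, SpellerSession]:
    """Full chain: band-pass, then the two decimation stages.

    Returns ``(session_phase, session_clf)`` at ``phase_fs`` and
    ``clf_fs``; the classification stream is decimated from the phase
    stream, mirroring the two-stage protocol.
    """
    filtered = bandpass_session(session, *band)
    sess_phase = decimate_session(filtered, phase_fs)
    sess_clf = decimate_session(sess_phase, clf_fs)
    return sess_phase, sess_clf


def permute_events(session: SpellerSession,
                   order: Sequence[int]) -> SpellerSession:
    """Reorder the schedule (pairing of trials to events follows it)."""
    sched: list[StimulusEvent] = [session.schedule[i] for i in order]
    return replace(session, schedule=sched)
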