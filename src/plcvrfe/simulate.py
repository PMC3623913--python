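"""Seeded P300 speller simulator under the oscillatory phase-reset model.

Each EEG source is an ongoing oscillation with a slowly drifting
instantaneous frequency plus 1/f background activity; channels are
linear mixtures of sources plus white sensor noise.  When a *target*
stimulus flashes, the sources feeding the task-relevant channels have
their phase redrawn from a von Mises distribution a fixed latency
after onset (blended in over a short raised-cosine ramp so the
band-pass filter sees no discontinuity) and then resume free-running.
Non-target flashes leave the oscillations untouched, so target trials
show inter-trial phase concentration at the relevant channels and
non-target trials do not — exactly the contrast the PLCV statistics
are built to detect.

An additive evoked variant (fixed-latency, fixed-polarity bump on
target trials) is available through ``evoked_amplitude`` for
contrasting the two ERP generation accounts.

The stimulus schedule follows the row/column paradigm: a 6x6 matrix,
12 intensifications of 100 ms with 75 ms blank per repetition in
randomized order, 15 repetitions per character block, and a 2.5 s
blank before each block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    DEFAULT_MATRIX,
    Montage,
    ParameterError,
    SpellerSession,
    StimulusEvent,
    ValidationError,
    codes_for_char,
)


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the recording protocol.

    Units: seconds, Hz, microvolts.  ``relevant_channels`` receive the
    target-locked phase reset.  ``mixing`` (channels x sources) defaults
    to the identity, i.e. one private source per channel; give two
    channels the same source column to make them homologous.
    """

    n_channels: int = 16
    n_blocks: int = 80
    n_repetitions: int = 15
    fs: float = 1000.0
    relevant_channels: tuple[int, ...] = (8, 11, 14, 15)  # Cz, P7, P8, Oz
    kappa: float = 5.0
    mu_reset: float = 0.0
    reset_latency_s: float = 0.05
    reset_duration_s: float = 0.05
    mixing: Optional[np.ndarray] = None
    osc_freqs: Optional[tuple[float, ...]] = None
    osc_amplitude: float = 10.0
    freq_drift_sd: float = 0.3
    freq_drift_cutoff_hz: float = 0.3
    pink_sd: float = 3.0
    noise_sd: float = 2.0
    evoked_amplitude: float = 0.0
    evoked_latency_s: float = 0.3
    evoked_width_s: float = 0.06
    target_characters: Optional[str] = None
    matrix: tuple[str, ...] = DEFAULT_MATRIX
    pre_blank_s: float = 2.5
    flash_s: float = 0.100
    isi_s: float = 0.075
    tail_s: float = 2.0
    seed: int = 0

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing is None:
            return np.eye(self.n_channels)
        m = np.asarray(self.mixing, dtype=float)
        if m.ndim != 2 or m.shape[0] != self.n_channels:
            raise ValidationError("mixing must be (n_channels, n_sources)")
        if not np.all(np.isfinite(m)):
            raise ValidationError("mixing contains non-finite values")
        return m

    def validate(self) -> None:
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        if self.n_channels < 2:
            raise ParameterError("need at least 2 channels")
        for c in self.relevant_channels:
            if not 0 <= c < self.n_channels:
                raise ValidationError(
                    f"relevant channel index {c} out of range 0..{self.n_channels - 1}"
                )
        if self.target_characters is not None and \
                len(self.target_characters) != self.n_blocks:
            raise ValidationError("target_characters length must equal n_blocks")
        self.resolved_mixing()


def shared_source_mixing(n_channels: int,
                         homologous_pairs: Sequence[tuple[int, int]],
                         ) -> np.ndarray:
    """Identity-like mixing where each listed pair shares one source.

    Both members of a pair get unit weight on a common source and lose
    their private one, making them maximally homologous.
    """
    partner: dict[int, int] = {}
    for a, b in homologous_pairs:
        partner[a] = b
        partner[b] = a
    owner: dict[int, int] = {}
    columns: list[np.ndarray] = []
    for ch in range(n_channels):
        if ch in owner:
            continue
        col = np.zeros(n_channels)
        col[ch] = 1.0
        owner[ch] = len(columns)
        if ch in partner and partner[ch] > ch:
            col[partner[ch]] = 1.0
            owner[partner[ch]] = len(columns)
        columns.append(col)
    return np.stack(columns, axis=1)


def build_schedule(config: SimConfig, rng: np.random.Generator,
                   ) -> tuple[list[StimulusEvent], str, float]:
    """Randomized row/column schedule; returns (events, targets, duration)."""
    chars = "".join(config.matrix)
    if config.target_characters is None:
        targets = "".join(rng.choice(list(chars), size=config.n_blocks))
    else:
        targets = config.target_characters
    soa = config.flash_s + config.isi_s
    events: list[StimulusEvent] = []
    t = 0.0
    for b in range(config.n_blocks):
        t += config.pre_blank_s
        row_code, col_code = codes_for_char(targets[b], config.matrix)
        for rep in range(config.n_repetitions):
            for code in rng.permutation(12) + 1:
                events.append(StimulusEvent(
                    code=int(code), onset_time=t,
                    is_target=code in (row_code, col_code),
                    block_index=b, repetition_index=rep))
                t += soa
    return events, targets, t + config.tail_s


def _pink_noise(rng: np.random.Generator, n: int, sd: float,
                fs: float, f_floor: float = 0.5) -> np.ndarray:
    """1/f-amplitude noise, flat below ``f_floor`` to bound the variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _drifting_phase(rng: np.random.Generator, n: int, fs: float, f0: float,
                    drift_sd: float, cutoff_hz: float) -> np.ndarray:
    """Unwrapped phase of an oscillator whose frequency wanders slowly."""
    if drift_sd > 0:
        sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
        drift = sps.sosfilt(sos, rng.standard_normal(n))
        s = drift.std()
        if s > 0:
            drift *= drift_sd / s
    else:
        drift = np.zeros(n)
    inst_freq = f0 + drift
    phi0 = rng.uniform(-np.pi, np.pi)
    return phi0 + 2.0 * np.pi * np.cumsum(inst_freq) / fs


def _wrap(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


def _apply_resets(phase: np.ndarray, reset_samples: np.ndarray,
                  new_phases: np.ndarray, n_blend: int) -> np.ndarray:
    """Redraw the oscillator phase at each reset, raised-cosine blended.

    Each reset adds a constant offset from its blend end onward, so the
    oscillator free-runs from the redrawn phase; blends are assumed
    non-overlapping (target flashes are >= one SOA apart).
    """
    n = phase.shape[0]
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n_blend + 1) / n_blend))
    steps = np.zeros(n)
    blend = np.zeros(n)
    cum = 0.0
    for i0, psi in zip(reset_samples, new_phases):
        delta = float(_wrap(psi - (phase[min(i0 + n_blend, n - 1)] + cum)))
        stop = min(i0 + n_blend, n)
        blend[i0:stop] += delta * ramp[:stop - i0]
        if stop < n:
            steps[stop] += delta
        cum += delta
    return phase + np.cumsum(steps) + blend


def _evoked_kernel(fs: float, latency: float, width: float) -> tuple[int, np.ndarray]:
    """Positive Gaussian bump peaking ``latency`` after onset; unit peak."""
    half = int(round(3 * width * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(-0.5 * (t / width) ** 2)
    return int(round(latency * fs)) - half, kern


def simulate_session(config: SimConfig) -> SpellerSession:
    """Generate one fully annotated speller session.

    All randomness derives from ``config.seed`` through a fixed
    generator-splitting scheme (schedule, oscillators, background,
    resets, sensor noise are independent streams), so equal configs
    give bit-identical sessions.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sched, rng_src, rng_pink, rng_reset, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5))

    events, targets, duration = build_schedule(config, rng_sched)
    fs = config.fs
    n_samples = int(round(duration * fs))
    mixing = config.resolved_mixing()
    n_sources = mixing.shape[1]
    freqs = (np.asarray(config.osc_freqs, dtype=float)
             if config.osc_freqs is not None
             else np.linspace(8.0, 13.0, n_sources))
    if freqs.shape[0] != n_sources:
        raise ValidationError("osc_freqs length must match the source count")

    # sources feeding any relevant channel get target-locked phase resets
    relevant = np.zeros(config.n_channels, dtype=bool)
    relevant[list(config.relevant_channels)] = True
    reset_sources = np.flatnonzero(np.abs(mixing[relevant]).sum(axis=0) > 0)

    target_onsets = np.array([e.onset_time for e in events if e.is_target])
    reset_samples = np.round(
        (target_onsets + config.reset_latency_s) * fs).astype(int)
    n_blend = max(int(round(config.reset_duration_s * fs)), 1)

    sources = np.empty((n_sources, n_samples))
    for s in range(n_sources):
        phase = _drifting_phase(rng_src, n_samples, fs, freqs[s],
                                config.freq_drift_sd,
                                config.freq_drift_cutoff_hz)
        if s in reset_sources and config.kappa >= 0:
            psi = rng_reset.vonmises(config.mu_reset, config.kappa,
                                     size=reset_samples.shape[0]) \
                if config.kappa > 0 else \
                rng_reset.uniform(-np.pi, np.pi, size=reset_samples.shape[0])
            phase = _apply_resets(phase, reset_samples, psi, n_blend)
        sources[s] = config.osc_amplitude * np.cos(phase)
        if config.pink_sd > 0:
            sources[s] += _pink_noise(rng_pink, n_samples, config.pink_sd, fs)

    signals = config.noise_sd * rng_noise.standard_normal(
        (config.n_channels, n_samples))
    chunk = 200_000
    for i in range(0, n_samples, chunk):
        signals[:, i:i + chunk] += mixing @ sources[:, i:i + chunk]

    if config.evoked_amplitude > 0:
        off, kern = _evoked_kernel(fs, config.evoked_latency_s,
                                   config.evoked_width_s)
        rel_idx = np.flatnonzero(relevant)
        for t0 in target_onsets:
            i0 = int(round(t0 * fs)) + off
            i1 = min(i0 + kern.shape[0], n_samples)
            if i0 < 0 or i1 <= i0:
                continue
            signals[np.ix_(rel_idx, np.arange(i0, i1))] += \
                config.evoked_amplitude * kern[:i1 - i0]

    montage = Montage.standard(config.n_channels)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["mixing"] = mixing.tolist()
    cfg_dict["osc_freqs"] = freqs.tolist()
    cfg_dict["target_characters"] = targets
    ground_truth = {
        "relevant_channels": [int(c) for c in config.relevant_channels],
        "mixing": mixing.tolist(),
        "osc_freqs": freqs.tolist(),
        "reset_sources": [int(s) for s in reset_sources],
        "config": cfg_dict,
    }
    return SpellerSession(
        fs=fs, schedule=events, montage=montage, signals=signals,
        matrix=config.matrix, target_characters=targets,
        ground_truth=ground_truth,
    )


def homologous_pairs(mixing: np.ndarray, tol: float = 1e-12) -> list[tuple[int, int]]:
    """Channel pairs sharing at least one source with nonzero weight."""
    m = np.asarray(mixing)
    pairs = []
    n = m.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            if np.any((np.abs(m[a]) > tol) & (np.abs(m[b]) > tol)):
                pairs.append((a, b))
    return pairs


def ground_truth_report(session: SpellerSession) -> pd.DataFrame:
    """Per-channel relevance and source sharing of a simulated session.

    Columns: channel label, relevant flag, source indices feeding the
    channel, and labels of homologous partners (channels sharing a
    source).  Raises for sessions without simulator annotations.
    """
    if session.ground_truth is None:
        raise ValidationError("session carries no simulator ground truth")
    gt = session.ground_truth
    mixing = np.asarray(gt["mixing"], dtype=float)
    labels = session.montage.labels
    pairs = homologous_pairs(mixing)
    partners: dict[int, list[str]] = {i: [] for i in range(len(labels))}
    for a, b in pairs:
        partners[a].append(labels[b])
        partners[b].append(labels[a])
    rows = []
    relevant = set(gt["relevant_channels"])
    for i, lab in enumerate(labels):
        srcs = np.flatnonzero(np.abs(mixing[i]) > 1e-12)
        rows.append({
            "channel": lab,
            "relevant": i in relevant,
            "sources": ",".join(str(int(s)) for s in srcs),
            "homologous_with": ",".join(partners[i]),
        })
    return pd.DataFrame(rows)
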