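"""On-disk formats: native HDF5 session container, EDF ingestion,
delimited event tables and rank lists.

EDF carries no epoch or paradigm semantics, so it is supported for raw
signal exchange only (read through MNE; written by a minimal EDF+
writer with 16-bit quantization).  The native container is a single
HDF5 file holding the signal tensor, sampling rate, event table,
montage, matrix and any simulator ground truth, and round-trips
bit-exactly.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_MATRIX,
    FormatError,
    Montage,
    SpellerSession,
    StimulusEvent,
    ValidationError,
)

_EVENT_COLUMNS = ("onset", "code", "is_target", "block", "repetition")


# ---------------------------------------------------------------------------
# event tables

def write_events_table(schedule: Sequence[StimulusEvent], path: str | os.PathLike) -> None:
    df = pd.DataFrame({
        "onset": [e.onset_time for e in schedule],
        "code": [e.code for e in schedule],
        "is_target": [int(e.is_target) for e in schedule],
        "block": [e.block_index for e in schedule],
        "repetition": [e.repetition_index for e in schedule],
    })
    df.to_csv(path, sep="\t", index=False)


def read_events_table(path: str | os.PathLike) -> list[StimulusEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table misses columns {sorted(missing)}")
    return [
        StimulusEvent(code=int(r.code), onset_time=float(r.onset),
                      is_target=bool(int(r.is_target)),
                      block_index=int(r.block),
                      repetition_index=int(r.repetition))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# rank lists

def write_rank_list(ranks: Sequence[str], path: str | os.PathLike,
                    weights: Optional[Sequence[float]] = None) -> None:
    """Write a ranked channel list as TSV (rank, label, weight)."""
    ranks = list(ranks)
    if len(set(ranks)) != len(ranks):
        dupes = sorted({r for r in ranks if ranks.count(r) > 1})
        raise ValidationError(f"duplicate channel labels in rank list: {dupes}")
    if weights is not None and len(weights) != len(ranks):
        raise ValidationError("weights length must match rank list")
    df = pd.DataFrame({
        "rank": np.arange(1, len(ranks) + 1),
        "label": ranks,
        "weight": weights if weights is not None else [np.nan] * len(ranks),
    })
    df.to_csv(path, sep="\t", index=False)


def read_rank_list(path: str | os.PathLike) -> tuple[list[str], Optional[list[float]]]:
    df = pd.read_csv(path, sep="\t")
    if not {"rank", "label"} <= set(df.columns):
        raise FormatError("rank list needs 'rank' and 'label' columns")
    df = df.sort_values("rank")
    labels = [str(x) for x in df["label"]]
    weights = None
    if "weight" in df.columns and not df["weight"].isna().all():
        weights = [float(w) for w in df["weight"]]
    return labels, weights


# ---------------------------------------------------------------------------
# native HDF5 container

def write_session(session: SpellerSession, path: str | os.PathLike) -> None:
    """Write the native hierarchical container (see module docstring)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "plcvrfe-session"
        f.attrs["fs"] = float(session.fs)
        f.attrs["matrix"] = json.dumps(list(session.matrix))
        if session.target_characters is not None:
            f.attrs["target_characters"] = session.target_characters
        if session.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(session.ground_truth)
        if session.signals is not None:
            f.create_dataset("signals", data=session.signals)
        if session.epochs is not None:
            g = f.create_group("epochs")
            g.create_dataset("data", data=session.epochs.data)
            g.attrs["fs"] = float(session.epochs.fs)
            g.attrs["t0"] = float(session.epochs.t0)
        ev = f.create_group("events")
        ev.create_dataset("onset", data=np.array(
            [e.onset_time for e in session.schedule]))
        ev.create_dataset("code", data=np.array(
            [e.code for e in session.schedule], dtype=np.int64))
        ev.create_dataset("is_target", data=np.array(
            [e.is_target for e in session.schedule], dtype=bool))
        ev.create_dataset("block", data=np.array(
            [e.block_index for e in session.schedule], dtype=np.int64))
        ev.create_dataset("repetition", data=np.array(
            [e.repetition_index for e in session.schedule], dtype=np.int64))
        mg = f.create_group("montage")
        mg.create_dataset("labels", data=np.array(
            session.montage.labels, dtype=h5py.string_dtype()))
        if session.montage.positions:
            pos = np.array([session.montage.positions.get(lb, (np.nan, np.nan))
                            for lb in session.montage.labels])
            mg.create_dataset("positions", data=pos)


def _read_native(path: str | os.PathLike) -> SpellerSession:
    from .containers import EpochSet
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "plcvrfe-session":
            raise FormatError(f"{path} is not a session container")
        fs = float(f.attrs["fs"])
        matrix = tuple(json.loads(f.attrs["matrix"]))
        targets = f.attrs.get("target_characters")
        gt = f.attrs.get("ground_truth")
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["montage"]["labels"][()])
        positions = None
        if "positions" in f["montage"]:
            pos = f["montage"]["positions"][()]
            positions = {lb: (float(x), float(y))
                         for lb, (x, y) in zip(labels, pos)
                         if np.isfinite(x)}
        montage = Montage(labels=labels, positions=positions)
        ev = f["events"]
        schedule = [
            StimulusEvent(code=int(c), onset_time=float(t), is_target=bool(g),
                          block_index=int(b), repetition_index=int(r))
            for t, c, g, b, r in zip(ev["onset"][()], ev["code"][()],
                                     ev["is_target"][()], ev["block"][()],
                                     ev["repetition"][()])
        ]
        signals = f["signals"][()] if "signals" in f else None
        epochs = None
        if "epochs" in f:
            g = f["epochs"]
            epochs = EpochSet(data=g["data"][()], fs=float(g.attrs["fs"]),
                              events=schedule, montage=montage,
                              t0=float(g.attrs["t0"]))
    return SpellerSession(
        fs=fs, schedule=schedule, montage=montage, signals=signals,
        epochs=epochs, matrix=matrix,
        target_characters=None if targets is None else str(targets),
        ground_truth=None if gt is None else json.loads(gt),
    )


# ---------------------------------------------------------------------------
# EDF

def write_edf(session: SpellerSession, path: str | os.PathLike) -> None:
    """Minimal EDF+ writer: int16 samples, 1 s records, 'uV' units.

    The last partial record is zero-padded; amplitudes are quantized to
    the per-channel physical range over 16 bits.
    """
    if session.signals is None:
        raise ValidationError("EDF export needs continuous signals")
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF export needs an integer sampling rate")
    fs_i = int(round(fs))
    data = np.asarray(session.signals, dtype=float)
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs_i))
    padded = np.zeros((n_ch, n_rec * fs_i))
    padded[:, :n_samp] = data

    pmax = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768
    scale = pmax / dig_max

    def _f(x, width):
        s = f"{x}"[:width]
        return s.ljust(width)

    header = b""
    header += _f("0", 8).encode()
    header += _f("X X X X", 80).encode()
    header += _f("Startdate X X X X", 80).encode()
    header += b"01.01.00"
    header += b"00.00.00"
    header += _f(str(256 * (1 + n_ch)), 8).encode()
    header += _f("EDF+C", 44).encode()
    header += _f(str(n_rec), 8).encode()
    header += _f("1", 8).encode()
    header += _f(str(n_ch), 4).encode()

    def _fields(values, width):
        return "".join(_f(v, width) for v in values).encode()

    labels = [f"EEG {lb}"[:16] for lb in session.montage.labels]
    header += _fields(labels, 16)
    header += _fields([""] * n_ch, 80)                       # transducer
    header += _fields(["uV"] * n_ch, 8)
    header += _fields([f"{-p:.6g}"[:8] for p in pmax], 8)     # phys min
    header += _fields([f"{p:.6g}"[:8] for p in pmax], 8)      # phys max
    header += _fields([str(dig_min)] * n_ch, 8)
    header += _fields([str(dig_max)] * n_ch, 8)
    header += _fields([""] * n_ch, 80)                       # prefilter
    header += _fields([str(fs_i)] * n_ch, 8)
    header += _fields([""] * n_ch, 32)

    # physical ranges were formatted to 8 ASCII chars; quantize against
    # the values a reader will parse back, not the unrounded ones
    pmax_rt = np.array([float(f"{p:.6g}"[:8]) for p in pmax])
    scale = pmax_rt / dig_max
    digital = np.clip(np.round(padded / scale[:, None]), dig_min, dig_max
                      ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs_i:(r + 1) * fs_i].tobytes())


def _read_edf(path: str | os.PathLike,
              schedule: list[StimulusEvent]) -> SpellerSession:
    import mne
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    labels = tuple(ch.removeprefix("EEG ").strip() for ch in raw.ch_names)
    signals = raw.get_data(units="uV")
    return SpellerSession(
        fs=float(raw.info["sfreq"]), schedule=schedule,
        montage=Montage(labels=labels), signals=signals,
        matrix=DEFAULT_MATRIX,
    )


def read_session(path: str | os.PathLike,
                 event_table: Optional[str | os.PathLike] = None,
                 ) -> SpellerSession:
    """Load a session from the native container or from EDF + event table.

    For EDF input the event table is mandatory; extra channels in the
    file are kept in file order.  Event onsets outside the signal
    duration raise a validation error.
    """
    p = str(path)
    if p.endswith((".h5", ".hdf5")):
        session = _read_native(path)
        if event_table is not None:
            raise ValidationError(
                "native containers embed their events; drop the event table")
        return session
    if p.endswith(".edf"):
        if event_table is None:
            raise ValidationError("EDF input needs an event table")
        schedule = read_events_table(event_table)
        return _read_edf(path, schedule)
    raise FormatError(f"unrecognized session file extension: {path}")
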