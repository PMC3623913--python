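"""Character decoding with Fisher's linear discriminant and CRE curves.

A binary FLDA is trained on single-trial feature vectors (the 20 Hz
samples of the selected channels, concatenated in montage order, 14
samples per channel for a 700 ms window).  Characters are decoded per
block by summing discriminant scores over repetitions for each of the
12 stimulus codes and intersecting the best row with the best column.
The character-recognition-error (CRE) curve sweeps nested channel
subsets (top-n of a rank list) against the number of repetitions used,
and the optimal channel subset (OCS) is the smallest subset attaining
the row minimum of that curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import (
    DEFAULT_MATRIX,
    EpochSet,
    SpellerSession,
    ValidationError,
    char_for_codes,
)
from .preprocess import preprocess_session, extract_epochs


@dataclass
class FldaModel:
    """Linear discriminant: score(f) = w . f + b, higher = more target-like."""

    weights: np.ndarray
    bias: float

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


@dataclass
class CreCurve:
    """Character recognition error over (channel-subset size, repetitions)."""

    n_channels: np.ndarray
    repetitions: np.ndarray
    cre: np.ndarray  # shape (len(n_channels), len(repetitions)), fractions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cre, index=pd.Index(self.n_channels,
                                                     name="n_channels"),
                            columns=pd.Index(self.repetitions,
                                             name="repetitions"))


@dataclass
class OcsResult:
    subset_size: int
    cre: float


def features(epochs: EpochSet,
             channels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Trials x d matrix: per selected channel, its samples, channels concatenated.

    Channels default to the full montage; a subset is taken in the
    order given (rank order), each contributing ``n_samples`` columns.
    """
    if channels is None:
        data = epochs.data
    else:
        idx = [c if isinstance(c, (int, np.integer))
               else epochs.montage.index(c) for c in channels]
        data = epochs.data[:, idx, :]
    return data.reshape(data.shape[0], data.shape[1] * data.shape[2])


def flda_train(X: np.ndarray, y: np.ndarray,
               shrinkage_scale: float = 1e-6) -> FldaModel:
    """Fisher discriminant with lightly shrunk pooled covariance.

    The pooled within-class covariance gets an additive ridge
    ``lambda I`` with ``lambda = shrinkage_scale * trace / d``, keeping
    the solve well posed when d approaches the trial count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (trials, d) aligned with y")
    if y.all() or (~y).all():
        raise ValidationError("both classes must be present")
    X0, X1 = X[~y], X[y]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = X0.shape[0], X1.shape[0]
    d = X.shape[1]
    scatter = np.zeros((d, d))
    for Xi, mui in ((X0, mu0), (X1, mu1)):
        C = Xi - mui
        scatter += C.T @ C
    dof = max(n0 + n1 - 2, 1)
    Sw = scatter / dof
    lam = shrinkage_scale * np.trace(Sw) / d
    if lam <= 0:
        lam = shrinkage_scale
    w = linalg.solve(Sw + lam * np.eye(d), mu1 - mu0, assume_a="pos")
    b = -0.5 * float(w @ (mu0 + mu1))
    return FldaModel(weights=w, bias=b)


def decode_character(scores: np.ndarray, codes: Sequence[int], n_reps: int,
                     matrix: tuple[str, ...] = DEFAULT_MATRIX) -> str:
    """Decode one block from per-trial scores.

    ``scores``/``codes`` are in presentation order; the first
    ``12 * n_reps`` trials (the first ``n_reps`` repetitions) are used.
    Scores are summed per code; the best row code (1-6) and best column
    code (7-12) intersect at the decoded cell.  Argmax ties go to the
    lowest code index.
    """
    scores = np.asarray(scores, dtype=float)
    codes = np.asarray(codes, dtype=int)
    need = 12 * n_reps
    if scores.shape[0] < need or codes.shape[0] < need:
        raise ValidationError(
            f"block provides {scores.shape[0]} trials, need {need}"
        )
    sums = np.zeros(12)
    for r in range(n_reps):
        chunk = codes[12 * r:12 * (r + 1)]
        if sorted(chunk.tolist()) != list(range(1, 13)):
            raise ValidationError(
                f"repetition {r} is missing stimulus codes"
            )
        np.add.at(sums, chunk - 1, scores[12 * r:12 * (r + 1)])
    row_code = 1 + int(np.argmax(sums[:6]))
    col_code = 7 + int(np.argmax(sums[6:]))
    return char_for_codes(row_code, col_code, matrix)


def _blocks(epochs: EpochSet) -> dict[int, np.ndarray]:
    """Trial indices per block, sorted by onset (presentation order)."""
    order: dict[int, list[tuple[float, int]]] = {}
    for i, ev in enumerate(epochs.events):
        order.setdefault(ev.block_index, []).append((ev.onset_time, i))
    return {b: np.array([i for _, i in sorted(v)])
            for b, v in order.items()}


def true_character(epochs: EpochSet, block_trials: np.ndarray,
                   matrix: tuple[str, ...] = DEFAULT_MATRIX) -> str:
    """Block's intended character, from its flagged target codes."""
    row = col = None
    for i in block_trials:
        ev = epochs.events[i]
        if ev.is_target:
            if ev.code <= 6:
                row = ev.code
            else:
                col = ev.code
    if row is None or col is None:
        raise ValidationError("block lacks a target row or column code")
    return char_for_codes(row, col, matrix)


def cre_curve(epochs_train: EpochSet, epochs_test: EpochSet,
              rank_list: Sequence[str],
              max_reps: Optional[int] = None,
              matrix: tuple[str, ...] = DEFAULT_MATRIX) -> CreCurve:
    """CRE over nested channel subsets and repetition counts.

    For each subset size n the FLDA is retrained on the training epochs
    restricted to the n best-ranked channels; every test block is then
    decoded with 1..max_reps repetitions.
    """
    if epochs_test.n_trials == 0:
        raise ValidationError("empty test set")
    if sorted(rank_list) != sorted(epochs_train.montage.labels):
        raise ValidationError("rank list does not cover the montage")
    blocks = _blocks(epochs_test)
    if max_reps is None:
        max_reps = 1 + max(ev.repetition_index for ev in epochs_test.events)
    reps = np.arange(1, max_reps + 1)
    sizes = np.arange(1, len(rank_list) + 1)
    y_train = epochs_train.target_mask
    cre = np.zeros((sizes.size, reps.size))
    truth = {b: true_character(epochs_test, idx, matrix)
             for b, idx in blocks.items()}
    for si, n_ch in enumerate(sizes):
        chans = list(rank_list[:n_ch])
        model = flda_train(features(epochs_train, chans), y_train)
        scores = model.score(features(epochs_test, chans))
        for ri, n_reps in enumerate(reps):
            wrong = 0
            for b, idx in blocks.items():
                codes = [epochs_test.events[i].code for i in idx]
                decoded = decode_character(scores[idx], codes, int(n_reps),
                                           matrix)
                wrong += decoded != truth[b]
            cre[si, ri] = wrong / len(blocks)
    return CreCurve(n_channels=sizes, repetitions=reps, cre=cre)


def ocs(curve: CreCurve, n_reps: int) -> OcsResult:
    """Smallest subset size attaining the minimum CRE at ``n_reps``."""
    if curve.cre.size == 0:
        raise ValidationError("empty CRE curve")
    ri = np.flatnonzero(curve.repetitions == n_reps)
    if ri.size == 0:
        raise ValidationError(f"curve has no column for {n_reps} repetitions")
    col = curve.cre[:, ri[0]]
    best = col.min()
    si = int(np.flatnonzero(col == best)[0])
    return OcsResult(subset_size=int(curve.n_channels[si]), cre=float(best))


def evaluate_session(session: SpellerSession, rank_list: Sequence[str],
                     split: float = 0.5,
                     max_reps: Optional[int] = None) -> tuple[CreCurve, dict]:
    """Preprocess, split blocks train/test, sweep the CRE curve.

    The first ``split`` fraction of blocks trains the FLDA; the rest is
    decoded.  Returns the curve and a per-repetition OCS summary
    ``{reps: {"ocs_size": ..., "cre": ...}}``.
    """
    if not 0 < split < 1:
        raise ValidationError("split must be a fraction in (0, 1)")
    _, sess_clf = preprocess_session(session)
    epochs = extract_epochs(sess_clf)
    n_blocks = session.n_blocks
    n_train = int(round(split * n_blocks))
    if n_train < 1 or n_train >= n_blocks:
        raise ValidationError("split leaves an empty train or test set")
    blk = np.array([ev.block_index for ev in epochs.events])
    ep_train = epochs.select_trials(blk < n_train)
    ep_test = epochs.select_trials(blk >= n_train)
    curve = cre_curve(ep_train, ep_test, rank_list, max_reps=max_reps,
                      matrix=session.matrix)
    summary = {}
    for r in curve.repetitions:
        res = ocs(curve, int(r))
        summary[int(r)] = {"reps": int(r), "ocs_size": res.subset_size,
                           "cre": res.cre}
    return curve, summary
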