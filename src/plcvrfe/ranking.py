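"""PLCV-RFE: recursive channel ranking from pairwise target effects.

The similarity between two channels is the maximum of their target
effect (TE) series in a post-stimulus window; a *low* similarity marks
a redundant couple (same source, or jointly task-irrelevant).  Each
iteration builds a single-linkage hierarchy over the surviving
channels, identifies the unique two-member cluster — equivalently the
global minimum-similarity pair — and eliminates its member with the
lower task-relativity value (TRV, the mean similarity to all other
surviving channels).  Channels eliminated earlier rank lower; the
last survivor ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import (
    EpochSet,
    ParameterError,
    SpellerSession,
    ValidationError,
)
from .phase_metrics import (
    PhaseTensor,
    analytic_phase,
    phase_from_continuous,
    split_by_target,
    target_effect,
)
from .preprocess import WINDOW_S, preprocess_session


@dataclass
class RankConfig:
    """Knobs of the ranking recursion.

    window
        Post-stimulus interval (seconds) over which the TE maximum is
        taken; defaults to the full response window.
    recompute_similarity
        If True, the TE/similarity matrix is recomputed from phases on
        the surviving subset at every iteration instead of subsetting
        the initial matrix.  Pairwise TE does not depend on other
        channels, so both routes give the same ranking; the flag exists
        for fidelity checks.
    """

    window: tuple[float, float] = (0.0, WINDOW_S)
    recompute_similarity: bool = False
    pad_s: float = 1.0
    phase_fs: float = 200.0
    band: tuple[float, float] = (0.1, 40.0)


@dataclass
class SimilarityMatrix:
    """Windowed TE maxima between all channel pairs; diagonal is 0."""

    S: np.ndarray
    window: tuple[float, float]
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if not np.all(np.isfinite(self.S)):
            raise ValidationError("similarity matrix contains non-finite values")


@dataclass
class RfeStep:
    """Log entry for one elimination."""

    iteration: int
    k: int
    surviving: tuple[str, ...]
    couple: Optional[tuple[str, str]]
    trv_couple: Optional[tuple[float, float]]
    eliminated: str
    min_similarity: Optional[float]
    linkage_tree: Optional[np.ndarray] = field(default=None, repr=False)


def similarity_matrix(te_series: np.ndarray, fs: float,
                      window: tuple[float, float] = (0.0, WINDOW_S),
                      channel_labels: Optional[Sequence[str]] = None,
                      ) -> SimilarityMatrix:
    """Max of each pair's TE series over the window.

    ``te_series`` has shape (channels, channels, samples) with time 0
    at stimulus onset.
    """
    te_arr = np.asarray(te_series, dtype=float)
    if te_arr.ndim != 3 or te_arr.shape[0] != te_arr.shape[1]:
        raise ValidationError("TE array must be (channels, channels, samples)")
    n = te_arr.shape[0]
    start, stop = window
    i0 = int(np.floor(start * fs))
    i1 = int(np.ceil(stop * fs))
    i1 = min(i1, te_arr.shape[2])
    if i1 <= i0 or i0 < 0:
        raise ParameterError(f"window {window} selects no samples at fs={fs}")
    S = te_arr[:, :, i0:i1].max(axis=2)
    S = 0.5 * (S + S.T)  # enforce exact symmetry against rounding
    np.fill_diagonal(S, 0.0)
    labels = tuple(channel_labels) if channel_labels is not None else tuple(
        f"ch{i}" for i in range(n))
    return SimilarityMatrix(S=S, window=window, channel_labels=labels)


def trv(S: SimilarityMatrix | np.ndarray, x: int,
        surviving: Optional[Sequence[int]] = None) -> float:
    """Task-relativity value: mean similarity of ``x`` to the other survivors."""
    mat = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    sc = list(range(mat.shape[0])) if surviving is None else list(surviving)
    if x not in sc:
        raise IndexError(f"channel {x} is not in the surviving set")
    k = len(sc)
    if k < 2:
        raise ParameterError("TRV needs at least 2 surviving channels")
    others = [y for y in sc if y != x]
    return float(mat[x, others].sum() / (k - 1))


def _min_pair(S_sub: np.ndarray) -> tuple[int, int]:
    """Global minimum off-diagonal entry; lexicographic (x, y) on ties."""
    k = S_sub.shape[0]
    masked = S_sub.copy()
    np.fill_diagonal(masked, np.inf)
    iu = np.triu_indices(k, 1)
    vals = masked[iu]
    best = np.argmin(vals)  # argmin returns the first minimum: lexicographic
    return int(iu[0][best]), int(iu[1][best])


def _cluster_couple(S_sub: np.ndarray) -> tuple[np.ndarray, Optional[tuple[int, int]]]:
    """Single-linkage tree on S-as-distance, cut into k-1 classes.

    Returns the linkage matrix and the unique two-member class, or
    ``None`` if ties make the cut degenerate (the caller then falls
    back to the direct minimum pair, which the cut equals whenever it
    is well defined).
    """
    k = S_sub.shape[0]
    # linkage needs non-negative distances; a common shift preserves order
    shifted = S_sub - S_sub.min()
    np.fill_diagonal(shifted, 0.0)
    Z = linkage(squareform(shifted, checks=False), method="single")
    labels = fcluster(Z, t=k - 1, criterion="maxclust")
    couple = None
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 2:
            if couple is not None:
                couple = None
                break
            couple = (int(members[0]), int(members[1]))
    return Z, couple


def plcv_rfe_rank(epochs_train: Optional[EpochSet] = None, *,
                  phase_target: Optional[PhaseTensor] = None,
                  phase_nontarget: Optional[PhaseTensor] = None,
                  config: Optional[RankConfig] = None,
                  ) -> tuple[list[str], list[RfeStep]]:
    """Rank all channels by recursive elimination.

    Either pass an :class:`EpochSet` at the phase-analysis rate (phases
    are then computed per epoch) or pre-split phase tensors for the
    target and nontarget conditions.  Returns the rank list ``R`` (most
    important first) and the per-step log, one entry per eliminated
    channel.
    """
    config = config or RankConfig()
    if epochs_train is not None:
        if epochs_train.n_channels < 2:
            raise ValidationError("ranking needs at least 2 channels")
        mask = epochs_train.target_mask
        if mask.sum() < 1 or (~mask).sum() < 1:
            raise ValidationError("need at least one target and one nontarget trial")
        phase = analytic_phase(epochs_train, keep_amplitude=False)
        phase_target, phase_nontarget = split_by_target(phase)
    if phase_target is None or phase_nontarget is None:
        raise ValidationError("pass either epochs_train or both phase tensors")
    if phase_target.n_trials < 1 or phase_nontarget.n_trials < 1:
        raise ValidationError("need at least one target and one nontarget trial")

    labels = phase_target.channel_labels or tuple(
        f"ch{i}" for i in range(phase_target.n_channels))
    fs = phase_target.fs
    te_full = target_effect(phase_target, phase_nontarget)
    S_full = similarity_matrix(te_full, fs, window=config.window,
                               channel_labels=labels).S

    sc = list(range(len(labels)))
    rank: list[str] = []
    steps: list[RfeStep] = []
    iteration = 0
    while sc:
        iteration += 1
        k = len(sc)
        if k == 1:
            rank.insert(0, labels[sc[0]])
            steps.append(RfeStep(iteration=iteration, k=1,
                                 surviving=(labels[sc[0]],), couple=None,
                                 trv_couple=None, eliminated=labels[sc[0]],
                                 min_similarity=None))
            break
        if config.recompute_similarity:
            sub_t = phase_target.select_channels(sc)
            sub_n = phase_nontarget.select_channels(sc)
            S_sub = similarity_matrix(target_effect(sub_t, sub_n), fs,
                                      window=config.window).S
        else:
            S_sub = S_full[np.ix_(sc, sc)]
        Z, couple = _cluster_couple(S_sub)
        if couple is None:  # degenerate ties in the tree cut
            couple = _min_pair(S_sub)
        p, q = sorted(couple)
        trv_p = trv(S_sub, p)
        trv_q = trv(S_sub, q)
        # eliminate the lower-TRV member; ties drop the lower montage index
        w = p if trv_p <= trv_q else q
        rank.insert(0, labels[sc[w]])
        steps.append(RfeStep(
            iteration=iteration, k=k,
            surviving=tuple(labels[i] for i in sc),
            couple=(labels[sc[p]], labels[sc[q]]),
            trv_couple=(trv_p, trv_q),
            eliminated=labels[sc[w]],
            min_similarity=float(S_sub[p, q]),
            linkage_tree=Z,
        ))
        del sc[w]
    return rank, steps


def rank_session(session: SpellerSession,
                 config: Optional[RankConfig] = None,
                 ) -> tuple[list[str], list[RfeStep]]:
    """Full chain on a raw session: filter, decimate, phase, rank.

    Phases are computed on padded windows cut from the continuous
    200 Hz stream so that Hilbert edge artifacts fall outside the
    analysis window.
    """
    config = config or RankConfig()
    sess_phase, _ = preprocess_session(session, band=config.band,
                                       phase_fs=config.phase_fs)
    phase = phase_from_continuous(sess_phase, window_s=WINDOW_S,
                                  pad_s=config.pad_s)
    phase_t, phase_n = split_by_target(phase)
    return plcv_rfe_rank(phase_target=phase_t, phase_nontarget=phase_n,
                         config=config)


def aggregate_channel_weights(rank_lists: Sequence[Sequence[str]]) -> pd.Series:
    """Average z-scored rank positions across runs/subjects.

    Within each list a channel at position ``p`` (0 = most important)
    scores ``n - p``; scores are standardized to zero mean and unit
    variance within the list, then averaged across lists.  Higher
    weight = more important.
    """
    if not rank_lists:
        raise ValidationError("no rank lists given")
    ref = sorted(rank_lists[0])
    zs = []
    for rl in rank_lists:
        if sorted(rl) != ref:
            raise ValidationError("rank lists cover different channel sets")
        n = len(rl)
        scores = pd.Series({lab: float(n - p) for p, lab in enumerate(rl)})
        zs.append((scores - scores.mean()) / scores.std(ddof=0))
    weights = pd.concat(zs, axis=1).mean(axis=1)
    return weights.sort_values(ascending=False)


def steps_to_frame(steps: Sequence[RfeStep]) -> pd.DataFrame:
    """Per-step log as a flat table (for TSV export)."""
    rows = []
    for st in steps:
        rows.append({
            "iteration": st.iteration,
            "k": st.k,
            "eliminated": st.eliminated,
            "couple": "" if st.couple is None else "|".join(st.couple),
            "trv_p": np.nan if st.trv_couple is None else st.trv_couple[0],
            "trv_q": np.nan if st.trv_couple is None else st.trv_couple[1],
            "min_similarity": np.nan if st.min_similarity is None
                              else st.min_similarity,
        })
    return pd.DataFrame(rows)
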