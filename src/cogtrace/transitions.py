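"""Markov-chain layer: initial-state and transition-probability estimation.

The hidden process is the examinee's mastery state (a pattern index, or a
single attribute's 0/1 state); the observation model is the trained SSOM
classifier, so state sequences are classified, not decoded.  Estimation is
therefore plain maximum likelihood on the classified sequences: the initial
distribution is the wave-1 class frequency (pi_i = P(q_1 = s_i)) and each
transition matrix row is the normalized count of moves out of that state
(a_ij = P(q_t = s_j | q_{t-1} = s_i)).  Rows never observed are reported as
NaN rather than an invented distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError, check_row_stochastic
from .patterns import decode_patterns, encode_patterns

__all__ = ["TransitionEstimate", "HMMSpec", "estimate_initial",
           "estimate_transition", "attribute_transitions_from_patterns",
           "correct_transition_rate", "TransitionAgreement", "forward_mastery"]


@dataclass(frozen=True)
class TransitionEstimate:
    """Counts and row-normalized transition probabilities for one interval."""

    counts: np.ndarray
    probabilities: np.ndarray
    interval: tuple = (1, 2)
    granularity: str = "pattern"
    attribute_id: int | None = None

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    def occupied_rows(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    def to_frame(self, labels=None) -> pd.DataFrame:
        if labels is None:
            labels = [str(i) for i in range(self.n_states)]
        return pd.DataFrame(self.probabilities, index=labels, columns=labels)


@dataclass(frozen=True)
class HMMSpec:
    """A fitted hidden-Markov specification: states, pi, A per interval.

    The observation model B is realized by a trained SSOM network (held by
    reference); it is never re-estimated here.
    """

    states: tuple
    pi: np.ndarray
    transitions: tuple  # TransitionEstimate per interval
    observation_model: object = None

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.size != len(self.states):
            raise ValidationError("pi length must equal the state count")
        if not np.isclose(pi.sum(), 1.0) or ((pi < 0) | (pi > 1)).any():
            raise ValidationError("pi must be a probability distribution")
        object.__setattr__(self, "pi", pi)


def estimate_initial(assignments, n_states: int) -> np.ndarray:
    """Empirical wave-1 state distribution (pi)."""
    a = np.asarray(assignments, dtype=np.int64)
    if a.size == 0:
        raise ValidationError("need at least one examinee")
    if (a < 0).any() or (a >= n_states).any():
        raise ValidationError("state index out of range")
    return np.bincount(a, minlength=n_states) / a.size


def estimate_transition(assignments_t, assignments_t1, n_states: int,
                        interval: tuple = (1, 2), granularity: str = "pattern",
                        attribute_id: int | None = None,
                        smoothing: float = 0.0) -> TransitionEstimate:
    """ML transition estimate between two aligned waves of state assignments.

    ``smoothing`` adds a constant to every cell of occupied rows before
    normalizing (additive smoothing for sparse pattern matrices; default off).
    Rows with no outgoing observations stay NaN.
    """
    a = np.asarray(assignments_t, dtype=np.int64)
    b = np.asarray(assignments_t1, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("wave assignments must be aligned 1-D arrays")
    if a.size == 0:
        raise ValidationError("need at least one examinee")
    for arr in (a, b):
        if (arr < 0).any() or (arr >= n_states).any():
            raise ValidationError("state index out of range")
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    probs = np.full((n_states, n_states), np.nan)
    occupied = counts.sum(axis=1) > 0
    smoothed = counts[occupied].astype(float) + smoothing
    probs[occupied] = smoothed / smoothed.sum(axis=1, keepdims=True)
    return TransitionEstimate(counts=counts, probabilities=probs,
                              interval=interval, granularity=granularity,
                              attribute_id=attribute_id)


def attribute_transitions_from_patterns(assignments_t, assignments_t1, k: int,
                                        interval: tuple = (1, 2)) -> list:
    """Decode pattern chains to attribute bits and estimate each 2x2 matrix."""
    bits_t = decode_patterns(np.asarray(assignments_t, dtype=np.int64), k)
    bits_t1 = decode_patterns(np.asarray(assignments_t1, dtype=np.int64), k)
    return [estimate_transition(bits_t[:, a], bits_t1[:, a], 2,
                                interval=interval, granularity="attribute",
                                attribute_id=a)
            for a in range(k)]


@dataclass(frozen=True)
class TransitionAgreement:
    """Agreement between true and estimated transitions over one interval.

    ``pairwise`` is the fraction of examinees whose estimated ordered state
    pair (t, t+1) equals the true pair — both waves must be classified right.
    ``matrix`` compares the transition-probability matrices themselves,
    ``1 - mean |A_est - A_true|`` over rows occupied in both chains, i.e. how
    closely the estimated transfer probabilities track the true ones.
    """

    pairwise: float
    matrix: float
    n: int


def correct_transition_rate(true_profiles_t, true_profiles_t1,
                            est_patterns_t, est_patterns_t1) -> TransitionAgreement:
    """Correct-transition agreement between true and estimated chains."""
    tt = encode_patterns(true_profiles_t)
    tt1 = encode_patterns(true_profiles_t1)
    et = np.asarray(est_patterns_t, dtype=np.int64)
    et1 = np.asarray(est_patterns_t1, dtype=np.int64)
    if not (tt.shape == tt1.shape == et.shape == et1.shape):
        raise ValidationError("all four inputs must be aligned 1-D arrays")
    k = np.asarray(true_profiles_t).shape[1]
    n_states = 1 << k
    pairwise = float(np.mean((tt == et) & (tt1 == et1)))
    a_true = estimate_transition(tt, tt1, n_states)
    a_est = estimate_transition(et, et1, n_states)
    both = a_true.occupied_rows() & a_est.occupied_rows()
    if both.any():
        diff = np.abs(a_est.probabilities[both] - a_true.probabilities[both])
        matrix = float(1.0 - diff.mean())
    else:
        matrix = np.nan
    return TransitionAgreement(pairwise=pairwise, matrix=matrix, n=tt.size)


def forward_mastery(initial_mastery, transitions) -> pd.DataFrame:
    """Chapman–Kolmogorov forward mastery probabilities and growth per wave.

    ``transitions`` is a sequence over intervals, each a sequence over
    attributes of 2x2 row-stochastic matrices.  Returns a tidy frame with
    one row per (wave, attribute): mastery probability and growth versus the
    previous wave.
    """
    p = np.asarray(initial_mastery, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("initial mastery must lie in [0, 1]")
    k = p.size
    waves = [p.copy()]
    for t, interval in enumerate(transitions):
        if len(interval) != k:
            raise ValidationError(f"interval {t} needs one matrix per attribute")
        nxt = np.empty(k)
        for a in range(k):
            m = check_row_stochastic(interval[a], f"transition[{t}][{a}]")
            nxt[a] = waves[-1][a] * m[1, 1] + (1 - waves[-1][a]) * m[0, 1]
        waves.append(nxt)
    rows = []
    for t, vec in enumerate(waves):
        for a in range(k):
            growth = np.nan if t == 0 else vec[a] - waves[t - 1][a]
            rows.append({"wave": t + 1, "attribute": f"A{a + 1}",
                         "mastery": vec[a], "growth": growth})
    return pd.DataFrame(rows)
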