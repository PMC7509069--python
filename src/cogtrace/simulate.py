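"""Longitudinal DINA response simulator.

The DINA ("deterministic inputs, noisy AND gate") model is conjunctive: an
examinee with mastery profile alpha produces the ideal response
``eta_j = prod_k alpha_k ** q_jk`` on item j, observed through slip/guess
noise, ``P(X_j = 1 | alpha) = (1 - s_j) ** eta_j * g_j ** (1 - eta_j)``.

Longitudinal samples draw wave-1 profiles from a Gaussian copula with
exchangeable latent correlation (so per-attribute mastery rates are exact
marginals), then evolve each attribute independently through its own
two-state Markov chain per wave interval; responses are regenerated
independently at every wave given that wave's profiles.

All randomness derives from one root seed via named ``numpy`` SeedSequence
substreams, so profiles, transitions and responses are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from json import dump
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import roots_hermitenorm

from ._validate import (ValidationError, as_binary_matrix, check_probabilities,
                        check_row_stochastic)
from .design import ItemParams, QMatrix, ResponseMatrix, StudyDesign
from .patterns import all_profiles, encode_patterns, n_patterns

__all__ = ["ideal_response", "simulate_responses", "sample_initial_profiles",
           "advance_profiles", "simulate_longitudinal", "build_training_set",
           "pattern_distribution", "LongitudinalSample"]


def ideal_response(profile, q: QMatrix) -> np.ndarray:
    """Noise-free DINA response: 1 iff every attribute the item requires is mastered.

    Accepts a single K-vector (returns a J-vector) or an N x K matrix
    (returns N x J).
    """
    arr = np.asarray(profile)
    single = arr.ndim == 1
    profiles = as_binary_matrix(arr.reshape(1, -1) if single else arr, "profiles")
    if profiles.shape[1] != q.n_attributes:
        raise ValidationError(
            f"profile length {profiles.shape[1]} != Q attributes {q.n_attributes}")
    lacking = ((1 - profiles)[:, None, :] * q.entries[None, :, :]).sum(axis=2)
    eta = (lacking == 0).astype(np.int8)
    return eta[0] if single else eta


def simulate_responses(profiles, q: QMatrix, params: ItemParams,
                       rng: np.random.Generator) -> ResponseMatrix:
    """Draw dichotomous responses cell-wise from the DINA success probability."""
    if params.n_items != q.n_items:
        raise ValidationError("item parameter count must match Q matrix items")
    eta = ideal_response(profiles, q)
    prob = np.where(eta == 1, 1.0 - params.slip, params.guess)
    scores = (rng.random(prob.shape) < prob).astype(np.int8)
    return ResponseMatrix(scores=scores)


def _latent_thresholds(initial_mastery) -> np.ndarray:
    p = check_probabilities(initial_mastery, "initial_mastery")
    return stats.norm.ppf(1.0 - p)  # mastery iff latent normal exceeds threshold


def sample_initial_profiles(n: int, initial_mastery, correlation: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Correlated binary mastery profiles via an exchangeable Gaussian copula.

    Latent ``Z_k = sqrt(rho) * F + sqrt(1 - rho) * E_k`` with a shared factor
    F; attribute k is mastered iff ``Z_k`` exceeds the (1 - p_k) normal
    quantile, so marginal mastery rates are exactly ``initial_mastery`` while
    every latent pair correlates at ``rho``.
    """
    if not 0 <= correlation < 1:
        raise ValidationError("correlation must lie in [0, 1)")
    if n < 1:
        raise ValidationError("need n >= 1")
    thr = _latent_thresholds(initial_mastery)
    k = thr.size
    factor = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    z = np.sqrt(correlation) * factor + np.sqrt(1.0 - correlation) * noise
    return (z > thr[None, :]).astype(np.int8)


def pattern_distribution(initial_mastery, correlation: float,
                         n_nodes: int = 64) -> np.ndarray:
    """Exact copula-implied probability of each of the 2**K mastery patterns.

    Integrates the shared factor out by Gauss–Hermite quadrature: conditional
    on F = f the attributes are independent with mastery probability
    ``1 - Phi((thr_k - sqrt(rho) f) / sqrt(1 - rho))``.
    """
    thr = _latent_thresholds(initial_mastery)
    k = thr.size
    if not 0 <= correlation < 1:
        raise ValidationError("correlation must lie in [0, 1)")
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()
    cond = 1.0 - stats.norm.cdf(
        (thr[None, :] - np.sqrt(correlation) * nodes[:, None])
        / np.sqrt(1.0 - correlation))
    profiles = all_profiles(k)  # 2^K x K
    per_attr = np.where(profiles[None, :, :] == 1, cond[:, None, :],
                        1.0 - cond[:, None, :])
    probs = weights @ per_attr.prod(axis=2)
    return probs / probs.sum()


def advance_profiles(profiles, transitions, rng: np.random.Generator) -> np.ndarray:
    """Evolve each attribute independently through its own 2x2 Markov matrix."""
    mat = as_binary_matrix(profiles, "profiles")
    k = mat.shape[1]
    if len(transitions) != k:
        raise ValidationError("need one 2x2 transition matrix per attribute")
    out = np.empty_like(mat)
    for a in range(k):
        trans = check_row_stochastic(transitions[a], f"transition[{a}]")
        p_master = np.where(mat[:, a] == 1, trans[1, 1], trans[0, 1])
        out[:, a] = rng.random(mat.shape[0]) < p_master
    return out


@dataclass(frozen=True)
class LongitudinalSample:
    """True profiles and simulated responses over T waves for one replication."""

    profiles: tuple      # per wave: N x K binary
    responses: tuple     # per wave: ResponseMatrix
    design: StudyDesign
    seed: object = None

    @property
    def n_waves(self) -> int:
        return len(self.profiles)

    @property
    def n_examinees(self) -> int:
        return self.profiles[0].shape[0]

    def pattern_indices(self) -> tuple:
        """Canonical pattern index of the true profile at every wave."""
        return tuple(encode_patterns(p) for p in self.profiles)

    def save(self, directory) -> None:
        """Write per-wave response CSVs, a profile CSV and a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for t, resp in enumerate(self.responses):
            path = directory / f"responses_T{t + 1}.csv"
            resp.to_csv(path)
            files[f"responses_T{t + 1}"] = path.name
        import pandas as pd
        prof = pd.concat(
            [pd.DataFrame(p, columns=[f"A{a+1}" for a in range(p.shape[1])])
             .assign(wave=t + 1) for t, p in enumerate(self.profiles)],
            ignore_index=True)
        prof.to_csv(directory / "profiles.csv", index=False)
        files["profiles"] = "profiles.csv"
        manifest = {
            "seed": None if self.seed is None else int(self.seed),
            "n_examinees": int(self.n_examinees),
            "n_waves": int(self.n_waves),
            "n_attributes": int(self.design.n_attributes),
            "n_items": int(self.design.n_items),
            "regime": self.design.regime,
            "files": files,
        }
        with open(directory / "manifest.json", "w") as fh:
            dump(manifest, fh, indent=2)


def simulate_longitudinal(design: StudyDesign, q: QMatrix, params: ItemParams,
                          seed=None) -> LongitudinalSample:
    """Simulate a full T-wave longitudinal sample under one study design."""
    if q.n_attributes != design.n_attributes or q.n_items != design.n_items:
        raise ValidationError("Q matrix does not match the study design")
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    ss_profiles, ss_transitions, ss_responses = root.spawn(3)
    rng_prof = np.random.default_rng(ss_profiles)
    rng_trans = np.random.default_rng(ss_transitions)
    rng_resp = np.random.default_rng(ss_responses)

    profiles = [sample_initial_profiles(design.n_examinees, design.initial_mastery,
                                        design.initial_correlation, rng_prof)]
    for interval in design.transitions:
        profiles.append(advance_profiles(profiles[-1], interval, rng_trans))
    responses = []
    for t, prof in enumerate(profiles):
        resp = simulate_responses(prof, q, params, rng_resp)
        responses.append(ResponseMatrix(scores=resp.scores,
                                        examinee_ids=resp.examinee_ids,
                                        time_point=f"T{t + 1}"))
    return LongitudinalSample(profiles=tuple(profiles), responses=tuple(responses),
                              design=design, seed=seed if np.isscalar(seed) else None)


def build_training_set(q: QMatrix, pattern_weights=None, size: int | None = None,
                       rng: np.random.Generator | None = None):
    """Ideal-response training set: (inputs, pattern-index labels).

    With uniform weights (the default) and ``size`` a multiple of 2**K the
    patterns are enumerated exactly ``size / 2**K`` times each (stratified);
    otherwise patterns are drawn i.i.d. from ``pattern_weights`` using ``rng``.
    Rows are ideal responses under ``q``; labels are the generating patterns.
    """
    m = n_patterns(q.n_attributes)
    if size is None:
        size = m
    if size < 1:
        raise ValidationError("training-set size must be >= 1")
    if pattern_weights is None and size % m == 0:
        labels = np.tile(np.arange(m), size // m)
    else:
        w = np.full(m, 1.0 / m) if pattern_weights is None else np.asarray(
            pattern_weights, dtype=float)
        if w.size != m or (w < 0).any():
            raise ValidationError("pattern_weights must be 2**K non-negative values")
        total = w.sum()
        if total <= 0:
            raise ValidationError("pattern_weights must have positive total mass")
        if rng is None:
            raise ValidationError("weighted draws need an rng")
        labels = rng.choice(m, size=size, p=w / total)
    ideal = q.ideal_responses()
    return ideal[labels].astype(float), labels.astype(np.int64)
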