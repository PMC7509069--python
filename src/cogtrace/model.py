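"""Model/Results interface for the longitudinal HMM + SSOM pipeline.

``LongitudinalCDA`` is constructed from per-wave dichotomous response
matrices and a Q matrix, in the spirit of a statsmodels model object.
``fit`` runs the two-step procedure:

1. Measurement step — train the supervised SOM on the ideal responses
   implied by the Q matrix (patterns drawn uniformly or from the
   population's copula-implied distribution) and classify every examinee at
   every wave into a mastery pattern.
2. Transition step — estimate the Markov layer by maximum likelihood from
   the classified chains: the initial pattern distribution pi, the
   pattern-level transition matrix per wave interval, and its attribute-level
   2x2 marginals.

The returned ``LongitudinalCDAResults`` carries the classified trajectories,
probability estimates and a ``summary()``; when true profiles are available
(simulation studies) ``score`` computes ACCR/PCCR per wave and
correct-transition agreement per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError
from .design import QMatrix, ResponseMatrix, load_q_matrix, load_responses
from .fixtures import default_initial_mastery
from .metrics import accuracy_report
from .patterns import decode_patterns, n_patterns
from .simulate import build_training_set, pattern_distribution
from .ssom import SSOMConfig, SSOMNetwork, classify, train
from .transitions import (HMMSpec, attribute_transitions_from_patterns,
                          correct_transition_rate, estimate_initial,
                          estimate_transition)

__all__ = ["LongitudinalCDA", "LongitudinalCDAResults", "default_ssom_config"]


def default_ssom_config(n_attributes: int) -> SSOMConfig:
    """Grid and pass count defaults by attribute count.

    The competition grid holds roughly 4-10 neurons per mastery pattern:
    10x10 for K=3 and 20x20 for K=6.  Two passes suffice for K=3 designs;
    K=6 uses four.
    """
    if n_attributes <= 3:
        return SSOMConfig(grid_shape=(10, 10), iterations=2)
    return SSOMConfig(grid_shape=(20, 20), iterations=4)


class LongitudinalCDA:
    """Longitudinal cognitive diagnosis of T waves of item responses.

    Parameters
    ----------
    responses : sequence of ResponseMatrix (or N x J binary arrays)
        One matrix per time point, same examinees in the same order.
    q : QMatrix
        Item-skill requirements shared by all waves.
    ssom_config : SSOMConfig, optional
        Classifier hyperparameters; defaults depend on the attribute count.
    training : {"population", "uniform"}
        Pattern distribution of the ideal-response training set.  The
        population policy draws patterns from the Gaussian-copula
        distribution implied by ``initial_mastery`` and ``correlation``;
        the uniform policy enumerates every pattern equally often.
    initial_mastery : K-vector, optional
        Marginal mastery rates for the population policy; defaults to the
        built-in study values for K in {3, 6}.
    correlation : float
        Exchangeable latent correlation of the copula (default 0.5).
    train_size : int, optional
        Training rows; defaults to the examinee count (at least 2**K).
    """

    def __init__(self, responses, q: QMatrix, ssom_config: SSOMConfig | None = None,
                 training: str = "population", initial_mastery=None,
                 correlation: float = 0.5, train_size: int | None = None):
        waves = []
        for t, r in enumerate(responses):
            if not isinstance(r, ResponseMatrix):
                r = ResponseMatrix(scores=np.asarray(r), time_point=f"T{t + 1}")
            waves.append(r)
        if not waves:
            raise ValidationError("need at least one wave of responses")
        for r in waves:
            if r.n_items != q.n_items:
                raise ValidationError(
                    f"wave {r.time_point} has {r.n_items} items, Q has {q.n_items}")
        ids0 = waves[0].examinee_ids
        mismatched = [r.time_point for r in waves[1:] if r.examinee_ids != ids0]
        if mismatched:
            raise ValidationError(
                f"examinee IDs do not align across waves: {mismatched}")
        if training not in ("population", "uniform"):
            raise ValidationError("training must be 'population' or 'uniform'")
        self.responses = tuple(waves)
        self.q = q
        self.training = training
        self.correlation = correlation
        k = q.n_attributes
        if initial_mastery is None and training == "population":
            try:
                initial_mastery = default_initial_mastery(k)
            except KeyError:
                raise ValidationError(
                    "population training needs initial_mastery for K="
                    f"{k}; pass it explicitly or use training='uniform'")
        self.initial_mastery = None if initial_mastery is None else np.asarray(
            initial_mastery, dtype=float)
        m = n_patterns(k)
        n = waves[0].n_examinees
        self.train_size = max(train_size or n, m)
        self.ssom_config = ssom_config or default_ssom_config(k)

    @classmethod
    def from_csv(cls, wave_paths, q_path, **kwargs) -> "LongitudinalCDA":
        """Build a model from response CSVs (one per wave) and a Q-matrix CSV."""
        q = load_q_matrix(q_path)
        waves = [load_responses(p, time_point=f"T{t + 1}")
                 for t, p in enumerate(wave_paths)]
        return cls(waves, q, **kwargs)

    @property
    def n_waves(self) -> int:
        return len(self.responses)

    @property
    def n_examinees(self) -> int:
        return self.responses[0].n_examinees

    def _training_set(self, rng: np.random.Generator):
        k = self.q.n_attributes
        m = n_patterns(k)
        if self.training == "uniform":
            size = (self.train_size // m) * m or m
            return build_training_set(self.q, size=size)
        weights = pattern_distribution(self.initial_mastery, self.correlation)
        return build_training_set(self.q, pattern_weights=weights,
                                  size=self.train_size, rng=rng)

    def fit(self, seed=None) -> "LongitudinalCDAResults":
        """Train the measurement model, classify every wave, estimate the chain."""
        self.q.warn_if_incomplete()
        root = seed if isinstance(seed, np.random.SeedSequence) \
            else np.random.SeedSequence(seed)
        ss_train_draw, ss_net = root.spawn(2)
        inputs, labels = self._training_set(np.random.default_rng(ss_train_draw))
        k = self.q.n_attributes
        m = n_patterns(k)
        net = train(inputs, labels, self.ssom_config, n_classes=m,
                    seed=ss_net)
        assignments = tuple(classify(r, net) for r in self.responses)
        pi = estimate_initial(assignments[0], m)
        pattern_trans = tuple(
            estimate_transition(assignments[t], assignments[t + 1], m,
                                interval=(t + 1, t + 2))
            for t in range(self.n_waves - 1))
        attr_trans = tuple(
            attribute_transitions_from_patterns(assignments[t], assignments[t + 1],
                                                k, interval=(t + 1, t + 2))
            for t in range(self.n_waves - 1))
        return LongitudinalCDAResults(model=self, network=net,
                                      assignments=assignments, pi=pi,
                                      pattern_transitions=pattern_trans,
                                      attribute_transitions=attr_trans,
                                      seed=seed)


@dataclass
class LongitudinalCDAResults:
    """Fitted trajectories and Markov estimates of a :class:`LongitudinalCDA`."""

    model: LongitudinalCDA
    network: SSOMNetwork
    assignments: tuple          # per wave: N pattern indices
    pi: np.ndarray              # initial pattern distribution
    pattern_transitions: tuple  # TransitionEstimate per interval
    attribute_transitions: tuple  # per interval: list of 2x2 TransitionEstimates
    seed: object = None

    @property
    def k(self) -> int:
        return self.model.q.n_attributes

    def estimated_profiles(self) -> tuple:
        """Per-wave N x K estimated mastery matrices."""
        return tuple(decode_patterns(a, self.k) for a in self.assignments)

    def hmm_spec(self) -> HMMSpec:
        labels = tuple(self.pattern_labels())
        return HMMSpec(states=labels, pi=self.pi,
                       transitions=self.pattern_transitions,
                       observation_model=self.network)

    def pattern_labels(self) -> list:
        k = self.k
        return [format(i, f"0{k}b") for i in range(n_patterns(k))]

    def mastery(self) -> pd.DataFrame:
        """Estimated per-attribute mastery probability at every wave."""
        rows = []
        for t, prof in enumerate(self.estimated_profiles()):
            rates = prof.mean(axis=0)
            for a, attr in enumerate(self.model.q.attribute_ids):
                rows.append({"wave": t + 1, "attribute": attr,
                             "mastery": float(rates[a])})
        return pd.DataFrame(rows)

    def trajectories(self) -> pd.DataFrame:
        """Per-examinee classified pattern (as a bit string) at every wave."""
        labels = self.pattern_labels()
        data = {"id": list(self.model.responses[0].examinee_ids)}
        for t, a in enumerate(self.assignments):
            data[f"T{t + 1}"] = [labels[i] for i in a]
        return pd.DataFrame(data)

    def score(self, true_profiles) -> dict:
        """Accuracy versus known truth: ACCR/PCCR per wave, agreement per interval."""
        true_profiles = [np.asarray(p) for p in true_profiles]
        if len(true_profiles) != len(self.assignments):
            raise ValidationError("need one true-profile matrix per wave")
        est = self.estimated_profiles()
        reports = [accuracy_report(true_profiles[t], est[t], time_point=f"T{t + 1}")
                   for t in range(len(est))]
        agreements = [
            correct_transition_rate(true_profiles[t], true_profiles[t + 1],
                                    self.assignments[t], self.assignments[t + 1])
            for t in range(len(est) - 1)]
        return {"reports": reports, "agreements": agreements}

    def summary(self) -> str:
        """Plain-text summary of the fitted longitudinal diagnosis."""
        q = self.model.q
        lines = []
        lines.append("Longitudinal Cognitive Diagnosis (HMM + supervised SOM)")
        lines.append("=" * 58)
        lines.append(f"Examinees: {self.model.n_examinees}   Waves: {self.model.n_waves}"
                     f"   Items: {q.n_items}   Attributes: {q.n_attributes}")
        lines.append(f"Training policy: {self.model.training}   "
                     f"SSOM grid: {self.network.config.grid_shape}   "
                     f"passes: {self.network.config.iterations}")
        if self.network.history:
            lines.append("Training accuracy per pass: "
                         + ", ".join(f"{a:.3f}" for a in self.network.history))
        lines.append("")
        lines.append("Initial pattern distribution (pi):")
        labels = self.pattern_labels()
        occupied = [(lab, p) for lab, p in zip(labels, self.pi) if p > 0]
        lines.append("  " + "  ".join(f"{lab}:{p:.3f}" for lab, p in occupied))
        lines.append("")
        lines.append("Estimated attribute mastery by wave:")
        mast = self.mastery().pivot(index="attribute", columns="wave",
                                    values="mastery")
        mast.columns = [f"T{c}" for c in mast.columns]
        lines.append(mast.round(3).to_string())
        for t, interval in enumerate(self.attribute_transitions):
            lines.append("")
            lines.append(f"Attribute transition probabilities T{t + 1} -> T{t + 2} "
                         "(rows: from-state 0/1):")
            for a, est in enumerate(interval):
                p = est.probabilities
                lines.append(f"  {q.attribute_ids[a]}: "
                             f"0 -> [{p[0, 0]:.2f}, {p[0, 1]:.2f}]   "
                             f"1 -> [{p[1, 0]:.2f}, {p[1, 1]:.2f}]")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Write trajectories, mastery, pi and transition tables as CSVs."""
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trajectories().to_csv(directory / "trajectories.csv", index=False)
        self.mastery().to_csv(directory / "mastery.csv", index=False)
        labels = self.pattern_labels()
        pd.Series(self.pi, index=labels, name="pi").to_csv(
            directory / "initial_distribution.csv")
        for t, est in enumerate(self.pattern_transitions):
            est.to_frame(labels).to_csv(
                directory / f"pattern_transitions_T{t + 1}_T{t + 2}.csv")
        for t, interval in enumerate(self.attribute_transitions):
            frames = []
            for a, e in enumerate(interval):
                df = e.to_frame(["0", "1"])
                df.insert(0, "attribute", self.model.q.attribute_ids[a])
                df.insert(1, "from_state", ["0", "1"])
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                directory / f"attribute_transitions_T{t + 1}_T{t + 2}.csv",
                index=False)
        self.network.save(directory / "ssom_network.npz")
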