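"""Core design objects: Q matrix, item parameters, responses, study designs.

The Q matrix is the binary item x attribute incidence matrix of a cognitive
diagnostic assessment: entry ``q[j, k] = 1`` declares that item ``j`` requires
skill ``k``.  Item parameters are the DINA slip/guess pair per item.  A
``StudyDesign`` bundles everything a longitudinal simulation condition needs
(sample size, initial mastery rates, attribute-wise transition matrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import (ValidationError, as_binary_matrix, check_probabilities,
                        check_row_stochastic)
from .patterns import all_profiles

__all__ = ["QMatrix", "ItemParams", "ResponseMatrix", "StudyDesign",
           "load_q_matrix", "load_item_params", "load_responses",
           "IncompleteQMatrixWarning"]

REGIME_RANGES = {"high": (0.0, 0.20), "mixed": (0.0, 0.40)}


class IncompleteQMatrixWarning(UserWarning):
    """Some mastery patterns share an ideal response and cannot be told apart."""


@dataclass(frozen=True)
class QMatrix:
    """Binary item x attribute incidence matrix.

    Parameters
    ----------
    entries : (J, K) array of 0/1
        Skill requirements; each item must require at least one attribute.
    item_ids, attribute_ids : sequences of labels, optional
        Default to ``item1..itemJ`` / ``A1..AK``.
    """

    entries: np.ndarray
    item_ids: tuple = None
    attribute_ids: tuple = None

    def __post_init__(self):
        mat = as_binary_matrix(self.entries, "Q matrix")
        if mat.shape[0] < 1 or mat.shape[1] < 1:
            raise ValidationError("Q matrix needs at least one item and one attribute")
        empty = np.flatnonzero(mat.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(f"Q matrix row {int(empty[0])} requires no attribute")
        object.__setattr__(self, "entries", mat)
        items = tuple(self.item_ids) if self.item_ids is not None else tuple(
            f"item{j + 1}" for j in range(mat.shape[0]))
        attrs = tuple(self.attribute_ids) if self.attribute_ids is not None else tuple(
            f"A{k + 1}" for k in range(mat.shape[1]))
        if len(items) != mat.shape[0] or len(attrs) != mat.shape[1]:
            raise ValidationError("label lengths must match Q matrix shape")
        object.__setattr__(self, "item_ids", items)
        object.__setattr__(self, "attribute_ids", attrs)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def ideal_responses(self) -> np.ndarray:
        """Ideal (noise-free DINA) response of every pattern: 2**K x J matrix."""
        profiles = all_profiles(self.n_attributes)
        lacking = ((1 - profiles)[:, None, :] * self.entries[None, :, :]).sum(axis=2)
        return (lacking == 0).astype(np.int8)

    def collision_groups(self) -> list[list[int]]:
        """Groups (size >= 2) of pattern indices sharing one ideal response.

        Brute-force enumeration over all 2**K patterns; colliding patterns are
        indistinguishable from item responses no matter the classifier.
        """
        ideal = self.ideal_responses()
        seen: dict[bytes, list[int]] = {}
        for idx, row in enumerate(ideal):
            seen.setdefault(row.tobytes(), []).append(idx)
        return [grp for grp in seen.values() if len(grp) > 1]

    @property
    def is_complete(self) -> bool:
        """True when every mastery pattern has a distinct ideal response."""
        return not self.collision_groups()

    def warn_if_incomplete(self) -> None:
        groups = self.collision_groups()
        if groups:
            warnings.warn(
                f"Q matrix is incomplete: pattern index groups {groups} share "
                "ideal responses and cannot be distinguished",
                IncompleteQMatrixWarning, stacklevel=2)

    def to_csv(self, path, header: bool = True) -> None:
        df = pd.DataFrame(self.entries, index=list(self.item_ids),
                          columns=list(self.attribute_ids))
        df.to_csv(path, index=False, header=header)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.item_ids),
                            columns=list(self.attribute_ids))


@dataclass(frozen=True)
class ItemParams:
    """Per-item DINA slip/guess probabilities, optionally tagged by regime.

    ``slip[j]`` is the probability that a student mastering everything item j
    requires still answers wrong; ``guess[j]`` the probability a non-master
    answers right.  High-discrimination items draw both from U(0, 0.2), mixed
    from U(0, 0.4).
    """

    slip: np.ndarray
    guess: np.ndarray
    regime: str | None = None

    def __post_init__(self):
        s = check_probabilities(self.slip, "slip")
        g = check_probabilities(self.guess, "guess")
        if s.ndim != 1 or s.shape != g.shape:
            raise ValidationError("slip and guess must be 1-D and equally long")
        if self.regime is not None and self.regime not in REGIME_RANGES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        object.__setattr__(self, "slip", s)
        object.__setattr__(self, "guess", g)

    @property
    def n_items(self) -> int:
        return self.slip.size

    @classmethod
    def draw(cls, n_items: int, regime: str, rng: np.random.Generator) -> "ItemParams":
        """Draw slip/guess uniformly from the regime's range."""
        lo, hi = REGIME_RANGES[regime]
        return cls(slip=rng.uniform(lo, hi, n_items),
                   guess=rng.uniform(lo, hi, n_items), regime=regime)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item": np.arange(1, self.n_items + 1),
                             "slip": self.slip, "guess": self.guess})


@dataclass(frozen=True)
class ResponseMatrix:
    """Dichotomous scores of N examinees on J items at one time point."""

    scores: np.ndarray
    examinee_ids: tuple = None
    time_point: str = "T1"

    def __post_init__(self):
        mat = as_binary_matrix(self.scores, "response matrix")
        object.__setattr__(self, "scores", mat)
        ids = tuple(self.examinee_ids) if self.examinee_ids is not None else tuple(
            f"s{i + 1}" for i in range(mat.shape[0]))
        if len(ids) != mat.shape[0]:
            raise ValidationError("examinee id count must match row count")
        object.__setattr__(self, "examinee_ids", ids)

    @property
    def n_examinees(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.scores, columns=[f"item{j+1}" for j in range(self.n_items)])
        df.insert(0, "id", list(self.examinee_ids))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class StudyDesign:
    """One simulation condition of the longitudinal study.

    Defaults follow the simulation design: three time points, latent
    correlation 0.5 between attributes at intake, 30 replications.
    """

    n_attributes: int
    n_items: int
    n_examinees: int
    regime: str
    initial_mastery: np.ndarray
    transitions: tuple  # per interval: tuple over attributes of 2x2 matrices
    initial_correlation: float = 0.5
    n_waves: int = 3
    replications: int = 30

    def __post_init__(self):
        p = check_probabilities(self.initial_mastery, "initial_mastery")
        if p.size != self.n_attributes:
            raise ValidationError("initial_mastery length must equal n_attributes")
        object.__setattr__(self, "initial_mastery", p)
        if not 0 <= self.initial_correlation < 1:
            raise ValidationError("initial_correlation must lie in [0, 1)")
        if self.regime not in REGIME_RANGES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        trans = []
        for t, interval in enumerate(self.transitions):
            if len(interval) != self.n_attributes:
                raise ValidationError(f"interval {t} needs one 2x2 matrix per attribute")
            trans.append(tuple(
                check_row_stochastic(m, f"transition[{t}][{k}]")
                for k, m in enumerate(interval)))
        if len(trans) != self.n_waves - 1:
            raise ValidationError("need n_waves - 1 transition intervals")
        object.__setattr__(self, "transitions", tuple(trans))


def _read_table(path, dialect: str, header: bool) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    try:
        return pd.read_csv(path, sep=sep, header=0 if header else None)
    except FileNotFoundError:
        raise
    except Exception as exc:  # ragged rows, parse errors
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def load_q_matrix(path, dialect: str = "csv", header: bool = True) -> QMatrix:
    """Read a Q matrix from CSV/TSV (rows = items, columns = attributes)."""
    df = _read_table(path, dialect, header)
    attrs = [str(c) for c in df.columns] if header else None
    q = QMatrix(entries=df.to_numpy(), attribute_ids=attrs)
    q.warn_if_incomplete()
    return q


def load_item_params(path, dialect: str = "csv") -> ItemParams:
    """Read an item-parameter table with columns ``item``, ``slip``, ``guess``."""
    df = _read_table(path, dialect, header=True)
    cols = {c.lower(): c for c in df.columns}
    missing = {"slip", "guess"} - set(cols)
    if missing:
        raise ValidationError(f"item parameter table lacks columns {sorted(missing)}")
    return ItemParams(slip=df[cols["slip"]].to_numpy(float),
                      guess=df[cols["guess"]].to_numpy(float))


def load_responses(path, dialect: str = "csv", time_point: str = "T1",
                   id_column: str | None = "id") -> ResponseMatrix:
    """Read a response matrix (rows = examinees, optional leading ID column)."""
    df = _read_table(path, dialect, header=True)
    ids = None
    if id_column is not None and id_column in df.columns:
        ids = tuple(str(v) for v in df[id_column])
        df = df.drop(columns=[id_column])
    return ResponseMatrix(scores=df.to_numpy(), examinee_ids=ids,
                          time_point=time_point)
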