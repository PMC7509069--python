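"""Classification-accuracy criteria: ACCR and PCCR.

ACCR (attribute correct classification rate) is the per-skill fraction of
examinees whose estimated mastery bit matches the truth; PCCR (pattern
correct classification rate) requires the whole K-bit pattern to match, so
PCCR <= min_k ACCR_k always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError, as_binary_matrix

__all__ = ["AccuracyReport", "accr", "pccr", "accuracy_report", "aggregate"]


def _paired(true_profiles, est_profiles):
    t = as_binary_matrix(true_profiles, "true profiles")
    e = as_binary_matrix(est_profiles, "estimated profiles")
    if t.shape != e.shape:
        raise ValidationError(f"shape mismatch {t.shape} vs {e.shape}")
    return t, e


def accr(true_profiles, est_profiles) -> np.ndarray:
    """Per-attribute agreement rate between true and estimated mastery."""
    t, e = _paired(true_profiles, est_profiles)
    return (t == e).mean(axis=0)


def pccr(true_profiles, est_profiles) -> float:
    """Whole-pattern agreement rate (every attribute right simultaneously)."""
    t, e = _paired(true_profiles, est_profiles)
    return float((t == e).all(axis=1).mean())


@dataclass(frozen=True)
class AccuracyReport:
    """ACCR/PCCR for one wave of one replication."""

    accr: np.ndarray
    pccr: float
    n: int
    time_point: str = "T1"

    @property
    def n_attributes(self) -> int:
        return self.accr.size


def accuracy_report(true_profiles, est_profiles, time_point: str = "T1") -> AccuracyReport:
    t, e = _paired(true_profiles, est_profiles)
    return AccuracyReport(accr=(t == e).mean(axis=0),
                          pccr=float((t == e).all(axis=1).mean()),
                          n=t.shape[0], time_point=time_point)


def aggregate(reports) -> pd.DataFrame:
    """Mean and standard error of ACCR/PCCR over replications, per time point.

    Rows are time points; columns are A1..AK means, the pattern (PCCR) mean,
    and matching standard errors across replications — the layout of the
    condition summary tables.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("need at least one report")
    k = reports[0].n_attributes
    if any(r.n_attributes != k for r in reports):
        raise ValidationError("reports mix attribute counts")
    rows = []
    for tp in dict.fromkeys(r.time_point for r in reports):
        group = [r for r in reports if r.time_point == tp]
        acc = np.vstack([r.accr for r in group])
        pcc = np.array([r.pccr for r in group])
        m = len(group)
        se = np.sqrt(m) if m > 1 else np.nan
        row = {"time_point": tp, "replications": m}
        for a in range(k):
            row[f"A{a + 1}"] = acc[:, a].mean()
            row[f"A{a + 1}_se"] = acc[:, a].std(ddof=1) / se if m > 1 else np.nan
        row["pattern"] = pcc.mean()
        row["pattern_se"] = pcc.std(ddof=1) / se if m > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
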