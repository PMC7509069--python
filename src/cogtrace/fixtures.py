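"""Built-in study designs: Q matrices, item parameters, transition matrices.

The reference simulation design shipped with the package: 20-item Q
matrices for three and six attributes with their high/mixed slip-guess
draws, attribute-wise transition matrices for both attribute counts, and
the 8-item reading-assessment Q matrix (skills: acquisition, integration,
evaluation).  ``builtin_fixture`` is the single lookup point.
"""

from __future__ import annotations

import numpy as np

from .design import ItemParams, QMatrix

__all__ = ["builtin_fixture", "FIXTURE_NAMES", "default_initial_mastery"]

# K=3, 20 items: (A1, A2, A3, s_high, g_high, s_mixed, g_mixed)
_T1_K3 = [
    (1, 1, 0, 0.16, 0.04, 0.33, 0.10),
    (0, 1, 1, 0.17, 0.15, 0.24, 0.28),
    (1, 1, 0, 0.01, 0.10, 0.26, 0.24),
    (1, 1, 1, 0.17, 0.05, 0.12, 0.22),
    (0, 1, 1, 0.10, 0.13, 0.37, 0.15),
    (0, 1, 0, 0.12, 0.07, 0.35, 0.04),
    (1, 0, 0, 0.07, 0.15, 0.09, 0.34),
    (1, 0, 1, 0.08, 0.17, 0.39, 0.14),
    (0, 1, 0, 0.03, 0.10, 0.19, 0.36),
    (0, 1, 1, 0.16, 0.07, 0.31, 0.30),
    (1, 0, 1, 0.10, 0.17, 0.11, 0.38),
    (0, 1, 0, 0.16, 0.11, 0.30, 0.04),
    (1, 0, 1, 0.13, 0.10, 0.33, 0.19),
    (0, 1, 1, 0.03, 0.13, 0.09, 0.18),
    (1, 0, 1, 0.05, 0.17, 0.37, 0.39),
    (1, 1, 0, 0.05, 0.01, 0.29, 0.06),
    (1, 0, 1, 0.14, 0.05, 0.39, 0.10),
    (1, 0, 0, 0.10, 0.17, 0.31, 0.01),
    (0, 1, 0, 0.11, 0.03, 0.12, 0.19),
    (0, 1, 1, 0.14, 0.18, 0.18, 0.06),
]

# K=6, 20 items: (A1..A6, s_high, g_high, s_mixed, g_mixed)
_T1_K6 = [
    (1, 0, 1, 1, 0, 0, 0.08, 0.17, 0.40, 0.35),
    (1, 1, 0, 0, 0, 1, 0.00, 0.05, 0.35, 0.09),
    (1, 0, 1, 1, 0, 1, 0.03, 0.15, 0.21, 0.22),
    (0, 1, 0, 1, 1, 0, 0.11, 0.05, 0.40, 0.21),
    (1, 0, 0, 0, 1, 0, 0.03, 0.14, 0.39, 0.03),
    (0, 0, 1, 0, 0, 1, 0.03, 0.13, 0.02, 0.02),
    (1, 1, 0, 1, 0, 1, 0.19, 0.02, 0.31, 0.16),
    (1, 1, 1, 1, 1, 0, 0.18, 0.19, 0.03, 0.14),
    (1, 0, 0, 1, 0, 0, 0.07, 0.06, 0.28, 0.16),
    (1, 1, 0, 0, 0, 0, 0.03, 0.19, 0.30, 0.00),
    (0, 0, 0, 1, 0, 0, 0.08, 0.16, 0.06, 0.05),
    (0, 0, 0, 1, 0, 0, 0.06, 0.05, 0.11, 0.32),
    (1, 0, 0, 1, 0, 0, 0.00, 0.00, 0.32, 0.21),
    (0, 1, 0, 0, 1, 1, 0.12, 0.04, 0.33, 0.00),
    (1, 1, 1, 1, 1, 1, 0.05, 0.04, 0.08, 0.11),
    (0, 1, 0, 1, 1, 1, 0.15, 0.06, 0.12, 0.12),
    (0, 0, 1, 0, 0, 0, 0.05, 0.16, 0.32, 0.09),
    (1, 1, 0, 0, 0, 1, 0.07, 0.01, 0.22, 0.04),
    (1, 0, 0, 0, 0, 1, 0.06, 0.05, 0.32, 0.05),
    (1, 1, 1, 1, 0, 1, 0.20, 0.04, 0.14, 0.23),
]

# 8-item empirical reading Q matrix (acquisition, integration, evaluation).
_Q_EMPIRICAL = [
    (1, 0, 0),
    (1, 0, 0),
    (0, 1, 0),
    (0, 1, 0),
    (0, 0, 1),
    (0, 0, 1),
    (0, 0, 1),
    (0, 1, 0),
]

# Attribute-wise conditional transition matrices, rows [from-state 0, 1],
# columns [to-state 0, 1]; one tuple of K matrices per wave interval.
_TRANSITIONS_K3 = (
    (  # T1 -> T2
        ((0.55, 0.45), (0.03, 0.97)),
        ((0.71, 0.29), (0.03, 0.97)),
        ((0.93, 0.07), (0.87, 0.13)),
    ),
    (  # T2 -> T3
        ((0.66, 0.34), (0.06, 0.94)),
        ((0.82, 0.18), (0.05, 0.95)),
        ((0.90, 0.10), (0.54, 0.46)),
    ),
)

_TRANSITIONS_K6 = (
    (  # T1 -> T2
        ((0.45, 0.55), (0.03, 0.97)),
        ((0.56, 0.44), (0.04, 0.96)),
        ((0.61, 0.39), (0.13, 0.87)),
        ((0.72, 0.28), (0.25, 0.75)),
        ((0.78, 0.22), (0.43, 0.57)),
        ((0.83, 0.17), (0.54, 0.46)),
    ),
    (  # T2 -> T3
        ((0.36, 0.64), (0.02, 0.98)),
        ((0.42, 0.58), (0.05, 0.95)),
        ((0.54, 0.46), (0.14, 0.86)),
        ((0.46, 0.54), (0.06, 0.94)),
        ((0.42, 0.58), (0.18, 0.82)),
        ((0.59, 0.41), (0.12, 0.88)),
    ),
)

_INITIAL_MASTERY = {3: (0.4, 0.4, 0.2), 6: (0.4, 0.4, 0.3, 0.3, 0.2, 0.2)}

FIXTURE_NAMES = (
    "q3_20", "q6_20", "q_empirical",
    "transitions_k3", "transitions_k6",
    "params_high_20", "params_mixed_20",
    "params_high_20_k6", "params_mixed_20_k6",
)


def default_initial_mastery(k: int) -> np.ndarray:
    """Per-attribute initial mastery probabilities of the study design."""
    if k not in _INITIAL_MASTERY:
        raise KeyError(f"no default initial mastery for K={k}")
    return np.asarray(_INITIAL_MASTERY[k], dtype=float)


def _q_from(rows, k):
    return QMatrix(entries=np.array([r[:k] for r in rows], dtype=np.int8))


def _params_from(rows, k, regime):
    off = k + (0 if regime == "high" else 2)
    return ItemParams(slip=np.array([r[off] for r in rows]),
                      guess=np.array([r[off + 1] for r in rows]),
                      regime=regime)


def _transition_arrays(table):
    return tuple(tuple(np.asarray(m, dtype=float) for m in interval)
                 for interval in table)


def builtin_fixture(name: str):
    """Return an exact in-memory copy of a built-in design table.

    Raises ``KeyError`` for unknown names; ``FIXTURE_NAMES`` lists the valid
    ones.  The ``params_*`` fixtures default to the three-attribute column of
    the 20-item table; append ``_k6`` for the six-attribute column.
    """
    if name == "q3_20":
        return _q_from(_T1_K3, 3)
    if name == "q6_20":
        return _q_from(_T1_K6, 6)
    if name == "q_empirical":
        return QMatrix(entries=np.array(_Q_EMPIRICAL, dtype=np.int8),
                       attribute_ids=("acquisition", "integration", "evaluation"))
    if name == "transitions_k3":
        return _transition_arrays(_TRANSITIONS_K3)
    if name == "transitions_k6":
        return _transition_arrays(_TRANSITIONS_K6)
    if name == "params_high_20":
        return _params_from(_T1_K3, 3, "high")
    if name == "params_mixed_20":
        return _params_from(_T1_K3, 3, "mixed")
    if name == "params_high_20_k6":
        return _params_from(_T1_K6, 6, "high")
    if name == "params_mixed_20_k6":
        return _params_from(_T1_K6, 6, "mixed")
    raise KeyError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
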