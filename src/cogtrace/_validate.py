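"""Shared validation helpers."""

from __future__ import annotations

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


def as_binary_matrix(values, name: str) -> np.ndarray:
    """Coerce to a 2-D 0/1 integer array, naming the offending row on failure."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be two-dimensional, got shape {arr.shape}")
    try:
        arr = arr.astype(np.int8, casting="unsafe")
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} contains non-numeric entries") from exc
    bad = ~np.isin(arr, (0, 1)).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{name} row {row} contains entries outside {{0, 1}}")
    return arr


def as_binary_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    arr = np.asarray(arr, dtype=np.int8)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} contains entries outside {{0, 1}}")
    return arr


def check_probabilities(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError(f"{name} must lie in [0, 1]")
    return arr


def check_row_stochastic(matrix, name: str, atol: float = 1e-8) -> np.ndarray:
    arr = check_probabilities(matrix, name)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {arr.shape}")
    sums = arr.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValidationError(f"{name} rows must sum to 1 (got row sums {sums})")
    return arr
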