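"""Canonical integer encoding of attribute-mastery patterns.

A mastery pattern is a binary vector of length K (one bit per skill).  The
canonical index treats the *first* attribute as the most significant bit, so
for K = 3 the patterns order as 000, 001, 010, 011, 100, 101, 110, 111 with
indices 0..7.  All pipeline components exchange patterns through this
encoding.
"""

from __future__ import annotations

import numpy as np

from ._validate import ValidationError, as_binary_matrix, as_binary_vector

__all__ = ["encode_pattern", "decode_pattern", "encode_patterns", "decode_patterns",
           "n_patterns", "all_profiles"]


def n_patterns(k: int) -> int:
    """Number of distinct mastery patterns over ``k`` attributes (2**k)."""
    if k < 1:
        raise ValidationError("attribute count must be >= 1")
    return 1 << k


def encode_pattern(profile) -> int:
    """Map a binary mastery vector to its canonical index (first bit = MSB)."""
    bits = as_binary_vector(profile, "profile")
    if bits.size < 1:
        raise ValidationError("profile must have at least one attribute")
    weights = 1 << np.arange(bits.size - 1, -1, -1)
    return int(bits @ weights)


def decode_pattern(index: int, k: int) -> np.ndarray:
    """Inverse of :func:`encode_pattern` for a given attribute count."""
    if not 0 <= index < n_patterns(k):
        raise ValidationError(f"pattern index {index} out of range for K={k}")
    return np.array([(index >> (k - 1 - i)) & 1 for i in range(k)], dtype=np.int8)


def encode_patterns(profiles) -> np.ndarray:
    """Vectorised :func:`encode_pattern` over rows of an N x K matrix."""
    mat = as_binary_matrix(profiles, "profiles")
    k = mat.shape[1]
    weights = 1 << np.arange(k - 1, -1, -1)
    return mat @ weights


def decode_patterns(indices, k: int) -> np.ndarray:
    """Vectorised :func:`decode_pattern`; returns an N x K binary matrix."""
    idx = np.asarray(indices, dtype=np.int64)
    if ((idx < 0) | (idx >= n_patterns(k))).any():
        raise ValidationError(f"pattern indices out of range for K={k}")
    shifts = np.arange(k - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def all_profiles(k: int) -> np.ndarray:
    """All 2**k mastery patterns in canonical index order (2**k x k matrix)."""
    return decode_patterns(np.arange(n_patterns(k)), k)
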