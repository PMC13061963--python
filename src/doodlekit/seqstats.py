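"""Per-read and pool-level sequence statistics.

Three per-read descriptors drive all downstream characterization of
untemplated synthesis pools:

* base composition — the fraction of A/C/G/T among called bases;
* the base transition matrix — a 4x4 row-stochastic matrix of the
  probability that base b is immediately followed by base b';
* the normalized string autocorrelation r(k) — for lag k, the number of
  positions at which the sequence equals itself shifted by k, divided by the
  full sequence length N. Tandem repeats of period p produce peaks of r at
  multiples of p, which is the periodicity signature used to recognize
  repetitive reads.

Only perfectly matching bases count; ``N`` is a non-call and is excluded
from every count and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reads import ReadPool

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "CompositionVector",
    "TransitionMatrix",
    "AutocorrProfile",
    "base_composition",
    "transition_matrix",
    "aggregate_transitions",
    "autocorrelation_profile",
]


@dataclass(frozen=True)
class CompositionVector:
    fractions: np.ndarray  # order A, C, G, T

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BASES, map(float, self.fractions)))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities with per-row support counts.

    Rows with zero support (source base never observed with a successor) are
    NaN, not zero-filled: they are undefined, and consumers must impute
    explicitly if they need finite values.
    """

    probabilities: np.ndarray  # 4x4, rows may be NaN
    support_counts: np.ndarray  # pair count per source base, length 4

    def row(self, base: str) -> np.ndarray:
        return self.probabilities[_BASE_INDEX[base]]

    def defined_rows(self) -> np.ndarray:
        return self.support_counts > 0


@dataclass(frozen=True)
class AutocorrProfile:
    r: np.ndarray  # r(0) .. r(max_lag)
    N: int  # sequence length used as the normalization denominator

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.r))


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3 and N (or anything else) to -1."""
    raw = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(raw.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[raw == ord(base)] = idx
    return out


def base_composition(sequence: str) -> CompositionVector:
    """Fraction of each base among non-N positions."""
    codes = _encode(sequence)
    called = codes[codes >= 0]
    if called.size == 0:
        raise ValueError("base_composition undefined: no called (non-N) bases")
    counts = np.bincount(called, minlength=4)
    return CompositionVector(counts / called.size)


def _pair_counts(sequence: str) -> np.ndarray:
    codes = _encode(sequence)
    a, b = codes[:-1], codes[1:]
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return counts


def _normalize_rows(counts: np.ndarray) -> TransitionMatrix:
    support = counts.sum(axis=1)
    probs = np.full((4, 4), np.nan)
    nz = support > 0
    probs[nz] = counts[nz] / support[nz, None]
    return TransitionMatrix(probs, support)


def transition_matrix(sequence: str) -> TransitionMatrix:
    """P(b -> b') from adjacent ordered pairs; pairs involving N are skipped."""
    if len(sequence) < 2:
        raise ValueError("transition_matrix requires sequence length >= 2")
    return _normalize_rows(_pair_counts(sequence))


def aggregate_transitions(pool: ReadPool, min_length: int = 65) -> TransitionMatrix:
    """Count-weighted pooled transition matrix over reads longer than ``min_length``.

    Pair counts are pooled across qualifying reads and rows normalized once,
    so each observed transition contributes equally regardless of which read
    it came from.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    n_used = 0
    for r in pool:
        if len(r) > min_length and len(r) >= 2:
            counts += _pair_counts(r.sequence)
            n_used += 1
    if n_used == 0:
        raise ValueError(f"no reads longer than {min_length} nt to aggregate")
    return _normalize_rows(counts)


def autocorrelation_profile(
    sequence: str, max_lag: int, denominator: str = "N"
) -> AutocorrProfile:
    """Normalized string autocorrelation r(k), k = 0..max_lag.

    r(k) = |{i : s_i == s_{i+k}, both called}| / N with N the full sequence
    length; the fixed /N denominator makes r decay toward zero at large lags
    (the finite-length envelope). ``denominator="N-k"`` divides by the number
    of compared positions instead, for comparability with overlap-normalized
    definitions; it is not the default.
    """
    N = len(sequence)
    if N < 1:
        raise ValueError("autocorrelation undefined for an empty sequence")
    if max_lag >= N:
        raise ValueError(f"max_lag {max_lag} must be < sequence length {N}")
    if denominator not in ("N", "N-k"):
        raise ValueError("denominator must be 'N' or 'N-k'")
    codes = _encode(sequence)
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = codes[: N - k] if k else codes
        b = codes[k:]
        matches = int(np.sum((a == b) & (a >= 0)))
        denom = N if denominator == "N" else (N - k)
        r[k] = matches / denom
    return AutocorrProfile(r, N)
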