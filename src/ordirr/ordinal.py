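"""Ordinal (permutation) pattern encoding and time-reversal pairing.

A window of ``D`` values spaced ``tau`` samples apart is summarised by the
permutation that sorts it in increasing order: the ordinal pattern
``pi = (r_0, ..., r_{D-1})`` such that ``x[s + r_0] <= x[s + r_1] <= ...``.
Reversing the window in time maps each pattern onto a partner pattern
(elementwise complement ``r -> D - 1 - r`` under this index-based encoding),
which partitions the ``D!`` patterns into reversal pairs.  Asymmetric
occurrence frequencies within a pair are the footprint of time
irreversibility that the rest of the package tests for.

Two encoding conventions circulate in the ordinal-analysis literature: the
index convention used here (``pi[k]`` = position of the k-th smallest value)
and the rank convention (its inverse permutation).  They relabel individual
patterns but induce the *same* partition of windows into reversal-pair
classes, so every pair-level count in this package is convention-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from math import factorial
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

Pattern = tuple[int, ...]

#: Default embedding dimension (window length of the ordinal encoding).
DEFAULT_D = 3
#: Default embedding delay (spacing between the samples of a window).
DEFAULT_TAU = 1

#: Relative scale of the optional pre-jitter used to break ties (fraction of
#: the signal standard deviation).
JITTER_SCALE = 1e-9


def _validate_pattern(p: Sequence[int]) -> Pattern:
    p = tuple(int(r) for r in p)
    d = len(p)
    if d < 2 or sorted(p) != list(range(d)):
        raise ValueError(f"not a valid ordinal pattern: {p!r}")
    return p


def encode_window(window: Sequence[float], tie_rule: str = "stable") -> Pattern:
    """Encode one window of ``D`` values as its ordinal pattern.

    Parameters
    ----------
    window
        Sequence of ``D >= 2`` finite values.
    tie_rule
        ``"stable"``: equal values are ordered by ascending time index,
        making the sort deterministic.  ``"jitter"`` is accepted for
        interface symmetry with :func:`count_patterns`; jitter is applied
        to the whole series upstream, so at the single-window level both
        rules reduce to the stable sort.

    Returns
    -------
    tuple of int
        The permutation ``pi`` with ``window[pi[0]] <= window[pi[1]] <= ...``.
    """
    if tie_rule not in ("stable", "jitter"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"window must be 1-D with length >= 2, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return tuple(int(i) for i in np.argsort(w, kind="stable"))


def reverse_pattern(p: Sequence[int]) -> Pattern:
    """Ordinal pattern of the time-reversed window.

    Under the index-based encoding, reversing the window sends the position
    of the k-th smallest value from ``r_k`` to ``D - 1 - r_k``, so the
    reversed pattern is the elementwise complement.  The map is an
    involution and (for ``D >= 2``) has no fixed point, so it pairs the
    ``D!`` patterns into ``D!/2`` disjoint reversal classes.
    """
    p = _validate_pattern(p)
    d = len(p)
    return tuple(d - 1 - r for r in p)


@dataclass(frozen=True)
class PatternPair:
    """An unordered reversal pair of ordinal patterns.

    ``forward`` is the lexicographically smaller member; ``reversed_`` is
    its image under time reversal.
    """

    forward: Pattern
    reversed_: Pattern

    def __post_init__(self) -> None:
        f = _validate_pattern(self.forward)
        r = _validate_pattern(self.reversed_)
        if reverse_pattern(f) != r:
            raise ValueError(f"{r} is not the time reversal of {f}")
        if r < f:
            raise ValueError("pair orientation must be lexicographic (forward < reversed)")

    @property
    def members(self) -> tuple[Pattern, Pattern]:
        return (self.forward, self.reversed_)


def pattern_pairs(D: int = DEFAULT_D) -> tuple[PatternPair, ...]:
    """All reversal pairs at embedding dimension ``D``, in canonical order.

    Partitions the ``D!`` ordinal patterns into ``D!/2`` disjoint pairs;
    for ``D = 3`` these are the three pairs
    ``(0,1,2)/(2,1,0)``, ``(0,2,1)/(2,0,1)`` and ``(1,0,2)/(1,2,0)``.
    """
    if int(D) != D or D < 2:
        raise ValueError(f"embedding dimension must be an integer >= 2, got {D}")
    D = int(D)
    pairs = []
    seen: set[Pattern] = set()
    for p in permutations(range(D)):
        if p in seen:
            continue
        q = reverse_pattern(p)
        seen.add(p)
        seen.add(q)
        lo, hi = (p, q) if p < q else (q, p)
        pairs.append(PatternPair(lo, hi))
    assert len(pairs) == factorial(D) // 2
    return tuple(sorted(pairs, key=lambda pr: pr.forward))


@dataclass
class PatternCounts:
    """Occurrence counts of ordinal patterns over a scanned series."""

    embedding_dimension: int
    embedding_delay: int
    counts: dict[Pattern, int]
    n_windows: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_windows:
            raise ValueError("counts must sum to n_windows")
        for p in self.counts:
            q = _validate_pattern(p)
            if len(q) != self.embedding_dimension:
                raise ValueError(f"pattern {p} does not match D={self.embedding_dimension}")

    def get(self, pattern: Sequence[int]) -> int:
        return self.counts.get(tuple(int(r) for r in pattern), 0)


# -- vectorized scanning ------------------------------------------------------


def _code_radix(D: int) -> np.ndarray:
    return D ** np.arange(D - 1, -1, -1)


def pattern_code(p: Sequence[int]) -> int:
    """Mixed-radix integer code of a pattern (base-``D`` digits)."""
    p = _validate_pattern(p)
    return int(np.dot(p, _code_radix(len(p))))


def _decode(code: int, D: int) -> Pattern:
    digits = []
    for _ in range(D):
        digits.append(code % D)
        code //= D
    return tuple(reversed(digits))


def min_series_length(D: int, tau: int) -> int:
    """Shortest series that admits at least one ordinal window."""
    return (D - 1) * tau + 1


def _prepare_series(
    series: Sequence[float],
    D: int,
    tau: int,
    tie_rule: str,
    rng: np.random.Generator | int | None,
) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if int(D) != D or D < 2:
        raise ValueError(f"embedding dimension must be an integer >= 2, got {D}")
    if int(tau) != tau or tau < 1:
        raise ValueError(f"embedding delay must be a positive integer, got {tau}")
    nmin = min_series_length(D, tau)
    if x.size < nmin:
        raise ValueError(
            f"series of length {x.size} too short for D={D}, tau={tau}: "
            f"at least {nmin} samples are required"
        )
    if tie_rule == "jitter":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sd = float(np.std(x))
        scale = JITTER_SCALE * (sd if sd > 0 else 1.0)
        x = x + gen.uniform(-scale, scale, size=x.size)
    elif tie_rule != "stable":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return x


def pattern_code_sequence(
    series: Sequence[float],
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    stride: int = 1,
    tie_rule: str = "stable",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Integer pattern code of every scanned window, in scan order.

    The workhorse behind :func:`count_patterns` and the multiscale
    prefix-sum machinery: windows ``x[s], x[s+tau], ..., x[s+(D-1)tau]``
    for ``s = 0, stride, 2*stride, ...`` are encoded in one vectorized
    stable argsort.
    """
    x = _prepare_series(series, D, tau, tie_rule, rng)
    if int(stride) != stride or stride < 1:
        raise ValueError(f"stride must be a positive integer, got {stride}")
    span = (D - 1) * tau + 1
    windows = sliding_window_view(x, span)[::stride, ::tau]
    perms = np.argsort(windows, axis=1, kind="stable")
    return perms @ _code_radix(D)


def count_patterns(
    series: Sequence[float],
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    stride: int = 1,
    tie_rule: str = "stable",
    rng: np.random.Generator | int | None = None,
) -> PatternCounts:
    """Count the ordinal patterns of all scanned windows of a series.

    With ``stride=1`` (maximal overlap) a series of length ``N`` yields
    ``N - (D-1)*tau`` windows.  Ties are resolved by the stable rule
    (ascending time index) or, with ``tie_rule="jitter"``, by adding seeded
    uniform noise at ``1e-9`` of the signal standard deviation before
    encoding.
    """
    codes = pattern_code_sequence(series, D, tau, stride, tie_rule, rng)
    binc = np.bincount(codes, minlength=D**D)
    counts = {_decode(c, D): int(n) for c, n in enumerate(binc) if n > 0}
    return PatternCounts(
        embedding_dimension=int(D),
        embedding_delay=int(tau),
        counts=counts,
        n_windows=int(codes.size),
    )


def pair_counts(pc: PatternCounts) -> dict[PatternPair, tuple[int, int]]:
    """Occurrences of each reversal pair as ``(forward, reversed)`` counts."""
    return {
        pair: (pc.get(pair.forward), pc.get(pair.reversed_))
        for pair in pattern_pairs(pc.embedding_dimension)
    }


def has_tied_neighbours(series: Sequence[float], tau: int = DEFAULT_TAU) -> bool:
    """True if any two samples ``tau`` apart are exactly equal.

    Quantized or constant signals produce tied windows whose stable-rule
    patterns are an artifact of the tie-break, not of the dynamics; callers
    use this to flag degenerate inputs.
    """
    x = np.asarray(series, dtype=float)
    return bool(np.any(x[tau:] == x[:-tau]))
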