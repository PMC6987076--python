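"""Per-series time-irreversibility tests from ordinal pattern-pair counts.

A stationary reversible series must show, for every reversal pair of
ordinal patterns, statistically indistinguishable occurrence counts of the
two members.  Each pair is therefore tested with an exact two-sided binomial
test of the pair-frequency statistic

    p = n_forward / (n_forward + n_reversed)

against the null proportion 0.5; the series is declared irreversible when
any pair rejects (optionally with a Bonferroni correction over the pairs).
The analytic test treats pattern occurrences as exchangeable, which makes
it equivalent to testing against randomly shuffled series; an empirical
surrogate null (random shuffles or IAAFT surrogates, which in addition
preserve the linear autocorrelation) is provided for the same decision,
and the two nulls together classify the *strength* of the irreversibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .ordinal import (
    DEFAULT_D,
    DEFAULT_TAU,
    PatternPair,
    count_patterns,
    has_tied_neighbours,
    pair_counts,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01

Correction = Literal["none", "bonferroni"]
Strength = Literal["reversible", "weak", "strong"]


def asymmetry_statistic(count_forward: int, count_reversed: int) -> float:
    """Pair-frequency statistic ``n_fwd / (n_fwd + n_rev)``.

    Equals 0.5 in expectation for a reversible series.  Undefined when the
    pair never occurs; callers skip such pairs.
    """
    if count_forward < 0 or count_reversed < 0:
        raise ValueError("pattern counts must be non-negative")
    total = count_forward + count_reversed
    if total == 0:
        raise ValueError("pair never occurred: statistic undefined")
    return count_forward / total


def exact_binomial_pvalue(k: int, n: int) -> float:
    """Exact two-sided binomial p-value of ``k`` successes out of ``n`` at p0=0.5.

    Two-sided in the minimum-likelihood sense (sum of the probabilities of
    all outcomes no more likely than ``k``); for the symmetric null this
    coincides with doubling the smaller tail, capped at 1.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if int(k) != k or not 0 <= k <= n:
        raise ValueError(f"k must be an integer in [0, {n}], got {k}")
    return float(binomial_pvalue_half(np.asarray(k), np.asarray(n)))


def binomial_pvalue_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p-value at null proportion 0.5.

    By symmetry of Binomial(n, 1/2), the minimum-likelihood two-sided
    p-value equals ``min(1, 2 * CDF(min(k, n - k)))``.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    m = np.minimum(k, n - k)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(m, n, 0.5))


_CRIT_CACHE: dict[tuple[int, float], int] = {}


def _critical_fold(nv: int, alpha: float) -> int:
    """Largest folded count m with ``2 * CDF(m; nv, 0.5) < alpha`` (-1 if none)."""
    key = (nv, alpha)
    crit = _CRIT_CACHE.get(key)
    if crit is None:
        guess = int(stats.binom.ppf(alpha / 2.0, nv, 0.5))
        crit = -1
        for c in range(max(guess - 2, -1), min(guess + 3, int(nv // 2) + 1)):
            if c >= 0 and 2.0 * stats.binom.cdf(c, nv, 0.5) < alpha:
                crit = c
        _CRIT_CACHE[key] = crit
    return crit


def binomial_rejects_half(k: np.ndarray, n: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rejection decision ``pvalue < alpha`` without forming p-values.

    Uses cached per-``n`` critical values of the folded tail count
    ``min(k, n-k)``: reject iff ``2 * CDF(min(k, n-k)) < alpha``.  Exactly
    equivalent to thresholding :func:`binomial_pvalue_half`, but O(#unique
    n) calls into the binomial CDF — the workhorse of the multiscale scan.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    m = np.minimum(k, n - k)
    out = np.zeros(np.broadcast(k, n).shape, dtype=bool)
    for nv in np.unique(n):
        if nv < 1:
            continue
        sel = n == nv
        out[sel] = m[sel] <= _critical_fold(int(nv), alpha)
    return out


@dataclass
class PairTestResult:
    """Binomial test of one reversal pair's count asymmetry."""

    pair: PatternPair
    count_forward: int
    count_reversed: int
    statistic_p: float | None
    p_value: float | None
    reject: bool

    @property
    def skipped(self) -> bool:
        return self.p_value is None


@dataclass
class IrreversibilityResult:
    """Outcome of the per-series irreversibility test."""

    per_pair: list[PairTestResult]
    irreversible: bool
    alpha: float
    correction: Correction
    degenerate: bool

    @property
    def min_pvalue(self) -> float:
        """Smallest per-pair p-value (1.0 if every pair was skipped)."""
        ps = [r.p_value for r in self.per_pair if r.p_value is not None]
        return min(ps) if ps else 1.0


def test_series(
    series: Sequence[float],
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    alpha: float = DEFAULT_ALPHA,
    correction: Correction = "none",
    tie_rule: str = "stable",
    rng: np.random.Generator | int | None = None,
) -> IrreversibilityResult:
    """Test a single series for time irreversibility.

    Counts ordinal patterns with unit stride, then for every reversal pair
    runs the exact two-sided binomial test on
    ``(n_forward, n_forward + n_reversed)``.  The series is irreversible
    when any pair rejects at ``alpha`` (``correction="none"``) or at
    ``alpha / n_pairs`` (``correction="bonferroni"``).  Pairs that never
    occur are skipped (no evidence either way).

    A ``degenerate`` flag marks series whose single observed pattern is an
    artifact of tie-breaking (constant or otherwise tied input); such
    results are computed but excluded from dataset-level aggregation.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    pc = count_patterns(series, D=D, tau=tau, stride=1, tie_rule=tie_rule, rng=rng)
    per_pair_counts = pair_counts(pc)
    level = alpha if correction == "none" else alpha / len(per_pair_counts)

    results: list[PairTestResult] = []
    any_reject = False
    for pair, (cf, cr) in per_pair_counts.items():
        total = cf + cr
        if total == 0:
            results.append(PairTestResult(pair, cf, cr, None, None, False))
            continue
        stat = asymmetry_statistic(cf, cr)
        pval = exact_binomial_pvalue(cf, total)
        reject = pval < level
        any_reject = any_reject or reject
        results.append(PairTestResult(pair, cf, cr, stat, pval, reject))

    degenerate = len(pc.counts) == 1 and (
        tie_rule == "stable" and has_tied_neighbours(series, tau)
    )
    if degenerate:
        logger.warning(
            "degenerate series: single pattern %s produced by tied values",
            next(iter(pc.counts)),
        )
    return IrreversibilityResult(
        per_pair=results,
        irreversible=any_reject,
        alpha=alpha,
        correction=correction,
        degenerate=degenerate,
    )


def is_degenerate(series: Sequence[float], tau: int = DEFAULT_TAU) -> bool:
    """Cheap pre-check used by aggregation: constant series are degenerate."""
    x = np.asarray(series, dtype=float)
    return bool(x.size == 0 or np.ptp(x) == 0)


@dataclass
class SurrogateTestResult:
    """Empirical test of the observed statistic against a surrogate null."""

    observed_statistic: float
    surrogate_statistics: np.ndarray
    empirical_p: float
    n_surrogates: int
    seed: int | None
    method: str
    degenerate: bool


def surrogate_null_test(
    series: Sequence[float],
    M: int = 99,
    method: Literal["iaaft", "shuffle"] = "iaaft",
    statistic: Literal["min_pair_pvalue"] = "min_pair_pvalue",
    seed: int | None = None,
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    alpha: float = DEFAULT_ALPHA,
) -> SurrogateTestResult:
    """Empirical irreversibility test against a surrogate ensemble.

    The observed statistic is the minimum per-pair binomial p-value
    (mirroring the any-pair decision rule); it is recomputed on ``M``
    surrogates — random shuffles (plain exchangeability null, agreeing in
    distribution with the analytic binomial test) or IAAFT surrogates
    (which additionally preserve the linear autocorrelation).  The
    empirical p-value uses the rank-with-offset formula
    ``(1 + #{surrogate <= observed}) / (M + 1)``.
    """
    if M < 19:
        raise ValueError(f"need at least 19 surrogates for alpha <= 0.05, got {M}")
    if statistic != "min_pair_pvalue":
        raise ValueError(f"unknown statistic {statistic!r}")
    if method not in ("iaaft", "shuffle"):
        raise ValueError(f"unknown surrogate method {method!r}")
    x = np.asarray(series, dtype=float)
    observed = test_series(x, D=D, tau=tau, alpha=alpha)
    rng = np.random.default_rng(seed)

    if method == "iaaft":
        from .surrogates import iaaft  # local import: avoids a module cycle

    surr_stats = np.empty(M)
    for i in range(M):
        if method == "shuffle":
            s = rng.permutation(x)
        else:
            s = iaaft(x, rng=rng)
        surr_stats[i] = test_series(s, D=D, tau=tau, alpha=alpha).min_pvalue

    obs = observed.min_pvalue
    emp_p = (1 + int(np.sum(surr_stats <= obs))) / (M + 1)
    return SurrogateTestResult(
        observed_statistic=obs,
        surrogate_statistics=surr_stats,
        empirical_p=emp_p,
        n_surrogates=M,
        seed=seed,
        method=method,
        degenerate=observed.degenerate,
    )


def classify_strength(shuffle_significant: bool, surrogate_significant: bool) -> Strength:
    """Classify irreversibility strength from the two null models.

    Not significant against shuffles: ``reversible``.  Significant against
    shuffles but not against IAAFT surrogates: ``weak`` — the asymmetry is
    attributable to the linear autocorrelation structure, which IAAFT
    preserves.  Significant against both: ``strong`` — linear
    autocorrelation is excluded as the cause.
    """
    if not shuffle_significant:
        return "reversible"
    return "strong" if surrogate_significant else "weak"
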