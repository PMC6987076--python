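"""Multiscale irreversibility: window scans, cohort curves, topographies.

The per-series binomial test says nothing about the time scale at which
irreversibility appears and is confounded by series length.  The scaling
analysis fixes both: for a window length ``n`` (the irreversibility scale),
all overlapping length-``n`` sub-windows of a series are tested, and the
series counts as irreversible *at scale n* when at least 90% of its
sub-windows reject at alpha = 0.01.  Aggregating the per-(channel x trial)
decisions over a cohort gives the fraction of irreversible units as a
function of ``n`` (a :class:`ScaleCurve`); two cohorts are compared by
reading both curves at matched window lengths (a :class:`ComparisonCurve`),
and per-channel averages over all scales give scalp topographies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ordinal import DEFAULT_D, DEFAULT_TAU, min_series_length, pattern_code, pattern_code_sequence, pattern_pairs
from .irrtest import DEFAULT_ALPHA, Correction, binomial_rejects_half, is_degenerate

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.90
DEFAULT_X_STEP = 0.01

#: Floor applied before taking log10 of equality-test p-values.
_P_FLOOR = 1e-300


# -- per-series window scan ---------------------------------------------------


def _pair_cumsums(
    series: np.ndarray,
    D: int,
    tau: int,
    tie_rule: str,
    rng,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cumulative per-pair counts of forward/reversed pattern codes.

    Returns arrays ``F, R`` of shape ``(n_pairs, W + 1)`` with
    ``F[j, b] - F[j, a]`` the number of windows starting in ``[a, b)`` whose
    pattern is pair ``j``'s forward member, plus the number of windows W.
    """
    codes = pattern_code_sequence(series, D=D, tau=tau, stride=1, tie_rule=tie_rule, rng=rng)
    pairs = pattern_pairs(D)
    W = codes.size
    F = np.zeros((len(pairs), W + 1), dtype=np.int64)
    R = np.zeros_like(F)
    for j, pair in enumerate(pairs):
        np.cumsum(codes == pattern_code(pair.forward), out=F[j, 1:])
        np.cumsum(codes == pattern_code(pair.reversed_), out=R[j, 1:])
    return F, R, W


def window_fraction(
    series: Sequence[float],
    n: int,
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    alpha: float = DEFAULT_ALPHA,
    sub_stride: int = 1,
    correction: Correction = "none",
    tie_rule: str = "stable",
    rng=None,
) -> float:
    """Fraction of length-``n`` sub-windows that test irreversible.

    Every sub-window ``x[a : a+n]`` (``a = 0, sub_stride, ...``) is tested
    exactly as :func:`ordirr.irrtest.test_series` would, via cumulative
    pattern-pair counts and per-``n`` binomial critical values, so the scan
    is linear in the series length rather than quadratic.
    """
    x = np.asarray(series, dtype=float)
    N = x.size
    span = min_series_length(D, tau)
    if int(n) != n or n < span:
        raise ValueError(f"window length n={n} too small: need at least {span} samples")
    if n > N:
        raise ValueError(f"window length n={n} exceeds series length {N}")
    if int(sub_stride) != sub_stride or sub_stride < 1:
        raise ValueError(f"sub_stride must be a positive integer, got {sub_stride}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")

    F, R, W = _pair_cumsums(x, D, tau, tie_rule, rng)
    n_pairs = F.shape[0]
    level = alpha if correction == "none" else alpha / n_pairs
    starts = np.arange(0, N - n + 1, sub_stride)
    width = n - (span - 1)  # pattern windows fully inside a length-n sub-window
    kf = F[:, starts + width] - F[:, starts]  # (n_pairs, n_subwindows)
    kr = R[:, starts + width] - R[:, starts]
    tot = kf + kr
    reject = np.zeros(kf.shape, dtype=bool)
    occupied = tot > 0
    if np.any(occupied):
        reject[occupied] = binomial_rejects_half(kf[occupied], tot[occupied], level)
    return float(np.mean(np.any(reject, axis=0)))


def is_irreversible_at_scale(
    series: Sequence[float],
    n: int,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    **kwargs,
) -> bool:
    """Series-level decision at scale ``n``: sub-window fraction >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return window_fraction(series, n, alpha=alpha, **kwargs) >= threshold


# -- cohort aggregation -------------------------------------------------------


@dataclass
class ScaleCurve:
    """Fraction of irreversible (channel x trial) units per window length."""

    window_lengths: list[int]
    fractions: list[float]
    n_units: int
    label: str = ""
    #: per-scale numerator (units irreversible) and denominator (units long enough)
    counts: list[int] = field(default_factory=list)
    denominators: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.window_lengths) != len(self.fractions):
            raise ValueError("window_lengths and fractions must have equal length")
        if any(not 0 <= f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if list(self.window_lengths) != sorted(self.window_lengths):
            raise ValueError("window_lengths must be increasing")
        if not self.counts:
            self.counts = [round(f * self.n_units) for f in self.fractions]
        if not self.denominators:
            self.denominators = [self.n_units] * len(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_length": self.window_lengths,
                "fraction_irreversible": self.fractions,
                "n_irreversible": self.counts,
                "n_units": self.denominators,
                "label": self.label,
            }
        )


def default_n_grid(
    max_length: int,
    sampling_rate: float | None = None,
    n_points: int = 25,
    min_length: int = 50,
    max_seconds: float = 100.0,
) -> list[int]:
    """Log-spaced window-length grid from ``min_length`` samples up to the
    shorter of the series and ``max_seconds`` of signal."""
    hi = max_length if sampling_rate is None else min(max_length, int(max_seconds * sampling_rate))
    if hi < min_length:
        raise ValueError(f"series too short for the scale grid (max usable length {hi})")
    grid = np.unique(np.round(np.geomspace(min_length, hi, n_points)).astype(int))
    return [int(g) for g in grid]


def _iter_units(recordings: Iterable, selector: Callable | None = None):
    """Yield (recording, channel label, 1-D series) units from a cohort."""
    for rec in recordings:
        if selector is not None and not selector(rec):
            continue
        for label, row in zip(rec.channel_labels, rec.data):
            yield rec, label, row


def make_selector(group: str | None = None, condition: str | None = None) -> Callable:
    def _sel(rec) -> bool:
        return (group is None or rec.group == group) and (
            condition is None or rec.condition == condition
        )

    return _sel


def dataset_scale_curve(
    recordings: Sequence,
    n_grid: Sequence[int],
    selector: Callable | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    sub_stride: int = 1,
    label: str = "",
) -> ScaleCurve:
    """Cohort-level fraction of irreversible units at each window length.

    A unit is one channel of one recording.  Degenerate (constant) units
    are excluded with a warning; units shorter than a given ``n`` are
    excluded from that scale's denominator rather than padded, so short
    recordings never masquerade as reversible at long scales.
    """
    n_grid = sorted(int(n) for n in n_grid)
    units: list[np.ndarray] = []
    n_degenerate = 0
    for rec, chan, series in _iter_units(recordings, selector):
        if is_degenerate(series):
            n_degenerate += 1
            logger.warning("excluding degenerate unit %s/%s", rec.subject_id, chan)
            continue
        units.append(np.asarray(series, dtype=float))
    if not units:
        raise ValueError(
            "no usable units in selection"
            + (f" ({n_degenerate} degenerate units excluded)" if n_degenerate else "")
        )

    lengths, fractions, counts, denoms = [], [], [], []
    for n in n_grid:
        eligible = [u for u in units if u.size >= n]
        if not eligible:
            logger.warning("no unit long enough for scale n=%d; scale dropped", n)
            continue
        k = sum(
            is_irreversible_at_scale(
                u, n, threshold=threshold, alpha=alpha, D=D, tau=tau, sub_stride=sub_stride
            )
            for u in eligible
        )
        if len(eligible) < len(units):
            logger.info("scale n=%d: %d/%d units long enough", n, len(eligible), len(units))
        lengths.append(n)
        counts.append(int(k))
        denoms.append(len(eligible))
        fractions.append(k / len(eligible))
        logger.info("scale n=%d: fraction %.3f (%d/%d)", n, k / len(eligible), k, len(eligible))
    if not lengths:
        raise ValueError("every scale in n_grid exceeded all unit lengths")
    return ScaleCurve(
        window_lengths=lengths,
        fractions=fractions,
        n_units=len(units),
        label=label,
        counts=counts,
        denominators=denoms,
    )


# -- cohort comparison --------------------------------------------------------


@dataclass
class ComparisonCurve:
    """Fraction-vs-fraction comparison of two cohorts at matched scales.

    For each target ``x`` on a grid, the reference cohort determines the
    minimum window length at which its fraction reaches ``x``; ``y`` is the
    comparison cohort's fraction at that same window length.  Points above
    the diagonal mean the comparison cohort is more irreversible at equal
    scale.  Each point carries the log10 p-value of an exact binomial test
    of the comparison count against the reference fraction.
    """

    x_grid: list[float]
    y_values: list[float]
    window_lengths_used: list[int]
    log10_pvalues: list[float]
    labels: tuple[str, str] = ("reference", "comparison")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_fraction_ref": self.x_grid,
                "y_fraction_cmp": self.y_values,
                "window_length": self.window_lengths_used,
                "log10_pvalue": self.log10_pvalues,
                "reference": self.labels[0],
                "comparison": self.labels[1],
            }
        )


def comparison_curve(
    curve_ref: ScaleCurve,
    curve_cmp: ScaleCurve,
    x_step: float = DEFAULT_X_STEP,
) -> ComparisonCurve:
    """Build the fraction-vs-fraction comparison of two scale curves.

    Both curves must be computed over the same window-length grid.  Grid
    points ``x`` that the reference curve never attains are omitted.  The
    equality test at each point is the exact two-sided binomial test of the
    comparison cohort's irreversible-unit count against a null proportion
    equal to the reference cohort's fraction at the matched window length.
    """
    if list(curve_ref.window_lengths) != list(curve_cmp.window_lengths):
        raise ValueError("comparison requires scale curves over the same window-length grid")
    if not 0 < x_step <= 1:
        raise ValueError(f"x_step must be in (0, 1], got {x_step}")
    fr = np.asarray(curve_ref.fractions)
    xs, ys, ns, logps = [], [], [], []
    for x in np.arange(0.0, 1.0 + x_step / 2, x_step):
        attained = np.nonzero(fr >= x)[0]
        if attained.size == 0:
            continue
        i = int(attained[0])  # minimum window length reaching x
        f_ref = float(fr[i])
        k = int(curve_cmp.counts[i])
        m = int(curve_cmp.denominators[i])
        pval = float(stats.binomtest(k, m, p=f_ref).pvalue)
        xs.append(round(float(x), 10))
        ys.append(float(curve_cmp.fractions[i]))
        ns.append(int(curve_ref.window_lengths[i]))
        logps.append(float(np.log10(max(pval, _P_FLOOR))))
    return ComparisonCurve(
        x_grid=xs,
        y_values=ys,
        window_lengths_used=ns,
        log10_pvalues=logps,
        labels=(curve_ref.label or "reference", curve_cmp.label or "comparison"),
    )


# -- per-channel topography ---------------------------------------------------


@dataclass
class TopographyTable:
    """Per-channel mean irreversibility over all window lengths."""

    channel_labels: list[str]
    mean_fraction: list[float]
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.channel_labels) != len(self.mean_fraction):
            raise ValueError("one mean fraction per channel required")
        if any(not 0 <= f <= 1 for f in self.mean_fraction):
            raise ValueError("mean fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel_labels,
                "mean_fraction": self.mean_fraction,
                "group": self.group,
            }
        )


def channel_topography(
    recordings: Sequence,
    n_grid: Sequence[int],
    selector: Callable | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    sub_stride: int = 1,
    group: str = "",
) -> TopographyTable:
    """Average per-channel irreversibility across the whole scale grid.

    For each montage channel, the fraction of trials irreversible at each
    window length is averaged over all window lengths — a summary of the
    channel's behaviour at every probed time scale.  All selected
    recordings must share the same montage labels.
    """
    recs = [r for r in recordings if selector is None or selector(r)]
    if not recs:
        raise ValueError("empty recording selection")
    labels = list(recs[0].channel_labels)
    for r in recs[1:]:
        if list(r.channel_labels) != labels:
            offending = sorted(set(r.channel_labels) ^ set(labels))
            raise ValueError(f"montage mismatch across recordings: {offending}")
    n_grid = sorted(int(n) for n in n_grid)

    means = []
    for ci, chan in enumerate(labels):
        units = [
            np.asarray(r.data[ci], dtype=float)
            for r in recs
            if not is_degenerate(r.data[ci])
        ]
        if not units:
            raise ValueError(f"channel {chan}: all trials degenerate")
        per_scale = []
        for n in n_grid:
            eligible = [u for u in units if u.size >= n]
            if not eligible:
                continue
            k = sum(
                is_irreversible_at_scale(
                    u, n, threshold=threshold, alpha=alpha, D=D, tau=tau, sub_stride=sub_stride
                )
                for u in eligible
            )
            per_scale.append(k / len(eligible))
        if not per_scale:
            raise ValueError(f"channel {chan}: no scale in n_grid is computable")
        means.append(float(np.mean(per_scale)))
        logger.info("channel %s: mean fraction %.3f", chan, means[-1])
    return TopographyTable(channel_labels=labels, mean_fraction=means, group=group)


def topography_difference(patients: TopographyTable, controls: TopographyTable) -> pd.DataFrame:
    """Patients-minus-controls per-channel difference map.

    Positive values indicate higher irreversibility in patients.
    """
    if list(patients.channel_labels) != list(controls.channel_labels):
        offending = sorted(set(patients.channel_labels) ^ set(controls.channel_labels))
        raise ValueError(f"montage mismatch between groups: {offending}")
    diff = np.asarray(patients.mean_fraction) - np.asarray(controls.mean_fraction)
    return pd.DataFrame(
        {
            "channel": patients.channel_labels,
            "patients": patients.mean_fraction,
            "controls": controls.mean_fraction,
            "difference": diff,
        }
    )
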