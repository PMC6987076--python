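"""IAAFT surrogate series and surrogate-ensemble irreversibility curves.

An IAAFT (Iterative Amplitude Adjusted Fourier Transform) surrogate keeps
a signal's amplitude distribution *exactly* (the surrogate is a
permutation of the original values) and its linear autocorrelation —
equivalently its power spectrum — approximately.  It is the canonical null
for "a static transform of a linear Gaussian process": irreversibility
that survives IAAFT surrogation can be blamed on linear autocorrelation
(weak), irreversibility that is destroyed by it cannot (strong).

The iteration alternates two projections starting from a random shuffle:
impose the original Fourier amplitude spectrum (keeping phases), then
restore the original amplitude multiset by rank remapping, until the
relative spectrum discrepancy converges.  The amplitude step runs last, so
the value multiset is preserved bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import multiscale
from .irrtest import DEFAULT_ALPHA
from .ordinal import DEFAULT_D, DEFAULT_TAU

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 100
DEFAULT_SPECTRUM_TOL = 1e-4
DEFAULT_M_ENSEMBLES = 20


def _spectrum_error(amp: np.ndarray, target_amp: np.ndarray) -> float:
    denom = float(np.linalg.norm(target_amp))
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(amp - target_amp) / denom)


def iaaft(
    series: Sequence[float],
    max_iter: int = DEFAULT_MAX_ITER,
    spectrum_tol: float = DEFAULT_SPECTRUM_TOL,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_info: bool = False,
):
    """One IAAFT surrogate of ``series``.

    Parameters
    ----------
    series
        Finite 1-D signal, length >= 8.  Constant signals are rejected
        (no phase content to randomize).
    max_iter, spectrum_tol
        Stop after ``max_iter`` iterations or once the relative L2
        discrepancy between the surrogate's and the original's Fourier
        amplitudes drops to ``spectrum_tol``.
    seed, rng
        Seed a fresh generator, or pass one (``rng`` wins); the start is a
        random permutation of the values.
    return_info
        Also return ``(n_iterations_used, converged)``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no phase content to surrogate")
    gen = rng if rng is not None else np.random.default_rng(seed)

    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = gen.permutation(x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # spectrum step: impose original amplitudes, keep current phases
        spec = np.fft.rfft(s)
        phases = np.exp(1j * np.angle(spec))
        s = np.fft.irfft(target_amp * phases, n=x.size)
        # amplitude step: restore the exact value multiset by rank
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        err = _spectrum_error(np.abs(np.fft.rfft(s)), target_amp)
        if err <= spectrum_tol:
            converged = True
            break
    if not converged:
        logger.debug("IAAFT stopped at max_iter=%d (spectrum error %.2e)", max_iter, err)
    if return_info:
        return s, it, converged
    return s


@dataclass
class SurrogateEnsemble:
    """A set of IAAFT surrogates of one series."""

    original_id: str
    surrogates: list[np.ndarray]
    n_iterations_used: list[int]
    converged: list[bool]
    seed: int | None


def iaaft_ensemble(
    series: Sequence[float],
    M: int,
    original_id: str = "",
    seed: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    spectrum_tol: float = DEFAULT_SPECTRUM_TOL,
) -> SurrogateEnsemble:
    """``M`` independent IAAFT surrogates driven by one master seed."""
    streams = np.random.SeedSequence(seed).spawn(M)
    surrogates, iters, convs = [], [], []
    for ss in streams:
        s, it, conv = iaaft(
            series,
            max_iter=max_iter,
            spectrum_tol=spectrum_tol,
            rng=np.random.default_rng(ss),
            return_info=True,
        )
        surrogates.append(s)
        iters.append(it)
        convs.append(conv)
    return SurrogateEnsemble(original_id, surrogates, iters, convs, seed)


def surrogate_scale_curve(
    recordings: Sequence,
    M: int = DEFAULT_M_ENSEMBLES,
    n_grid: Sequence[int] | None = None,
    seed: int | None = None,
    selector=None,
    threshold: float = multiscale.DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    D: int = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    sub_stride: int = 1,
    label: str = "surrogate",
    max_iter: int = DEFAULT_MAX_ITER,
    spectrum_tol: float = DEFAULT_SPECTRUM_TOL,
) -> tuple[multiscale.ScaleCurve, np.ndarray]:
    """Mean and dispersion of the cohort scale curve under IAAFT surrogation.

    Every unit's series is replaced by a fresh IAAFT surrogate and the
    cohort scale curve is recomputed; over ``M`` such ensemble replicates
    this yields the mean surrogate curve and the per-scale standard
    deviation of the surrogate irreversibility fraction.  A drop of the
    surrogate curve below the original flags strong irreversibility.

    Each (replicate, unit) pair gets its own substream of the master seed,
    so results are reproducible yet surrogates are independent.
    """
    if M < 2:
        raise ValueError("need at least 2 surrogate ensembles for a dispersion estimate")
    if n_grid is None:
        raise ValueError("n_grid is required")
    recs = [r for r in recordings if selector is None or selector(r)]
    if not recs:
        raise ValueError("empty recording selection")
    master = np.random.SeedSequence(seed)
    rep_curves: list[multiscale.ScaleCurve] = []
    lengths_ref: list[int] | None = None
    for rep, rep_ss in enumerate(master.spawn(M)):
        unit_streams = iter(rep_ss.spawn(sum(r.data.shape[0] for r in recs)))
        surr_recs = []
        for r in recs:
            surr_data = np.vstack(
                [
                    iaaft(
                        row,
                        max_iter=max_iter,
                        spectrum_tol=spectrum_tol,
                        rng=np.random.default_rng(next(unit_streams)),
                    )
                    for row in r.data
                ]
            )
            surr_recs.append(r.with_data(surr_data))
        curve = multiscale.dataset_scale_curve(
            surr_recs,
            n_grid,
            threshold=threshold,
            alpha=alpha,
            D=D,
            tau=tau,
            sub_stride=sub_stride,
            label=f"{label}[{rep}]",
        )
        if lengths_ref is None:
            lengths_ref = curve.window_lengths
        elif curve.window_lengths != lengths_ref:
            raise RuntimeError("surrogate replicates disagree on usable scales")
        rep_curves.append(curve)
        logger.info("surrogate replicate %d/%d done", rep + 1, M)

    fracs = np.array([c.fractions for c in rep_curves])  # (M, n_scales)
    mean_curve = multiscale.ScaleCurve(
        window_lengths=list(lengths_ref),
        fractions=[float(f) for f in fracs.mean(axis=0)],
        n_units=rep_curves[0].n_units,
        label=label,
    )
    return mean_curve, fracs.std(axis=0, ddof=0)
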