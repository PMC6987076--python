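"""Frequency-band preprocessing: zero-phase low-pass + decimation, spectral QC.

Band-limited variants of the analysis require a low-pass filter, and the
choice of filter is not innocuous here: a causal (IIR or one-sided FIR)
filter has an asymmetric impulse response and *injects temporal asymmetry
into the very quantity under study*.  All filtering in this module is
therefore strictly zero-phase — a symmetric linear-phase FIR kernel
applied with reflect padding — so that filtering commutes with time
reversal except for edge effects, and reversible inputs stay reversible.

After low-passing at ``cutoff`` the signal is decimated to
``output_rate`` (default twice the cutoff): keeping the original sampling
rate after removing high frequencies would oversample the remaining slow
dynamics and bias the ordinal statistics toward spurious monotone runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Band presets: cutoff in Hz (None = broadband, no filtering).
BAND_PRESETS: dict[str, float | None] = {"broadband": None, "lp50": 50.0, "lp30": 30.0}


@dataclass
class FilterSpec:
    """Zero-phase FIR low-pass + decimation parameters."""

    cutoff: float
    output_rate: float | None = None  # default 2 * cutoff
    transition_hz: float | None = None  # default 0.25 * cutoff
    attenuation_db: float = 60.0

    def resolved_output_rate(self) -> float:
        return self.output_rate if self.output_rate is not None else 2.0 * self.cutoff

    def resolved_transition(self) -> float:
        return self.transition_hz if self.transition_hz is not None else 0.25 * self.cutoff


def _design_fir(spec: FilterSpec, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    width = spec.resolved_transition() / nyq
    numtaps, beta = sps.kaiserord(spec.attenuation_db, width)
    numtaps |= 1  # odd length -> exactly symmetric, integer group delay
    taps = sps.firwin(numtaps, spec.cutoff / nyq, window=("kaiser", beta))
    assert np.allclose(taps, taps[::-1])  # symmetric kernel, zero phase
    return taps


def zero_phase_lowpass(values: Sequence[float], rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase FIR low-pass at ``spec.cutoff`` without rate change.

    Reflect-pads by the kernel half-width, convolves with the symmetric
    kernel, and trims the padded margin, so the output has the input's
    length and no group delay.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if spec.cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below the Nyquist rate {rate / 2} Hz")
    taps = _design_fir(spec, rate)
    half = len(taps) // 2
    if x.size <= half:
        raise ValueError(f"signal too short for the filter kernel ({len(taps)} taps)")
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, taps, mode="valid")


def lowpass_decimate(
    values: Sequence[float],
    rate: float,
    spec: FilterSpec,
) -> tuple[np.ndarray, float]:
    """Zero-phase low-pass then resample to the spec's output rate.

    Returns ``(signal, output_rate)``.  Integer decimation factors are
    plain sample picking on the already band-limited signal; rational
    factors go through polyphase resampling with a symmetric (zero-phase)
    anti-alias kernel.
    """
    out_rate = spec.resolved_output_rate()
    if out_rate < 2.0 * spec.cutoff:
        raise ValueError(
            f"output rate {out_rate} Hz would alias the {spec.cutoff} Hz passband"
        )
    if out_rate > rate:
        raise ValueError("output rate cannot exceed the input rate")
    y = zero_phase_lowpass(values, rate, spec)
    if out_rate == rate:
        return y, rate
    ratio = rate / out_rate
    if abs(ratio - round(ratio)) < 1e-9:
        return y[:: int(round(ratio))], out_rate
    frac = math.gcd(int(round(out_rate * 1000)), int(round(rate * 1000)))
    up = int(round(out_rate * 1000)) // frac
    down = int(round(rate * 1000)) // frac
    logger.info("polyphase resampling %g -> %g Hz (up=%d, down=%d)", rate, out_rate, up, down)
    return sps.resample_poly(y, up, down), out_rate


def preprocess_recording(recording, band: str | FilterSpec):
    """Apply a band preset (or explicit :class:`FilterSpec`) to a recording."""
    if isinstance(band, str):
        if band not in BAND_PRESETS:
            raise ValueError(f"unknown band preset {band!r} (choose from {sorted(BAND_PRESETS)})")
        cutoff = BAND_PRESETS[band]
        if cutoff is None:
            return recording
        band = FilterSpec(cutoff=cutoff)
    rows = []
    for row in recording.data:
        y, out_rate = lowpass_decimate(row, recording.sampling_rate, band)
        rows.append(y)
    return recording.with_data(np.vstack(rows), sampling_rate=out_rate)


def welch_psd(
    values: Sequence[float],
    rate: float,
    segment_length: int = 1024,
    overlap: float = 0.5,
):
    """Averaged-periodogram (Welch) PSD estimate.

    Returns ``(frequencies, psd)`` with density normalization, so the PSD
    integrates to the signal variance (Parseval).  Used as QC on synthetic
    cohorts' spectra.
    """
    x = np.asarray(values, dtype=float)
    if segment_length > x.size:
        raise ValueError(
            f"segment_length {segment_length} exceeds signal length {x.size}"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    f, p = sps.welch(
        x - np.mean(x),
        fs=rate,
        nperseg=segment_length,
        noverlap=int(segment_length * overlap),
        detrend=False,
    )
    return f, p
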