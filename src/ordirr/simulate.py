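"""Synthetic benchmark signals and EEG-like multichannel cohorts.

Three generator families drive every test of the pipeline without any
external data:

* the fully chaotic logistic map ``x_{t+1} = r x_t (1 - x_t)`` with ``r=4``,
  observed through additive Gaussian noise ``y_t = x_t + sigma xi_t`` —
  a strongly time-irreversible reference whose asymmetry is progressively
  masked as the observation noise grows;
* stationary linear Gaussian AR(1) processes (optionally passed through a
  static monotone transform) — the canonical *reversible* null family;
* multichannel, multi-subject cohorts mixing a rescaled logistic component
  of weight ``w`` into an AR background per group and condition, with
  standard 10-20/10-10 montage labels and group/condition metadata, so
  that cohort-level contrasts (patients vs controls, eyes open vs closed)
  can be dialled in and recovered end to end.

The noise in the logistic model is applied at the *observation* stage:
with the printed noise amplitudes (sigma around 0.6-0.7, twice the map's
own standard deviation) noise inside the recursion would leave the map's
basin almost surely, whereas measurement noise on the bounded orbit keeps
the model well defined at any sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Recording

logger = logging.getLogger(__name__)

DEFAULT_BURN_IN = 1000

#: International 10-20 montage, the 19 classical scalp positions.
MONTAGE_10_20 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: 64-channel 10-10 montage (BCI2000-style layout).
MONTAGE_10_10_64 = [
    "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6",
    "Fp1", "Fpz", "Fp2", "Af7", "Af3", "Afz", "Af4", "Af8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Ft8", "T7", "T8", "T9", "T10", "Tp7", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8", "O1", "Oz", "O2", "Iz",
]


def montage_labels(n_channels: int) -> list[str]:
    """Channel labels for an ``n_channels``-electrode cap.

    Uses the classical 10-20 names up to 19 channels and the 64-channel
    10-10 layout beyond.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    if n_channels <= len(MONTAGE_10_20):
        return MONTAGE_10_20[:n_channels]
    if n_channels <= len(MONTAGE_10_10_64):
        return MONTAGE_10_10_64[:n_channels]
    raise ValueError(f"no montage with {n_channels} channels (max {len(MONTAGE_10_10_64)})")


# -- logistic map -------------------------------------------------------------


@dataclass
class LogisticSpec:
    """Parameters of the noisy logistic-map observation model."""

    length: int
    growth: float = 4.0
    noise: float = 0.0
    x0: float | None = None  # None: drawn uniformly in (0, 1) from the seed
    burn_in: int = DEFAULT_BURN_IN
    seed: int | None = None


def logistic_series(spec: LogisticSpec) -> np.ndarray:
    """Simulate the logistic map and observe it through Gaussian noise.

    The noiseless state ``x_{t+1} = r x_t (1 - x_t)`` is iterated from
    ``x0`` (burn-in discarded); the returned observations are
    ``y_t = x_t + noise * xi_t`` with iid standard-normal ``xi``.  State
    and observation noise use separate seed substreams, so the underlying
    orbit is identical for any noise level at a fixed seed.
    """
    if spec.length < 1:
        raise ValueError("length must be positive")
    if spec.noise < 0:
        raise ValueError("noise must be non-negative")
    if spec.burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    state_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    if spec.x0 is None:
        x = float(np.random.default_rng(state_ss).uniform(0.0, 1.0))
        while x in (0.0, 1.0):  # pragma: no cover - measure-zero guard
            x = float(np.random.default_rng(state_ss).uniform(0.0, 1.0))
    else:
        x = float(spec.x0)
        if not 0.0 < x < 1.0:
            raise ValueError(f"x0 must lie strictly inside (0, 1), got {x}")
    r = float(spec.growth)
    for _ in range(spec.burn_in):
        x = r * x * (1.0 - x)
    states = np.empty(spec.length)
    for t in range(spec.length):
        states[t] = x
        x = r * x * (1.0 - x)
    if spec.noise == 0:
        return states
    xi = np.random.default_rng(noise_ss).standard_normal(spec.length)
    return states + spec.noise * xi


# -- reversible null family ---------------------------------------------------


def gaussian_ar_series(
    N: int,
    phi: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    transform=None,
    burn_in: int = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Stationary zero-mean Gaussian AR(1) with unit innovation variance.

    ``phi = 0`` gives iid Gaussian noise.  An optional static monotone
    ``transform`` is applied pointwise; static transforms of linear
    Gaussian processes remain time-reversible, making this the package's
    null family.
    """
    if not abs(phi) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
    if N < 1:
        raise ValueError("N must be positive")
    gen = rng if rng is not None else np.random.default_rng(seed)
    eps = gen.standard_normal(N + burn_in)
    if phi == 0:
        x = eps[burn_in:]
    else:
        from scipy.signal import lfilter

        x = lfilter([1.0], [1.0, -phi], eps)[burn_in:]
    x = np.array(x, dtype=float)
    return transform(x) if transform is not None else x


# -- EEG-like cohorts ---------------------------------------------------------


@dataclass
class SyntheticCohortSpec:
    """Shape and dynamics of a two-group, two-condition synthetic cohort.

    Geometry defaults follow the smallest of the emulated clinical set-ups
    (19-channel 10-20 cap at 250 Hz) with 30 s of signal per recording —
    the lower end of the emulated recording lengths, enough for the full
    multiscale analysis while keeping cohorts cheap to regenerate.

    ``mixture_weights`` maps ``(group, condition)`` to the weight ``w`` of
    the (standardized) chaotic logistic component mixed into a reversible
    AR(1) background; ``w = 0`` yields a fully reversible cohort.  The
    defaults encode the qualitative contrasts the pipeline is meant to
    resolve: patients below controls, eyes open above eyes closed.
    """

    n_controls: int = 14
    n_patients: int = 14
    n_channels: int = 19
    sampling_rate: float = 250.0
    duration: float = 30.0
    conditions: tuple[str, ...] = ("eyes_open", "eyes_closed")
    mixture_weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("control", "eyes_open"): 0.6,
            ("control", "eyes_closed"): 0.5,
            ("patient", "eyes_open"): 0.4,
            ("patient", "eyes_closed"): 0.3,
        }
    )
    ar_phi: float = 0.95
    observation_noise: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0 or self.n_controls + self.n_patients == 0:
            raise ValueError("cohort must contain at least one subject")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        for c in self.conditions:
            if c not in ("eyes_open", "eyes_closed"):
                raise ValueError(f"unknown condition {c!r}")
        for (g, c), w in self.mixture_weights.items():
            if not 0 <= w <= 1:
                raise ValueError(f"mixture weight for {(g, c)} must lie in [0, 1], got {w}")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        montage_labels(self.n_channels)  # raises for unsupported counts

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / (sd if sd > 0 else 1.0)


def synthetic_dataset(spec: SyntheticCohortSpec) -> list[Recording]:
    """Generate a full synthetic cohort of :class:`~ordirr.io.Recording`.

    Every (subject, condition) pair yields one recording whose channels
    are independent realizations of

        ``w * z(logistic) + (1 - w) * z(AR(phi)) + noise * xi``

    with ``z`` denoting standardization to zero mean and unit variance, so
    ``w`` controls the relative power of the irreversible component.
    Identical spec and seed reproduce the dataset bit for bit.
    """
    N = spec.n_samples
    labels = montage_labels(spec.n_channels)
    subjects = [("control", f"c{i:03d}") for i in range(spec.n_controls)] + [
        ("patient", f"p{i:03d}") for i in range(spec.n_patients)
    ]
    master = np.random.SeedSequence(spec.seed)
    rec_streams = iter(master.spawn(len(subjects) * len(spec.conditions)))
    recordings = []
    for group, sid in subjects:
        for condition in spec.conditions:
            w = spec.mixture_weights.get((group, condition))
            if w is None:
                raise ValueError(f"no mixture weight for {(group, condition)}")
            chan_streams = next(rec_streams).spawn(spec.n_channels)
            data = np.empty((spec.n_channels, N))
            for ci, ss in enumerate(chan_streams):
                log_ss, ar_ss, obs_ss = ss.spawn(3)
                chaotic = _standardize(
                    logistic_series(
                        LogisticSpec(length=N, seed=int(log_ss.generate_state(1)[0] % 2**31))
                    )
                )
                background = _standardize(
                    gaussian_ar_series(N, phi=spec.ar_phi, rng=np.random.default_rng(ar_ss))
                )
                obs = np.random.default_rng(obs_ss).standard_normal(N)
                data[ci] = w * chaotic + (1 - w) * background + spec.observation_noise * obs
            recordings.append(
                Recording(
                    data=data,
                    channel_labels=list(labels),
                    sampling_rate=spec.sampling_rate,
                    subject_id=sid,
                    group=group,
                    condition=condition,
                )
            )
    logger.info(
        "generated %d recordings (%d channels x %d samples each)",
        len(recordings), spec.n_channels, N,
    )
    return recordings


#: Cohort geometries mirroring the four emulated clinical set-ups
#: (channels, sampling rate, nominal duration in seconds).
COHORT_PRESETS: dict[str, dict] = {
    "motor_imagery": dict(n_channels=64, sampling_rate=160.0, duration=60.0),
    "parkinsons": dict(n_channels=32, sampling_rate=500.0, duration=180.0),
    "epilepsy_scalp": dict(n_channels=22, sampling_rate=256.0, duration=30.0),
    "schizophrenia": dict(n_channels=19, sampling_rate=250.0, duration=900.0),
}
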