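"""Run configuration: every knob of a full analysis in one reproducible record."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Parameters controlling a complete irreversibility analysis.

    Defaults reproduce the standard protocol: ordinal patterns at
    embedding dimension 3 with unit delay, per-pair exact binomial tests
    at alpha = 0.01 with no multiplicity correction, a series counted as
    irreversible at a scale when at least 90% of its sub-windows reject,
    and a log-spaced scale grid from 50 samples up to 100 s of signal.
    """

    D: int = 3
    tau: int = 1
    alpha: float = 0.01
    threshold: float = 0.90
    correction: str = "none"  # "none" | "bonferroni"
    tie_rule: str = "stable"  # "stable" | "jitter"
    # scale grid
    n_grid_points: int = 25
    n_grid_min: int = 50
    n_grid_max_seconds: float = 100.0
    sub_stride: int = 1
    # comparison curves
    x_step: float = 0.01
    # preprocessing band preset
    band: str = "broadband"  # "broadband" | "lp50" | "lp30"
    # surrogate analysis
    surrogate_m: int = 20
    # unit filtering
    min_duration: float = 0.0  # seconds; generalizes the >= 30 s segment rule
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.threshold <= 1:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.tie_rule not in ("stable", "jitter"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        if self.D < 2 or self.tau < 1 or self.sub_stride < 1:
            raise ValueError("D >= 2, tau >= 1 and sub_stride >= 1 are required")
        if not 0 < self.x_step <= 1:
            raise ValueError(f"x_step must be in (0, 1], got {self.x_step}")
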