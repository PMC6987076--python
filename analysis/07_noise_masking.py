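#!/usr/bin/env python
"""Noise masking of chaotic irreversibility: the logistic-map benchmark.

Simulates the fully chaotic logistic map observed through additive
Gaussian noise at four amplitudes (sigma = 0.63, 0.66, 0.69, 0.72) and
measures the fraction of detected-irreversible realizations as a function
of the series length.  Expected: detection grows with length and is
ordered top-to-bottom by noise level — heavier observation noise pushes
the detectable scale outward without erasing the asymmetry.  Writes
results/noise_masking.csv.
"""

from pathlib import Path

import pandas as pd

from ordirr import io
from ordirr.irrtest import test_series
from ordirr.simulate import LogisticSpec, logistic_series

OUT = Path("results/noise_masking.csv")
SEED = 13
SIGMAS = (0.63, 0.66, 0.69, 0.72)
LENGTHS = (1000, 2500, 5000, 10000, 20000, 40000)
N_CHANNELS = 100


def main() -> None:
    rows = []
    for sigma_i, sigma in enumerate(SIGMAS):
        for n in LENGTHS:
            hits = sum(
                test_series(
                    logistic_series(
                        LogisticSpec(length=n, noise=sigma,
                                     seed=SEED + 10_000 * sigma_i + i)
                    )
                ).irreversible
                for i in range(N_CHANNELS)
            )
            rows.append(dict(sigma=sigma, window_length=n,
                             detection_fraction=hits / N_CHANNELS, n_series=N_CHANNELS))
        by_sigma = [r["detection_fraction"] for r in rows if r["sigma"] == sigma]
        print(f"sigma={sigma}: detection {by_sigma} over lengths {list(LENGTHS)}")
    io.write_table(pd.DataFrame(rows), OUT)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
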