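#!/usr/bin/env python
"""Condition and group comparison curves with binomial equality tests.

Builds two fraction-vs-fraction comparison curves from the synthetic
cohort: eyes-open vs eyes-closed within controls (expected above the
diagonal: more irreversible with eyes open) and patients vs controls
within eyes-closed (expected below: the patient mixture is weaker).  Each
point carries the log10 p-value of an exact binomial test of equality.
Writes results/comparison_conditions.csv and results/comparison_groups.csv.
"""

from pathlib import Path

from ordirr import io, multiscale

MANIFEST = Path("scratch/cohort/manifest.csv")

CONTRASTS = {
    "comparison_conditions.csv": (("control", "eyes_closed"), ("control", "eyes_open")),
    "comparison_groups.csv": (("control", "eyes_closed"), ("patient", "eyes_closed")),
}


def main() -> None:
    recs = io.load_cohort(MANIFEST)
    grid = multiscale.default_n_grid(
        max(r.n_samples for r in recs), recs[0].sampling_rate, n_points=12
    )
    for fname, (ref, cmp_) in CONTRASTS.items():
        curves = [
            multiscale.dataset_scale_curve(
                recs, grid, selector=multiscale.make_selector(*gc), label="/".join(gc)
            )
            for gc in (ref, cmp_)
        ]
        comp = multiscale.comparison_curve(curves[0], curves[1], x_step=0.05)
        io.write_table(comp.to_frame(), Path("results") / fname)
        above = sum(y > x for x, y in zip(comp.x_grid, comp.y_values))
        below = sum(y < x for x, y in zip(comp.x_grid, comp.y_values))
        print(f"{'/'.join(cmp_)} vs {'/'.join(ref)}: "
              f"{above} points above the diagonal, {below} below "
              f"(of {len(comp.x_grid)} attained); min log10 p = "
              f"{min(comp.log10_pvalues):.1f} -> results/{fname}")


if __name__ == "__main__":
    main()
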