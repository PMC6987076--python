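#!/usr/bin/env python
"""Generate the synthetic two-group, two-condition EEG-like cohort.

Writes one delimited recording per (subject, condition) plus a manifest to
scratch/cohort/ (regenerable at any time; everything downstream reads the
manifest).  The cohort encodes the contrasts the later analyses recover:
patients carry a weaker chaotic component than controls, and eyes-open
recordings a slightly stronger one than eyes-closed.
"""

from pathlib import Path

from ordirr import io
from ordirr.simulate import SyntheticCohortSpec, synthetic_dataset

OUT = Path("scratch/cohort")
SEED = 7


def main() -> None:
    spec = SyntheticCohortSpec(n_controls=6, n_patients=6, seed=SEED)
    recs = synthetic_dataset(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        fname = f"{rec.subject_id}_{rec.condition}.csv"
        io.write_delimited(rec, OUT / fname)
        rows.append(
            dict(file=fname, format="delimited", subject=rec.subject_id,
                 group=rec.group, condition=rec.condition,
                 sampling_rate=rec.sampling_rate)
        )
    io.write_manifest(rows, OUT / "manifest.csv")
    print(f"wrote {len(recs)} recordings "
          f"({spec.n_channels} ch x {spec.n_samples} samples at {spec.sampling_rate:g} Hz) "
          f"and manifest to {OUT}")
    print(f"groups: {spec.n_controls} controls / {spec.n_patients} patients; "
          f"conditions: {', '.join(spec.conditions)}; "
          f"mixture weights: {spec.mixture_weights}")


if __name__ == "__main__":
    main()
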