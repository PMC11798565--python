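#!/usr/bin/env python
"""Study design: sample size and quota allocation.

The survey targets a single population proportion with a 95% CI, a 1%
margin of error and an assumed 2% prevalence, giving n = ceil(752.95) = 753
(rounded to a 750-respondent recruitment target).  The 750 respondents are
apportioned over the 130 age x gender x region cells by largest remainder
against the composition table.

Writes results/quota_table.csv and prints the design numbers.
"""

from pathlib import Path

import prevadjust as pa

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = pa.SampleSizeSpec(z=1.96, p_assumed=0.02, e=0.01)
    n_formula = pa.required_sample_size(spec)
    print(f"sample size formula: ceil({spec.z}^2 * {spec.p_assumed} * "
          f"{1 - spec.p_assumed} / {spec.e}^2) = {n_formula}")
    print("recruitment target used by the study design: 750")

    comp = pa.default_composition()
    quota = pa.build_quota_table(comp, 750)
    quota.to_csv(RESULTS / "quota_table.csv", index=False)
    nonzero = (quota["count"] > 0).sum()
    print(f"quota table: {len(quota)} cells, {nonzero} non-empty, "
          f"counts {quota['count'].min()}..{quota['count'].max()}, "
          f"total {quota['count'].sum()}")
    print(f"wrote {RESULTS / 'quota_table.csv'}")


if __name__ == "__main__":
    main()
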