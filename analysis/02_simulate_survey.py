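#!/usr/bin/env python
"""Simulate the synthetic survey: panel, features, quota-matched sample.

Draws a 15,000-member synthetic panel with the default latent-class mix
(80% healthy, 7.9% MDD, 0.4% BD, 1.6% schizophrenia, 10.1% other),
generates the class-conditional survey features, and quota-samples 750
respondents to match the composition table.

Writes results/survey.csv.
"""

from pathlib import Path

import prevadjust as pa

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240101


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    comp = pa.default_composition()
    panel = pa.simulate_panel(pa.PopulationMix(), comp, panel_n=15000, seed=SEED)
    panel = pa.generate_features(panel, pa.default_schema(), seed=SEED + 1)
    quota = pa.build_quota_table(comp, 750)
    sample = pa.quota_sample(panel, quota, seed=SEED + 2)
    pa.write_survey(sample, RESULTS / "survey.csv")

    counts = sample["latent_class"].value_counts()
    print(f"panel: {len(panel)} members; quota-matched sample: {len(sample)}")
    print("latent classes in the sample:")
    for cls in pa.LATENT_CLASSES:
        print(f"  {cls:8s} {counts.get(cls, 0):4d}")
    print(f"wrote {RESULTS / 'survey.csv'}")


if __name__ == "__main__":
    main()
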