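"""Simulation experiments that validate the estimator end to end.

Two study-level checks live here so that the analysis drivers, the test
suite and the acceptance script all run exactly the same code:

* :func:`parameter_recovery` — simulate whole surveys with a known true
  prevalence and an oracle classifier whose error rates match the
  correction profile, and check that the corrected estimate recovers the
  truth on average.
* :func:`bootstrap_coverage` — simulate surveys at a known prevalence and
  measure how often the nominal 95% bootstrap interval covers the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    PopulationMix,
    build_quota_table,
    default_composition,
    mix_with_prevalence,
    quota_sample,
    simulate_panel,
)
from .classifier import oracle_classify
from .correction import (
    MisclassificationProfile,
    adjusted_prevalence_array,
    expected_false_positives,
)
from .uncertainty import bootstrap_prevalence_ci


@dataclass
class RecoveryResult:
    true_prevalence: float
    mean_adjusted: float
    mc_se: float
    n_replicates: int
    sample_n: int

    @property
    def bias(self) -> float:
        return self.mean_adjusted - self.true_prevalence

    @property
    def z(self) -> float:
        """Bias in Monte-Carlo standard errors."""
        return self.bias / self.mc_se


def parameter_recovery(
    true_p_sz: float,
    n_replicates: int = 200,
    sample_n: int = 750,
    panel_n: int = 15000,
    profile: MisclassificationProfile | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """Simulate ``n_replicates`` quota-matched surveys and correct each.

    Every replicate draws a fresh panel with schizophrenia prevalence
    ``true_p_sz`` (confuser proportions held at the profile's mix), quota
    samples ``sample_n`` respondents, labels them with the oracle classifier
    at the profile's rates (sensitivity p/(1+p)), and applies the
    correction.  The replicate average uses the unclamped linear estimator,
    which is the quantity whose expectation equals the true prevalence;
    clamping would truncate the lower tail and bias the mean upward near
    zero prevalence.
    """
    profile = profile or MisclassificationProfile()
    mix = mix_with_prevalence(true_p_sz, profile.mix)
    rates = profile.oracle_rates()
    comp = default_composition()
    quota = build_quota_table(comp, sample_n)
    estimates = np.empty(n_replicates)
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        s_panel, s_quota, s_oracle = ss.spawn(3)
        panel = simulate_panel(mix, comp, panel_n, seed=s_panel)
        sample = quota_sample(panel, quota, seed=s_quota)
        n_crude = int(oracle_classify(sample, rates, seed=s_oracle).sum())
        estimates[i] = adjusted_prevalence_array(
            np.array([n_crude]), sample_n, profile, clamp=False)[0]
    return RecoveryResult(
        true_prevalence=true_p_sz,
        mean_adjusted=float(estimates.mean()),
        mc_se=float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
        n_replicates=n_replicates,
        sample_n=sample_n,
    )


def bootstrap_coverage(
    true_p: float = 0.016,
    n: int = 750,
    n_surveys: int = 1000,
    replicates: int = 10000,
    method: str = "normal_boot",
    seed: int = 0,
) -> float:
    """Fraction of simulated surveys whose 95% bootstrap CI covers truth.

    Each survey draws its case count from Binomial(n, true_p) — the
    distribution of positives in an iid sample — then forms the bootstrap
    interval around the observed proportion.
    """
    ss = np.random.SeedSequence(seed)
    count_rng = np.random.default_rng(ss.spawn(1)[0])
    counts = count_rng.binomial(n, true_p, size=n_surveys)
    boot_seeds = ss.spawn(n_surveys + 1)[1:]
    covered = 0
    for k, bs in zip(counts, boot_seeds):
        ci = bootstrap_prevalence_ci(int(k), n, replicates, method, seed=bs)
        covered += ci.lower <= true_p <= ci.upper
    return covered / n_surveys
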