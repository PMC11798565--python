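"""Bootstrap confidence intervals for crude and adjusted prevalence.

The point estimates are proportions of a fixed-size sample, so the bootstrap
resamples the n individual case indicators with replacement.  Two interval
types are provided: ``normal_boot`` (point +/- 1.96 x bootstrap SD, the
default, which reproduces the published adjusted interval at one decimal
percent) and ``percentile_boot`` (empirical 2.5/97.5 percentiles).  A
full-pipeline variant resamples respondents and re-applies the entire
correction in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ValidationError
from .correction import MisclassificationProfile, adjusted_prevalence_array

METHODS = ("normal_boot", "percentile_boot")
Z_95 = 1.96


@dataclass
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    replicates: int
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.lower = min(max(self.lower, 0.0), 1.0)
        self.upper = min(max(self.upper, 0.0), 1.0)
        if not self.lower <= self.point <= self.upper:
            # guard against pathological replicate distributions
            self.lower = min(self.lower, self.point)
            self.upper = max(self.upper, self.point)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "replicates": self.replicates,
            "method": self.method,
            "seed": self.seed,
        }


def _interval(point: float, reps: np.ndarray, method: str,
              replicates: int, seed) -> IntervalEstimate:
    if method == "normal_boot":
        sd = float(reps.std(ddof=1))
        lo, hi = point - Z_95 * sd, point + Z_95 * sd
    elif method == "percentile_boot":
        lo, hi = (float(q) for q in np.quantile(reps, [0.025, 0.975]))
    else:
        raise ValidationError(f"unknown interval method {method!r}; use one of {METHODS}")
    return IntervalEstimate(point=point, lower=lo, upper=hi,
                            replicates=replicates, method=method,
                            seed=seed if isinstance(seed, int) else None)


def bootstrap_prevalence_ci(
    case_count: int,
    n: int,
    replicates: int = 10000,
    method: str = "normal_boot",
    seed: int | np.random.SeedSequence = 0,
) -> IntervalEstimate:
    """Bootstrap CI for a proportion of ``case_count`` positives among n.

    Each replicate resamples the n binary case indicators with replacement;
    the replicate positive count is therefore Binomial(n, case_count/n),
    which is drawn directly.  Bounds are clamped to [0, 1].
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if not 0 <= case_count <= n:
        raise ValidationError(f"case_count={case_count} outside [0, {n}]")
    rng = np.random.default_rng(seed)
    p_hat = case_count / n
    reps = rng.binomial(n, p_hat, size=replicates) / n
    return _interval(p_hat, reps, method, replicates, seed)


def bootstrap_corrected_ci(
    sample: pd.DataFrame,
    profile: MisclassificationProfile | None = None,
    replicates: int = 10000,
    method: str = "normal_boot",
    seed: int | np.random.SeedSequence = 0,
    label_column: str = "predicted_label",
) -> IntervalEstimate:
    """Full-pipeline bootstrap: resample respondents, re-correct each time.

    Every replicate resamples the sample rows with replacement, recounts the
    classifier positives and re-applies the misclassification correction,
    so the interval reflects the correction's discreteness as well as the
    sampling noise.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if label_column not in sample.columns:
        raise ValidationError(f"sample has no {label_column!r} column")
    labels = sample[label_column].to_numpy(dtype=int)
    n = len(labels)
    if n == 0:
        raise ValidationError("empty sample")
    rng = np.random.default_rng(seed)
    # with-replacement row resampling: the replicate positive count is a
    # draw of sum(labels[resampled rows]); counted explicitly per replicate
    idx = rng.integers(0, n, size=(replicates, n))
    crude_counts = labels[idx].sum(axis=1)
    reps = adjusted_prevalence_array(crude_counts, n, profile)
    point = float(adjusted_prevalence_array(np.array([labels.sum()]), n, profile)[0])
    return _interval(point, reps, method, replicates, seed)
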