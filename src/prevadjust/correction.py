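"""Misclassification correction of a classifier-based prevalence estimate.

A screening classifier applied to a quota-matched sample of n respondents
yields a crude case count N_crude.  Because the classifier also flags some
respondents without the disease (healthy people at rate r_hc, MDD patients
at r_MDD, BD patients at r_BD) and misses some true cases, the crude
prevalence N_crude/n is biased.  The correction removes the expected false
positives,

    N_fp = (P_hc*r_hc + P_MDD*r_MDD + P_BD*r_BD) * n,

back-calculates the true positives N_tp = N_crude - N_fp, restores the
expected false negatives from the externally validated true-positive to
false-negative ratio p (N_tp/N_fn = p, i.e. N_fn = N_tp/p), and reports

    P_population = (N_crude - N_fp + N_fn) / n.

This is a Rogan-Gladen-style adjustment with several confuser classes whose
population proportions (P_hc, P_MDD, P_BD) and misclassification rates are
plug-in constants from the literature and from external validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .cohort import PopulationMix, ValidationError

#: confuser classes that contribute expected false positives
CONFUSER_CLASSES = ("healthy", "mdd", "bd")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class MisclassificationProfile:
    """Plug-in constants of the correction.

    ``mix`` carries the population proportions (only the confuser entries
    are used by the correction); ``rates`` the per-class false-positive
    rates; ``tp_fn_ratio`` the externally validated true-positive to
    false-negative ratio p (default 46:15, equivalent to a sensitivity of
    p/(1+p) = 46/61 ~ 0.754).
    """

    mix: PopulationMix = field(default_factory=PopulationMix)
    rates: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": 0.031, "mdd": 0.554, "bd": 0.594}
    )
    tp_fn_ratio: float = 46 / 15

    def __post_init__(self) -> None:
        if self.tp_fn_ratio <= 0:
            raise ValidationError(f"tp_fn_ratio must be > 0, got {self.tp_fn_ratio}")
        missing = [c for c in CONFUSER_CLASSES if c not in self.rates]
        if missing:
            raise ValidationError(f"profile missing rates for: {missing}")
        bad = {c: r for c, r in self.rates.items() if not 0.0 <= r <= 1.0}
        if bad:
            raise ValidationError(f"rates outside [0, 1]: {bad}")

    @property
    def sensitivity(self) -> float:
        """Implied classifier sensitivity p/(1+p)."""
        return self.tp_fn_ratio / (1.0 + self.tp_fn_ratio)

    def oracle_rates(self) -> dict[str, float]:
        """Per-class positive rates for the oracle classifier consistent
        with this profile: confuser rates as configured, true cases at the
        implied sensitivity, residual 'other' class never positive unless
        given explicitly."""
        out = {c: float(self.rates[c]) for c in CONFUSER_CLASSES}
        out["sz"] = float(self.rates.get("sz", self.sensitivity))
        out["other"] = float(self.rates.get("other", 0.0))
        return out

    def to_dict(self) -> dict:
        return {
            "mix": self.mix.as_dict(),
            "rates": dict(self.rates),
            "tp_fn_ratio": self.tp_fn_ratio,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MisclassificationProfile":
        mixd = d.get("mix", {})
        mix = PopulationMix(
            p_healthy=mixd.get("healthy", 0.80),
            p_mdd=mixd.get("mdd", 0.079),
            p_bd=mixd.get("bd", 0.004),
            p_sz=mixd.get("sz", 0.016),
            p_other=mixd.get("other", 0.101),
        )
        return cls(mix=mix, rates=dict(d["rates"]),
                   tp_fn_ratio=float(d.get("tp_fn_ratio", 46 / 15)))


#: the published study's plug-in profile: 80% of the population without
#: mental disorders (false-positive rate 3.1%), MDD prevalence 7.9%
#: (misclassified 55.4%), BD prevalence 0.4% (misclassified 59.4%),
#: TP:FN = 46:15 from external validation.
PUBLISHED_PROFILE = MisclassificationProfile()


class FalsePositiveEstimate(NamedTuple):
    real: float
    rounded: int
    by_class: dict[str, float]


@dataclass
class CorrectionResult:
    """All intermediate and final quantities of one correction."""

    n: int
    n_crude: int
    n_fp_real: float
    n_fp: int
    n_tp: int
    n_fn_real: float
    n_fn: int
    n_adjusted: int
    crude_prevalence: float
    adjusted_prevalence: float
    fp_by_class: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_crude": self.n_crude,
            "n_fp_real": self.n_fp_real,
            "n_fp": self.n_fp,
            "n_tp": self.n_tp,
            "n_fn_real": self.n_fn_real,
            "n_fn": self.n_fn,
            "n_adjusted": self.n_adjusted,
            "crude_prevalence": self.crude_prevalence,
            "adjusted_prevalence": self.adjusted_prevalence,
            "fp_by_class": dict(self.fp_by_class),
            "warnings": list(self.warnings),
        }


def crude_prevalence(n_crude: int, n: int) -> float:
    """Proportion of sampled respondents the classifier labels positive."""
    if n <= 0:
        raise ValidationError(f"sample size must be positive, got {n}")
    if not 0 <= n_crude <= n:
        raise ValidationError(f"n_crude={n_crude} outside [0, {n}]")
    return n_crude / n


def expected_false_positives(
    profile: MisclassificationProfile, n: int
) -> FalsePositiveEstimate:
    """Expected false-positive count N_fp among classifier positives.

    Per-class components are reported unrounded; only the summed total is
    rounded (half away from zero) to an integer count.
    """
    if n <= 0:
        raise ValidationError(f"sample size must be positive, got {n}")
    mix = profile.mix.as_dict()
    by_class = {c: mix[c] * profile.rates[c] * n for c in CONFUSER_CLASSES}
    real = float(sum(by_class.values()))
    return FalsePositiveEstimate(real=real, rounded=round_half_away(real), by_class=by_class)


def correct_counts(n_crude: int, n_fp: int, tp_fn_ratio: float) -> dict:
    """Back-calculate true positives and false negatives.

    N_tp = N_crude - N_fp (clamped at zero with a warning if the expected
    false positives exceed the crude count, which can happen in bootstrap
    replicates); N_fn = N_tp / p rounded half away from zero.
    """
    if tp_fn_ratio <= 0:
        raise ValidationError(f"tp_fn_ratio must be > 0, got {tp_fn_ratio}")
    if n_crude < 0 or n_fp < 0:
        raise ValidationError("counts must be non-negative")
    warns = []
    n_tp = n_crude - n_fp
    if n_tp < 0:
        warns.append(
            f"expected false positives ({n_fp}) exceed crude count ({n_crude}); "
            "true positives clamped to 0"
        )
        n_tp = 0
    n_fn_real = n_tp / tp_fn_ratio
    return {
        "n_tp": int(n_tp),
        "n_fn_real": float(n_fn_real),
        "n_fn": round_half_away(n_fn_real),
        "warnings": warns,
    }


def adjusted_prevalence(n_crude: int, n_fp: int, n_fn: int, n: int) -> float:
    """P_population = (N_crude - N_fp + N_fn) / n, clamped to [0, 1]."""
    if n <= 0:
        raise ValidationError(f"sample size must be positive, got {n}")
    p = (n_crude - n_fp + n_fn) / n
    if p < 0 or p > 1:
        warnings.warn(f"adjusted prevalence {p:.4f} clamped to [0, 1]", stacklevel=2)
        p = min(max(p, 0.0), 1.0)
    return p


def correct_prevalence(
    n_crude: int, n: int, profile: MisclassificationProfile | None = None
) -> CorrectionResult:
    """Run the full correction for one crude count."""
    profile = profile or PUBLISHED_PROFILE
    crude = crude_prevalence(n_crude, n)
    fp = expected_false_positives(profile, n)
    cc = correct_counts(n_crude, fp.rounded, profile.tp_fn_ratio)
    n_adjusted = cc["n_tp"] + cc["n_fn"]
    adj = adjusted_prevalence(n_crude, fp.rounded, cc["n_fn"], n)
    return CorrectionResult(
        n=n,
        n_crude=n_crude,
        n_fp_real=fp.real,
        n_fp=fp.rounded,
        n_tp=cc["n_tp"],
        n_fn_real=cc["n_fn_real"],
        n_fn=cc["n_fn"],
        n_adjusted=n_adjusted,
        crude_prevalence=crude,
        adjusted_prevalence=adj,
        fp_by_class=fp.by_class,
        warnings=cc["warnings"],
    )


def adjusted_prevalence_array(
    n_crude: np.ndarray,
    n: int,
    profile: MisclassificationProfile | None = None,
    clamp: bool = True,
) -> np.ndarray:
    """Vectorised correction over an array of crude counts.

    With ``clamp=True`` (default, used for reported estimates and bootstrap
    replicates) this applies exactly the same arithmetic as
    :func:`correct_prevalence`: integer N_fp, N_tp clamped at zero,
    half-away-rounded N_fn, result clipped to [0, 1].

    With ``clamp=False`` the linear estimator (N_crude - N_fp + N_fn)/n is
    returned even when negative.  Clamping truncates the lower tail and
    therefore biases the *mean* of the estimator upward when the true
    prevalence is near zero, so bias/recovery experiments must average the
    unclamped form.
    """
    profile = profile or PUBLISHED_PROFILE
    n_fp = expected_false_positives(profile, n).rounded
    crude = np.asarray(n_crude, dtype=float)
    n_tp = crude - n_fp
    if clamp:
        n_tp = np.maximum(n_tp, 0.0)
    n_fn = np.floor(n_tp / profile.tp_fn_ratio + 0.5)
    adj = (crude - n_fp + n_fn) / n
    return np.clip(adj, 0.0, 1.0) if clamp else adj


def confusion_table(result: CorrectionResult) -> np.ndarray:
    """2x2 adjusted confusion counts.

    Rows: predicted schizophrenia / predicted non-schizophrenia; columns:
    adjusted case / adjusted non-case.  Cells (TP, FP; FN, TN) are
    non-negative and sum to n.  The predicted-positive row always splits
    the observed n_crude, so the FP cell is n_crude - n_tp (which caps the
    expected false positives at the observed positives when they exceed
    them).
    """
    fp_cell = result.n_crude - result.n_tp
    tn = result.n - result.n_crude - result.n_fn
    table = np.array([[result.n_tp, fp_cell], [result.n_fn, tn]], dtype=int)
    if (table < 0).any():
        raise ValidationError(f"negative confusion cell in {table.tolist()}")
    return table


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the single-population-proportion sample-size formula."""

    z: float = 1.96
    p_assumed: float = 0.02
    e: float = 0.01

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValidationError(f"z must be > 0, got {self.z}")
        if not 0.0 < self.p_assumed < 1.0:
            raise ValidationError(f"p_assumed must be in (0, 1), got {self.p_assumed}")
        if self.e <= 0:
            raise ValidationError(f"e must be > 0, got {self.e}")


def required_sample_size(spec: SampleSizeSpec = SampleSizeSpec()) -> int:
    """n = ceil(Z^2 p(1-p) / e^2).

    With Z=1.96, p=0.02, e=0.01 this is ceil(752.95) = 753; the study this
    package replicates rounded its recruitment target to 750.
    """
    return math.ceil(spec.z ** 2 * spec.p_assumed * (1 - spec.p_assumed) / spec.e ** 2)


def format_percent(p: float) -> str:
    """Prevalence as a percentage to one decimal, halves away from zero."""
    return f"{round_half_away(p * 1000) / 10:.1f}"
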