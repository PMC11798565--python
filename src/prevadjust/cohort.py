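"""Synthetic survey cohorts with quota-matched demographic structure.

The study design this package replicates recruits a fixed number of web-panel
respondents per demographic cell (5 age groups x 2 genders x 13 Japanese
regions, 130 cells) so the sample matches a national population composition,
then screens each respondent for schizophrenia with a classifier.  The real
panel is proprietary, so this module generates panels with the same shape:
each simulated respondent carries a demographic cell, a latent diagnostic
class (healthy / MDD / BD / schizophrenia / other mental disorder) and survey
features drawn from class-conditional distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

AGE_GROUPS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-75")
GENDERS: tuple[str, ...] = ("male", "female")
REGIONS: tuple[str, ...] = (
    "Hokkaido",
    "Tohoku",
    "North Kanto",
    "Greater Tokyo",
    "Koshinetsu",
    "Hokuriku",
    "Tokai",
    "Kinki excl. Keihanshin",
    "Keihanshin",
    "Chugoku",
    "Shikoku",
    "Kyushu excl. Okinawa",
    "Okinawa",
)
LATENT_CLASSES: tuple[str, ...] = ("healthy", "mdd", "bd", "sz", "other")

FEATURE_CATEGORIES: tuple[str, ...] = (
    "demographic",
    "health_background",
    "physical_comorbidity",
    "psychiatric_comorbidity",
    "social_comorbidity",
)

CELL_COLUMNS = ["age_group", "gender", "region"]

#: number of distinct demographic cells (5 x 2 x 13)
N_CELLS = len(AGE_GROUPS) * len(GENDERS) * len(REGIONS)


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its invariants."""


# ---------------------------------------------------------------------------
# population mix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationMix:
    """Latent diagnostic-class proportions in the general population.

    ``p_healthy``, ``p_mdd`` and ``p_bd`` are the plug-in population
    fractions used by the false-positive correction; ``p_sz`` is the
    (simulated) true schizophrenia prevalence and ``p_other`` closes the
    simplex with all remaining mental disorders.
    """

    p_healthy: float = 0.80
    p_mdd: float = 0.079
    p_bd: float = 0.004
    p_sz: float = 0.016
    p_other: float = 0.101

    def __post_init__(self) -> None:
        probs = self.as_dict()
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total!r}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "healthy": self.p_healthy,
            "mdd": self.p_mdd,
            "bd": self.p_bd,
            "sz": self.p_sz,
            "other": self.p_other,
        }

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[c] for c in LATENT_CLASSES], dtype=float)

    def replace(self, **kwargs: float) -> "PopulationMix":
        vals = {
            "p_healthy": self.p_healthy,
            "p_mdd": self.p_mdd,
            "p_bd": self.p_bd,
            "p_sz": self.p_sz,
            "p_other": self.p_other,
        }
        vals.update(kwargs)
        return PopulationMix(**vals)


def mix_with_prevalence(p_sz: float, base: PopulationMix | None = None) -> PopulationMix:
    """Return a mix with schizophrenia prevalence ``p_sz``.

    The difference to the base mix's ``p_sz`` is absorbed by the residual
    "other" class so the confuser proportions (healthy, MDD, BD) that enter
    the correction stay fixed.
    """
    base = base or PopulationMix()
    delta = p_sz - base.p_sz
    return base.replace(p_sz=p_sz, p_other=base.p_other - delta)


# ---------------------------------------------------------------------------
# composition and quota tables
# ---------------------------------------------------------------------------


def all_cells() -> pd.DataFrame:
    """Every demographic cell, one row each, in canonical order."""
    rows = list(itertools.product(AGE_GROUPS, GENDERS, REGIONS))
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


# Synthetic marginals, loosely shaped like the Japanese adult population.
# The real October-2021 census composition is not redistributable here; any
# user-supplied composition table can be passed instead.
_AGE_WEIGHTS = {"20-29": 0.15, "30-39": 0.17, "40-49": 0.20, "50-59": 0.18, "60-75": 0.30}
_GENDER_WEIGHTS = {"male": 0.49, "female": 0.51}
_REGION_WEIGHTS = {
    "Hokkaido": 0.041,
    "Tohoku": 0.068,
    "North Kanto": 0.055,
    "Greater Tokyo": 0.290,
    "Koshinetsu": 0.041,
    "Hokuriku": 0.024,
    "Tokai": 0.120,
    "Kinki excl. Keihanshin": 0.036,
    "Keihanshin": 0.120,
    "Chugoku": 0.057,
    "Shikoku": 0.029,
    "Kyushu excl. Okinawa": 0.103,
    "Okinawa": 0.012,
}


def default_composition() -> pd.DataFrame:
    """Synthetic default composition table (product of marginals).

    Columns ``age_group, gender, region, proportion``; proportions sum to 1.
    """
    cells = all_cells()
    w = (
        cells["age_group"].map(_AGE_WEIGHTS)
        * cells["gender"].map(_GENDER_WEIGHTS)
        * cells["region"].map(_REGION_WEIGHTS)
    ).to_numpy(dtype=float)
    cells["proportion"] = w / w.sum()
    return cells


def validate_composition(composition: pd.DataFrame) -> pd.DataFrame:
    """Check a composition table and return it in canonical cell order."""
    missing = [c for c in CELL_COLUMNS + ["proportion"] if c not in composition.columns]
    if missing:
        raise ValidationError(f"composition table missing columns: {missing}")
    comp = composition.copy()
    key = comp[CELL_COLUMNS].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise ValidationError("composition table contains duplicate cells")
    canonical = all_cells()
    canonical_key = canonical[CELL_COLUMNS].agg("|".join, axis=1)
    lookup = dict(zip(key, comp["proportion"].astype(float)))
    unknown = sorted(set(key) - set(canonical_key))
    if unknown:
        raise ValidationError(f"unknown demographic cells: {unknown[:5]}")
    absent = [k for k in canonical_key if k not in lookup]
    if absent:
        raise ValidationError(f"{len(absent)} of {N_CELLS} cells absent, e.g. {absent[:3]}")
    props = np.array([lookup[k] for k in canonical_key], dtype=float)
    if (props < 0).any():
        raise ValidationError("negative proportions in composition table")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {props.sum()!r}, not 1")
    out = canonical.copy()
    out["proportion"] = props
    return out


def read_composition(path) -> pd.DataFrame:
    return validate_composition(pd.read_csv(path))


def write_composition(composition: pd.DataFrame, path) -> None:
    validate_composition(composition).to_csv(path, index=False)


def build_quota_table(composition: pd.DataFrame, total_n: int) -> pd.DataFrame:
    """Apportion ``total_n`` respondents to cells by largest remainder.

    Each cell receives the floor of its proportional share; leftover units go
    to the cells with the largest fractional remainders, ties broken by
    canonical cell order (age, then gender, then region).  Every count is
    within 1 of exact proportionality and the counts sum to ``total_n``.
    """
    if total_n < 1:
        raise ValidationError(f"total_n must be >= 1, got {total_n}")
    comp = validate_composition(composition)
    shares = comp["proportion"].to_numpy() * total_n
    counts = np.floor(shares).astype(int)
    leftover = total_n - int(counts.sum())
    frac = shares - np.floor(shares)
    order = np.argsort(-frac, kind="stable")  # stable sort = cell-order ties
    counts[order[:leftover]] += 1
    quota = comp[CELL_COLUMNS].copy()
    quota["count"] = counts
    return quota


# ---------------------------------------------------------------------------
# feature schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """One survey feature with class-conditional generating parameters.

    type ``continuous``: normal with per-class mean and a common sd.
    type ``ordinal``: integer codes 0..n_levels-1 drawn binomially with a
    per-class success probability (a crude graded-response stand-in).
    type ``categorical``: string levels with per-class probability vectors.
    """

    name: str
    category: str
    type: str
    params: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValidationError(
                f"feature {self.name!r}: unknown category {self.category!r}"
            )
        if self.type not in ("continuous", "ordinal", "categorical"):
            raise ValidationError(f"feature {self.name!r}: unknown type {self.type!r}")
        by_class = self._class_params()
        unknown = set(by_class) - set(LATENT_CLASSES)
        if unknown:
            raise ValidationError(
                f"feature {self.name!r}: parameters for unknown classes {sorted(unknown)}"
            )
        missing = set(LATENT_CLASSES) - set(by_class)
        if missing:
            raise ValidationError(
                f"feature {self.name!r}: missing parameters for classes {sorted(missing)}"
            )

    def _class_params(self) -> Mapping[str, object]:
        key = {"continuous": "class_means", "ordinal": "class_p", "categorical": "class_probs"}
        return self.params[key[self.type]]  # type: ignore[index]


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in schema")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def categories_present(self) -> set[str]:
        return {f.category for f in self.features}

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": f.name, "category": f.category, "type": f.type,
                 "params": _plain(f.params)}
                for f in self.features
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        feats = tuple(
            FeatureSpec(f["name"], f["category"], f["type"], f["params"])
            for f in d["features"]
        )
        return cls(feats)


def _plain(obj):
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_schema(path) -> FeatureSchema:
    with open(path, "r", encoding="utf-8") as fh:
        return FeatureSchema.from_dict(yaml.safe_load(fh))


def save_schema(schema: FeatureSchema, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(schema.to_dict(), fh, sort_keys=False)


def _cont(name, category, means, sd):
    return FeatureSpec(name, category, "continuous", {"class_means": means, "sd": sd})


def _ord(name, category, n_levels, p):
    return FeatureSpec(name, category, "ordinal", {"n_levels": n_levels, "class_p": p})


def _cat(name, category, levels, probs):
    return FeatureSpec(
        name, category, "categorical", {"levels": list(levels), "class_probs": probs}
    )


def default_schema() -> FeatureSchema:
    """Synthetic default survey schema across the five feature categories.

    Class-conditional locations were chosen once so that a linear classifier
    separates schizophrenia from healthy respondents with AUC near the
    mid-0.80s (the separability level the screening study reports), while
    MDD and BD sit close to schizophrenia and are therefore frequently
    confused with it.  None of the parameters estimate real survey marginals.
    """
    H, M, B, S, O = "healthy", "mdd", "bd", "sz", "other"
    return FeatureSchema((
        _cont("age_years", "demographic",
              {H: 45.0, M: 44.0, B: 43.5, S: 44.5, O: 44.5}, 14.0),
        _cont("bmi", "health_background",
              {H: 22.3, M: 22.8, B: 23.0, S: 23.5, O: 22.7}, 3.5),
        _cont("sleep_hours", "psychiatric_comorbidity",
              {H: 7.0, M: 6.45, B: 6.45, S: 6.5, O: 6.8}, 1.2),
        _cont("bedtime_hour", "psychiatric_comorbidity",
              {H: 23.2, M: 23.9, B: 23.95, S: 24.0, O: 23.5}, 1.5),
        _cont("internet_hours_week", "psychiatric_comorbidity",
              {H: 14.0, M: 17.0, B: 17.0, S: 17.5, O: 15.5}, 8.0),
        _cont("perceived_stress", "psychiatric_comorbidity",
              {H: 12.0, M: 15.5, B: 15.0, S: 15.0, O: 13.5}, 6.0),
        _ord("depressive_symptoms", "psychiatric_comorbidity", 28,
             {H: 0.12, M: 0.175, B: 0.165, S: 0.16, O: 0.14}),
        _ord("sleep_medication_freq", "psychiatric_comorbidity", 5,
             {H: 0.05, M: 0.12, B: 0.11, S: 0.10, O: 0.07}),
        _ord("ikigai", "psychiatric_comorbidity", 5,
             {H: 0.72, M: 0.62, B: 0.63, S: 0.64, O: 0.68}),
        _ord("functional_restriction", "health_background", 4,
             {H: 0.07, M: 0.11, B: 0.115, S: 0.12, O: 0.09}),
        _ord("self_rated_health", "health_background", 5,
             {H: 0.70, M: 0.61, B: 0.615, S: 0.62, O: 0.66}),
        _cat("smoking", "health_background", ["never", "former", "current"],
             {H: [0.60, 0.25, 0.15], M: [0.56, 0.25, 0.19], B: [0.54, 0.24, 0.22],
              S: [0.52, 0.24, 0.24], O: [0.58, 0.25, 0.17]}),
        _cat("hypertension", "physical_comorbidity", ["no", "yes"],
             {H: [0.85, 0.15], M: [0.83, 0.17], B: [0.82, 0.18],
              S: [0.80, 0.20], O: [0.84, 0.16]}),
        _cat("employment", "social_comorbidity",
             ["fulltime", "parttime", "unemployed", "retired"],
             {H: [0.55, 0.20, 0.10, 0.15], M: [0.47, 0.22, 0.16, 0.15],
              B: [0.46, 0.21, 0.18, 0.15], S: [0.45, 0.21, 0.19, 0.15],
              O: [0.51, 0.20, 0.14, 0.15]}),
        _cat("marital_status", "social_comorbidity", ["married", "single", "divorced"],
             {H: [0.55, 0.35, 0.10], M: [0.48, 0.40, 0.12], B: [0.46, 0.41, 0.13],
              S: [0.45, 0.42, 0.13], O: [0.52, 0.37, 0.11]}),
        _cat("household_income", "social_comorbidity", ["low", "middle", "high"],
             {H: [0.25, 0.50, 0.25], M: [0.32, 0.48, 0.20], B: [0.33, 0.48, 0.19],
              S: [0.35, 0.47, 0.18], O: [0.28, 0.49, 0.23]}),
    ))


def null_schema() -> FeatureSchema:
    """Zero-separation variant of the default schema (all classes identical).

    Every class-conditional parameter is replaced by the healthy one, so no
    feature carries any diagnostic signal; useful as a negative control.
    """
    feats = []
    for f in default_schema().features:
        params = dict(f.params)
        if f.type == "continuous":
            ref = params["class_means"]["healthy"]
            params["class_means"] = {c: ref for c in LATENT_CLASSES}
        elif f.type == "ordinal":
            ref = params["class_p"]["healthy"]
            params["class_p"] = {c: ref for c in LATENT_CLASSES}
        else:
            ref = params["class_probs"]["healthy"]
            params["class_probs"] = {c: list(ref) for c in LATENT_CLASSES}
        feats.append(FeatureSpec(f.name, f.category, f.type, params))
    return FeatureSchema(tuple(feats))


# ---------------------------------------------------------------------------
# panel simulation and quota sampling
# ---------------------------------------------------------------------------


def _cell_categoricals(df: pd.DataFrame) -> pd.DataFrame:
    df["age_group"] = pd.Categorical(df["age_group"], categories=AGE_GROUPS)
    df["gender"] = pd.Categorical(df["gender"], categories=GENDERS)
    df["region"] = pd.Categorical(df["region"], categories=REGIONS)
    if "latent_class" in df.columns:
        df["latent_class"] = pd.Categorical(df["latent_class"], categories=LATENT_CLASSES)
    return df


def simulate_panel(
    mix: PopulationMix,
    composition: pd.DataFrame | None = None,
    panel_n: int = 15000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate a registered survey panel (no features yet).

    Demographic cells are drawn iid from the composition table and latent
    diagnostic classes iid from ``mix``; the two are independent.  Identical
    seeds give identical tables.
    """
    if panel_n < 1:
        raise ValidationError(f"panel_n must be >= 1, got {panel_n}")
    comp = validate_composition(composition if composition is not None else default_composition())
    rng = np.random.default_rng(seed)
    cell_idx = rng.choice(len(comp), size=panel_n, p=comp["proportion"].to_numpy())
    class_idx = rng.choice(len(LATENT_CLASSES), size=panel_n, p=mix.as_array())
    df = pd.DataFrame({
        "id": np.arange(panel_n),
        "age_group": comp["age_group"].to_numpy()[cell_idx],
        "gender": comp["gender"].to_numpy()[cell_idx],
        "region": comp["region"].to_numpy()[cell_idx],
        "latent_class": np.array(LATENT_CLASSES, dtype=object)[class_idx],
    })
    return _cell_categoricals(df)


def generate_features(
    participants: pd.DataFrame,
    schema: FeatureSchema | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Append class-conditional survey features to a participant table."""
    schema = schema or default_schema()
    if "latent_class" not in participants.columns:
        raise ValidationError("participant table has no latent_class column")
    rng = np.random.default_rng(seed)
    df = participants.copy()
    classes = df["latent_class"].astype(str).to_numpy()
    n = len(df)
    for f in schema.features:
        if f.type == "continuous":
            means = np.array([f.params["class_means"][c] for c in classes])
            df[f.name] = rng.normal(means, f.params["sd"])
        elif f.type == "ordinal":
            p = np.array([f.params["class_p"][c] for c in classes])
            df[f.name] = rng.binomial(int(f.params["n_levels"]) - 1, p)
        else:
            levels = np.array(f.params["levels"], dtype=object)
            out = np.empty(n, dtype=object)
            for c in np.unique(classes):
                m = classes == c
                probs = np.asarray(f.params["class_probs"][c], dtype=float)
                out[m] = rng.choice(levels, size=int(m.sum()), p=probs / probs.sum())
            df[f.name] = out
    return df


def quota_sample(
    panel: pd.DataFrame,
    quota: pd.DataFrame,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Draw the quota-matched sample: per cell, without replacement.

    Raises a ``ValidationError`` naming the first deficient cell if the panel
    cannot fill a quota.
    """
    rng = np.random.default_rng(seed)
    key = panel[CELL_COLUMNS].astype(str).agg("|".join, axis=1)
    groups = {k: idx.to_numpy() for k, idx in panel.groupby(key, observed=True).groups.items()}
    picks: list[np.ndarray] = []
    for _, row in quota.iterrows():
        count = int(row["count"])
        if count == 0:
            continue
        k = "|".join(str(row[c]) for c in CELL_COLUMNS)
        avail = groups.get(k, np.array([], dtype=int))
        if len(avail) < count:
            raise ValidationError(
                f"panel has {len(avail)} rows in cell {k!r} but quota requires {count}"
            )
        picks.append(rng.choice(avail, size=count, replace=False))
    if not picks:
        return panel.iloc[0:0].copy()
    idx = np.concatenate(picks)
    return panel.loc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# survey file round-trip
# ---------------------------------------------------------------------------

REQUIRED_SURVEY_COLUMNS = ["id", "age_group", "gender", "region"]


def write_survey(table: pd.DataFrame, path) -> None:
    missing = [c for c in REQUIRED_SURVEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"survey table missing required columns: {missing}")
    table.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"survey file missing required columns: {missing}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"survey file contains missing values in columns: {bad}")
    return _cell_categoricals(df)
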