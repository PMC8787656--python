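"""Synthetic respondent cohorts with a latent risk-class mixture structure.

The Bergen Social Media Addiction Scale (BSMAS) comprises six items —
salience, tolerance, mood modification, loss of control, withdrawal,
conflict — each rated 1 ("very rarely") to 5 ("very often").  Survey studies
of problematic social media use typically find a small number of latent risk
tiers (low-risk, at-risk, high-risk) with distinct mean item profiles, plus
elevated depression (CES-D, 0-60) and state anxiety (STAI-S, 20-80) in the
high-risk tier.

This module generates cohorts with exactly that structure:

* latent class drawn from mixture weights;
* each item rating drawn as a class-conditional normal deviate, rounded to
  the nearest integer and clipped to [1, 5];
* CES-D / STAI totals drawn from class-conditional normals, rounded and
  clipped to their scale ranges;
* sex and age-band drawn independently of class from stated margins (an
  optional per-class age weighting is available, since prevalence is
  age-graded in survey data).

The generating class is stored in a ``true_class`` column so that parameter
recovery can be tested, but :func:`analysis_view` strips it so downstream
stages never see it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_NAMES",
    "ITEM_COLUMNS",
    "SEX_LEVELS",
    "AGE_LEVELS",
    "ClassProfile",
    "CohortSpec",
    "generate_cohort",
    "analysis_view",
    "uk_like_spec",
    "us_like_spec",
    "cohort_to_csv",
    "cohort_from_csv",
    "spec_to_json",
    "spec_from_json",
]

ITEM_NAMES = (
    "salience",
    "tolerance",
    "mood_modification",
    "loss_of_control",
    "withdrawal",
    "conflict",
)
ITEM_COLUMNS = tuple(f"bsmas{i}" for i in range(1, 7))
SEX_LEVELS = ("male", "female")
AGE_LEVELS = ("18-34", "35-49", "50-65")

N_ITEMS = 6
_WEIGHT_TOL = 1e-12


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class ClassProfile:
    """One latent risk tier: mixture weight plus class-conditional moments."""

    label: str
    weight: float
    item_means: tuple[float, ...]
    item_sds: tuple[float, ...]
    depression_mean: float
    depression_sd: float
    anxiety_mean: float
    anxiety_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_means", tuple(float(m) for m in self.item_means))
        object.__setattr__(self, "item_sds", tuple(float(s) for s in self.item_sds))
        if len(self.item_means) != N_ITEMS or len(self.item_sds) != N_ITEMS:
            raise CohortSpecError(
                f"profile {self.label!r}: expected {N_ITEMS} item means and sds"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise CohortSpecError(f"profile {self.label!r}: weight must lie in [0, 1]")
        if any(not 1.0 <= m <= 5.0 for m in self.item_means):
            raise CohortSpecError(f"profile {self.label!r}: item means must lie in [1, 5]")
        if any(s <= 0 for s in self.item_sds):
            raise CohortSpecError(f"profile {self.label!r}: item sds must be positive")
        if self.depression_sd <= 0 or self.anxiety_sd <= 0:
            raise CohortSpecError(f"profile {self.label!r}: comorbidity sds must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``age_splits_by_class`` optionally overrides the marginal age
    distribution per latent class (outer index follows ``profiles``);
    by default demographics are independent of class.
    """

    n: int
    profiles: tuple[ClassProfile, ...]
    sex_split: float
    age_splits: tuple[float, float, float]
    seed: int = 0
    age_splits_by_class: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "age_splits", tuple(float(a) for a in self.age_splits))
        if self.n < 1:
            raise CohortSpecError("n must be at least 1")
        if not self.profiles:
            raise CohortSpecError("at least one class profile is required")
        total = sum(p.weight for p in self.profiles)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise CohortSpecError(f"class weights must sum to 1 (got {total!r})")
        if not 0.0 <= self.sex_split <= 1.0:
            raise CohortSpecError("sex_split must lie in [0, 1]")
        if len(self.age_splits) != len(AGE_LEVELS):
            raise CohortSpecError(f"age_splits must have {len(AGE_LEVELS)} entries")
        if abs(sum(self.age_splits) - 1.0) > _WEIGHT_TOL:
            raise CohortSpecError("age_splits must sum to 1")
        if self.age_splits_by_class is not None:
            aby = tuple(tuple(float(a) for a in row) for row in self.age_splits_by_class)
            object.__setattr__(self, "age_splits_by_class", aby)
            if len(aby) != len(self.profiles):
                raise CohortSpecError("age_splits_by_class needs one row per profile")
            for row in aby:
                if abs(sum(row) - 1.0) > _WEIGHT_TOL:
                    raise CohortSpecError("each age_splits_by_class row must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of ``spec.n`` respondents.

    Returns a DataFrame with columns ``bsmas1..bsmas6`` (int, 1-5), ``sex``,
    ``age_group``, ``cesd_total`` (int, 0-60), ``stai_total`` (int, 20-80)
    and ``true_class`` (generating class index, ordered as ``spec.profiles``).
    The same spec (including its seed) always yields a bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = len(spec.profiles)

    cls = rng.choice(k, size=n, p=spec.weights)
    means = np.array([p.item_means for p in spec.profiles])  # (k, 6)
    sds = np.array([p.item_sds for p in spec.profiles])
    latent = rng.normal(means[cls], sds[cls])
    ratings = np.clip(np.rint(latent), 1, 5).astype(np.int64)

    dep_mu = np.array([p.depression_mean for p in spec.profiles])[cls]
    dep_sd = np.array([p.depression_sd for p in spec.profiles])[cls]
    cesd = np.clip(np.rint(rng.normal(dep_mu, dep_sd)), 0, 60).astype(np.int64)
    anx_mu = np.array([p.anxiety_mean for p in spec.profiles])[cls]
    anx_sd = np.array([p.anxiety_sd for p in spec.profiles])[cls]
    stai = np.clip(np.rint(rng.normal(anx_mu, anx_sd)), 20, 80).astype(np.int64)

    sex = np.where(rng.random(n) < spec.sex_split, SEX_LEVELS[0], SEX_LEVELS[1])
    if spec.age_splits_by_class is None:
        age = rng.choice(AGE_LEVELS, size=n, p=np.asarray(spec.age_splits))
    else:
        # Class-dependent draw: one uniform per respondent against the
        # class-specific cumulative age distribution.
        cum = np.cumsum(np.asarray(spec.age_splits_by_class), axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum[cls]).sum(axis=1)
        age = np.asarray(AGE_LEVELS)[idx]

    data = {col: ratings[:, j] for j, col in enumerate(ITEM_COLUMNS)}
    data["sex"] = pd.Categorical(sex, categories=list(SEX_LEVELS))
    data["age_group"] = pd.Categorical(age, categories=list(AGE_LEVELS))
    data["cesd_total"] = cesd
    data["stai_total"] = stai
    data["true_class"] = cls
    return pd.DataFrame(data)


def analysis_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return the cohort without the generating ``true_class`` column.

    All analysis stages should consume this view; the hidden class is only
    for parameter-recovery checks.
    """
    return cohort.drop(columns=["true_class"], errors="ignore")


def uk_like_spec(n: int = 573, seed: int = 0) -> CohortSpec:
    """Three-tier spec emulating a UK adult sample (n=573 by default).

    Class proportions 55 / 33.1 / 11.9 %.  Low-risk item means sit well
    below 1.34; the at-risk tier endorses only the first three symptoms
    (means near the scale midpoint, 2.62-2.97) with the remaining three
    below 2.07; high-risk means all exceed 3.18.  Comorbidity means/SDs
    mixture-average to the pooled high-risk vs low-to-at-risk contrast
    reported for such samples (CES-D ~26.6 vs ~15.8; STAI ~50.1 vs ~38.9).
    """
    profiles = (
        ClassProfile(
            label="low-risk",
            weight=0.55,
            item_means=(1.2, 1.2, 1.2, 1.2, 1.2, 1.2),
            item_sds=(0.5,) * 6,
            depression_mean=14.0,
            depression_sd=10.0,
            anxiety_mean=37.0,
            anxiety_sd=12.5,
        ),
        ClassProfile(
            label="at-risk",
            weight=0.331,
            item_means=(2.8, 2.8, 2.9, 1.8, 1.8, 1.8),
            item_sds=(0.8,) * 6,
            depression_mean=18.5,
            depression_sd=10.5,
            anxiety_mean=42.0,
            anxiety_sd=12.5,
        ),
        ClassProfile(
            label="high-risk",
            weight=0.119,
            item_means=(3.6, 3.7, 3.8, 3.5, 3.6, 3.5),
            item_sds=(0.8,) * 6,
            depression_mean=26.6,
            depression_sd=12.7,
            anxiety_mean=50.1,
            anxiety_sd=14.0,
        ),
    )
    return CohortSpec(
        n=n,
        profiles=profiles,
        sex_split=0.456,
        age_splits=(0.335, 0.333, 0.332),
        seed=seed,
    )


def us_like_spec(n: int = 474, seed: int = 0) -> CohortSpec:
    """Three-tier spec emulating a US adult sample (n=474 by default).

    Class proportions 62.2 / 28.7 / 9.1 %.  The high-risk tier here exceeds
    the midpoint only on salience, tolerance, mood modification and
    withdrawal (means > 3.34), with loss of control and conflict below it —
    a four-of-six symptom profile.
    """
    profiles = (
        ClassProfile(
            label="low-risk",
            weight=0.622,
            item_means=(1.3, 1.3, 1.3, 1.3, 1.3, 1.3),
            item_sds=(0.5,) * 6,
            depression_mean=13.5,
            depression_sd=10.0,
            anxiety_mean=36.0,
            anxiety_sd=12.5,
        ),
        ClassProfile(
            label="at-risk",
            weight=0.287,
            item_means=(2.8, 2.9, 3.0, 1.7, 1.8, 1.8),
            item_sds=(0.8,) * 6,
            depression_mean=20.2,
            depression_sd=10.8,
            anxiety_mean=42.0,
            anxiety_sd=12.8,
        ),
        ClassProfile(
            label="high-risk",
            weight=0.091,
            item_means=(3.6, 3.7, 3.9, 2.8, 3.5, 2.7),
            item_sds=(0.8,) * 6,
            depression_mean=24.0,
            depression_sd=11.0,
            anxiety_mean=46.0,
            anxiety_sd=13.1,
        ),
    )
    return CohortSpec(
        n=n,
        profiles=profiles,
        sex_split=0.474,
        age_splits=(0.356, 0.321, 0.323),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization

def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sex", "age_group"):
        if col in df.columns:
            levels = SEX_LEVELS if col == "sex" else AGE_LEVELS
            df[col] = pd.Categorical(df[col], categories=list(levels))
    return df


def spec_to_json(spec: CohortSpec) -> str:
    return json.dumps(asdict(spec), indent=2)


def spec_from_json(text: str) -> CohortSpec:
    raw = json.loads(text)
    profiles = tuple(ClassProfile(**p) for p in raw.pop("profiles"))
    aby = raw.pop("age_splits_by_class", None)
    if aby is not None:
        aby = tuple(tuple(row) for row in aby)
    return CohortSpec(profiles=profiles, age_splits_by_class=aby, **raw)
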