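"""Monothetic and polythetic criterion-counting classification schemes.

A respondent meets a symptom criterion when the corresponding item rating
reaches a cutoff: the scale midpoint 3, or the stricter 4.  A *monothetic*
scheme requires every criterion; a *polythetic* scheme requires more than
half (>= 4 of 6).  Crossing the two cutoffs with the two counting rules
gives the four schemes evaluated throughout this package:

==================  ======  ===============
name                cutoff  counting rule
==================  ======  ===============
strict monothetic   4       all criteria
strict polythetic   4       more than half
monothetic          3       all criteria
polythetic          3       more than half
==================  ======  ===============
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ITEM_COLUMNS

__all__ = [
    "SchemeSpec",
    "SCHEMES",
    "SCHEME_ORDER",
    "dichotomize",
    "classify",
    "apply_scheme",
    "composite_score",
    "prevalence",
    "prevalence_by",
    "ratings_matrix",
]

N_ITEMS = 6
VALID_CUTOFFS = (3, 4)
RULE_ALL = "all-criteria"
RULE_MAJORITY = "more-than-half"
# "More than half" of six criteria means strictly more than 3, i.e. >= 4.
MAJORITY_COUNT = N_ITEMS // 2 + 1


class RatingError(ValueError):
    """Raised when an item rating falls outside the 1-5 Likert range."""


@dataclass(frozen=True)
class SchemeSpec:
    name: str
    item_cutoff: int
    rule: str

    def __post_init__(self) -> None:
        if self.item_cutoff not in VALID_CUTOFFS:
            raise ValueError(f"item_cutoff must be one of {VALID_CUTOFFS}")
        if self.rule not in (RULE_ALL, RULE_MAJORITY):
            raise ValueError(f"rule must be {RULE_ALL!r} or {RULE_MAJORITY!r}")


SCHEMES: dict[str, SchemeSpec] = {
    "strict monothetic": SchemeSpec("strict monothetic", 4, RULE_ALL),
    "strict polythetic": SchemeSpec("strict polythetic", 4, RULE_MAJORITY),
    "monothetic": SchemeSpec("monothetic", 3, RULE_ALL),
    "polythetic": SchemeSpec("polythetic", 3, RULE_MAJORITY),
}
SCHEME_ORDER = tuple(SCHEMES)


def ratings_matrix(data) -> np.ndarray:
    """Coerce a cohort DataFrame or array-like to an (n, 6) integer matrix."""
    if isinstance(data, pd.DataFrame):
        data = data[list(ITEM_COLUMNS)].to_numpy()
    arr = np.asarray(data)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != N_ITEMS:
        raise RatingError(f"expected {N_ITEMS} item columns, got {arr.shape[1]}")
    return arr


def _validate_ratings(arr: np.ndarray) -> np.ndarray:
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            bad = np.argwhere(np.mod(arr, 1) != 0)[0]
            raise RatingError(
                f"non-integer rating at row {bad[0]}, item {bad[1] + 1}"
            )
        arr = arr.astype(np.int64)
    bad = np.argwhere((arr < 1) | (arr > 5))
    if bad.size:
        r, j = bad[0]
        raise RatingError(
            f"rating out of range 1-5 at row {r}, item {j + 1} (value {arr[r, j]})"
        )
    return arr


def dichotomize(ratings, cutoff: int) -> np.ndarray:
    """Criterion matrix: entry true iff rating >= cutoff (3 or 4)."""
    if cutoff not in VALID_CUTOFFS:
        raise ValueError(f"cutoff must be one of {VALID_CUTOFFS}")
    arr = _validate_ratings(ratings_matrix(ratings))
    return arr >= cutoff


def classify(criteria: np.ndarray, rule: str) -> np.ndarray:
    """Binary labels (True = positive / high-risk) from a criterion matrix."""
    criteria = np.asarray(criteria, dtype=bool)
    if criteria.ndim == 1:
        criteria = criteria.reshape(1, -1)
    if criteria.shape[1] != N_ITEMS:
        raise ValueError(f"criterion matrix must have {N_ITEMS} columns")
    counts = criteria.sum(axis=1)
    if rule == RULE_ALL:
        return counts == N_ITEMS
    if rule == RULE_MAJORITY:
        return counts >= MAJORITY_COUNT
    raise ValueError(f"unknown rule {rule!r}")


def apply_scheme(ratings, scheme: SchemeSpec | str) -> np.ndarray:
    """Classify every respondent under one scheme."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    return classify(dichotomize(ratings, scheme.item_cutoff), scheme.rule)


def composite_score(ratings) -> np.ndarray:
    """Summed six-item score, 6-30.  Exposed for description only; no
    composite-score cutoff scheme is implemented — classification is always
    by criterion counting."""
    return _validate_ratings(ratings_matrix(ratings)).sum(axis=1)


def prevalence(labels) -> tuple[int, int, float]:
    """(positive count, n, proportion) for a vector of binary labels."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    pos = int(labels.sum())
    return pos, int(labels.size), pos / labels.size


def prevalence_by(labels, by: pd.Series) -> pd.DataFrame:
    """Prevalence per stratum of a demographic factor.

    Empty strata get ``proportion = NaN`` (not computable) rather than an
    error, mirroring how survey tables flag empty cells.
    """
    labels = pd.Series(np.asarray(labels, dtype=bool), index=by.index)
    rows = []
    levels = by.cat.categories if hasattr(by, "cat") else pd.unique(by)
    for level in levels:
        mask = by == level
        n = int(mask.sum())
        pos = int(labels[mask].sum())
        rows.append(
            {
                "stratum": level,
                "count": pos,
                "n": n,
                "proportion": pos / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
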