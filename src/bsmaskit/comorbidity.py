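"""Comorbid mental-health screening, risk ratios, and scale reliability.

Probable depression is screened with the conventional CES-D total cutoff of
16 (range 0-60); probable state anxiety with the STAI-S cutoff of 40 (range
20-80), both inclusive.  Risk ratios compare outcome risk between an exposed
and a reference stratum; a zero reference risk or empty stratum yields the
defined "not computable" state (NaN) rather than an error, matching how
such cells are flagged in epidemiological tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schemes import ratings_matrix, dichotomize
from .simulate import ITEM_NAMES

__all__ = [
    "INSTRUMENTS",
    "probable_case",
    "RiskRatioResult",
    "risk_ratio",
    "item_level_rr",
    "GroupDescriptives",
    "group_comparison",
    "cronbach_alpha",
    "demographic_rr",
]

# instrument -> (cutoff, minimum, maximum); cases are scored inclusively (>=)
INSTRUMENTS: dict[str, tuple[int, int, int]] = {
    "depression": (16, 0, 60),
    "anxiety": (40, 20, 80),
}


def probable_case(scores, instrument: str) -> np.ndarray:
    """Binary probable-case screen: score >= the instrument's cutoff."""
    if instrument not in INSTRUMENTS:
        raise ValueError(f"instrument must be one of {tuple(INSTRUMENTS)}")
    cutoff, lo, hi = INSTRUMENTS[instrument]
    arr = np.asarray(scores)
    bad = np.argwhere((arr < lo) | (arr > hi))
    if bad.size:
        i = bad.ravel()[0]
        raise ValueError(
            f"{instrument} score out of range [{lo}, {hi}] at row {i} "
            f"(value {arr.ravel()[i]})"
        )
    return arr >= cutoff


@dataclass(frozen=True)
class RiskRatioResult:
    exposed_events: int
    exposed_n: int
    unexposed_events: int
    unexposed_n: int
    rr: float  # NaN when not computable

    @property
    def computable(self) -> bool:
        return not math.isnan(self.rr)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Log-normal (Katz) confidence interval; NaN bounds if degenerate."""
        if not self.computable or 0 in (self.exposed_events, self.unexposed_events):
            return (float("nan"), float("nan"))
        se = math.sqrt(
            1 / self.exposed_events - 1 / self.exposed_n
            + 1 / self.unexposed_events - 1 / self.unexposed_n
        )
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.rr * math.exp(-z * se), self.rr * math.exp(z * se))


def risk_ratio(exposure, outcome) -> RiskRatioResult:
    """Risk ratio of a binary outcome for exposed vs unexposed."""
    e = np.asarray(exposure, dtype=bool)
    o = np.asarray(outcome, dtype=bool)
    if e.shape != o.shape:
        raise ValueError("exposure and outcome must have equal length")
    a, n1 = int((e & o).sum()), int(e.sum())
    c, n0 = int((~e & o).sum()), int((~e).sum())
    if n1 == 0 or n0 == 0 or c == 0:
        rr = float("nan")
    else:
        rr = (a / n1) / (c / n0)
    return RiskRatioResult(a, n1, c, n0, rr)


def item_level_rr(ratings, item_cutoff: int, outcome) -> pd.DataFrame:
    """Risk ratio of the outcome per symptom criterion.

    Each of the six items is dummy-coded at ``item_cutoff`` (3 or 4) and
    treated as the exposure.  Returns one row per item with the 2x2 counts
    and the RR (NaN where not computable).
    """
    crit = dichotomize(ratings_matrix(ratings), item_cutoff)
    rows = []
    for j, name in enumerate(ITEM_NAMES):
        res = risk_ratio(crit[:, j], outcome)
        rows.append(
            {
                "item": name,
                "exposed_events": res.exposed_events,
                "exposed_n": res.exposed_n,
                "unexposed_events": res.unexposed_events,
                "unexposed_n": res.unexposed_n,
                "rr": res.rr,
            }
        )
    return pd.DataFrame(rows).set_index("item")


@dataclass(frozen=True)
class GroupDescriptives:
    n_high: int
    mean_high: float
    sd_high: float
    n_rest: int
    mean_rest: float
    sd_rest: float
    t: float
    p_value: float  # one-tailed, alternative: high-risk mean greater

    @property
    def computable(self) -> bool:
        return not math.isnan(self.t)


def group_comparison(scores, high_risk) -> GroupDescriptives:
    """Descriptives and a one-tailed Welch t test, high-risk vs the rest.

    Means and SDs use the n-1 denominator.  The alternative hypothesis is
    that the high-risk group mean is greater.  Either group having fewer
    than 2 members makes the test not computable (NaN statistics).
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(high_risk, dtype=bool)
    hi, lo = scores[mask], scores[~mask]

    def _desc(x):
        if x.size == 0:
            return float("nan"), float("nan")
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else float("nan")

    mh, sh = _desc(hi)
    mr, sr = _desc(lo)
    if hi.size < 2 or lo.size < 2:
        t = p = float("nan")
    else:
        t, p = stats.ttest_ind(hi, lo, equal_var=False, alternative="greater")
        t, p = float(t), float(p)
    return GroupDescriptives(hi.size, mh, sh, lo.size, mr, sr, t, p)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item variances)/var(total)).

    Variances use the n-1 denominator.  NaN when the total-score variance
    is zero.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def demographic_rr(
    labels, factor: pd.Series, reference: str
) -> pd.DataFrame:
    """Risk ratio of scheme positivity per demographic level vs a reference.

    Mirrors prevalence tables where the reference rows (e.g. female sex,
    oldest age band) are marked "Ref" and each remaining level is compared
    against it.  NaN marks not-computable ratios (zero reference risk).
    """
    labels = np.asarray(labels, dtype=bool)
    factor = pd.Series(factor).reset_index(drop=True)
    levels = list(factor.cat.categories) if hasattr(factor, "cat") else list(
        pd.unique(factor)
    )
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    ref_mask = (factor == reference).to_numpy()
    rows = []
    for level in levels:
        if level == reference:
            rows.append({"level": level, "rr": float("nan"), "reference": True})
            continue
        mask = (factor == level).to_numpy()
        keep = mask | ref_mask
        res = risk_ratio(mask[keep], labels[keep])
        rows.append({"level": level, "rr": res.rr, "reference": False})
    return pd.DataFrame(rows).set_index("level")
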