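"""Concordance of classification schemes with the latent-class benchmark.

The data-driven benchmark codes the latent high-risk tier as positive and
the low-risk and at-risk tiers together as negative.  Each scheme's binary
labels are cross-tabulated against the benchmark and summarized by five
indices: sensitivity, specificity, positive and negative predictive value,
and overall consistency (proportion identically grouped).  Any index with a
zero denominator is reported as not computable (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schemes as _schemes

__all__ = [
    "ConfusionTable",
    "DiagnosticIndices",
    "cross_tabulate",
    "diagnostic_indices",
    "scheme_benchmark_report",
    "format_report_percent",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticIndices:
    """Each field is a proportion in [0, 1], or NaN when not computable."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    overall_consistency: float


def _as_binary(labels, name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"{name} must be binary (0/1 or bool)")
        arr = arr.astype(bool)
    return arr


def cross_tabulate(scheme_labels, benchmark_labels) -> ConfusionTable:
    """Exact 2x2 counts of scheme-positive vs benchmark (latent high-risk)."""
    s = _as_binary(scheme_labels, "scheme_labels")
    b = _as_binary(benchmark_labels, "benchmark_labels")
    if s.shape != b.shape:
        raise ValueError(
            f"label length mismatch: {s.shape[0]} scheme vs {b.shape[0]} benchmark"
        )
    return ConfusionTable(
        tp=int((s & b).sum()),
        fp=int((s & ~b).sum()),
        fn=int((~s & b).sum()),
        tn=int((~s & ~b).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_indices(ct: ConfusionTable) -> DiagnosticIndices:
    """The five concordance indices of a 2x2 table.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), overall consistency = (TP+TN)/n.  A zero denominator
    yields NaN rather than an error.
    """
    return DiagnosticIndices(
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn),
        specificity=_ratio(ct.tn, ct.tn + ct.fp),
        ppv=_ratio(ct.tp, ct.tp + ct.fp),
        npv=_ratio(ct.tn, ct.tn + ct.fn),
        overall_consistency=_ratio(ct.tp + ct.tn, ct.n),
    )


def scheme_benchmark_report(
    data, scheme_list, benchmark_labels
) -> pd.DataFrame:
    """One row of concordance indices per scheme, full precision.

    ``data`` is a cohort table (or ratings matrix); ``scheme_list`` an
    iterable of scheme names or :class:`~bsmaskit.schemes.SchemeSpec`;
    ``benchmark_labels`` the binary latent high-risk indicator.  Raw
    confusion counts are kept alongside the indices so nothing is lost to
    rounding; :func:`format_report_percent` renders the integer-percent
    presentation.
    """
    rows = []
    for scheme in scheme_list:
        spec = _schemes.SCHEMES[scheme] if isinstance(scheme, str) else scheme
        labels = _schemes.apply_scheme(data, spec)
        ct = cross_tabulate(labels, benchmark_labels)
        ind = diagnostic_indices(ct)
        rows.append(
            {
                "scheme": spec.name,
                "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn,
                "sensitivity": ind.sensitivity,
                "specificity": ind.specificity,
                "ppv": ind.ppv,
                "npv": ind.npv,
                "overall_consistency": ind.overall_consistency,
            }
        )
    return pd.DataFrame(rows).set_index("scheme")


def format_report_percent(report: pd.DataFrame) -> pd.DataFrame:
    """Render the five indices as integer percentages ('N/A' if NaN)."""
    cols = ["sensitivity", "specificity", "ppv", "npv", "overall_consistency"]
    out = report[cols].copy()
    for c in cols:
        out[c] = [
            "N/A" if np.isnan(v) else f"{round(100 * v):d}" for v in report[c]
        ]
    return out
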