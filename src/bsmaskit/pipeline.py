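"""End-to-end study pipeline: cohort -> schemes -> LPA -> concordance -> comorbidity.

:func:`run_pipeline` executes the whole workflow on a respondent table
(loaded from CSV or synthesized from a :class:`~bsmaskit.simulate.CohortSpec`)
and writes a report bundle:

* ``fit_report.csv``      — fit indices per candidate class count;
* ``selection.txt``       — the model-selection audit trail;
* ``prevalence.csv``      — counts/percentages per scheme, overall and by
  sex and age band, with demographic risk ratios;
* ``concordance.csv``     — the five indices per scheme vs the latent
  benchmark (plus raw confusion counts);
* ``descriptives.csv``    — depression/anxiety group descriptives with
  one-tailed Welch tests, per scheme and for the latent benchmark;
* ``risk_ratios.csv``     — scale-level and item-level (cutoffs 4 and 3)
  comorbidity risk ratios;
* ``profiles.csv``        — class-by-item mean matrix (plot data);
* ``assignments.csv``     — per-respondent posterior, class and risk tier;
* ``manifest.json``       — config echo, derived seeds and versions, enough
  to reproduce the bundle bit-for-bit with the same build.

Every stochastic stage consumes a deterministic child seed derived from the
master seed and a fixed stage tag, so toggling one stage does not perturb
the randomness of another.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import benchmark as _benchmark
from . import comorbidity as _comorbidity
from . import lpa as _lpa
from . import schemes as _schemes
from .simulate import (
    AGE_LEVELS,
    ITEM_COLUMNS,
    SEX_LEVELS,
    CohortSpec,
    analysis_view,
    cohort_from_csv,
    generate_cohort,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "validate_input", "stage_seed"]

# Fixed tags so each stage's seed is independent of which stages run.
_STAGE_TAGS = {"simulate": 11, "lpa": 23, "blrt": 37}

_FLOAT_FORMAT = "%.10g"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_TAGS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    input_csv: str | None = None
    spec: CohortSpec | None = None
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    scheme_names: tuple[str, ...] = _schemes.SCHEME_ORDER
    n_starts: int = 50
    n_boot: int = 20  # bootstrap LRT replicates; 0 disables the BLRT column
    tol: float = 1e-6
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.k_range = tuple(sorted(set(int(k) for k in self.k_range)))
        if not self.k_range or self.k_range[0] < 1:
            raise ValueError("k_range must be nonempty with minimum >= 1")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0 (0 disables the BLRT)")
        if (self.input_csv is None) == (self.spec is None):
            raise ValueError("exactly one of input_csv or spec must be given")
        unknown = set(self.scheme_names) - set(_schemes.SCHEMES)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")


@dataclass
class ReportBundle:
    fit_report: pd.DataFrame
    selection: _lpa.SelectionResult
    prevalence: pd.DataFrame
    concordance: pd.DataFrame
    descriptives: pd.DataFrame
    risk_ratios: pd.DataFrame
    profiles: pd.DataFrame
    assignments: pd.DataFrame
    manifest: dict
    rejections: pd.DataFrame
    partial: bool = False
    errors: list[str] = field(default_factory=list)


def validate_input(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into clean rows and a rejection log.

    Rows violating any range or category domain are rejected with a reason;
    nothing is ever imputed.  Raises if every row is rejected.
    """
    required = list(ITEM_COLUMNS) + ["sex", "age_group", "cesd_total", "stai_total"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    if len(table) == 0:
        raise ValueError("input table is empty")

    reasons = pd.Series("", index=table.index, dtype=object)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask.fillna(True) if hasattr(mask, "fillna") else mask
        reasons[mask & (reasons == "")] = reason

    for col in ITEM_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        flag(vals.isna() | (vals % 1 != 0) | (vals < 1) | (vals > 5),
             f"{col} not an integer in 1-5")
    flag(~table["sex"].astype(str).isin(SEX_LEVELS), "sex not in " + "/".join(SEX_LEVELS))
    flag(~table["age_group"].astype(str).isin(AGE_LEVELS),
         "age_group not in " + "/".join(AGE_LEVELS))
    cesd = pd.to_numeric(table["cesd_total"], errors="coerce")
    flag(cesd.isna() | (cesd < 0) | (cesd > 60), "cesd_total not in 0-60")
    stai = pd.to_numeric(table["stai_total"], errors="coerce")
    flag(stai.isna() | (stai < 20) | (stai > 80), "stai_total not in 20-80")

    bad = reasons != ""
    rejections = pd.DataFrame(
        {"row": table.index[bad], "reason": reasons[bad].to_numpy()}
    )
    clean = table[~bad].copy()
    if len(clean) == 0:
        raise ValueError(
            f"all {len(table)} rows rejected; first reason: {rejections['reason'].iloc[0]}"
        )
    for col in ITEM_COLUMNS:
        clean[col] = clean[col].astype(np.int64)
    clean["cesd_total"] = clean["cesd_total"].astype(np.int64)
    clean["stai_total"] = clean["stai_total"].astype(np.int64)
    clean["sex"] = pd.Categorical(clean["sex"].astype(str), categories=list(SEX_LEVELS))
    clean["age_group"] = pd.Categorical(
        clean["age_group"].astype(str), categories=list(AGE_LEVELS)
    )
    return clean.reset_index(drop=True), rejections


def _prevalence_table(df: pd.DataFrame, labels_by_scheme: dict[str, np.ndarray]) -> pd.DataFrame:
    """Counts, percentages and demographic RRs per scheme and stratum."""
    rows = []
    for name, labels in labels_by_scheme.items():
        pos, n, prop = _schemes.prevalence(labels)
        rows.append(
            {"scheme": name, "stratum": "total", "level": "total",
             "count": pos, "n": n, "percent": 100 * prop, "rr": np.nan,
             "reference": False}
        )
        for stratum, ref in (("sex", SEX_LEVELS[1]), ("age_group", AGE_LEVELS[-1])):
            per = _schemes.prevalence_by(labels, df[stratum])
            rrs = _comorbidity.demographic_rr(labels, df[stratum], ref)
            for _, r in per.iterrows():
                level = r["stratum"]
                rows.append(
                    {"scheme": name, "stratum": stratum, "level": level,
                     "count": r["count"], "n": r["n"],
                     "percent": 100 * r["proportion"],
                     "rr": rrs.loc[level, "rr"],
                     "reference": bool(rrs.loc[level, "reference"])}
                )
    return pd.DataFrame(rows)


def _descriptives_table(df, labels_by_scheme):
    rows = []
    for name, labels in labels_by_scheme.items():
        for outcome, col in (("depression", "cesd_total"), ("anxiety", "stai_total")):
            d = _comorbidity.group_comparison(df[col].to_numpy(), labels)
            rows.append(
                {"scheme": name, "outcome": outcome,
                 "n_high": d.n_high, "mean_high": d.mean_high, "sd_high": d.sd_high,
                 "n_rest": d.n_rest, "mean_rest": d.mean_rest, "sd_rest": d.sd_rest,
                 "t": d.t, "p_one_tailed": d.p_value}
            )
    return pd.DataFrame(rows)


def _risk_ratio_table(df, labels_by_scheme):
    cases = {
        "depression": _comorbidity.probable_case(df["cesd_total"].to_numpy(), "depression"),
        "anxiety": _comorbidity.probable_case(df["stai_total"].to_numpy(), "anxiety"),
    }
    rows = []
    for name, labels in labels_by_scheme.items():
        for outcome, case in cases.items():
            res = _comorbidity.risk_ratio(labels, case)
            rows.append(
                {"panel": "scheme", "exposure": name, "outcome": outcome,
                 "rr": res.rr}
            )
    for cutoff in (4, 3):
        for outcome, case in cases.items():
            tab = _comorbidity.item_level_rr(df, cutoff, case)
            for item, r in tab.iterrows():
                rows.append(
                    {"panel": f"item_cutoff_{cutoff}", "exposure": item,
                     "outcome": outcome, "rr": r["rr"]}
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and (if ``config.outdir`` is set) write the bundle.

    Stage failures after the LPA stage mark the bundle partial instead of
    aborting, with the failing stage recorded in ``errors``.
    """
    errors: list[str] = []

    if config.spec is not None:
        spec = dataclasses.replace(
            config.spec, seed=stage_seed(config.seed, "simulate")
        )
        raw = generate_cohort(spec)
        source = "synthetic"
    else:
        raw = cohort_from_csv(config.input_csv)
        source = str(config.input_csv)
    df, rejections = validate_input(analysis_view(raw))

    labels_by_scheme = {
        name: _schemes.apply_scheme(df, name) for name in config.scheme_names
    }

    X = df[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    fit_report, fits = _lpa.fit_profile_range(
        X, config.k_range, n_starts=config.n_starts, n_boot=config.n_boot,
        seed=stage_seed(config.seed, "lpa"), tol=config.tol,
    )
    selection = _lpa.select_model(fit_report)
    model, post = fits[selection.n_classes]
    assignment, risk_labels, high = _lpa.assign_and_label(model, post)

    profiles = pd.DataFrame(
        model.means, columns=list(ITEM_COLUMNS),
        index=pd.Index(range(model.n_classes), name="class"),
    )
    profiles.insert(0, "weight", model.weights)

    assignments = pd.DataFrame(
        {"class_index": assignment, "risk_label": risk_labels, "high_risk": high}
    )
    for k in range(model.n_classes):
        assignments[f"posterior_{k}"] = post[:, k]

    all_labels = dict(labels_by_scheme)
    all_labels["latent profile"] = high

    prevalence = _prevalence_table(df, all_labels)
    try:
        concordance = _benchmark.scheme_benchmark_report(
            df, config.scheme_names, high
        )
    except Exception as exc:  # pragma: no cover - defensive
        errors.append(f"concordance: {exc}")
        concordance = pd.DataFrame()
    try:
        descriptives = _descriptives_table(df, all_labels)
        risk_ratios = _risk_ratio_table(df, all_labels)
    except Exception as exc:  # pragma: no cover - defensive
        errors.append(f"comorbidity: {exc}")
        descriptives = pd.DataFrame()
        risk_ratios = pd.DataFrame()

    manifest = {
        "package": "bsmaskit",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "source": source,
        "n_respondents": int(len(df)),
        "n_rejected": int(len(rejections)),
        "config": {
            "k_range": list(config.k_range),
            "schemes": list(config.scheme_names),
            "n_starts": config.n_starts,
            "n_boot": config.n_boot,
            "tol": config.tol,
            "seed": config.seed,
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_TAGS},
        "selected_classes": selection.n_classes,
        "selection_audit": selection.audit,
    }

    bundle = ReportBundle(
        fit_report=fit_report,
        selection=selection,
        prevalence=prevalence,
        concordance=concordance,
        descriptives=descriptives,
        risk_ratios=risk_ratios,
        profiles=profiles,
        assignments=assignments,
        manifest=manifest,
        rejections=rejections,
        partial=bool(errors),
        errors=errors,
    )
    if config.outdir is not None:
        write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kw = {"float_format": _FLOAT_FORMAT}
    bundle.fit_report.to_csv(out / "fit_report.csv", **kw)
    bundle.prevalence.to_csv(out / "prevalence.csv", index=False, **kw)
    bundle.concordance.to_csv(out / "concordance.csv", **kw)
    bundle.descriptives.to_csv(out / "descriptives.csv", index=False, **kw)
    bundle.risk_ratios.to_csv(out / "risk_ratios.csv", index=False, **kw)
    bundle.profiles.to_csv(out / "profiles.csv", **kw)
    bundle.assignments.to_csv(out / "assignments.csv", index=False, **kw)
    bundle.rejections.to_csv(out / "rejections.csv", index=False)
    (out / "selection.txt").write_text("\n".join(bundle.selection.audit) + "\n")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")
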