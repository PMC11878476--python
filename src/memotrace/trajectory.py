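"""Per-patient trajectory features and the association analyses.

A :class:`TrajectoryRecord` summarizes one analysis patient: index dates,
the complaint-to-diagnosis interval in whole days, the number of distinct
pre-diagnosis complaint dates, whether a cognition-enhancing medication
was ordered strictly before diagnosis, the departments of the first
complaint and of the diagnosis, demographics, and the caregiver group.

Two models are fitted on these records, mirroring the study's analyses:

* a linear model of interval days on age group, insurance, both
  locations and caregiver group, with per-coefficient Wald chi-square
  tests and 95% CIs (reference levels: 85+, commercial insurance,
  primary care for both locations, husband);
* a logistic model of prior medication use on age group, both locations,
  caregiver group and the complaint count, reported as odds ratios.

Caregiver relation is missing for roughly half of real patients; rows
without it are dropped before fitting (complete-case for that factor)
and the n used is reported.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .normalize import (CAREGIVER_RELATIONS, ConceptLexicon, UNMAPPED,
                        group_caregiver)
from .phenotype import CohortResult, PatientRecord, age_group

logger = logging.getLogger(__name__)

LOCATIONS = ("geriatrics", "primary_care", "neurology", "other")
REFERENCE_LEVELS = {
    "age_group": "85+",
    "insurance": "commercial",
    "complaint_location": "primary_care",
    "dx_location": "primary_care",
    "caregiver_group": "husband",
}


@dataclass
class TrajectoryRecord:
    patient_id: str
    first_complaint_date: date
    first_dx_date: date
    interval_days: int
    n_complaints: int
    prior_med: bool
    complaint_location: str
    dx_location: str
    age_group: str
    insurance: str
    caregiver_group: Optional[str] = None

    def __post_init__(self):
        if self.interval_days < 1:
            raise ValueError(
                f"{self.patient_id}: interval_days must be >= 1 "
                f"(same-day patients are excluded upstream)")
        if self.n_complaints < 1:
            raise ValueError(f"{self.patient_id}: n_complaints must be >= 1")


_RECORD_COLUMNS = [f.name for f in fields(TrajectoryRecord)]


def records_to_frame(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=_RECORD_COLUMNS)
    df["prior_med"] = df["prior_med"].astype(int)
    return df


def build_trajectories(cohort: CohortResult, extractions: pd.DataFrame,
                       patients: Sequence[PatientRecord],
                       lexicon: Optional[ConceptLexicon] = None
                       ) -> List[TrajectoryRecord]:
    """One record per analysis patient, from phenotyper output plus the
    normalized extraction table and structured rows."""
    from .normalize import SYMPTOM_CONCEPTS
    lexicon = lexicon or ConceptLexicon.default()
    by_id = {p.patient_id: p for p in patients}
    ex = extractions.copy()
    ex["note_date"] = pd.to_datetime(ex["note_date"]).dt.date
    groups = {str(pid): g for pid, g in ex.groupby("patient_id")}
    empty = ex.iloc[0:0]
    records: List[TrajectoryRecord] = []
    for pid in cohort.analysis:
        p = by_id[pid]
        complaint, dx = cohort.index_dates[pid]
        rows = groups.get(str(pid), empty)
        sx = rows[(rows["label"] == "SX")
                  & rows["canonical"].isin(SYMPTOM_CONCEPTS)]
        n_complaints = len({d for d in sx["note_date"] if d < dx})
        # Department of the first-complaint note.
        first_sx = sx[sx["note_date"] == complaint]
        complaint_loc = (first_sx["department"].iloc[0]
                         if len(first_sx) else "other") or "other"
        # Department of the diagnosis event: the DX note on the diagnosis
        # date if any, else the visit on the structured code date.
        dx_rows = rows[(rows["label"] == "DX") & (rows["note_date"] == dx)]
        if len(dx_rows):
            dx_loc = dx_rows["department"].iloc[0] or "other"
        else:
            visit_depts = [dept for d, dept in p.visits if d == dx]
            dx_loc = visit_depts[0] if visit_depts else "other"
        # Prior medication: structured order or RX note strictly before dx.
        prior_med = any(
            d < dx and lexicon.normalize_medication(drug) != UNMAPPED
            for d, drug in p.med_orders)
        if not prior_med:
            rx = rows[(rows["label"] == "RX") & (rows["canonical"] != UNMAPPED)]
            prior_med = any(d < dx for d in rx["note_date"])
        # Caregiver group from the earliest caregiver mention.
        cg_rows = rows[(rows["label"] == "CAREGIVER_RELATION")
                       & rows["canonical"].isin(CAREGIVER_RELATIONS)]
        caregiver = None
        if len(cg_rows):
            first_cg = cg_rows.sort_values("note_date").iloc[0]
            caregiver = group_caregiver(first_cg["canonical"]).value
        records.append(TrajectoryRecord(
            patient_id=pid,
            first_complaint_date=complaint,
            first_dx_date=dx,
            interval_days=(dx - complaint).days,
            n_complaints=max(n_complaints, 1),
            prior_med=bool(prior_med),
            complaint_location=complaint_loc,
            dx_location=dx_loc,
            age_group=age_group(p.birth_year, dx),
            insurance=p.insurance,
            caregiver_group=caregiver,
        ))
    return records


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def _tukey_quartiles(values: Sequence[float]) -> Tuple[float, float]:
    """Lower/upper quartiles by the inclusive (Tukey hinge) method: the
    medians of the lower and upper halves, each half including the
    middle observation when n is odd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def describe_intervals(records: Sequence[TrajectoryRecord]) -> Dict[str, dict]:
    """Median/IQR/min/max for interval days and complaint counts."""
    if not records:
        raise ValueError("need at least one record")
    out = {}
    for name, values in (
            ("interval_days", [r.interval_days for r in records]),
            ("n_complaints", [r.n_complaints for r in records])):
        q1, q3 = _tukey_quartiles(values)
        out[name] = {
            "median": float(np.median(values)),
            "q1": q1,
            "q3": q3,
            "min": float(min(values)),
            "max": float(max(values)),
        }
    return out


# ---------------------------------------------------------------------------
# Association models
# ---------------------------------------------------------------------------

@dataclass
class EffectRow:
    factor: str
    level: str
    estimate: Optional[float]   # days (linear) or odds ratio (logistic)
    ci_low: Optional[float]
    ci_high: Optional[float]
    chi2: Optional[float]
    p: Optional[float]
    reference: bool = False


@dataclass
class AssociationResult:
    outcome: str
    model: str                  # "linear" or "logistic"
    n_used: int
    rows: List[EffectRow] = field(default_factory=list)
    separation_flag: bool = False

    def row(self, factor: str, level: str) -> EffectRow:
        for r in self.rows:
            if r.factor == factor and r.level == level:
                return r
        raise KeyError((factor, level))

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "model": self.model,
                "n_used": self.n_used,
                "separation_flag": self.separation_flag,
                "rows": [asdict(r) for r in self.rows]}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        unit = "days" if self.model == "linear" else "OR"
        lines = [f"| Factor | Level | Estimate ({unit}) | 95% CI | P |",
                 "|---|---|---|---|---|"]
        for r in self.rows:
            if r.reference:
                lines.append(f"| {r.factor} | {r.level} | Ref | — | — |")
            else:
                lines.append(
                    f"| {r.factor} | {r.level} | {r.estimate:.1f} | "
                    f"({r.ci_low:.1f} to {r.ci_high:.1f}) | {r.p:.3g} |")
        return "\n".join(lines)


_FACTORS = ("age_group", "insurance", "complaint_location", "dx_location",
            "caregiver_group")


def _formula(outcome: str, factors: Sequence[str],
             extra_terms: Sequence[str] = ()) -> str:
    terms = [
        f"C({f}, Treatment(reference={REFERENCE_LEVELS[f]!r}))"
        for f in factors
    ] + list(extra_terms)
    return f"{outcome} ~ " + " + ".join(terms)


def _levels_present(df: pd.DataFrame, factor: str) -> List[str]:
    return sorted(df[factor].dropna().unique().tolist())


def _collect_rows(fit, df: pd.DataFrame, factors: Sequence[str],
                  extra_terms: Sequence[str], exponentiate: bool
                  ) -> List[EffectRow]:
    conf = fit.conf_int()
    rows: List[EffectRow] = []
    for factor in factors:
        ref = REFERENCE_LEVELS[factor]
        for level in _levels_present(df, factor):
            if level == ref:
                rows.append(EffectRow(factor, level, None, None, None,
                                      None, None, reference=True))
                continue
            name = (f"C({factor}, Treatment(reference={ref!r}))"
                    f"[T.{level}]")
            if name not in fit.params.index:
                logger.warning("level %s/%s dropped from the fit",
                               factor, level)
                continue
            coef = float(fit.params[name])
            lo, hi = float(conf.loc[name, 0]), float(conf.loc[name, 1])
            z = coef / float(fit.bse[name])
            chi2 = z * z
            p = float(scipy.stats.chi2.sf(chi2, df=1))
            if exponentiate:
                coef, lo, hi = math.exp(coef), math.exp(lo), math.exp(hi)
            rows.append(EffectRow(factor, level, coef, lo, hi, chi2, p))
    for term in extra_terms:
        coef = float(fit.params[term])
        lo, hi = float(conf.loc[term, 0]), float(conf.loc[term, 1])
        z = coef / float(fit.bse[term])
        chi2 = z * z
        p = float(scipy.stats.chi2.sf(chi2, df=1))
        if exponentiate:
            coef, lo, hi = math.exp(coef), math.exp(lo), math.exp(hi)
        rows.append(EffectRow(term, "", coef, lo, hi, chi2, p))
    return rows


def _complete_case(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    df = records_to_frame(records)
    n_missing = int(df["caregiver_group"].isna().sum())
    if n_missing:
        logger.info("dropping %d records without caregiver information "
                    "(complete-case)", n_missing)
    return df.dropna(subset=["caregiver_group"]).copy()


def fit_interval_model(records: Sequence[TrajectoryRecord],
                       log_outcome: bool = False,
                       min_records: int = 30) -> AssociationResult:
    """Linear model of the complaint-to-diagnosis interval (days) on the
    categorical factors; per-coefficient Wald chi-square tests.

    ``log_outcome=True`` models log(interval) instead; estimates are then
    on the log-day scale.
    """
    df = _complete_case(records)
    if len(df) < min_records:
        raise ValueError(f"need >= {min_records} complete records, "
                         f"got {len(df)}")
    outcome = "interval_days"
    if log_outcome:
        df["log_interval"] = np.log(df["interval_days"])
        outcome = "log_interval"
    factors = [f for f in _FACTORS if df[f].nunique() > 1]
    # HC1 robust errors: interval spread grows with the cell mean, so
    # homoscedastic OLS errors would undercover the large-shift levels.
    fit = smf.ols(_formula(outcome, factors), data=df).fit(cov_type="HC1")
    rows = _collect_rows(fit, df, factors, (), exponentiate=False)
    return AssociationResult(outcome=outcome, model="linear",
                             n_used=len(df), rows=rows)


class _RidgeFit:
    """Minimal results shim (params/bse/conf_int) for the penalized fit."""

    def __init__(self, params: pd.Series, cov: np.ndarray):
        self.params = params
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({0: self.params - z * self.bse,
                             1: self.params + z * self.bse})


def _ridge_logit(model, alpha: float = 1.0) -> _RidgeFit:
    """L2-penalized logistic fit; covariance from the penalized Hessian.

    The intercept is not penalized.  A small ``alpha`` keeps estimates
    finite under complete separation with negligible shrinkage of
    well-identified coefficients.
    """
    X = np.asarray(model.exog)
    y = np.asarray(model.endog)
    names = model.exog_names
    pen = np.full(X.shape[1], alpha)
    pen[[i for i, n in enumerate(names) if n == "Intercept"]] = 0.0
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - 2 * pen * beta
        hess = X.T @ (X * w[:, None]) + 2 * np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    hess = X.T @ (X * (mu * (1 - mu))[:, None]) + 2 * np.diag(pen)
    cov = np.linalg.inv(hess)
    return _RidgeFit(pd.Series(beta, index=names), cov)


def fit_medication_model(records: Sequence[TrajectoryRecord]
                         ) -> AssociationResult:
    """Logistic model of prior medication use on age group, locations,
    caregiver group and complaint count; reported as odds ratios.

    Raises on a single-class outcome; flags and falls back to an
    L2-penalized fit under (near-)complete separation.
    """
    df = _complete_case(records)
    if df["prior_med"].nunique() < 2:
        raise ValueError("outcome is single-class (complete separation)")
    factors = [f for f in _FACTORS if f != "insurance"
               and df[f].nunique() > 1]
    formula = _formula("prior_med", factors, ("n_complaints",))
    separation = False
    model = smf.logit(formula, data=df)
    try:
        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(method="lbfgs", maxiter=500, disp=0)
        if not np.all(np.isfinite(fit.bse)) or np.any(
                np.abs(fit.params) > 15):
            raise sm.tools.sm_exceptions.PerfectSeparationError
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            np.linalg.LinAlgError):
        # Sparse factor cells (e.g. the tiny "other" diagnosis location)
        # can be single-class; fall back to a lightly ridge-penalized fit
        # with Wald CIs from the penalized Hessian.
        separation = True
        logger.warning("separation detected; using L2-penalized logistic fit")
        fit = _ridge_logit(model, alpha=1.0)
    rows = _collect_rows(fit, df, factors, ("n_complaints",),
                         exponentiate=True)
    return AssociationResult(outcome="prior_med", model="logistic",
                             n_used=len(df), rows=rows,
                             separation_flag=separation)


def write_trajectories_csv(records: Sequence[TrajectoryRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_report(records: Sequence[TrajectoryRecord], out_dir) -> dict:
    """Render descriptives + both models to JSON and Markdown files."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    desc = describe_intervals(records)
    results = {"descriptives": desc}
    # The association models need enough complete-case records; small
    # cohorts still get descriptives plus an explanatory stub.
    try:
        interval = fit_interval_model(records)
        results["interval_model"] = interval.to_dict()
    except ValueError as exc:
        interval = None
        results["interval_model"] = {"error": str(exc)}
    try:
        medication = fit_medication_model(records)
        results["medication_model"] = medication.to_dict()
    except ValueError as exc:
        medication = None
        results["medication_model"] = {"error": str(exc)}
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2)
    md = [
        "# Complaint-to-diagnosis trajectory report",
        "",
        f"Analysis patients: {len(records)}",
        "",
        "## Interval and complaint-count distribution",
        "",
        "```json",
        json.dumps(desc, indent=2),
        "```",
        "",
        "## Time-interval model (days)",
        "",
        interval.to_markdown() if interval else
        f"Not fitted: {results['interval_model']['error']}",
        "",
        "## Prior-medication model (odds ratios)",
        "",
        medication.to_markdown() if medication else
        f"Not fitted: {results['medication_model']['error']}",
        "",
    ]
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write("\n".join(md))
    return results
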