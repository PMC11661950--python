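"""Aligning daily metrics to weekly assessments and fitting the model suite.

Each assessment covers the 6 days preceding it plus the assessment day.  A
day with data is used at most once: when consecutive windows overlap it goes
to the nearest assessment date (ties to the earlier one).  Windowed features
are unweighted means over the assigned days, with per-metric pairwise
deletion of missing days.

The model suite (random intercepts nested in participants, REML,
Satterthwaite F-tests on the focal slope, all time-varying predictors
group-mean centered):

    1   relative interaction  ~ self-report index
    2-5 relative interaction / mean log duration / centrality / clustering ~ time
    6-9 PANSS total ~ relative interaction / mean log duration / centrality / clustering
    10  PANSS total ~ self-report index

Model 6 is additionally screened for influential observations by Cook's
distance (threshold 4/n by default); both the original and the screened fit
are reported.  Optional person-constant medication covariates
(olanzapine-equivalent dose at study start and end) enter grand-mean
centered, since group-mean centering would annihilate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wardsense.errors import ValidationError
from wardsense.mixedmodel import (
    RandomInterceptFit,
    cooks_outliers,
    fit_random_intercept,
    satterthwaite_ftest,
)

METRIC_COLUMNS = [
    "relative_interaction_time",
    "mean_log_duration",
    "eigenvector_centrality",
    "clustering",
]

MODEL_SPECS: dict[int, tuple[str, str]] = {
    1: ("relative_interaction_time", "self_report_index"),
    2: ("relative_interaction_time", "time"),
    3: ("mean_log_duration", "time"),
    4: ("eigenvector_centrality", "time"),
    5: ("clustering", "time"),
    6: ("panss_total", "relative_interaction_time"),
    7: ("panss_total", "mean_log_duration"),
    8: ("panss_total", "eigenvector_centrality"),
    9: ("panss_total", "clustering"),
    10: ("panss_total", "self_report_index"),
}

DEFAULT_WINDOW_DAYS = 7


def assign_days_to_assessments(
    days: list, assessment_dates: list, window_days: int = DEFAULT_WINDOW_DAYS
) -> dict:
    """Map each day with data to at most one assessment (for one participant).

    A day is eligible for an assessment dated d when it falls in
    [d - (window_days - 1), d].  Among eligible assessments the nearest date
    wins; exact ties go to the earlier assessment.  Days eligible for none
    map to None.
    """
    dates = pd.to_datetime(pd.Series(list(assessment_dates)))
    if dates.duplicated().any():
        raise ValidationError("duplicate assessment dates for one participant")
    dates = dates.sort_values(ignore_index=True)
    out = {}
    for day in days:
        d = pd.Timestamp(day)
        deltas = (dates - d).dt.days
        eligible = dates[(deltas >= 0) & (deltas <= window_days - 1)]
        if eligible.empty:
            out[day] = None
            continue
        dist = (eligible - d).dt.days.abs()
        best = eligible[dist == dist.min()].min()  # tie -> earlier date
        out[day] = best.strftime("%Y-%m-%d")
    return out


def window_features(
    daily: pd.DataFrame,
    assessments: pd.DataFrame,
    metrics: list[str] | None = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Per-assessment unweighted means of daily metrics.

    ``daily`` has columns participant, day and metric columns; ``assessments``
    has participant and date.  Missing metric values on a day are omitted
    pairwise (per metric); a (participant, date) with no assigned days is
    absent from the output.  Output columns: participant, date, the metric
    means, n_days_used (days assigned with any data) and per-metric counts
    n_<metric>.
    """
    metrics = metrics or [c for c in METRIC_COLUMNS if c in daily.columns]
    rows = []
    for participant, a_grp in assessments.groupby("participant", sort=True):
        d_grp = daily[daily["participant"] == participant]
        if d_grp.empty:
            continue
        mapping = assign_days_to_assessments(
            d_grp["day"].tolist(), a_grp["date"].tolist(), window_days
        )
        assigned = d_grp.assign(_a=d_grp["day"].map(mapping)).dropna(subset=["_a"])
        for date, w in assigned.groupby("_a"):
            row = {"participant": participant, "date": date, "n_days_used": len(w)}
            for m in metrics:
                vals = w[m].dropna()
                row[m] = vals.mean() if len(vals) else np.nan
                row[f"n_{m}"] = len(vals)
            rows.append(row)
    cols = ["participant", "date", "n_days_used"] + [x for m in metrics for x in (m, f"n_{m}")]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["participant", "date"], ignore_index=True
    )


def center_within_participant(
    df: pd.DataFrame, columns: list[str], group: str = "participant"
) -> pd.DataFrame:
    """Subtract each participant's own mean from the named columns."""
    out = df.copy()
    for c in columns:
        out[c] = df[c] - df.groupby(group)[c].transform("mean")
    return out


def add_time_variable(data: pd.DataFrame) -> pd.DataFrame:
    """'time' = days since the participant's first observation."""
    out = data.copy()
    d = pd.to_datetime(out["date"])
    out["time"] = (d - d.groupby(out["participant"]).transform("min")).dt.days.astype(float)
    return out


def assemble_analysis_table(features: pd.DataFrame, assessments: pd.DataFrame) -> pd.DataFrame:
    """Join windowed features with the assessment table on (participant, date)."""
    merged = features.merge(assessments, on=["participant", "date"], how="inner")
    return add_time_variable(merged)


@dataclass
class ModelFit:
    """One fitted model of the suite, in reporting form."""

    model: int
    outcome: str
    predictor: str
    beta0: float
    beta1: float
    se1: float
    random_intercept_var: float
    residual_var: float
    F: float
    df_den: float
    p_value: float
    n_obs: int
    n_participants: int
    singular: bool
    variant: str = "primary"
    excluded: list = field(default_factory=list)
    covariates: tuple = ()
    fit: RandomInterceptFit | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "variant": self.variant,
            "outcome": self.outcome,
            "predictor": self.predictor,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se1": self.se1,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "F": self.F,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "singular": self.singular,
            "n_excluded": len(self.excluded),
            "covariates": ",".join(self.covariates),
        }


def _is_person_constant(data: pd.DataFrame, col: str) -> bool:
    return bool((data.groupby("participant")[col].nunique(dropna=False) <= 1).all())


def fit_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
    model_id: int = 0,
    variant: str = "primary",
    exclude_rows: np.ndarray | None = None,
) -> ModelFit:
    """Fit one random-intercept model with the suite's centering conventions."""
    cols = ["participant", outcome, predictor, *covariates]
    d = data[cols].dropna().reset_index(drop=True)
    if exclude_rows is not None and len(exclude_rows):
        keep = np.setdiff1d(np.arange(len(d)), np.asarray(exclude_rows))
        d = d.iloc[keep].reset_index(drop=True)
    preds = [predictor, *covariates]
    for c in preds:
        if _is_person_constant(d, c):
            d[c] = d[c] - d[c].mean()  # group-mean centering would zero it
        else:
            d[c] = d[c] - d.groupby("participant")[c].transform("mean")
    X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(float) for c in preds])
    fit = fit_random_intercept(
        d[outcome].to_numpy(float), X, d["participant"].to_numpy(), ["Intercept", *preds]
    )
    test = satterthwaite_ftest(fit, predictor)
    return ModelFit(
        model=model_id,
        outcome=outcome,
        predictor=predictor,
        beta0=float(fit.beta[0]),
        beta1=test.estimate,
        se1=test.se,
        random_intercept_var=fit.sigma2_b,
        residual_var=fit.sigma2_e,
        F=test.F,
        df_den=test.df_den,
        p_value=test.p_value,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        singular=fit.singular,
        variant=variant,
        covariates=tuple(covariates),
        fit=fit,
    )


def run_model_suite(
    data: pd.DataFrame,
    models: list[int] | None = None,
    medication: bool = False,
    cooks_threshold: float | None = None,
    screen_model: int | None = 6,
) -> tuple[pd.DataFrame, dict]:
    """Fit the requested models (default all ten) on the assembled table.

    Returns (results table, dict of ModelFit by key).  Failures of individual
    models are recorded as rows with NaN statistics and do not stop the
    suite.  When ``screen_model`` is fitted, a Cook's-distance-screened refit
    is reported alongside it under variant 'screened'.  With ``medication``,
    olanzapine_mg_start/olanzapine_mg_end join every PANSS model as
    grand-mean-centered fixed covariates of no interest.
    """
    if "time" not in data.columns:
        data = add_time_variable(data)
    models = models or sorted(MODEL_SPECS)
    results: dict = {}
    rows = []
    for m in models:
        outcome, predictor = MODEL_SPECS[m]
        covs: tuple[str, ...] = ()
        if medication and outcome == "panss_total":
            covs = ("olanzapine_mg_start", "olanzapine_mg_end")
        try:
            mf = fit_model(data, outcome, predictor, covs, model_id=m)
        except (ValidationError, KeyError) as err:
            rows.append(
                {"model": m, "variant": "primary", "outcome": outcome, "predictor": predictor,
                 "error": str(err)}
            )
            continue
        results[m] = mf
        rows.append(mf.to_row())
        if m == screen_model and mf.fit is not None:
            flagged = cooks_outliers(mf.fit, cooks_threshold)
            if len(flagged):
                mf2 = fit_model(
                    data, outcome, predictor, covs, model_id=m,
                    variant="screened", exclude_rows=flagged,
                )
                mf2.excluded = list(map(int, flagged))
            else:
                mf2 = ModelFit(**{**mf.__dict__, "variant": "screened"})
            results[f"{m}s"] = mf2
            rows.append(mf2.to_row())
    return pd.DataFrame(rows), results


def run_subscale_suite(
    data: pd.DataFrame, cooks_threshold: float | None = None
) -> pd.DataFrame:
    """Directionality check: the PANSS models per subscale (supplementary table)."""
    rows = []
    for subscale in ("panss_positive", "panss_negative", "panss_general"):
        if subscale not in data.columns:
            continue
        for m in (6, 7, 8, 9):
            _, predictor = MODEL_SPECS[m]
            try:
                mf = fit_model(data, subscale, predictor, model_id=m, variant=subscale)
            except ValidationError as err:
                rows.append({"model": m, "variant": subscale, "error": str(err)})
                continue
            rows.append(mf.to_row())
    return pd.DataFrame(rows)
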