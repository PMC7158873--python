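"""Linear mixed-effects group comparison of tract-averaged metrics.

For each metric the model

    value ~ age + gender + group + timepoint
            + (1 | subject) + (1 | subject:hemisphere)

is fit by REML: fixed effects of age (years), gender (F = 0, M = 1), group
(control = 0, patient = 1) and timepoint (baseline = 0, after surgery = 1),
a random intercept per subject, and a random hemisphere-within-subject
intercept.  Hemisphere itself is not a fixed effect; it enters only through
the random term, encoded ipsi/contra in patients and left/right in
controls.  Significance uses the Wald statistic of each fixed effect with a
normal reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .cohort_sim import METRICS

__all__ = ["FixedEffectEstimates", "build_long_table", "fit_mixed_model", "sign_pattern"]

FIXED_EFFECTS = ("Intercept", "group", "timepoint", "gender", "age")

_PATIENT_HEMIS = {"ipsi", "contra"}
_CONTROL_HEMIS = {"left", "right"}


@dataclass
class FixedEffectEstimates:
    """Estimates, standard errors and Wald statistics per fixed effect."""

    metric: str
    table: pd.DataFrame  # index: effect; columns: estimate, se, tvalue, pvalue
    hemisphere_term_dropped: bool = False
    variance_components: dict = field(default_factory=dict)  # subject/hemisphere/residual

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def build_long_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Validate and tidy a long-format metric observation table.

    Expects columns subject, group, timepoint, hemisphere, age, gender,
    metric, value.  Enforces the hemisphere encoding (ipsi/contra for
    patients, left/right for controls), drops rows with missing covariates
    with a warning, and returns the cleaned table.
    """
    required = {"subject", "group", "timepoint", "hemisphere", "age", "gender", "metric", "value"}
    missing_cols = required - set(observations.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    df = observations.copy()

    bad_patient = (df["group"] == "patient") & ~df["hemisphere"].isin(_PATIENT_HEMIS)
    bad_control = (df["group"] == "control") & ~df["hemisphere"].isin(_CONTROL_HEMIS)
    if bad_patient.any() or bad_control.any():
        raise ValueError(
            "hemisphere must be ipsi/contra for patients and left/right for controls"
        )
    incomplete = df[["subject", "group", "timepoint", "hemisphere", "age", "gender", "metric"]].isna().any(axis=1)
    incomplete |= ~np.isfinite(df["value"].astype(float))
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} rows with missing covariates or values")
        df = df[~incomplete]
    return df.reset_index(drop=True)


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["group_code"] = (df["group"] == "patient").astype(float)
    df["timepoint_code"] = (df["timepoint"] == "after_surgery").astype(float)
    df["gender_code"] = (df["gender"] == "M").astype(float)
    return df


def fit_mixed_model(table: pd.DataFrame, metric: str) -> FixedEffectEstimates:
    """REML fit of the group-comparison mixed model for one metric.

    Falls back to a subject-intercept-only model (flagged) when the
    hemisphere variance component makes the fit singular.
    """
    df = table[table["metric"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    for group in ("patient", "control"):
        if df.loc[df["group"] == group, "subject"].nunique() < 2:
            raise ValueError(f"need at least 2 {group} subjects")
    patients = df[df["group"] == "patient"]
    if patients["timepoint"].nunique() < 2:
        raise ValueError("patients must have both baseline and after-surgery rows")
    df = _encode(df)

    formula = "value ~ age + gender_code + group_code + timepoint_code"
    dropped = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula,
                df,
                groups="subject",
                re_formula="1",
                vc_formula={"hemisphere": "0 + C(hemisphere)"},
            )
            fit = model.fit(reml=True, method="lbfgs")
            singular = not np.all(np.isfinite(fit.bse_fe)) or np.any(np.isnan(fit.params))
        except (np.linalg.LinAlgError, ValueError):
            singular = True
        if singular:
            dropped = True
            model = smf.mixedlm(formula, df, groups="subject", re_formula="1")
            fit = model.fit(reml=True)

    rename = {
        "Intercept": "Intercept",
        "age": "age",
        "gender_code": "gender",
        "group_code": "group",
        "timepoint_code": "timepoint",
    }
    rows = {}
    for name, label in rename.items():
        est = fit.params[name]
        se = fit.bse[name]
        t = est / se if se > 0 else np.nan
        rows[label] = {
            "estimate": est,
            "se": se,
            "tvalue": t,
            "pvalue": fit.pvalues[name],
        }
    out = pd.DataFrame(rows).T.loc[list(FIXED_EFFECTS)]
    vc = {
        "subject": float(np.asarray(fit.cov_re).ravel()[0]),
        "residual": float(fit.scale),
    }
    if not dropped and len(fit.vcomp):
        vc["hemisphere"] = float(fit.vcomp[0])
    return FixedEffectEstimates(
        metric=metric, table=out, hemisphere_term_dropped=dropped, variance_components=vc
    )


def fit_all_metrics(table: pd.DataFrame, metrics=METRICS) -> dict:
    """Convenience: one mixed-model fit per metric."""
    return {m: fit_mixed_model(table, m) for m in metrics}


def sign_pattern(estimates: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Classify group/timepoint effects per metric as up/down/null.

    Returns a DataFrame indexed by metric with columns 'group' and
    'timepoint' containing 'up', 'down' or '-' (not significant at alpha).
    """
    missing = [m for m in METRICS if m not in estimates]
    if missing:
        raise ValueError(f"estimates missing metrics: {missing}")
    rows = {}
    for metric in METRICS:
        est = estimates[metric]
        cells = {}
        for contrast in ("group", "timepoint"):
            e = est[contrast]
            if e["pvalue"] < alpha:
                cells[contrast] = "up" if e["estimate"] > 0 else "down"
            else:
                cells[contrast] = "-"
        rows[metric] = cells
    return pd.DataFrame(rows).T.loc[list(METRICS), ["group", "timepoint"]]
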