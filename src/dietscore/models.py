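"""Repeated cross-sectional logistic models and baseline descriptives.

Each cell of the outcome grid (outcome x survey x index x adjustment) is a
separate maximum-likelihood logistic regression of a 0/1 outcome on
diet-quality exposure categories, with the lowest quintile (Q1) as
reference.  Odds ratios are exponentiated coefficients with 95% Wald
confidence intervals exp(b +/- 1.96 SE).  Adjusted models add the fixed
covariate set (age centred continuous; the categorical covariates
dummy-coded); depression/anxiety and multimorbidity models additionally
adjust for depression/anxiety history, and mortality models for NCD
presence.  Mortality uses the collapsed Q4+5 exposure coding.

Failures are reported, never hidden: separation or non-convergence flags
the cell, zero cases yields an explicit inestimable result, and a singular
design raises naming the collinear columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exposure import ExposureAssignment, assignments_to_series
from . import outcomes as oc

Z_95 = 1.959963984540054

SOCIODEMOGRAPHIC = ("age", "area", "marital", "education", "occupation", "income_manage")
LIFESTYLE = ("smoking", "physical_activity", "prescribed_med", "otc_med")
DEFAULT_COVARIATES = SOCIODEMOGRAPHIC + LIFESTYLE

OUTCOMES = oc.CONDITION_GROUPS + ("multimorbidity", "mortality")
INDICES = ("HEIFA-2013", "MDS", "AHEI-2010")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    wave: int
    index: str
    adjusted: bool
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    extra_covariates: tuple[str, ...] = ()
    exposure_coding: str = "quintiles_ref_Q1"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure_coding not in ("quintiles_ref_Q1", "collapsed_ref_Q1"):
            raise ValueError(f"unknown exposure coding {self.exposure_coding!r}")


def make_spec(outcome: str, wave: int, index: str, adjusted: bool) -> ModelSpec:
    """The study's model specification for one grid cell: mortality uses
    the collapsed coding and the NCD-presence covariate; dep_anx and
    multimorbidity add the depression/anxiety history covariate."""
    extra: tuple[str, ...] = ()
    coding = "quintiles_ref_Q1"
    if outcome == "mortality":
        coding = "collapsed_ref_Q1"
        if adjusted:
            extra = ("ncd_present", "dep_anx_history")
    elif outcome in ("dep_anx", "multimorbidity") and adjusted:
        extra = ("dep_anx_history",)
    return ModelSpec(outcome, wave, index, adjusted, extra_covariates=extra, exposure_coding=coding)


@dataclass(frozen=True)
class ModelResult:
    spec: ModelSpec
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_used: int
    n_cases: int
    converged: bool
    message: str = ""

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.odds_ratio)


def _inestimable(spec, labels, n_used, n_cases, message) -> list[ModelResult]:
    return [
        ModelResult(spec, f"{lab} vs Q1", np.nan, np.nan, np.nan, n_used, n_cases, False, message)
        for lab in labels
    ]


def _design(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    df = pd.DataFrame({"_y": outcome})
    df = df.join(exposure.rename("_exposure"), how="inner")
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    y = df["_y"].astype(float)
    levels = [c for c in df["_exposure"].cat.categories if c != "Q1"]
    X = pd.get_dummies(df["_exposure"], prefix="exp", dtype=float).drop(columns=["exp_Q1"])
    X = X[[f"exp_{lev}" for lev in levels]]
    if covariates is not None:
        for col in covariates.columns:
            s = df[col]
            if pd.api.types.is_numeric_dtype(s):
                X[col] = s.astype(float) - s.astype(float).mean()
            else:
                dummies = pd.get_dummies(s, prefix=col, dtype=float)
                X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    X.insert(0, "const", 1.0)
    return y, X, levels


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(X.columns) * np.finfo(float).eps * 1e3
    return [c for c, d in zip(X.columns, diag) if d < tol]


def fit_quintile_logistic(
    outcome: pd.Series,
    exposure: Sequence[ExposureAssignment] | pd.Series,
    covariates: pd.DataFrame | None,
    spec: ModelSpec,
) -> list[ModelResult]:
    """Fit one cell; returns one ModelResult per non-reference exposure
    level (Q2..Q5, or Q2/Q3/Q4+5 under the collapsed coding)."""
    if not isinstance(exposure, pd.Series):
        exposure = assignments_to_series(exposure, collapsed=spec.exposure_coding == "collapsed_ref_Q1")
    y, X, levels = _design(outcome, exposure, covariates)
    n_used = int(len(y))
    n_cases = int(y.sum())
    if n_used == 0 or n_cases == 0 or n_cases == n_used:
        return _inestimable(spec, levels, n_used, n_cases, "no cases (or no non-cases)")

    # levels with no observations cannot be contrasted (and would make the
    # design singular); report them as inestimable and fit without them
    empty_levels = [lev for lev in levels if not (X[f"exp_{lev}"] == 1.0).any()]
    if empty_levels:
        X = X.drop(columns=[f"exp_{lev}" for lev in empty_levels])
        fitted = fit_quintile_logistic(
            outcome,
            exposure.cat.remove_categories(empty_levels)
            if hasattr(exposure, "cat")
            else exposure,
            covariates,
            spec,
        )
        fitted += _inestimable(spec, empty_levels, n_used, n_cases, "no observations in level")
        return fitted

    # a level with zero cases (or zero non-cases) separates perfectly
    sep_levels = set()
    for lev in levels:
        in_level = X[f"exp_{lev}"] == 1.0
        if in_level.any() and (y[in_level].sum() in (0.0, float(in_level.sum()))):
            sep_levels.add(lev)
    ref = X[[f"exp_{lev}" for lev in levels]].sum(axis=1) == 0
    ref_degenerate = y[ref].sum() in (0.0, float(ref.sum()))

    collinear = _collinear_columns(X)
    if collinear:
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {collinear}")

    if ref_degenerate or sep_levels == set(levels):
        return _inestimable(spec, levels, n_used, n_cases, "separation: empty exposure cells")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        message = "" if converged else "did not converge"
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return _inestimable(spec, levels, n_used, n_cases, f"fit failed: {exc}")

    results = []
    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    for lev in levels:
        col = f"exp_{lev}"
        if lev in sep_levels or not np.isfinite(bse[col]) or bse[col] > 1e3:
            results.append(
                ModelResult(
                    spec, f"{lev} vs Q1", np.nan, np.nan, np.nan, n_used, n_cases, False,
                    "separation in this exposure level",
                )
            )
            continue
        b, se = params[col], bse[col]
        results.append(
            ModelResult(
                spec,
                f"{lev} vs Q1",
                float(np.exp(b)),
                float(np.exp(b - Z_95 * se)),
                float(np.exp(b + Z_95 * se)),
                n_used,
                n_cases,
                converged,
                message,
            )
        )
    return results


def _outcome_vector(status, deaths, spec: ModelSpec, sample: pd.Index) -> pd.Series:
    if spec.outcome == "multimorbidity":
        return oc.multimorbidity_outcome(status, spec.wave, sample)
    if spec.outcome == "mortality":
        return oc.mortality_outcome(deaths, spec.wave, sample)
    return oc.incident_outcome(status, spec.wave, spec.outcome, sample)


def _covariate_frame(
    panel: pd.DataFrame, wave: int, covariates: Iterable[str], carry_forward: bool = False
) -> pd.DataFrame:
    if carry_forward:
        # last observed value at or before the wave (mortality cases cannot
        # report covariates at the outcome wave)
        sub = (
            panel[panel["wave"] <= wave]
            .sort_values("wave")
            .groupby("participant_id")
            .last()
        )
    else:
        sub = panel[panel["wave"] == wave].set_index("participant_id")
    return sub[[c for c in covariates]]


def run_survey_series(
    status,
    panel: pd.DataFrame,
    exposures: dict[str, Sequence[ExposureAssignment]],
    deaths: Iterable["oc.DeathRecord"],
    sample: pd.Index,
    outcomes_to_run: Sequence[str] = OUTCOMES,
    waves: Sequence[int] = oc.OUTCOME_WAVES,
    adjusted_variants: Sequence[bool] = (False, True),
) -> pd.DataFrame:
    """Fit the full grid: waves x outcomes x indices x {univariate,
    multivariate}.  Exposure is the fixed S3 assignment for every wave; a
    failed cell is recorded, never fatal.  Returns a tidy results table."""
    deaths = list(deaths)
    rows = []
    for outcome_name in outcomes_to_run:
        for wave in waves:
            for index_name, assigns in exposures.items():
                for adjusted in adjusted_variants:
                    spec = make_spec(outcome_name, wave, index_name, adjusted)
                    try:
                        y = _outcome_vector(status, deaths, spec, sample)
                        exp_series = assignments_to_series(
                            assigns, collapsed=spec.exposure_coding == "collapsed_ref_Q1"
                        )
                        cov = None
                        if adjusted:
                            cov = _covariate_frame(
                                panel,
                                wave,
                                spec.covariates,
                                carry_forward=spec.outcome == "mortality",
                            )
                            if "dep_anx_history" in spec.extra_covariates:
                                cov = cov.join(
                                    status.dep_anx_history(wave).rename("dep_anx_history")
                                )
                            if "ncd_present" in spec.extra_covariates:
                                cov = cov.join(
                                    status.ever_any_ncd(wave).rename("ncd_present")
                                )
                        cell = fit_quintile_logistic(y, exp_series, cov, spec)
                    except Exception as exc:  # a failed cell never aborts the grid
                        cell = _inestimable(spec, ["Q5"], 0, 0, f"cell failed: {exc}")
                    for r in cell:
                        rows.append(
                            {
                                "outcome": spec.outcome,
                                "wave": spec.wave,
                                "index": spec.index,
                                "adjusted": spec.adjusted,
                                "contrast": r.contrast,
                                "odds_ratio": r.odds_ratio,
                                "ci_low": r.ci_low,
                                "ci_high": r.ci_high,
                                "n_used": r.n_used,
                                "n_cases": r.n_cases,
                                "converged": r.converged,
                                "message": r.message,
                            }
                        )
    return pd.DataFrame(rows)


def describe_baseline(
    exposure: pd.Series,
    panel_baseline: pd.DataFrame,
    groups: tuple[str, str] = ("Q1", "Q5"),
    continuous: tuple[str, ...] = ("age",),
) -> pd.DataFrame:
    """Baseline characteristics by exposure group with the stated tests.

    Continuous characteristics report mean (sd) per group with a one-way
    ANOVA p-value; categorical ones report n (%) per level with a
    chi-squared p-value.  Low expected counts are flagged, not fatal.
    """
    df = panel_baseline.set_index("participant_id").join(exposure.rename("_g"), how="inner")
    df = df[df["_g"].astype(str).isin(groups)]
    rows = []
    for col in [c for c in panel_baseline.columns if c not in ("participant_id", "wave")]:
        if col in continuous:
            samples = [df.loc[df["_g"].astype(str) == g, col].dropna() for g in groups]
            if all(len(s) > 1 for s in samples):
                _, p = st.f_oneway(*samples)
            else:
                p = np.nan
            row = {"characteristic": col, "level": "", "test": "anova", "p_value": float(p)}
            for g, s in zip(groups, samples):
                row[g] = f"{s.mean():.2f} ({s.std():.2f})"
            rows.append(row)
        else:
            table = pd.crosstab(df[col], df["_g"].astype(str))
            table = table[[g for g in groups if g in table.columns]]
            warning = ""
            if table.size and table.to_numpy().sum() > 0:
                chi2, p, _, expected = st.chi2_contingency(table)
                if (expected < 5).any():
                    warning = "expected count < 5"
            else:
                p = np.nan
            for level in table.index:
                row = {
                    "characteristic": col,
                    "level": str(level),
                    "test": "chi2",
                    "p_value": float(p),
                    "warning": warning,
                }
                for g in groups:
                    n = int(table.loc[level, g]) if g in table.columns else 0
                    denom = int(table[g].sum()) if g in table.columns else 0
                    pct = 100.0 * n / denom if denom else np.nan
                    row[g] = f"{n} ({pct:.1f})"
                rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < 0.05
    return out
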