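"""EWAS designs: cross-sectional, prediction-of-change, repeat mixed-model.

Each design regresses a lung-function outcome (FEV1, FVC, or their ratio)
on one technical-bias-adjusted methylation predictor at a time, adjusted for
the base covariate model: age, age squared, height, squared deviation of
height from its analysis-sample mean, sex, the four sex interactions,
education, BMI, spirometer type, study centre and seven cell fractions
(M_base); the smoking-adjusted variant (M_smok) adds smoking status and
pack-years. The prediction design regresses annualized change on baseline
methylation, additionally adjusted for baseline lung function. The repeat
design is a random-intercept (subject) linear mixed model over both
timepoints fitted by REML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meta import p_from_estimate

log = logging.getLogger(__name__)

OUTCOMES = ("fev1", "fvc", "fev1_fvc")
DESIGNS = ("cross_sectional_t1", "cross_sectional_t2", "predict_change",
           "repeat")


@dataclass(frozen=True)
class ModelSpec:
    """Which EWAS to fit: covariate model, population, design, outcome."""

    model: str = "base"                     # 'base' | 'smok'
    population: str = "all"                 # 'all' | 'never_smokers'
    design: str = "cross_sectional_t2"
    outcome: str = "fev1_fvc"

    def __post_init__(self) -> None:
        if self.model not in ("base", "smok"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.population not in ("all", "never_smokers"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.model == "smok" and self.population == "never_smokers":
            raise ValueError(
                "smoking-adjusted model is undefined in never-smokers "
                "(smoking covariates are constant)")


def outcome_vector(phenotypes: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "fev1_fvc":
        return phenotypes["fev1"] / phenotypes["fvc"]
    if outcome in ("fev1", "fvc"):
        return phenotypes[outcome]
    raise ValueError(f"unknown outcome {outcome!r}")


def _dummies(series: pd.Series, prefix: str,
             order: tuple | None = None) -> pd.DataFrame:
    """Dummy-code with the first observed level as reference."""
    observed = set(series.dropna().unique())
    levels = ([lv for lv in order if lv in observed] if order is not None
              else sorted(observed))
    return pd.DataFrame(
        {f"{prefix}_{lv}": (series == lv).astype(float) for lv in levels[1:]},
        index=series.index)


def build_design(phenotypes: pd.DataFrame, cell_fractions: pd.DataFrame,
                 spec: ModelSpec) -> pd.DataFrame:
    """Covariate design matrix for one analysis sample (rows = samples).

    ``phenotypes`` must hold one row per sample (indexed by sample_id) and
    already be restricted to the analysis population; ``cell_fractions`` is
    samples x cell types. Constant and aliased columns are dropped with a
    logged warning; the squared height deviation uses the analysis-sample
    mean.
    """
    ph = phenotypes
    if ph.empty:
        raise ValueError("empty analysis sample")
    if outcome_vector(ph, spec.outcome).isna().all():
        raise ValueError(f"outcome {spec.outcome} missing for all samples")
    cf = cell_fractions.loc[ph.index]

    age = ph["age"].astype(float)
    height = ph["height"].astype(float)
    sex = ph["sex"].astype(float)
    hdev2 = (height - height.mean()) ** 2
    x = pd.DataFrame(index=ph.index)
    x["const"] = 1.0
    x["age"] = age
    x["age_sq"] = age ** 2
    x["height"] = height
    x["height_dev_sq"] = hdev2
    x["sex"] = sex
    x["sex_x_age"] = sex * age
    x["sex_x_age_sq"] = sex * age ** 2
    x["sex_x_height"] = sex * height
    x["sex_x_height_dev_sq"] = sex * hdev2
    edu = _dummies(ph["education"], "edu",
                   order=("low", "intermediate", "high"))
    for col in edu:
        x[col] = edu[col]
    x["bmi"] = ph["bmi"].astype(float)
    for block in ("spirometer", "centre"):
        d = _dummies(ph[block], block)
        for col in d:
            x[col] = d[col]
    for c in cf.columns:
        x[f"cell_{c}"] = cf[c].astype(float)

    if spec.model == "smok":
        statuses = set(ph["smoking_status"].dropna().unique())
        if len(statuses) < 2:
            raise ValueError(
                "smoking-adjusted model requires variation in smoking "
                f"status; sample has only {sorted(statuses)}")
        x["smoke_ex"] = (ph["smoking_status"] == "ex").astype(float)
        x["smoke_current"] = (ph["smoking_status"] == "current").astype(float)
        x["pack_years"] = ph["pack_years"].astype(float)

    # drop constant columns (single-level categoricals), keep intercept
    const_cols = [c for c in x.columns
                  if c != "const" and x[c].nunique(dropna=False) <= 1]
    if const_cols:
        log.info("dropping constant columns: %s", const_cols)
        x = x.drop(columns=const_cols)
    # drop aliased columns until full column rank
    while np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        for j in range(x.shape[1] - 1, 0, -1):
            sub = x.drop(columns=x.columns[j])
            if np.linalg.matrix_rank(sub.to_numpy()) == sub.shape[1] - 0:
                log.warning("dropping aliased column %s", x.columns[j])
                x = sub
                break
        else:                                        # pragma: no cover
            raise ValueError("design matrix irreparably rank deficient")
    return x


def cross_sectional_ewas(residuals: pd.DataFrame, outcome: pd.Series,
                         design: pd.DataFrame, use_t: bool = False
                         ) -> pd.DataFrame:
    """Per-probe covariate-adjusted OLS of outcome on methylation residual.

    Equivalent to, per probe, OLS of outcome on [design, probe residual];
    coefficient, SE and two-sided p (normal approximation by default; exact
    t with ``use_t``) are reported for the probe term. Probes with zero
    variance or too few complete observations are skipped with a log entry.
    """
    if list(residuals.columns) != list(design.index):
        raise ValueError("residuals and design cover different samples")
    if not outcome.index.equals(design.index):
        raise ValueError("outcome and design cover different samples")
    x = design.to_numpy()
    y = outcome.to_numpy(dtype=float)
    m = residuals.to_numpy()
    n, k = x.shape

    rows = {}
    skipped = 0
    ok_y = ~np.isnan(y)
    complete = ~np.isnan(m).any(axis=1)
    if not ok_y.all():
        complete &= False                           # route all through loop

    def _fit(idx: np.ndarray, mi: np.ndarray):
        xs, ys = x[idx], y[idx]
        q, _ = np.linalg.qr(xs)
        yt = ys - q @ (q.T @ ys)
        mt = mi[idx] - q @ (q.T @ mi[idx])
        mm = float(mt @ mt)
        if mm <= 1e-14 or len(ys) <= k + 1:
            return None
        slope = float(mt @ yt) / mm
        rss = float(yt @ yt) - slope ** 2 * mm
        df = len(ys) - k - 1
        # exact fits leave zero residual; keep SE positive so the p-value
        # saturates at the underflow-safe minimum instead of erroring
        se = max(np.sqrt(max(rss, 0.0) / df / mm), np.finfo(float).tiny)
        return slope, se, df, len(ys)

    if complete.any():
        q, _ = np.linalg.qr(x)
        yt = y - q @ (q.T @ y)
        mc = m[complete]
        mt = mc - (mc @ q) @ q.T
        mm = np.einsum("ij,ij->i", mt, mt)
        good = mm > 1e-14
        slope = np.where(good, (mt @ yt) / np.where(good, mm, 1.0), np.nan)
        rss = float(yt @ yt) - slope ** 2 * mm
        df = n - k - 1
        if df <= 0:
            raise ValueError("more covariates than samples")
        se = np.maximum(
            np.sqrt(np.maximum(rss, 0.0) / df / np.where(good, mm, 1.0)),
            np.finfo(float).tiny)
        for i, probe in enumerate(residuals.index[complete]):
            if not good[i]:
                skipped += 1
                continue
            rows[probe] = (slope[i], se[i], df, n)

    for i in np.where(~complete)[0]:
        idx = ~np.isnan(m[i]) & ok_y
        fit = _fit(idx, np.nan_to_num(m[i]))
        if fit is None:
            skipped += 1
            continue
        rows[residuals.index[i]] = fit

    if skipped:
        log.info("cross_sectional_ewas: skipped %d probes", skipped)
    if not rows:
        return pd.DataFrame(columns=["beta", "se", "p", "n"])
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["beta", "se", "df", "n"])
    out = out.loc[[p for p in residuals.index if p in out.index]]
    if use_t:
        from scipy.stats import t as t_dist
        out["p"] = 2.0 * t_dist.sf(np.abs(out["beta"] / out["se"]),
                                   out["df"])
    else:
        out["p"] = p_from_estimate(out["beta"].to_numpy(),
                                   out["se"].to_numpy())
    out.attrs["design_columns"] = list(design.columns)
    return out[["beta", "se", "p", "n"]]


def annual_change(lf_t1, lf_t2, follow_up_years):
    """(value at t2 - value at t1) / follow-up, per year."""
    fu = np.asarray(follow_up_years, dtype=float)
    if (fu <= 0).any():
        raise ValueError("follow-up must be positive")
    return (np.asarray(lf_t2, dtype=float)
            - np.asarray(lf_t1, dtype=float)) / fu


def prediction_ewas(residuals_t1: pd.DataFrame, lf_t1: pd.Series,
                    lf_t2: pd.Series, follow_up_years: pd.Series,
                    design: pd.DataFrame, use_t: bool = False
                    ) -> pd.DataFrame:
    """Baseline methylation predicting annualized lung-function change.

    Outcome is the annual change between timepoints; the design is augmented
    with baseline lung function (column ``baseline_lf``), then fitted as a
    cross-sectional EWAS on the timepoint-1 residuals.
    """
    if "baseline_lf" in design.columns:
        raise ValueError("design already contains a baseline_lf column")
    change = pd.Series(
        annual_change(lf_t1.loc[design.index], lf_t2.loc[design.index],
                      follow_up_years.loc[design.index]),
        index=design.index)
    aug = design.copy()
    aug["baseline_lf"] = lf_t1.loc[design.index].astype(float)
    return cross_sectional_ewas(residuals_t1, change, aug, use_t=use_t)


def repeat_ewas(residuals: pd.DataFrame, outcome: pd.Series,
                design: pd.DataFrame, groups: pd.Series,
                maxiter: int = 200) -> pd.DataFrame:
    """Random-intercept linear mixed model over both timepoints, per probe.

    Fitted by REML; the methylation predictor is time-varying (the residual
    at the concurrent timepoint); the Wald z test of its fixed effect is
    reported. Non-converged or degenerate probes are excluded with a log
    entry. Subjects with a single record are retained (the mixed model
    tolerates imbalance).
    """
    if list(residuals.columns) != list(design.index):
        raise ValueError("residuals and design cover different samples")
    counts = groups.loc[design.index].value_counts()
    if (counts > 2).any():
        raise ValueError("a subject contributes more than two records")
    x = design.to_numpy()
    y = outcome.loc[design.index].to_numpy(dtype=float)
    g = groups.loc[design.index].to_numpy()
    rows = {}
    skipped = 0
    for probe in residuals.index:
        mi = residuals.loc[probe].to_numpy(dtype=float)
        ok = ~np.isnan(mi) & ~np.isnan(y)
        if ok.sum() <= x.shape[1] + 2 or np.nanstd(mi[ok]) <= 1e-12:
            skipped += 1
            continue
        exog = np.column_stack([x[ok], mi[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y[ok], exog, groups=g[ok])
                fit = model.fit(reml=True, maxiter=maxiter)
            if not np.isfinite(fit.bse_fe[-1]):
                raise ValueError("undefined standard error")
        except Exception:                            # noqa: BLE001
            skipped += 1
            continue
        beta, se = float(fit.fe_params[-1]), float(fit.bse_fe[-1])
        rows[probe] = (beta, se, p_from_estimate(beta, se), int(ok.sum()))
    if skipped:
        log.info("repeat_ewas: skipped %d probes", skipped)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["beta", "se", "p", "n"])
    out.attrs["design_columns"] = list(design.columns)
    return out
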