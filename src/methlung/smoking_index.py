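"""Multi-CpG methylation smoking indices and their lung-function association.

An index is the equal-weight mean of direction-aligned z-scored methylation
residuals over a signed CpG set: probes hypomethylated with smoking carry
sign '-' and are flipped so that a higher score always means a more
smoking-like methylation profile. The index is evaluated by covariate-
adjusted association with lung function (cross-sectional and predicting
annual change, meta-analysed across cohorts), by adjusted-R^2 variance
decomposition against self-reported smoking history, and by its
covariate-adjusted distribution across smoking strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta as meta_mod
from .ewas import annual_change

log = logging.getLogger(__name__)


@dataclass
class CpGSet:
    """Signed probe set: '-' marks probes hypomethylated with smoking."""

    probe_ids: list[str]
    signs: list[str]
    label: str = "mediation"
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in CpG set")
        if set(self.signs) - {"+", "-"}:
            raise ValueError("signs must be '+' or '-'")
        if len(self.signs) != len(self.probe_ids):
            raise ValueError("signs and probe ids lengths differ")
        if self.weights is not None and len(self.weights) != len(
                self.probe_ids):
            raise ValueError("weights and probe ids lengths differ")


@dataclass
class SmokingIndex:
    """Per-sample scalar score with stored standardization parameters."""

    scores: pd.Series
    cpg_set: CpGSet
    used_probes: list[str]
    standardization: pd.DataFrame = field(repr=False)  # mean/sd per probe

    def score_new(self, residuals: pd.DataFrame) -> pd.Series:
        """Score new samples with the stored standardization parameters."""
        z = []
        for probe in self.used_probes:
            row = (residuals.loc[probe]
                   - self.standardization.loc[probe, "mean"]) \
                / self.standardization.loc[probe, "sd"]
            z.append(row * self.standardization.loc[probe, "orient"]
                     * self.standardization.loc[probe, "weight"])
        total_w = self.standardization.loc[self.used_probes, "weight"].sum()
        return sum(z) / total_w


def build_index(residuals: pd.DataFrame, cpg_set: CpGSet) -> SmokingIndex:
    """Direction-aligned mean of z-scored residuals over the set's probes.

    Requires at least half the set's probes present in the matrix; missing
    probes are logged and skipped.
    """
    present = [p for p in cpg_set.probe_ids if p in residuals.index]
    if len(present) < len(cpg_set.probe_ids) / 2:
        raise ValueError(
            f"only {len(present)}/{len(cpg_set.probe_ids)} set probes "
            "present in the residual matrix")
    missing = set(cpg_set.probe_ids) - set(present)
    if missing:
        log.info("build_index: %d probes missing: %s", len(missing),
                 sorted(missing))
    sign_of = dict(zip(cpg_set.probe_ids, cpg_set.signs))
    weight_of = (dict(zip(cpg_set.probe_ids, cpg_set.weights))
                 if cpg_set.weights is not None
                 else {p: 1.0 for p in cpg_set.probe_ids})
    rows = []
    scores = pd.Series(0.0, index=residuals.columns)
    total_w = 0.0
    for probe in present:
        vals = residuals.loc[probe].astype(float)
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd <= 0:
            raise ValueError(f"probe {probe} has zero variance")
        orient = -1.0 if sign_of[probe] == "-" else 1.0
        w = weight_of[probe]
        scores = scores + orient * w * (vals - mu) / sd
        total_w += w
        rows.append(dict(probe_id=probe, mean=mu, sd=sd, orient=orient,
                         weight=w))
    scores = scores / total_w
    return SmokingIndex(
        scores=scores, cpg_set=cpg_set, used_probes=present,
        standardization=pd.DataFrame(rows).set_index("probe_id"))


def _index_regression(index_vals: pd.Series, outcome: pd.Series,
                      design: pd.DataFrame) -> tuple[float, float, int]:
    """OLS of outcome on [design, index]; returns (beta, se, n)."""
    x = np.column_stack([design.to_numpy(),
                         index_vals.loc[design.index].to_numpy()])
    y = outcome.loc[design.index].to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x).any(axis=1)
    x, y = x[ok], y[ok]
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = len(y) - x.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    return float(coef[-1]), float(np.sqrt(sigma2 * xtx_inv[-1, -1])), len(y)


def index_association(per_cohort: list[dict], stratum: str, design: str
                      ) -> pd.DataFrame:
    """Meta-analysed association of the index with lung function.

    ``per_cohort`` entries hold cohort_id, index (Series), outcome (Series,
    already the annual change for the prediction design), and the covariate
    design matrix (baseline-adjusted for prediction). Single-cohort input
    returns that cohort's regression unchanged (meta identity).
    """
    if stratum not in ("all", "ever", "never"):
        raise ValueError(f"unknown stratum {stratum!r}")
    results, order = [], []
    for entry in per_cohort:
        if entry["design"].empty:
            raise ValueError(f"empty stratum for {entry['cohort_id']}")
        beta, se, n = _index_regression(entry["index"], entry["outcome"],
                                        entry["design"])
        results.append(pd.DataFrame(
            {"beta": [beta], "se": [se], "n": [n]}, index=["index"]))
        order.append(entry["cohort_id"])
    pooled = meta_mod.ivw_meta(results, order)
    pooled.attrs["stratum"] = stratum
    pooled.attrs["design"] = design
    return pooled


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    r2 = 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    n, p = x.shape
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p))   # p includes const


def variance_decomposition(outcome: pd.Series, base_design: pd.DataFrame,
                           index_vals: pd.Series,
                           smoking_covariates: pd.DataFrame) -> pd.DataFrame:
    """Adjusted-R^2 of nested models and the increment of each added block.

    Models: base; base+index; base+smoking (status dummies and pack-years,
    i.e. the smoking-adjusted covariate model); base+smoking+index. The
    increment column attributes the gain to the last-added block.
    """
    idx = base_design.index
    if not (index_vals.index.is_unique and smoking_covariates.index.is_unique):
        raise ValueError("duplicate sample ids")
    try:
        iv = index_vals.loc[idx].to_numpy(dtype=float)
        sc = smoking_covariates.loc[idx].to_numpy(dtype=float)
        y = outcome.loc[idx].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError("samples differ across nested models") from exc
    xb = base_design.to_numpy()
    ok = ~(np.isnan(y) | np.isnan(iv) | np.isnan(xb).any(axis=1)
           | np.isnan(sc).any(axis=1))
    y, iv, sc, xb = y[ok], iv[ok], sc[ok], xb[ok]

    r2_base = _adjusted_r2(y, xb)
    r2_base_index = _adjusted_r2(y, np.column_stack([xb, iv]))
    r2_smok = _adjusted_r2(y, np.column_stack([xb, sc]))
    r2_smok_index = _adjusted_r2(y, np.column_stack([xb, sc, iv]))
    rows = [
        ("M_base", r2_base, np.nan),
        ("M_base+index", r2_base_index, r2_base_index - r2_base),
        ("M_smok", r2_smok, r2_smok - r2_base),
        ("M_smok+index", r2_smok_index, r2_smok_index - r2_smok),
    ]
    return pd.DataFrame(rows, columns=["model", "adj_r2", "increment"]
                        ).set_index("model")


def adjusted_group_distribution(index_vals: pd.Series, grouping: pd.Series,
                                adjustment: pd.DataFrame) -> pd.DataFrame:
    """Covariate-adjusted index distribution per group.

    The index is residualized on the adjustment covariates (grouping
    excluded), the grand mean added back, and each group summarized by
    median, quartiles and 1.5-IQR whisker bounds.
    """
    groups = grouping.dropna()
    if groups.nunique() < 2:
        raise ValueError("need at least two grouping levels")
    idx = groups.index.intersection(index_vals.index)
    x = adjustment.loc[idx].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("adjustment covariates are collinear")
    g_dummies = pd.get_dummies(groups.loc[idx]).to_numpy(dtype=float)
    both = np.column_stack([x, g_dummies[:, 1:]])
    if np.linalg.matrix_rank(both) < both.shape[1]:
        raise ValueError("grouping is collinear with the adjustment set")
    y = index_vals.loc[idx].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    adj = y - x @ coef + y.mean()
    frame = pd.DataFrame({"group": groups.loc[idx].to_numpy(),
                          "adjusted": adj})
    out = []
    for name, sub in frame.groupby("group", sort=True):
        q1, med, q3 = np.percentile(sub["adjusted"], [25, 50, 75])
        iqr = q3 - q1
        out.append(dict(group=name, n=len(sub), median=med, q1=q1, q3=q3,
                        whisker_low=q1 - 1.5 * iqr,
                        whisker_high=q3 + 1.5 * iqr))
    return pd.DataFrame(out).set_index("group")
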