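"""Technical-bias adjustment and cell-composition estimation.

The methylation predictor used by every downstream association model is not
the raw beta-value but the residual of a per-probe linear regression of
beta-values on the first principal components of the array's control-probe
intensities; those components capture batch and technical structure shared
between control probes and CpGs. Blood cell-type fractions are estimated by
constrained projection of each sample onto a cell-type reference panel
(Houseman-style deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA

from .simulate import CellRefPanel


@dataclass
class PCScores:
    """samples x components control-probe PC scores."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def control_probe_pcs(control: pd.DataFrame, n_components: int = 30
                      ) -> PCScores:
    """Principal-component scores of the column-centered control matrix.

    ``control`` is control probes x samples, positive intensities, no
    missing values. Each probe is centered across samples (no scaling:
    control probes share an intensity scale); components are ordered by
    decreasing explained variance.
    """
    if control.isna().to_numpy().any():
        raise ValueError("control matrix contains missing values")
    n_probes, n_samples = control.shape
    max_comp = min(n_samples - 1, n_probes)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds achievable maximum "
            f"{max_comp} for {n_samples} samples x {n_probes} control probes")
    x = control.to_numpy().T                      # samples x probes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCScores(
        scores=pd.DataFrame(scores, index=control.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def residualize_methylation(beta: pd.DataFrame, pcs: PCScores
                            ) -> pd.DataFrame:
    """Per-probe OLS residuals of beta-values on intercept + PC scores.

    Probes with missing values get a complete-case fit; samples must match
    the PC scores exactly (same set, same order). The result is the
    technical-bias-adjusted methylation predictor (probes x samples,
    unbounded, per-probe mean ~ 0).
    """
    if list(beta.columns) != list(pcs.scores.index):
        raise ValueError("beta and PC scores cover different samples")
    s = pcs.scores.to_numpy()
    design = np.column_stack([np.ones(len(s)), s])
    b = beta.to_numpy()
    resid = np.full_like(b, np.nan, dtype=float)
    complete = ~np.isnan(b).any(axis=1)
    if complete.any():
        y = b[complete].T                          # samples x probes
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid[complete] = (y - design @ coef).T
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(b[i])
        if ok.sum() > design.shape[1]:
            coef, *_ = np.linalg.lstsq(design[ok], b[i, ok], rcond=None)
            resid[i, ok] = b[i, ok] - design[ok] @ coef
    return pd.DataFrame(resid, index=beta.index, columns=beta.columns)


def _solve_sum_to_one(a: np.ndarray, y: np.ndarray,
                      tol: float = 1e-10) -> np.ndarray:
    """min ||a w - y|| s.t. w >= 0, sum w = 1 (active-set on the KKT system).

    Zeroed coordinates are added while the equality-constrained solution
    goes negative and released while their multiplier violates dual
    feasibility; cell-type counts are small, so this converges in a few
    steps.
    """
    k = a.shape[1]
    ata, aty = a.T @ a, a.T @ y
    free = np.ones(k, dtype=bool)
    w = np.full(k, 1.0 / k)
    for _ in range(4 * k):
        idx = np.where(free)[0]
        m = len(idx)
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = ata[np.ix_(idx, idx)]
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        sol = np.linalg.solve(kkt, np.append(aty[idx], 1.0))
        w_free, lam = sol[:m], sol[m]
        if (w_free < -tol).any():
            free[idx[np.argmin(w_free)]] = False
            continue
        w = np.zeros(k)
        w[idx] = np.maximum(w_free, 0.0)
        mult = ata @ w - aty + lam        # KKT multipliers on zeroed coords
        violated = ~free & (mult < -tol)
        if violated.any():
            free[np.argmin(np.where(violated, mult, np.inf))] = True
            continue
        return w
    return w                               # pragma: no cover


def estimate_cell_fractions(beta: pd.DataFrame, panel: CellRefPanel,
                            constraint: str = "nonneg-sum-to-one"
                            ) -> pd.DataFrame:
    """Reference-based cell-fraction estimates (samples x cell types).

    Per sample, weights minimize the squared deviation from panel @ w under
    the chosen constraint: ``nonneg`` (w >= 0) or the default
    ``nonneg-sum-to-one`` (w >= 0, sum w = 1).
    """
    if constraint not in ("nonneg", "nonneg-sum-to-one"):
        raise ValueError(f"unknown constraint {constraint!r}")
    probes = panel.profiles.index.intersection(beta.index)
    counts_ok = len(probes) >= 2 * panel.profiles.shape[1]
    if len(probes) < 2 or not counts_ok:
        raise ValueError("too few reference probes overlap the beta matrix")
    a = panel.profiles.loc[probes].to_numpy()
    b = beta.loc[probes].to_numpy()
    out = np.empty((beta.shape[1], a.shape[1]))
    for j in range(beta.shape[1]):
        if constraint == "nonneg":
            out[j], _ = nnls(a, b[:, j])
        else:
            out[j] = _solve_sum_to_one(a, b[:, j])
    return pd.DataFrame(out, index=beta.columns,
                        columns=list(panel.cell_types))
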