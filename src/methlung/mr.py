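"""Generic two-sample Mendelian randomization on summary statistics.

Per instrument the Wald ratio divides the SNP->outcome effect by the
SNP->exposure effect (first-order delta-method SE); instruments are pooled
by inverse-variance weighting. Inputs are assumed pre-selected (no pruning
or clumping here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import p_from_estimate

INSTRUMENT_COLUMNS = ["instrument_id", "exposure_beta", "exposure_se",
                      "outcome_beta", "outcome_se", "cpg_id"]


def wald_ratio(bx: float, sx: float, by: float, sy: float
               ) -> tuple[float, float]:
    """Causal estimate by/bx with SE sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4)."""
    if bx == 0:
        raise ValueError("exposure effect is zero: instrument undefined")
    if sx < 0 or sy <= 0:
        raise ValueError("standard errors must be positive")
    est = by / bx
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return float(est), float(se)


@dataclass
class MRResult:
    estimate: float
    se: float
    p: float
    n_instruments: int
    per_instrument: pd.DataFrame


def ivw_mr(instruments: pd.DataFrame) -> MRResult:
    """IVW pooling of per-instrument Wald ratios.

    ``instruments`` needs columns exposure_beta/exposure_se/outcome_beta/
    outcome_se and unique instrument identifiers (index or instrument_id).
    A single instrument returns its Wald ratio unchanged.
    """
    if len(instruments) == 0:
        raise ValueError("empty instrument table")
    ids = (instruments["instrument_id"] if "instrument_id" in instruments
           else instruments.index.to_series())
    if ids.duplicated().any():
        raise ValueError("duplicate instrument identifiers")
    ratios = []
    for _, row in instruments.iterrows():
        est, se = wald_ratio(row["exposure_beta"], row["exposure_se"],
                             row["outcome_beta"], row["outcome_se"])
        ratios.append((est, se))
    per = pd.DataFrame(ratios, columns=["wald_ratio", "se"],
                       index=pd.Index(ids, name="instrument_id"))
    w = 1.0 / per["se"] ** 2
    est = float((w * per["wald_ratio"]).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return MRResult(estimate=est, se=se, p=p_from_estimate(est, se),
                    n_instruments=len(per), per_instrument=per)
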