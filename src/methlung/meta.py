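"""Fixed-effect inverse-variance-weighted meta-analysis and replication.

Cohort-level EWAS estimates are pooled with weights 1/SE^2 (METAL-style
fixed-effect meta-analysis); Cochran's Q quantifies between-study
heterogeneity; the genomic inflation factor lambda diagnoses systematic
test-statistic inflation (reported, never used to rescale). Discovery
sentinels (p < 5e-7) are forwarded to a replication gate: an
outcome-specific Bonferroni threshold plus (by default) direction
concordance with discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

CHI2_1_MEDIAN = chi2.ppf(0.5, 1)          # 0.4549364...
TINY_P = np.nextafter(0.0, 1.0)


def p_from_estimate(beta, se):
    """Two-sided normal p from an estimate and its standard error.

    Computed through the log-space normal survival function so extreme z
    never underflows to exactly zero.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    logp = np.log(2.0) + norm.logsf(np.abs(beta / se))
    p = np.maximum(np.exp(logp), TINY_P)
    return float(p) if p.ndim == 0 else p


def ivw_meta(results: list[pd.DataFrame], cohort_order: list[str]
             ) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect pooling across cohorts.

    ``results[i]`` is the EWAS table (index probe_id; columns beta, se, n)
    of ``cohort_order[i]``. Output per probe: pooled beta/se/p, Cochran Q
    with chi2(k-1) heterogeneity p, a direction string with one character
    per cohort ('+', '-', or '?' when the probe is absent), and the number
    of contributing cohorts. Probes absent everywhere are absent here.
    """
    if len(results) != len(cohort_order):
        raise ValueError("results and cohort_order lengths differ")
    if len(results) == 0:
        raise ValueError("no cohorts to meta-analyse")
    probes: list = []
    seen = set()
    for r in results:
        for probe in r.index:
            if probe not in seen:
                seen.add(probe)
                probes.append(probe)
    k = len(results)
    beta = np.full((len(probes), k), np.nan)
    se = np.full((len(probes), k), np.nan)
    ns = np.zeros((len(probes), k))
    pos = {probe: i for i, probe in enumerate(probes)}
    for j, r in enumerate(results):
        idx = [pos[probe] for probe in r.index]
        beta[idx, j] = r["beta"].to_numpy(dtype=float)
        se[idx, j] = r["se"].to_numpy(dtype=float)
        if "n" in r:
            ns[idx, j] = r["n"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 / se**2
    have = np.isfinite(beta) & np.isfinite(w)
    w = np.where(have, w, 0.0)
    b0 = np.where(have, beta, 0.0)
    wsum = w.sum(axis=1)
    pooled = (w * b0).sum(axis=1) / wsum
    pooled_se = 1.0 / np.sqrt(wsum)
    q = (w * (b0 - pooled[:, None]) ** 2).sum(axis=1)
    kk = have.sum(axis=1)
    het_p = np.where(kk > 1, chi2.sf(q, np.maximum(kk - 1, 1)), 1.0)
    direction = [
        "".join("?" if not have[i, j] else ("+" if beta[i, j] >= 0 else "-")
                for j in range(k))
        for i in range(len(probes))]
    out = pd.DataFrame({
        "beta": pooled, "se": pooled_se,
        "p": p_from_estimate(pooled, pooled_se),
        "q": q, "het_p": het_p, "direction": direction,
        "k": kk, "n": ns.sum(axis=1, where=have).astype(int),
    }, index=pd.Index(probes, name="probe_id"))
    out.attrs["cohort_order"] = list(cohort_order)
    return out


def genomic_lambda(p_values=None, z=None) -> float:
    """Genomic inflation factor: median observed chi2(1) / null median."""
    if z is not None:
        stats = np.asarray(z, dtype=float) ** 2
    elif p_values is not None:
        p = np.asarray(p_values, dtype=float)
        stats = chi2.isf(p, 1)
    else:
        raise ValueError("provide p_values or z")
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class SentinelSet:
    """Probes passing the discovery threshold for one outcome."""

    outcome: str
    probes: list[str]
    threshold: float
    discovery_sign: dict[str, float] = field(default_factory=dict)


def select_sentinels(meta: pd.DataFrame, outcome: str,
                     threshold: float = 5e-7) -> SentinelSet:
    """Discovery sentinels: probes with meta p strictly below threshold."""
    hits = meta[meta["p"] < threshold].sort_values("p")
    return SentinelSet(
        outcome=outcome, probes=list(hits.index), threshold=threshold,
        discovery_sign={probe: float(np.sign(hits.loc[probe, "beta"]))
                        for probe in hits.index})


def replication_gate(sentinels: SentinelSet, replication_meta: pd.DataFrame,
                     alpha: float = 0.05, require_concordance: bool = True
                     ) -> pd.DataFrame:
    """Outcome-specific Bonferroni replication of discovery sentinels.

    The threshold is alpha divided by the number of sentinels for the
    outcome; a sentinel replicates when its replication p falls below the
    threshold and (by default) its sign is concordant with discovery.
    """
    if not sentinels.probes:
        raise ValueError("empty sentinel set: replication threshold "
                         "undefined")
    threshold = bonferroni_threshold(alpha, len(sentinels.probes))
    rows = []
    for probe in sentinels.probes:
        if probe in replication_meta.index:
            rp = float(replication_meta.loc[probe, "p"])
            rsign = float(np.sign(replication_meta.loc[probe, "beta"]))
        else:
            rp, rsign = np.nan, np.nan
        concordant = rsign == sentinels.discovery_sign[probe]
        replicated = bool(np.isfinite(rp) and rp < threshold
                          and (concordant or not require_concordance))
        rows.append(dict(probe_id=probe, replication_p=rp,
                         threshold=threshold, sign_concordant=concordant,
                         replicated=replicated))
    return pd.DataFrame(rows).set_index("probe_id")


def combine_meta(discovery_results: list[pd.DataFrame],
                 replication_results: list[pd.DataFrame],
                 discovery_cohorts: list[str],
                 replication_cohorts: list[str]) -> pd.DataFrame:
    """IVW over the concatenated cohort-level results of both stages.

    By weight additivity this equals a single IVW over all cohorts (never an
    IVW of the two pooled estimates). Cohort sets must be disjoint.
    """
    overlap = set(discovery_cohorts) & set(replication_cohorts)
    if overlap:
        raise ValueError(f"cohorts in both stages: {sorted(overlap)}")
    return ivw_meta(discovery_results + replication_results,
                    discovery_cohorts + replication_cohorts)


def to_metal_table(meta: pd.DataFrame) -> pd.DataFrame:
    """METAL-style output columns for interoperability."""
    return pd.DataFrame({
        "MarkerName": meta.index,
        "Effect": meta["beta"].to_numpy(),
        "StdErr": meta["se"].to_numpy(),
        "P-value": meta["p"].to_numpy(),
        "Direction": meta["direction"].to_numpy(),
        "HetQ": meta["q"].to_numpy(),
        "HetPVal": meta["het_p"].to_numpy(),
        "N_cohorts": meta["k"].to_numpy(),
    })
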