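"""Synthetic multi-cohort, two-timepoint methylation/spirometry generator.

The generator emulates the data structure a blood-methylation EWAS of lung
function assumes: beta-values in [0, 1] produced on the logit scale, latent
technical factors loading on both control probes and CpGs (so control-probe
PCA can remove them), Dirichlet cell-composition mixing against a reference
panel, smoking-dose-dependent hypomethylation at designated CpGs, and
FEV1/FVC outcomes receiving a direct smoking effect plus effects mediated
through methylation. Every dataset carries a ground-truth effect table so
downstream recovery can be tested.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig

EDUCATION_LEVELS = ("low", "intermediate", "high")
SMOKING_STATUS = ("never", "ex", "current")


@dataclass
class CellRefPanel:
    """Reference methylation profiles of blood cell types.

    profiles: discriminating probes x cell types, beta scale in [0, 1],
    linearly independent across cell types.
    """

    cell_types: tuple[str, ...]
    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("reference profiles must lie in [0, 1]")


@dataclass
class CohortDataset:
    """One cohort: methylation, control probes, phenotypes, annotation.

    ``beta`` and ``control`` are probes x samples; one sample per
    subject-timepoint. ``latent`` holds per-sample ground truth (effective
    smoking dose, cell fractions, technical factors) used only for
    validation, never by the analysis itself.
    """

    cohort_id: str
    beta: pd.DataFrame
    control: pd.DataFrame
    phenotypes: pd.DataFrame
    annotation: pd.DataFrame
    latent: pd.DataFrame


def _check_effect_table(effects: pd.DataFrame) -> pd.DataFrame:
    if effects["probe_id"].duplicated().any():
        raise ValueError("duplicate probe in effect table")
    null = effects["is_null"]
    if ((effects.loc[null, "smoking_effect"] != 0).any()
            or (effects.loc[null, "outcome_effect"] != 0).any()):
        raise ValueError("null probes must carry zero effects")
    return effects


def simulate_reference_panel(config: SimulationConfig) -> CellRefPanel:
    """Build a full-rank cell-type reference panel.

    Each cell type owns a block of discriminating probes that are highly
    methylated in that type and lowly methylated elsewhere, plus mild
    probe-level jitter; the block structure makes the profile matrix
    full column rank by construction.
    """
    if config.n_cell_types < 2:
        raise ValueError("reference panel needs at least 2 cell types")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11]))
    k, m = config.n_cell_types, config.n_ref_probes
    if m < k:
        raise ValueError("need at least one discriminating probe per type")
    profiles = np.full((m, k), 0.15)
    blocks = np.array_split(np.arange(m), k)
    for j, idx in enumerate(blocks):
        profiles[idx, j] = 0.85
    profiles += rng.uniform(-0.08, 0.08, size=profiles.shape)
    profiles = np.clip(profiles, 0.02, 0.98)
    probe_ids = [f"cgref{i:05d}" for i in range(m)]
    return CellRefPanel(
        cell_types=config.cell_types,
        profiles=pd.DataFrame(profiles, index=probe_ids,
                              columns=list(config.cell_types)),
    )


def _probe_truth(config: SimulationConfig, panel: CellRefPanel):
    """Probe-level ground truth shared by every cohort of a study."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 23]))
    n_ref = config.n_ref_probes
    n_cpg = config.n_cpgs
    probe_ids = list(panel.profiles.index) + [
        f"cg{i:07d}" for i in range(n_cpg - n_ref)]
    if n_cpg <= n_ref:
        raise ValueError("n_cpgs must exceed n_ref_probes")

    mu = rng.normal(0.0, 1.5, size=n_cpg)           # logit baselines
    n_free = n_cpg - n_ref
    # sparse technical-factor loadings on non-reference CpGs
    load = rng.normal(0.0, config.technical_loading_sd,
                      size=(n_free, config.n_technical_factors))
    load *= rng.random(load.shape) < config.technical_sparsity
    # mild cell-composition loadings on non-reference CpGs
    cell_load = rng.normal(0.0, config.cell_loading_sd,
                           size=(n_free, config.n_cell_types))

    n_smoke = int(round(config.smoking_cpg_fraction * n_cpg))
    smoke_idx = n_ref + np.arange(min(n_smoke, n_free))
    smoking_effect = np.zeros(n_cpg)
    smoking_effect[smoke_idx] = (
        config.smoking_meth_slope * rng.uniform(0.5, 1.5, size=len(smoke_idx)))
    # smoking CpGs sit near baseline logit 0 so the dose effect is visible
    mu[smoke_idx] = rng.normal(0.0, 0.4, size=len(smoke_idx))

    if config.mediated_cpg_ids is not None:
        med_ids = list(config.mediated_cpg_ids)
        med_idx = np.array([probe_ids.index(p) for p in med_ids], dtype=int)
    else:
        med_idx = smoke_idx[: config.n_mediated_cpgs]
    outcome_effect = np.zeros(n_cpg)
    if len(med_idx):
        outcome_effect[med_idx] = (
            config.meth_outcome_slope * rng.uniform(0.75, 1.25,
                                                    size=len(med_idx)))

    control_base = rng.uniform(1500.0, 4000.0, size=config.n_control_probes)
    control_load = rng.normal(0.0, config.control_loading_sd,
                              size=(config.n_control_probes,
                                    config.n_technical_factors))

    is_mediator = np.zeros(n_cpg, dtype=bool)
    is_mediator[med_idx] = True
    effects = pd.DataFrame({
        "probe_id": probe_ids,
        "smoking_effect": smoking_effect,
        "outcome_effect": outcome_effect,
        "is_mediator": is_mediator,
        "is_null": (smoking_effect == 0) & (outcome_effect == 0),
        "baseline_logit": mu,
    })
    annotation = pd.DataFrame({
        "probe_id": probe_ids,
        "chr": [str(1 + i % 22) for i in range(n_cpg)],
        "pos": 1 + 997 * np.arange(n_cpg),           # 1-based
        "gene": [f"GENE{i // 4:05d}" for i in range(n_cpg)],
    })
    return dict(probe_ids=probe_ids, mu=mu, load=load, cell_load=cell_load,
                effects=_check_effect_table(effects), annotation=annotation,
                control_base=control_base, control_load=control_load,
                smoke_idx=smoke_idx, med_idx=np.asarray(med_idx, dtype=int))


def _dose(status: np.ndarray, pack_years: np.ndarray,
          years_since_quit: np.ndarray, half_life: float) -> np.ndarray:
    """Effective smoking dose: pack-years, decayed for ex-smokers."""
    dose = np.where(status == "current", pack_years, 0.0)
    ex = status == "ex"
    if half_life <= 0:
        raise ValueError("quit half-life must be positive")
    decay = np.exp(-np.log(2.0) * np.nan_to_num(years_since_quit) / half_life)
    return np.where(ex, pack_years * decay, dose)


def simulate_cohort(config: SimulationConfig, panel: CellRefPanel,
                    cohort_id: str, cohort_index: int | None = None
                    ) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate one cohort and its ground-truth effect table.

    Bit-reproducible given (config.seed, config, cohort_id). If
    ``disjoint_probe_fraction`` > 0 and ``cohort_index`` is given, the cohort
    is assigned a disjoint missing probe slice, emulating 450K/EPIC array
    non-overlap.
    """
    if config.n_cell_types != panel.profiles.shape[1]:
        raise ValueError("panel does not match config cell-type count")
    truth = _probe_truth(config, panel)
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed & 0x7FFFFFFF, 37,
         zlib.crc32(str(cohort_id).encode()) & 0x7FFFFFFF]))

    n_subj = config.n_subjects_per_cohort
    n_cpg = config.n_cpgs
    k = config.n_cell_types

    # ---- subjects -------------------------------------------------------
    sex = rng.integers(0, 2, size=n_subj)            # 0 female, 1 male
    age1 = np.clip(rng.normal(48.0, 8.0, size=n_subj), 25.0, 70.0)
    lo, hi = config.follow_up_years_range
    follow_up = rng.uniform(lo, hi, size=n_subj)
    height = np.where(sex == 1, rng.normal(176.0, 7.0, n_subj),
                      rng.normal(164.0, 6.5, n_subj))
    bmi1 = np.clip(rng.normal(25.5, 4.0, n_subj), 17.0, 45.0)
    bmi2 = np.clip(bmi1 + rng.normal(0.8, 1.2, n_subj), 17.0, 45.0)
    education = rng.choice(EDUCATION_LEVELS, size=n_subj,
                           p=(0.10, 0.55, 0.35))
    centre = rng.choice([f"{cohort_id}_centreA", f"{cohort_id}_centreB"],
                        size=n_subj)
    spirometer = rng.choice(["spiroA", "spiroB"], size=n_subj)

    status = rng.choice(SMOKING_STATUS, size=n_subj,
                        p=config.smoking_prevalence)
    ever = status != "never"
    py1 = np.where(ever, rng.gamma(2.0, 10.0, size=n_subj), 0.0)
    py2 = py1 + np.where(status == "current",
                         config.pack_year_accrual * follow_up, 0.0)
    ysq1 = np.where(status == "ex", rng.uniform(1.0, 20.0, size=n_subj),
                    np.nan)
    ysq2 = ysq1 + follow_up
    start_age = rng.uniform(15.0, 20.0, size=n_subj)
    duration1 = np.maximum(age1 - start_age, 1.0)
    cigs1 = np.where(status == "current", 20.0 * py1 / duration1, np.nan)
    cigs2 = np.where(status == "current", 20.0 * py2 / (duration1 + follow_up),
                     np.nan)

    subject_ids = [f"{cohort_id}_s{i:04d}" for i in range(n_subj)]

    # ---- per-sample latent structure -----------------------------------
    n_samp = 2 * n_subj
    tech = rng.normal(0.0, 1.0, size=(config.n_technical_factors, n_samp))
    alpha = np.resize(np.array([4.0, 8.0, 2.0, 3.0, 4.0, 1.5, 25.0]), k)
    cellfrac = rng.dirichlet(alpha, size=n_samp)     # samples x types
    subj_meth = rng.normal(0.0, config.subject_meth_sd, size=(n_cpg, n_subj))
    subj_ratio = rng.normal(0.0, config.subject_outcome_sd, size=n_subj)
    subj_fvc = rng.normal(0.0, 0.45, size=n_subj)

    doses = [
        _dose(status, py1, ysq1, config.quit_half_life_years),
        _dose(status, py2, ysq2, config.quit_half_life_years),
    ]
    ages = [age1, age1 + follow_up]
    pys = [py1, py2]
    ysqs = [ysq1, ysq2]
    bmis = [bmi1, bmi2]
    cigs = [cigs1, cigs2]

    beta = np.empty((n_cpg, n_samp))
    sample_ids: list[str] = []
    pheno_rows = []
    latent_rows = []
    mu = truth["mu"]
    n_ref = config.n_ref_probes
    ref_profiles = panel.profiles.to_numpy()
    med_idx = truth["med_idx"]

    for tp in (1, 2):
        cols = np.arange((tp - 1) * n_subj, tp * n_subj)
        dose = doses[tp - 1]
        age = ages[tp - 1]
        t = tech[:, cols]                            # factors x subjects
        w = cellfrac[cols]                           # subjects x types

        logit = (mu[:, None]
                 + np.vstack([np.zeros((n_ref, n_subj)),
                              truth["load"] @ t])
                 + np.vstack([np.zeros((n_ref, n_subj)),
                              truth["cell_load"] @ (w.T - 1.0 / k)])
                 + truth["effects"]["smoking_effect"].to_numpy()[:, None]
                 * dose[None, :]
                 + subj_meth
                 + rng.normal(0.0, config.meth_noise_sd, size=(n_cpg, n_subj)))
        m = expit(logit)
        # reference probes mix linearly on the beta scale
        m[:n_ref] = np.clip(
            ref_profiles @ w.T
            + rng.normal(0.0, config.ref_noise_sd, size=(n_ref, n_subj)),
            0.0, 1.0)
        beta[:, cols] = m

        fvc = (4.0 + 1.0 * sex + 0.04 * (height - 170.0)
               - 0.022 * (age - 50.0) + subj_fvc
               + rng.normal(0.0, config.fvc_noise_sd, size=n_subj))
        fvc = np.maximum(fvc, 1.0)
        mediated = np.zeros(n_subj)
        if len(med_idx):
            b = truth["effects"]["outcome_effect"].to_numpy()[med_idx]
            mediated = b @ (m[med_idx] - expit(mu[med_idx])[:, None])
        ratio = (0.82 - 0.0012 * (age - 50.0)
                 + config.direct_smoking_slope * dose
                 + mediated + subj_ratio
                 + rng.normal(0.0, config.outcome_noise_sd, size=n_subj))
        ratio = np.clip(ratio, 0.35, 0.97)
        fev1 = ratio * fvc

        for i in range(n_subj):
            sid = f"{subject_ids[i]}_t{tp}"
            sample_ids.append(sid)
            pheno_rows.append(dict(
                sample_id=sid, subject_id=subject_ids[i], timepoint=tp,
                age=ages[tp - 1][i], sex=int(sex[i]), height=height[i],
                bmi=bmis[tp - 1][i], education=education[i],
                centre=centre[i], spirometer=spirometer[i],
                smoking_status=status[i], pack_years=pys[tp - 1][i],
                years_since_quitting=ysqs[tp - 1][i],
                cigarettes_per_day=cigs[tp - 1][i],
                fev1=fev1[i], fvc=fvc[i],
            ))
            latent_rows.append(dict(
                sample_id=sid, dose=dose[i],
                **{f"cell_{c}": w[i, j]
                   for j, c in enumerate(config.cell_types)},
                **{f"tech{f}": t[f, i]
                   for f in range(config.n_technical_factors)},
            ))

    phenotypes = pd.DataFrame(pheno_rows)
    if (phenotypes["fev1"] > phenotypes["fvc"]).any():
        raise AssertionError("FEV1 exceeded FVC in generated data")

    control = (truth["control_base"][:, None]
               + truth["control_load"] @ tech
               + rng.normal(0.0, config.control_noise_sd,
                            size=(config.n_control_probes, n_samp)))
    control = np.maximum(control, 1.0)

    beta_df = pd.DataFrame(beta, index=truth["probe_ids"], columns=sample_ids)
    if config.disjoint_probe_fraction > 0 and cohort_index is not None:
        n_drop = int(config.disjoint_probe_fraction * n_cpg)
        if n_drop:
            stop = n_cpg - cohort_index * n_drop
            start = max(stop - n_drop, n_ref)
            beta_df = beta_df.drop(index=truth["probe_ids"][start:stop])

    dataset = CohortDataset(
        cohort_id=str(cohort_id),
        beta=beta_df,
        control=pd.DataFrame(
            control,
            index=[f"ctrl{i:04d}" for i in range(config.n_control_probes)],
            columns=sample_ids),
        phenotypes=phenotypes,
        annotation=truth["annotation"],
        latent=pd.DataFrame(latent_rows).set_index("sample_id"),
    )
    return dataset, truth["effects"]
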