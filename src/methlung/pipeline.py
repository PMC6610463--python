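"""End-to-end driver: simulate -> preprocess -> EWAS -> meta -> replicate ->
enrich -> mediate -> score.

Each stage is an importable function; :func:`run_pipeline` chains them,
failing fast with a stage-named error, deriving one deterministic seed per
stage from the global seed, and (optionally) writing every declared artifact
as TSV under ``out_dir``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as io_mod
from . import meta as meta_mod
from .config import RunConfig, SimulationConfig, stage_seed
from .enrichment import RankedResults, ks_enrichment_test
from .ewas import (ModelSpec, annual_change, build_design,
                   cross_sectional_ewas, outcome_vector, prediction_ewas,
                   repeat_ewas)
from .mediation import fit_mediator_outcome, quasi_bayesian_mediation
from .preprocess import (control_probe_pcs, estimate_cell_fractions,
                         residualize_methylation)
from .simulate import CohortDataset, simulate_cohort, simulate_reference_panel
from .smoking_index import (CpGSet, adjusted_group_distribution, build_index,
                            index_association, variance_decomposition)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- simulate
def simulate_study(config: SimulationConfig):
    """All cohorts of one study plus the shared ground-truth effect table."""
    panel = simulate_reference_panel(config)
    cohorts: dict[str, CohortDataset] = {}
    effects = None
    for i in range(config.n_cohorts):
        cid = f"cohort{i+1}"
        ds, effects = simulate_cohort(config, panel, cid, cohort_index=i)
        cohorts[cid] = ds
    return panel, cohorts, effects


# -------------------------------------------------------------- preprocess
def prepare_cohort(dataset: CohortDataset, panel, n_pcs: int = 30,
                   pcs_per_timepoint: bool = True) -> dict:
    """Residualize methylation on control-probe PCs; estimate cell fractions.

    PCs are computed per timepoint by default (both-timepoint pooling
    available via ``pcs_per_timepoint=False``).
    """
    ph = dataset.phenotypes.set_index("sample_id")
    blocks = ([ph.index[ph["timepoint"] == tp] for tp in (1, 2)]
              if pcs_per_timepoint else [ph.index])
    parts = []
    for samples in blocks:
        samples = [s for s in dataset.beta.columns if s in set(samples)]
        ctrl = dataset.control[samples]
        ncomp = min(n_pcs, len(samples) - 1, ctrl.shape[0])
        pcs = control_probe_pcs(ctrl, ncomp)
        parts.append(residualize_methylation(dataset.beta[samples], pcs))
    residuals = pd.concat(parts, axis=1)[dataset.beta.columns]
    cellfrac = estimate_cell_fractions(dataset.beta, panel)
    return dict(cohort_id=dataset.cohort_id, residuals=residuals,
                cell_fractions=cellfrac, phenotypes=ph, dataset=dataset)


# -------------------------------------------------------------------- EWAS
def _population_filter(ph: pd.DataFrame, population: str) -> pd.DataFrame:
    if population == "never_smokers":
        return ph[ph["smoking_status"] == "never"]
    return ph


def ewas_for_cohort(prep: dict, spec: ModelSpec,
                    probes: list[str] | None = None,
                    use_t: bool = False) -> pd.DataFrame:
    """Fit one EWAS design in one cohort, returning the per-probe table."""
    ph = _population_filter(prep["phenotypes"], spec.population)
    resid = prep["residuals"]
    if probes is not None:
        resid = resid.loc[[p for p in probes if p in resid.index]]

    if spec.design in ("cross_sectional_t1", "cross_sectional_t2"):
        tp = 1 if spec.design.endswith("t1") else 2
        ph_tp = ph[ph["timepoint"] == tp]
        design = build_design(ph_tp, prep["cell_fractions"], spec)
        y = outcome_vector(ph_tp.loc[design.index], spec.outcome)
        return cross_sectional_ewas(resid[list(design.index)], y, design,
                                    use_t=use_t)

    if spec.design == "predict_change":
        ph1 = ph[ph["timepoint"] == 1]
        ph2 = ph[ph["timepoint"] == 2].set_index("subject_id")
        both = ph1[ph1["subject_id"].isin(ph2.index)]
        design = build_design(both, prep["cell_fractions"], spec)
        both = both.loc[design.index]
        lf1 = outcome_vector(both, spec.outcome)
        at_t2 = ph2.loc[both["subject_id"]]
        lf2 = pd.Series(outcome_vector(at_t2, spec.outcome).to_numpy(),
                        index=both.index)
        fu = pd.Series(at_t2["age"].to_numpy() - both["age"].to_numpy(),
                       index=both.index)
        return prediction_ewas(resid[list(design.index)], lf1, lf2, fu,
                               design, use_t=use_t)

    if spec.design == "repeat":
        design = build_design(ph, prep["cell_fractions"], spec)
        y = outcome_vector(ph.loc[design.index], spec.outcome)
        groups = ph.loc[design.index, "subject_id"]
        return repeat_ewas(resid[list(design.index)], y, design, groups)

    raise ValueError(f"unknown design {spec.design!r}")


# --------------------------------------------------------------- mediation
def mediation_cpg_set(effects: pd.DataFrame, label: str = "mediation"
                      ) -> CpGSet:
    """Signed set of the ground-truth mediator CpGs."""
    med = effects[effects["is_mediator"]]
    if med.empty:
        raise ValueError("no mediator CpGs in the effect table")
    return CpGSet(
        probe_ids=med["probe_id"].tolist(),
        signs=["-" if s < 0 else "+" for s in med["smoking_effect"]],
        label=label)


def mediation_for_cohort(prep: dict, probe: str, outcome: str = "fev1_fvc",
                         treatment: str = "pack_years", timepoint: int = 2,
                         n_sims: int = 1000, seed: int | None = None):
    """Quasi-Bayesian mediation in one cohort at one timepoint.

    Default treatment is continuous pack-years among never- and current
    smokers (never-smokers anchor dose zero; ex-smokers are excluded because
    their effective dose has decayed). ``treatment='ever'`` gives the binary
    ever-vs-never contrast in all subjects.
    """
    ph = prep["phenotypes"]
    ph = ph[ph["timepoint"] == timepoint]
    if treatment == "pack_years":
        ph = ph[ph["smoking_status"].isin(["never", "current"])]
        treat = ph["pack_years"].astype(float)
    elif treatment == "ever":
        treat = (ph["smoking_status"] != "never").astype(float)
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    spec = ModelSpec(model="base", population="all",
                     design=f"cross_sectional_t{timepoint}", outcome=outcome)
    design = build_design(ph, prep["cell_fractions"], spec)
    data = pd.DataFrame({
        "treatment": treat.loc[design.index],
        "mediator": prep["residuals"].loc[probe, design.index],
        "outcome": outcome_vector(ph.loc[design.index], outcome),
    })
    fit = fit_mediator_outcome(data, "treatment", "mediator", "outcome",
                               covariates=design)
    return quasi_bayesian_mediation(fit, n_sims=n_sims, seed=seed), fit


def true_mediation_proportion(config: SimulationConfig,
                              effects: pd.DataFrame, prep: dict, probe: str,
                              timepoint: int = 2) -> float:
    """Configured-truth proportion mediated for the pack-year treatment.

    Computed from the generator's structural equations: each mediator's
    path slope is the regression of its noise-free mean expit(mu + s*dose)
    on dose over the analysis sample's latent doses. For the decomposition
    with ``probe`` as the single analyzed mediator, paths through the other
    mediating CpGs belong to the direct (non-mediator) pathway, so the
    total dose effect is the configured direct slope plus every mediated
    path, and the proportion is the analyzed probe's path over that total.
    """
    med = effects[effects["is_mediator"]].set_index("probe_id")
    if probe not in med.index:
        raise ValueError(f"{probe} is not a mediator CpG")
    ph = prep["phenotypes"]
    ph = ph[(ph["timepoint"] == timepoint)
            & ph["smoking_status"].isin(["never", "current"])]
    dose = prep["dataset"].latent.loc[ph.index, "dose"].to_numpy()
    paths = {}
    for pid, row in med.iterrows():
        m_mean = expit(row["baseline_logit"] + row["smoking_effect"] * dose)
        paths[pid] = np.polyfit(dose, m_mean, 1)[0] * row["outcome_effect"]
    total = config.direct_smoking_slope + sum(paths.values())
    return float(paths[probe] / total)


# ------------------------------------------------------------------- index
def index_run(preps: dict[str, dict], cpg_set: CpGSet,
              outcome: str = "fev1_fvc") -> dict:
    """Smoking-index construction and evaluation across cohorts.

    Builds the index per cohort from timepoint-2 residuals (timepoint-1 for
    the prediction design), meta-analyses its association by stratum and
    design, and adds the variance decomposition and the adjusted
    distribution across smoking strata for the first cohort.
    """
    assoc = {}
    indices = {}
    for design in ("cross_sectional_t2", "predict_change"):
        for stratum in ("all", "ever", "never"):
            entries = []
            for cid, prep in preps.items():
                ph = prep["phenotypes"]
                if stratum == "ever":
                    ph = ph[ph["smoking_status"] != "never"]
                elif stratum == "never":
                    ph = ph[ph["smoking_status"] == "never"]
                spec = ModelSpec(model="base", population="all",
                                 design=design, outcome=outcome)
                if design == "cross_sectional_t2":
                    ph_tp = ph[ph["timepoint"] == 2]
                    idx = build_index(
                        prep["residuals"][list(ph_tp.index)], cpg_set)
                    dm = build_design(ph_tp, prep["cell_fractions"], spec)
                    y = outcome_vector(ph_tp.loc[dm.index], outcome)
                else:
                    ph1 = ph[ph["timepoint"] == 1]
                    ph2 = (ph[ph["timepoint"] == 2]
                           .set_index("subject_id"))
                    ph1 = ph1[ph1["subject_id"].isin(ph2.index)]
                    idx = build_index(
                        prep["residuals"][list(ph1.index)], cpg_set)
                    dm = build_design(ph1, prep["cell_fractions"], spec)
                    ph1 = ph1.loc[dm.index]
                    lf1 = outcome_vector(ph1, outcome)
                    at2 = ph2.loc[ph1["subject_id"]]
                    lf2 = pd.Series(
                        outcome_vector(at2, outcome).to_numpy(),
                        index=ph1.index)
                    fu = pd.Series(
                        at2["age"].to_numpy() - ph1["age"].to_numpy(),
                        index=ph1.index)
                    y = pd.Series(annual_change(lf1, lf2, fu),
                                  index=ph1.index)
                    dm = dm.copy()
                    dm["baseline_lf"] = lf1
                entries.append(dict(cohort_id=cid, index=idx.scores,
                                    outcome=y, design=dm))
                if stratum == "all" and design == "cross_sectional_t2":
                    indices[cid] = idx
            assoc[(design, stratum)] = index_association(entries, stratum,
                                                         design)

    first = next(iter(preps.values()))
    ph2 = first["phenotypes"][first["phenotypes"]["timepoint"] == 2]
    idx2 = indices[first["cohort_id"]].scores
    spec = ModelSpec(model="base", population="all",
                     design="cross_sectional_t2", outcome=outcome)
    dm = build_design(ph2, first["cell_fractions"], spec)
    ph2 = ph2.loc[dm.index]
    smoking_cov = pd.DataFrame({
        "smoke_ex": (ph2["smoking_status"] == "ex").astype(float),
        "smoke_current": (ph2["smoking_status"] == "current").astype(float),
        "pack_years": ph2["pack_years"].astype(float),
    })
    var_table = variance_decomposition(
        outcome_vector(ph2, outcome), dm, idx2, smoking_cov)
    adj_cov = pd.concat([ph2[["age", "sex"]].astype(float),
                         pd.get_dummies(ph2["education"],
                                        drop_first=True, dtype=float)],
                        axis=1)
    groups = adjusted_group_distribution(
        idx2, ph2["smoking_status"], adj_cov)
    return dict(associations=assoc, variance=var_table,
                group_distribution=groups, indices=indices)


# --------------------------------------------------------- full pipeline
def discovery_replication_run(config: SimulationConfig,
                              n_discovery: int = 2,
                              outcome: str = "fev1_fvc",
                              sentinel_threshold: float = 5e-7,
                              alpha: float = 0.05, n_pcs: int = 30) -> dict:
    """Simulate, preprocess, run the cross-sectional discovery EWAS,
    select sentinels and apply the replication gate.

    Returns the per-cohort tables, discovery/replication/combined meta,
    the sentinel set and the gate table, plus the ground-truth effects.
    """
    panel, cohorts, effects = simulate_study(config)
    ids = list(cohorts)
    if not 1 <= n_discovery < len(ids):
        raise ValueError("need at least one discovery and one replication "
                         "cohort")
    preps = {cid: prepare_cohort(cohorts[cid], panel, n_pcs=n_pcs)
             for cid in ids}
    spec = ModelSpec(model="base", population="all",
                     design="cross_sectional_t2", outcome=outcome)
    tables = {cid: ewas_for_cohort(preps[cid], spec) for cid in ids}
    disc_ids, repl_ids = ids[:n_discovery], ids[n_discovery:]
    disc_meta = meta_mod.ivw_meta([tables[c] for c in disc_ids], disc_ids)
    repl_meta = meta_mod.ivw_meta([tables[c] for c in repl_ids], repl_ids)
    sentinels = meta_mod.select_sentinels(disc_meta, outcome,
                                          sentinel_threshold)
    gate = (meta_mod.replication_gate(sentinels, repl_meta, alpha=alpha)
            if sentinels.probes else None)
    combined = meta_mod.combine_meta(
        [tables[c] for c in disc_ids], [tables[c] for c in repl_ids],
        disc_ids, repl_ids)
    return dict(panel=panel, cohorts=cohorts, preps=preps, effects=effects,
                tables=tables, discovery_meta=disc_meta,
                replication_meta=repl_meta, sentinels=sentinels, gate=gate,
                combined_meta=combined, discovery_ids=disc_ids,
                replication_ids=repl_ids)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, failing fast with a stage-named error.

    When ``config.out_dir`` is set, writes the declared artifacts
    (cohort TSVs, EWAS tables, METAL-style meta tables, sentinel/replication
    tables, enrichment/mediation/index summaries).
    """
    out: dict = {}
    sim = config.simulation

    def stage(name):
        log.info("stage %s (seed %d)", name, stage_seed(config.seed, name))
        return stage_seed(config.seed, name)

    try:
        seed = stage("simulate")
        sim = SimulationConfig(**{**sim.__dict__, "seed": seed})
        run = discovery_replication_run(
            sim, n_discovery=config.n_discovery_cohorts,
            outcome=config.outcome,
            sentinel_threshold=config.sentinel_threshold,
            alpha=config.alpha, n_pcs=config.n_pcs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate/ewas/meta' failed: "
                           f"{exc}") from exc
    out.update(run)
    out["lambda_discovery"] = meta_mod.genomic_lambda(
        p_values=run["discovery_meta"]["p"].to_numpy())

    try:
        seed = stage("enrich")
        smoking_set = run["effects"].loc[
            run["effects"]["smoking_effect"] != 0, "probe_id"].tolist()
        ranked = RankedResults.from_meta(run["discovery_meta"])
        out["enrichment"] = ks_enrichment_test(
            ranked, smoking_set, n_perm=config.n_perm, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'enrich' failed: {exc}") from exc

    try:
        seed = stage("mediate")
        med_probes = run["effects"].loc[run["effects"]["is_mediator"],
                                        "probe_id"]
        probe = med_probes.iloc[0]
        prep1 = run["preps"][run["discovery_ids"][0]]
        out["mediation"], out["mediation_fit"] = mediation_for_cohort(
            prep1, probe, outcome=config.outcome, n_sims=config.n_sims,
            seed=seed)
        out["mediation_probe"] = probe
        out["mediation_truth"] = true_mediation_proportion(
            sim, run["effects"], prep1, probe)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'mediate' failed: {exc}") from exc

    try:
        stage("score")
        cpg_set = mediation_cpg_set(run["effects"])
        disc_preps = {c: run["preps"][c] for c in run["discovery_ids"]}
        out["index"] = index_run(disc_preps, cpg_set,
                                 outcome=config.outcome)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    if config.out_dir:
        _write_artifacts(out, config)
    return out


def _write_artifacts(out: dict, config: RunConfig) -> None:
    base = Path(config.out_dir)
    for cid, ds in out["cohorts"].items():
        d = base / "cohorts" / cid
        io_mod.write_matrix(ds.beta, d / "beta.tsv")
        io_mod.write_matrix(ds.control, d / "control.tsv")
        io_mod.write_table(ds.phenotypes, d / "phenotypes.tsv")
        io_mod.write_table(ds.annotation, d / "annotation.tsv")
    io_mod.write_table(out["effects"], base / "effects.tsv")
    for cid, table in out["tables"].items():
        io_mod.write_results(table, base / "ewas" / f"{cid}_cs2.tsv")
    io_mod.write_results(out["discovery_meta"], base / "meta_discovery.tsv",
                         format="metal_tsv")
    io_mod.write_results(out["replication_meta"],
                         base / "meta_replication.tsv", format="metal_tsv")
    io_mod.write_results(out["combined_meta"], base / "meta_combined.tsv",
                         format="metal_tsv")
    if out.get("gate") is not None:
        io_mod.write_table(out["gate"].reset_index(),
                           base / "replication_gate.tsv")
    io_mod.write_table(out["mediation"].table.reset_index(names="effect"),
                       base / "mediation.tsv")
    io_mod.write_table(out["index"]["variance"].reset_index(),
                       base / "index_variance.tsv")
    io_mod.write_table(out["index"]["group_distribution"].reset_index(),
                       base / "index_groups.tsv")
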