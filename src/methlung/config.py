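"""Configuration objects for the synthetic cohorts and the pipeline."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np

#: Canonical leukocyte types of reference-based blood deconvolution.
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Eos", "Neu")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-cohort, two-timepoint study.

    Methylation is generated on the logit scale (baseline + cell-mixture +
    shared technical factors + smoking dose effect + subject effect + noise)
    and mapped through the inverse logit, so beta-values stay in [0, 1].
    Lung function follows a spirometry-style mean model in age/height/sex with
    a direct smoking-dose effect plus effects mediated through methylation at
    designated CpGs.

    Effect-size units
    -----------------
    smoking_meth_slope      logit units per pack-year (negative = smoking
                            hypomethylation)
    meth_outcome_slope      FEV1/FVC units per unit beta-value at a mediating
                            CpG
    direct_smoking_slope    FEV1/FVC units per pack-year of effective dose
    """

    n_cohorts: int = 3
    n_subjects_per_cohort: int = 500
    n_cpgs: int = 2000
    n_control_probes: int = 200
    n_technical_factors: int = 5
    n_cell_types: int = 7
    n_ref_probes: int = 100
    follow_up_years_range: tuple[float, float] = (6.0, 15.0)
    smoking_cpg_fraction: float = 0.05
    n_mediated_cpgs: int = 20
    mediated_cpg_ids: tuple[str, ...] | None = None

    # effect sizes
    smoking_meth_slope: float = -0.04
    meth_outcome_slope: float = 0.08
    direct_smoking_slope: float = -0.0015

    # noise / variance parameters
    meth_noise_sd: float = 0.3          # logit scale, per sample
    subject_meth_sd: float = 0.3        # logit scale, shared across timepoints
    technical_loading_sd: float = 0.3   # logit scale, sparse CpG loadings
    technical_sparsity: float = 0.1     # fraction of CpGs loaded per factor
    cell_loading_sd: float = 0.5        # logit-scale cell-composition loadings
    control_loading_sd: float = 50.0    # intensity units per factor SD
    control_noise_sd: float = 20.0
    ref_noise_sd: float = 0.02          # beta scale, reference probes
    outcome_noise_sd: float = 0.03      # FEV1/FVC units, per record
    subject_outcome_sd: float = 0.04    # FEV1/FVC units, shared per subject
    fvc_noise_sd: float = 0.15          # litres

    # smoking behaviour
    smoking_prevalence: tuple[float, float, float] = (0.45, 0.30, 0.25)
    quit_half_life_years: float = 10.0
    pack_year_accrual: float = 0.75     # packs/day for a continuing smoker

    # array overlap: fraction of probes dropped per cohort (disjoint slices)
    disjoint_probe_fraction: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cohorts, self.n_subjects_per_cohort, self.n_cpgs,
            self.n_control_probes, self.n_technical_factors,
            self.n_cell_types, self.n_ref_probes,
        )
        if any(int(c) < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        lo, hi = self.follow_up_years_range
        if not (0 < lo <= hi <= 50):
            raise ValueError("follow-up interval must lie within (0, 50] years")
        for name in ("smoking_cpg_fraction", "technical_sparsity",
                     "disjoint_probe_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if abs(sum(self.smoking_prevalence) - 1.0) > 1e-9:
            raise ValueError("smoking prevalence must sum to 1")
        if self.n_mediated_cpgs > max(
                1, round(self.smoking_cpg_fraction * self.n_cpgs)):
            raise ValueError("more mediated CpGs than smoking CpGs")

    @property
    def cell_types(self) -> tuple[str, ...]:
        if self.n_cell_types <= len(CELL_TYPES):
            return CELL_TYPES[: self.n_cell_types]
        return CELL_TYPES + tuple(
            f"Cell{i}" for i in range(len(CELL_TYPES), self.n_cell_types))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one global seed.

    Stages are individually reproducible: the same (global seed, stage name)
    always yields the same value, kept below 2**31.
    """
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """End-to-end pipeline settings: cohort split, thresholds, seed, paths."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_discovery_cohorts: int = 2
    sentinel_threshold: float = 5e-7
    alpha: float = 0.05
    n_pcs: int = 30
    n_sims: int = 1000
    n_perm: int = 10000
    outcome: str = "fev1_fvc"
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("sentinel_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 1 <= self.n_discovery_cohorts <= self.simulation.n_cohorts:
            raise ValueError("n_discovery_cohorts out of range")

    @property
    def cohort_ids(self) -> list[str]:
        return [f"cohort{i+1}" for i in range(self.simulation.n_cohorts)]

    @property
    def discovery_cohorts(self) -> list[str]:
        return self.cohort_ids[: self.n_discovery_cohorts]

    @property
    def replication_cohorts(self) -> list[str]:
        return self.cohort_ids[self.n_discovery_cohorts:]
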