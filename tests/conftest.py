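import numpy as np
import pandas as pd
import pytest

from methlung.config import SimulationConfig
from methlung.pipeline import prepare_cohort, simulate_study


@pytest.fixture(scope="session")
def study_config():
    """Small but fully structured two-cohort study."""
    return SimulationConfig(n_cohorts=2, n_subjects_per_cohort=150,
                            n_cpgs=600, n_control_probes=80,
                            n_mediated_cpgs=10, seed=42)


@pytest.fixture(scope="session")
def study(study_config):
    panel, cohorts, effects = simulate_study(study_config)
    return dict(panel=panel, cohorts=cohorts, effects=effects)


@pytest.fixture(scope="session")
def prep(study):
    """Preprocessed first cohort: residuals, cell fractions, phenotypes."""
    return prepare_cohort(study["cohorts"]["cohort1"], study["panel"],
                          n_pcs=20)


@pytest.fixture()
def toy_phenotypes():
    """Deterministic phenotype frame with 2 centres, 2 spirometers,
    3 education levels and generic (non-degenerate) cell fractions."""
    rng = np.random.default_rng(7)
    n = 80
    ph = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "subject_id": [f"p{i:03d}" for i in range(n)],
        "timepoint": 2,
        "age": rng.uniform(35, 65, n),
        "sex": rng.integers(0, 2, n),
        "height": rng.uniform(150, 195, n),
        "bmi": rng.uniform(19, 33, n),
        "education": rng.choice(["low", "intermediate", "high"], n),
        "centre": rng.choice(["c1", "c2"], n),
        "spirometer": rng.choice(["sp1", "sp2"], n),
        "smoking_status": rng.choice(["never", "ex", "current"], n),
        "pack_years": rng.uniform(0, 40, n),
        "fev1": rng.uniform(2, 4, n),
        "fvc": rng.uniform(3.5, 5.5, n),
    }).set_index("sample_id")
    ph.loc[ph["smoking_status"] == "never", "pack_years"] = 0.0
    cells = rng.dirichlet(np.ones(7) * 5, n) + rng.uniform(0, 0.05, (n, 7))
    cf = pd.DataFrame(cells, index=ph.index,
                      columns=["CD8T", "CD4T", "NK", "Bcell", "Mono",
                               "Eos", "Neu"])
    return ph, cf
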