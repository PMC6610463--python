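"""Shared defaults for the numbered analysis drivers.

The default study mirrors the discovery design at desk scale: three cohorts
of 300 subjects measured at two timepoints 6-15 years apart, 2000 CpGs of
which 5% are smoking-responsive and 20 mediate the smoking effect on
FEV1/FVC; the first two cohorts are discovery, the third replication.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from methlung.config import SimulationConfig
from methlung.pipeline import prepare_cohort, simulate_study

N_DISCOVERY = 2


def default_config(seed: int) -> SimulationConfig:
    return SimulationConfig(n_cohorts=3, n_subjects_per_cohort=300,
                            n_cpgs=2000, n_mediated_cpgs=20, seed=seed)


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    return args


def simulate_and_prepare(seed: int):
    """Simulate the default study and preprocess every cohort."""
    config = default_config(seed)
    panel, cohorts, effects = simulate_study(config)
    preps = {cid: prepare_cohort(ds, panel) for cid, ds in cohorts.items()}
    return config, panel, cohorts, effects, preps
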