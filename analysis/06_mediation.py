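"""Causal mediation: smoking dose -> CpG methylation -> FEV1/FVC.

For each of the first five ground-truth mediator CpGs, fits the mediator
and outcome models in the first cohort (never- and current smokers,
pack-years as treatment) and decomposes the smoking effect into ACME, ADE,
total effect and proportion mediated via quasi-Bayesian Monte Carlo.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from methlung import io  # noqa: E402
from methlung.config import stage_seed  # noqa: E402
from methlung.pipeline import (mediation_for_cohort,  # noqa: E402
                               true_mediation_proportion)


def main() -> None:
    args = common.parse_args(__doc__)
    config, _, _, effects, preps = common.simulate_and_prepare(args.seed)
    prep = next(iter(preps.values()))
    probes = effects.loc[effects["is_mediator"], "probe_id"].head(5)

    rows = []
    for i, probe in enumerate(probes):
        res, _ = mediation_for_cohort(
            prep, probe, n_sims=1000,
            seed=stage_seed(args.seed, f"mediate-{i}"))
        t = res.table
        rows.append(dict(
            probe_id=probe,
            acme=t.loc["acme", "estimate"],
            acme_ci=f"({t.loc['acme', 'ci_low']:.4f}, "
                    f"{t.loc['acme', 'ci_high']:.4f})",
            acme_p=t.loc["acme", "p"],
            ade=t.loc["ade", "estimate"],
            total=t.loc["total", "estimate"],
            proportion=t.loc["proportion", "estimate"],
            proportion_truth=true_mediation_proportion(config, effects,
                                                       prep, probe)))
    table = pd.DataFrame(rows)
    io.write_table(table.round(5), args.out_dir / "mediation.tsv")
    with pd.option_context("display.float_format", "{:.4f}".format):
        print(table.to_string(index=False))
    print("\nACME/total are per pack-year of smoking dose on FEV1/FVC. "
          "With 20 simultaneous mediators, most of the dose effect lands "
          "in the direct (non-analyzed-mediator) pathway of each "
          "single-CpG decomposition; shared cell-composition/technical "
          "structure correlates the mediators even within treatment "
          "groups, so single-CpG ACMEs modestly exceed the per-CpG "
          "structural path (truth column).")


if __name__ == "__main__":
    main()
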