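"""Two-sample Mendelian randomization on summary statistics.

Demonstrates the generic estimator (per-instrument Wald ratios pooled by
IVW) on synthetic instrument tables with a known causal slope; real use
takes the same 6-column TSV (instrument_id, exposure_beta, exposure_se,
outcome_beta, outcome_se, cpg_id) from external mQTL/GWAS summary data.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from methlung import io  # noqa: E402
from methlung.config import stage_seed  # noqa: E402
from methlung.mr import ivw_mr  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    rng = np.random.default_rng(stage_seed(args.seed, "mr"))
    rows = []
    for cpg, true_slope in (("cpg_causal", 0.3), ("cpg_null", 0.0)):
        n = 12
        bx = rng.uniform(0.2, 0.6, n)
        sy = np.full(n, 0.02)
        table = pd.DataFrame({
            "instrument_id": [f"{cpg}_rs{i}" for i in range(n)],
            "exposure_beta": bx, "exposure_se": 0.01,
            "outcome_beta": true_slope * bx + rng.normal(0, sy),
            "outcome_se": sy, "cpg_id": cpg})
        res = ivw_mr(table)
        rows.append(dict(cpg_id=cpg, true_slope=true_slope,
                         estimate=res.estimate, se=res.se, p=res.p,
                         n_instruments=res.n_instruments))
        io.write_table(table, args.out_dir / "mr" / f"{cpg}_instruments.tsv")
    out = pd.DataFrame(rows)
    io.write_table(out, args.out_dir / "mr" / "estimates.tsv")
    with pd.option_context("display.float_format", "{:.4g}".format):
        print(out.to_string(index=False))
    print("\nThe IVW estimator recovers the simulated causal slope and "
          "stays null for the non-causal exposure.")


if __name__ == "__main__":
    main()
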