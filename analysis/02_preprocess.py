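"""Technical-bias residualization and cell-composition estimation.

Computes control-probe principal components per cohort and timepoint,
residualizes the methylation matrix on them, estimates blood cell-type
fractions against the reference panel, and reports how much technical
structure the residualization removed.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from methlung import io  # noqa: E402


def _mean_abs_corr(m: np.ndarray, tech: np.ndarray) -> float:
    mc = m - m.mean(axis=1, keepdims=True)
    tc = tech - tech.mean(axis=0)
    num = mc @ tc
    den = np.outer(np.sqrt((mc**2).sum(axis=1)),
                   np.sqrt((tc**2).sum(axis=0)))
    return float(np.abs(num / den).mean())


def main() -> None:
    args = common.parse_args(__doc__)
    _, panel, cohorts, _, preps = common.simulate_and_prepare(args.seed)

    rows = []
    for cid, prep in preps.items():
        ds = cohorts[cid]
        io.write_matrix(prep["cell_fractions"].T,
                        args.out_dir / "preprocess" / f"{cid}_cellfrac.tsv")
        samples = list(ds.beta.columns)
        tech = ds.latent.loc[samples,
                             [c for c in ds.latent.columns
                              if c.startswith("tech")]].to_numpy()
        raw = ds.beta.to_numpy()[100:600]
        adj = prep["residuals"].to_numpy()[100:600]
        rows.append(dict(
            cohort=cid,
            raw_tech_corr=_mean_abs_corr(raw, tech),
            residual_tech_corr=_mean_abs_corr(adj, tech),
            mean_cell_fraction_sum=float(
                prep["cell_fractions"].sum(axis=1).mean())))
    summary = pd.DataFrame(rows)
    io.write_table(summary.round(4),
                   args.out_dir / "preprocess" / "summary.tsv")
    print(summary.round(4).to_string(index=False))
    print("\nResidualization on control-probe PCs reduced the mean |r| "
          "between CpGs and the latent technical factors "
          f"by {100 * (1 - summary['residual_tech_corr'].mean() / summary['raw_tech_corr'].mean()):.0f}%.")


if __name__ == "__main__":
    main()
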