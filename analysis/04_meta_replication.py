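"""Discovery meta-analysis, sentinel selection and the replication gate.

Pools the discovery cohorts by fixed-effect IVW, selects sentinels at
p < 5e-7, tests them in the held-out replication cohort against the
outcome-specific Bonferroni threshold (with sign concordance), and writes
the combined meta-analysis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from methlung import io  # noqa: E402
from methlung.config import SimulationConfig  # noqa: E402
from methlung.meta import genomic_lambda  # noqa: E402
from methlung.pipeline import discovery_replication_run  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    config = common.default_config(args.seed)
    run = discovery_replication_run(config,
                                    n_discovery=common.N_DISCOVERY)
    out = args.out_dir / "meta"
    io.write_results(run["discovery_meta"], out / "discovery.tsv",
                     format="metal_tsv")
    io.write_results(run["replication_meta"], out / "replication.tsv",
                     format="metal_tsv")
    io.write_results(run["combined_meta"], out / "combined.tsv",
                     format="metal_tsv")
    gate = run["gate"]
    io.write_table(gate.reset_index(), out / "replication_gate.tsv")

    eff = run["effects"].set_index("probe_id")
    sent = run["sentinels"].probes
    true_sent = [p for p in sent if not eff.loc[p, "is_null"]]
    lam = genomic_lambda(p_values=run["discovery_meta"]["p"].to_numpy())
    print(f"Discovery meta-analysis of {len(run['discovery_meta'])} CpGs "
          f"(lambda = {lam:.2f}): {len(sent)} sentinels at p < "
          f"{run['sentinels'].threshold:g}, of which {len(true_sent)} carry "
          "a true smoking effect.")
    print(f"Replication threshold 0.05/{len(sent)} = "
          f"{gate['threshold'].iloc[0]:.2e}; "
          f"{int(gate['replicated'].sum())} sentinels replicated "
          f"({int(gate.loc[true_sent, 'replicated'].sum())} true, "
          f"{int(gate.drop(true_sent)['replicated'].sum())} null).")
    top = run["combined_meta"].sort_values("p").head(10)
    print("\nTop combined associations:")
    print(top[["beta", "se", "p", "direction", "het_p"]].to_string())


if __name__ == "__main__":
    main()
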