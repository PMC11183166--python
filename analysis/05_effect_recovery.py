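#!/usr/bin/env python
"""Planted-effect recovery: nodal detection and NBS localization.

Runs the effect-recovery design (38 vs 38 over 50 regions, five
well-connected effect nodes shifted down at a standardized effect size of
1.5) for a handful of seeds and reports, per replicate: whether every
effect node is FDR-significant in nodal-degree AUC, whether the effect
nodes occupy the top decile of |AUC difference|, and the recall of the
planted connectivity component by the network-based statistic (NBS,
primary t = 3.2, hypo-connectivity direction). Writes the replicate table
to results/effect_recovery.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from morphnet.study import effect_recovery_replicate

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 5  # a quick look; the test suite runs 20


def main() -> None:
    rows = []
    for seed in range(1, N_REPLICATES + 1):
        r = effect_recovery_replicate(seed, effect_size=1.5)
        r["seed"] = seed
        rows.append(r)
        print(f"seed {seed}: all effect nodes FDR-significant="
              f"{r['effect_nodes_significant']}, top-decile="
              f"{r['effect_nodes_top_decile']}, NBS recall={r['nbs_recall']:.2f}, "
              f"r(score)={r['r_hfmse']:+.2f}, r(duration)={r['r_duration']:+.2f}")
    table = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "effect_recovery.tsv", sep="\t", index=False)
    print(f"\nrecovered in {int(table['effect_nodes_significant'].sum())}"
          f"/{N_REPLICATES} replicates; mean NBS recall "
          f"{table['nbs_recall'].mean():.2f}")


if __name__ == "__main__":
    main()
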