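"""Build directed anti-symmetric networks and inspect weights across delays.

For each subject and delay 1..5: delayed correlation -> symmetric /
anti-symmetric split -> negativity-zeroed directed network.  Averaging
the individual weight matrices per group gives a representative network.
Delays at/near the coupling lag carry backbone structure and a wide
weight distribution; at longer delays the weights are mostly noise and
concentrate near zero, so their spread tends to contract — the reason
the analysis restricts itself to short delays.  On a single cohort this
is a tendency, not a law: strongly lattice-like groups keep structured
multi-step correlations out to intermediate delays.

Writes results/weight_iqr_by_delay.csv.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from delaynet.connectivity import (
    antisymmetric_decomposition,
    build_directed_network,
    delayed_correlation,
    group_average_network,
    positive_weight_iqr,
)
from delaynet.synthetic import read_cohort

COHORT_DIR = Path("scratch/analysis/cohort")
RESULTS = Path("results")
DELAYS = [1, 2, 3, 4, 5]


def main() -> None:
    cohort = read_cohort(COHORT_DIR)
    group_of = {s.subject_id: s.group for s in cohort.subjects}
    rows = []
    for delay in DELAYS:
        nets = defaultdict(list)
        for sid in cohort.subject_ids:
            C = delayed_correlation(cohort.timeseries[sid], delay).matrix
            _, K = antisymmetric_decomposition(C)
            nets[group_of[sid]].append(build_directed_network(K, delay))
        for group, members in nets.items():
            avg = group_average_network(members)
            rows.append(
                {"group": group, "delay": delay, "positive_weight_iqr": positive_weight_iqr(avg)}
            )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "weight_iqr_by_delay.csv", index=False)
    wide = table.pivot(index="delay", columns="group", values="positive_weight_iqr").round(4)
    print("IQR of positive weights in the group-average network, by delay:")
    print(wide.to_string())
    shrink = table.groupby("group", sort=False).apply(
        lambda g: g.sort_values("delay")["positive_weight_iqr"].iloc[-1]
        < g.sort_values("delay")["positive_weight_iqr"].iloc[0],
        include_groups=False,
    )
    print(
        f"\nWeight spread narrows from delay 1 to delay 5 in "
        f"{int(shrink.sum())}/{len(shrink)} groups."
    )


if __name__ == "__main__":
    main()
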