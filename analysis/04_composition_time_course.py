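#!/usr/bin/env python
"""Quantify death-state composition over the post-trauma time course.

Builds per-group and per-sample composition tables from the classified NK
cells, compares them with the planted mixing proportions, and tests the
per-sample fraction differences across time points (one-way ANOVA per
state, as the published composition analysis does).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nkfate import composition as comp

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"


def main() -> None:
    states = pd.read_csv(EXP / "death_states.tsv", sep="\t", dtype={"barcode": str})
    truth = pd.read_csv(
        EXP / "ground_truth" / "ground_truth_cells.tsv", sep="\t", dtype={"barcode": str}
    ).set_index("barcode")

    by_group = comp.state_fractions(states, truth, by=["group"])
    by_group.to_tsv(RESULTS / "04_composition_by_group.tsv")
    by_sample = comp.state_fractions(states, truth, by=["group", "sample"])

    print("recovered death-state fractions per time point:")
    print(by_group.fractions.round(3).to_string())

    planted = pd.read_csv(RESULTS / "01_planted_fractions.tsv", sep="\t").set_index("group")
    from nkfate.genesets import aggregate_state, HEALTHY_LABEL

    agg = {}
    for col in planted.columns:
        state = HEALTHY_LABEL if col == HEALTHY_LABEL else aggregate_state(col)
        agg[state] = agg.get(state, 0) + planted[col]
    planted_states = pd.DataFrame(agg)
    err = (
        by_group.fractions.reindex(columns=planted_states.columns, fill_value=0.0)
        - planted_states.reindex(by_group.fractions.index)
    ).abs()
    print(f"max |recovered - planted| = {100 * err.to_numpy().max():.2f} points")

    rows = []
    for state in by_group.fractions.columns:
        per_group = [
            by_sample.fractions.xs(g, level="group")[state].to_numpy()
            for g in by_group.fractions.index
        ]
        if all(len(v) >= 2 for v in per_group) and any(np.ptp(v) > 0 for v in per_group):
            stat, p = comp.compare_groups(per_group, test="anova")
            rows.append({"state": state, "anova_F": stat, "p": p})
    anova = pd.DataFrame(rows)
    anova.to_csv(RESULTS / "04_state_anova.tsv", sep="\t", index=False)
    print("per-state one-way ANOVA across time points:")
    print(anova.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
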