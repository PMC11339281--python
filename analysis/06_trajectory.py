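#!/usr/bin/env python
"""Infer the MST pseudotime trajectory across NK death states.

Fits centroids per death state in the NK PC embedding, joins them by a
minimum spanning tree rooted at healthy NK cells, projects every cell onto
its state's incident edges and reports pseudotime and decision points.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from nkfate import io_qc
from nkfate import trajectory as tj
from nkfate.genesets import HEALTHY_LABEL

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = io_qc.read_10x(EXP)
    matrix, _ = io_qc.qc_filter(matrix)
    x = io_qc.lognormalize(matrix)
    states = pd.read_csv(EXP / "death_states.tsv", sep="\t", dtype={"barcode": str})
    mask = np.isin(x.barcodes, states["barcode"])
    x_nk = x.subset_cells(mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hv = io_qc.select_hvg(x_nk)
        emb = io_qc.scale_and_pca(x_nk, hv)
    state_of = states.set_index("barcode")["state"].reindex(x_nk.barcodes).to_numpy()

    model = tj.fit_mst(emb.coords, state_of)
    root = HEALTHY_LABEL if HEALTHY_LABEL in model.nodes else model.nodes[0]
    pt = tj.pseudotime(model, emb.coords, state_of, root)
    model.to_json(RESULTS / "06_trajectory.json")

    summary = (
        pd.DataFrame({"state": state_of, "pseudotime": pt})
        .groupby("state")["pseudotime"]
        .agg(["mean", "std", "size"])
        .round(3)
    )
    summary.to_csv(RESULTS / "06_pseudotime_by_state.tsv", sep="\t")
    print(f"MST over {len(model.nodes)} state centroids, rooted at {root!r}")
    print("edges:", [(a, b, round(w, 2)) for a, b, w in model.edges])
    print("decision points (degree >= 3):", tj.decision_points(model))
    print(summary.to_string())


if __name__ == "__main__":
    main()
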