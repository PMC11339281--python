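#!/usr/bin/env python
"""Classify NK cells into regulated-cell-death paradigms.

Re-clusters the annotated NK cells (k-means vector quantization + modularity
communities on the centroid SNN graph), ranks each cluster's genes by log2
fold change, scores the twelve death signatures with the permutation GSEA
and assigns each cluster its max-NES paradigm (healthy when nothing is
enriched).  Writes the per-cluster enrichment evidence to results/ and the
per-cell labels to scratch.
"""

import warnings
from pathlib import Path

import pandas as pd

from nkfate import deathstate as ds
from nkfate import io_qc
from nkfate.genesets import read_gmt

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = io_qc.read_10x(EXP)
    matrix, _ = io_qc.qc_filter(matrix)
    x = io_qc.lognormalize(matrix)
    cells = pd.read_csv(EXP / "cell_types.tsv", sep="\t").set_index("barcode")
    nk_mask = cells.reindex(x.barcodes)["cell_type"].to_numpy() == "NK"
    x_nk = x.subset_cells(nk_mask)
    print(f"classifying {x_nk.n_cells} NK cells")

    collection = read_gmt(EXP / "death_paradigms.gmt")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hvgs = io_qc.select_hvg(x_nk)
        emb = io_qc.scale_and_pca(x_nk, hvgs)
        table = ds.classify_death_states(x_nk, emb, collection, n_perm=1000, seed=SEED)

    table.cells.to_csv(EXP / "death_states.tsv", sep="\t", index=False)
    table.cluster_evidence.round(5).to_csv(
        RESULTS / "03_cluster_enrichment.tsv", sep="\t", index=False
    )
    best = (
        table.cluster_evidence.sort_values("nes", ascending=False)
        .groupby("cluster")
        .head(1)[["cluster", "paradigm", "nes", "p_adj"]]
    )
    counts = table.cells.groupby(["cluster", "state"]).size().rename("n_cells").reset_index()
    print("top enrichment per cluster:")
    print(best.merge(counts.groupby("cluster")["n_cells"].sum().reset_index()).to_string(index=False))
    print("state totals:", table.cells["state"].value_counts().to_dict())


if __name__ == "__main__":
    main()
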