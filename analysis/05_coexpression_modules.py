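#!/usr/bin/env python
"""Discover co-expression modules and correlate them with the trauma course.

Aggregates the classified NK cells into sample x state pseudo-bulk columns,
builds the soft-thresholded (beta=6) topological-overlap network over the
most variable genes, cuts modules from the average-linkage dendrogram,
summarizes each by its eigengene, and correlates eigengenes with the
planted hypoxia trend and with per-sample state fractions.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from nkfate import coexpnet as cx
from nkfate import io_qc
from nkfate import pseudobulk as pbk

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = io_qc.read_10x(EXP)
    matrix, _ = io_qc.qc_filter(matrix)
    states = pd.read_csv(EXP / "death_states.tsv", sep="\t", dtype={"barcode": str})
    nk = matrix.subset_cells(np.isin(matrix.barcodes, states["barcode"]))
    pb = pbk.make_pseudobulk(nk, states.set_index("barcode")["state"])
    keep = ~pb.flagged
    pb = pbk.PseudoBulkMatrix(
        genes=pb.genes, columns=pb.columns[keep], counts=pb.counts[:, keep],
        n_cells=pb.n_cells[keep],
    )
    lc = pbk.log_cpm(pb)
    top = np.argsort(-lc.var(axis=1), kind="stable")[:1500]
    lc_top = lc[top]
    names = [str(g) for g in pb.genes[top]]

    params = cx.CoexpParams(min_module_size=20, seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, fit = cx.pick_soft_threshold(lc_top[:300])
        tom = cx.adjacency_tom(lc_top, params)
        modules = cx.detect_modules(tom, params, gene_names=names, x=lc_top)
    fit.round(3).to_csv(RESULTS / "05_scale_free_fit.tsv", sep="\t", index=False)
    modules.modules.to_csv(RESULTS / "05_gene_modules.tsv", sep="\t")
    print(f"soft-threshold scan suggests beta={beta}; network built at beta={params.beta}")
    print(f"{len(modules.module_ids)} modules; sizes:",
          {f"M{m}": len(modules.genes_in(m)) for m in modules.module_ids})

    with open(EXP / "ground_truth" / "ground_truth.json") as fh:
        import json

        gt = json.load(fh)
    samples = pb.columns.get_level_values("sample")
    trend = samples.str.rsplit("_", n=1).str[0].map(gt["group_trend"]).to_numpy(float)
    tc = cx.module_trait_correlation(modules.eigengenes, trend)
    tc.round(4).to_csv(RESULTS / "05_module_trend_correlation.tsv", sep="\t")
    print("module eigengene vs planted hypoxia trend (Spearman):")
    print(tc.round(3).to_string())

    planted = set(gt["module_genes"])
    for mid in modules.module_ids:
        genes = set(modules.genes_in(mid))
        j = len(genes & planted) / len(genes | planted)
        if j > 0.3:
            print(f"module M{mid} matches the planted hypoxia module (Jaccard {j:.2f})")


if __name__ == "__main__":
    main()
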