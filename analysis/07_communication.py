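#!/usr/bin/env python
"""Score ligand-receptor communication between death-state NK populations
and the other immune cells.

Ligands/receptors must be over-expressed in their populations; channel
probabilities follow the mass-action law on trimean expression; label
permutation assigns significance; significant pair probabilities aggregate
into pathway weights per (source, target).
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from nkfate import commnet as cn
from nkfate import io_qc
from nkfate import synthdata as sdt

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = io_qc.read_10x(EXP)
    matrix, _ = io_qc.qc_filter(matrix)
    x = io_qc.lognormalize(matrix)
    types = pd.read_csv(EXP / "cell_types.tsv", sep="\t", dtype={"barcode": str}).set_index("barcode")
    states = pd.read_csv(EXP / "death_states.tsv", sep="\t", dtype={"barcode": str}).set_index("barcode")

    type_of = types["cell_type"].reindex(x.barcodes).to_numpy()
    state_of = states["state"].reindex(x.barcodes).to_numpy(dtype=object)
    populations = np.where(
        type_of == "NK",
        np.array([f"NK_{s}" for s in state_of], dtype=object),
        type_of,
    )
    keep = populations != "ambiguous"

    cfg = sdt.default_config(seed=SEED)
    pairs = [cn.LRPair(p.ligand, (p.receptor,), p.pathway) for p in cfg.lr_pairs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = cn.score_communication(
            x.subset_cells(keep), populations[keep], pairs, n_perm=100, seed=SEED
        )
    graph.table.round(5).to_csv(RESULTS / "07_communication_weights.tsv", sep="\t", index=False)
    graph.pairs.round(5).to_csv(RESULTS / "07_communication_pairs.tsv", sep="\t", index=False)
    print("significant pathway weights (source -> target):")
    print(graph.table.round(3).to_string(index=False))
    planted = {(p.source, p.target, p.pathway) for p in cfg.lr_pairs}
    found = {
        (r.source, r.target, r.pathway) for r in graph.table.itertuples()
    }
    print(f"planted channels recovered: {len(planted & found)}/{len(planted)}")


if __name__ == "__main__":
    main()
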