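"""Ground-truth recovery experiments on the synthetic test bed.

Each function simulates a default experiment for one seed, runs the relevant
pipeline stages and measures recovery against the planted truth.  The
acceptance checks and the numbered analysis drivers both build on these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coexpnet as cx
from . import commnet as cn
from . import deathstate as ds
from . import io_qc
from . import pseudobulk as pbk
from . import synthdata as sdt
from . import trajectory as tj
from .genesets import HEALTHY_LABEL


@dataclass
class RecoveryResult:
    seed: int
    cell_accuracy: float
    cluster_accuracy: float
    max_fraction_error: float          # percentage points, worst group x state
    n_clusters: int
    fractions_true: pd.DataFrame = field(repr=False, default=None)
    fractions_est: pd.DataFrame = field(repr=False, default=None)


def _prepare(seed: int, n_cells_per_group: int):
    cfg = sdt.default_config(seed=seed, n_cells_per_group=n_cells_per_group)
    matrix, truth, collection = sdt.simulate_experiment(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, _ = io_qc.qc_filter(matrix)
        x = io_qc.lognormalize(matrix)
        hv = io_qc.select_hvg(x)
        emb = io_qc.scale_and_pca(x, hv)
        clusters = ds.two_step_cluster(emb, seed=seed)
        cell_types = io_qc.annotate_cell_types(
            x, {t: list(g) for t, g in sdt.DEFAULT_MARKERS.items()}, clusters=clusters.labels
        )
    return cfg, matrix, truth, collection, x, cell_types


def classification_recovery(
    seed: int,
    n_cells_per_group: int = 1000,
    n_perm: int = 1000,
) -> RecoveryResult:
    """Full classifier run against the planted paradigm labels.

    Measures per-cell state accuracy (over true NK cells), cluster-level
    accuracy (a cluster is correct when its assigned state matches its
    cells' majority true state) and the worst per-group per-state fraction
    error in percentage points.
    """
    return _classification_from(_prepare(seed, n_cells_per_group), seed, n_perm)


def _classification_from(prep, seed: int, n_perm: int) -> RecoveryResult:
    cfg, matrix, truth, collection, x, cell_types = prep
    nk_mask = cell_types == "NK"
    x_nk = x.subset_cells(nk_mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hv = io_qc.select_hvg(x_nk)
        emb_nk = io_qc.scale_and_pca(x_nk, hv)
        table = ds.classify_death_states(
            x_nk, emb_nk, collection, n_perm=n_perm, seed=seed
        )
    tr = truth.cells.set_index("barcode").loc[list(x_nk.barcodes)]
    true_state = tr["state"].replace("", HEALTHY_LABEL).to_numpy()
    is_nk = tr["cell_type"].to_numpy() == "NK"
    pred = table.cells.set_index("barcode").loc[list(x_nk.barcodes)]
    pred_state = pred["state"].to_numpy()
    cell_acc = float((pred_state[is_nk] == true_state[is_nk]).mean())

    # paradigm accuracy over clusters large enough to be ranked (clusters
    # below the classifier's min_cells default to healthy by contract and
    # never enter the enrichment path)
    pred_cluster = pred["cluster"].to_numpy()
    ok = tot = 0
    for cid in np.unique(pred_cluster):
        mask = pred_cluster == cid
        if mask.sum() < 10:
            continue
        majority = pd.Series(true_state[mask]).mode().iloc[0]
        tot += 1
        ok += int(pred_state[mask][0] == majority)
    cluster_acc = ok / max(tot, 1)

    groups = tr["group"].to_numpy()
    states = sorted(set(true_state[is_nk]) | set(pred_state))
    rows_t, rows_e = [], []
    errs = []
    for g in cfg.groups:
        gm = groups == g
        t_row = {s: float((true_state[gm & is_nk] == s).mean()) for s in states}
        e_row = {s: float((pred_state[gm] == s).mean()) for s in states}
        rows_t.append(t_row)
        rows_e.append(e_row)
        errs.extend(abs(t_row[s] - e_row[s]) for s in states)
    return RecoveryResult(
        seed=seed,
        cell_accuracy=cell_acc,
        cluster_accuracy=cluster_acc,
        max_fraction_error=100.0 * max(errs),
        n_clusters=int(pred["cluster"].nunique()),
        fractions_true=pd.DataFrame(rows_t, index=list(cfg.groups)),
        fractions_est=pd.DataFrame(rows_e, index=list(cfg.groups)),
    )


def module_recovery(
    seed: int,
    n_cells_per_group: int = 1000,
    n_top_genes: int = 1500,
    min_module_size: int = 20,
) -> dict:
    """Co-expression module analysis on NK sample x state pseudo-bulk:
    does the planted hypoxia-like module emerge, and is it the top
    |Spearman rho| module against the planted rise-then-fall trend?"""
    return _module_from(
        _prepare(seed, n_cells_per_group), seed, n_top_genes, min_module_size
    )


def _module_from(prep, seed: int, n_top_genes: int = 1500, min_module_size: int = 20) -> dict:
    cfg, matrix, truth, collection, x, cell_types = prep
    tr = truth.cells.set_index("barcode").loc[list(matrix.barcodes)]
    nk = (tr["cell_type"] == "NK").to_numpy()
    m_nk = matrix.subset_cells(nk)
    states = tr[nk]["state"].replace("", HEALTHY_LABEL)
    pb = pbk.make_pseudobulk(m_nk, pd.Series(states.to_numpy(), index=m_nk.barcodes))
    keep = ~pb.flagged
    pb = pbk.PseudoBulkMatrix(
        genes=pb.genes, columns=pb.columns[keep], counts=pb.counts[:, keep],
        n_cells=pb.n_cells[keep],
    )
    lc = pbk.log_cpm(pb)
    var = lc.var(axis=1)
    top = np.argsort(-var, kind="stable")[:n_top_genes]
    lc_top = lc[top]
    names = [str(g) for g in pb.genes[top]]
    params = cx.CoexpParams(min_module_size=min_module_size, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tom = cx.adjacency_tom(lc_top, params)
        mod = cx.detect_modules(tom, params, gene_names=names, x=lc_top)
    samples = pb.columns.get_level_values("sample")
    group_of_sample = samples.str.rsplit("_", n=1).str[0]
    trend = group_of_sample.map(truth.group_trend).to_numpy(dtype=float)
    if not mod.module_ids:
        return {"seed": seed, "n_modules": 0, "hit": False, "jaccard": 0.0, "top_rho": 0.0}
    tc = cx.module_trait_correlation(mod.eigengenes, trend)
    planted = set(truth.module_genes)
    best_mid, best_j = None, 0.0
    for mid in mod.module_ids:
        genes = set(mod.genes_in(mid))
        j = len(genes & planted) / len(genes | planted)
        if j > best_j:
            best_mid, best_j = mid, j
    top_mod = tc["rho"].abs().idxmax()
    return {
        "seed": seed,
        "n_modules": len(mod.module_ids),
        "planted_module": best_mid,
        "jaccard": best_j,
        "top_rho": float(tc["rho"].abs().max()),
        "hit": best_mid is not None and f"M{best_mid}" == top_mod,
    }


def communication_recovery(seed: int, n_cells: int = 60, n_perm: int = 100) -> dict:
    """Planted source-specific ligand / target-specific receptor design:
    does the planted channel rank first in aggregate weight?"""
    rng = np.random.default_rng(seed)
    genes = ["LIG1", "LIG2", "REC1", "REC2", "HK1", "HK2", "BG1", "BG2"]
    pops = np.repeat(["NK_apoptosis", "neutrophil", "dendritic", "T_CD8"], n_cells)
    n = len(pops)
    vals = np.abs(rng.normal(0.6, 0.2, size=(len(genes), n)))
    vals[0:2, pops == "NK_apoptosis"] += 2.5      # ligands in source
    vals[2:4, pops == "neutrophil"] += 2.5        # receptors in target
    vals[4:6] = 1.0                               # housekeeping
    x = io_qc.ExpressionMatrix(
        genes=np.asarray(genes, dtype=object),
        barcodes=np.asarray([f"c{i}" for i in range(n)], dtype=object),
        x=vals,
        cell_meta=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
    )
    pairs = [
        cn.LRPair("LIG1", ("REC1",), "CXCL"),
        cn.LRPair("LIG2", ("REC2",), "CXCL"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = cn.score_communication(x, pops, pairs, n_perm=n_perm, seed=seed)
    if len(graph.table) == 0:
        return {"seed": seed, "hit": False, "weight": 0.0}
    totals = graph.table.groupby(["source", "target"])["weight"].sum()
    best = totals.idxmax()
    return {
        "seed": seed,
        "hit": best == ("NK_apoptosis", "neutrophil"),
        "weight": float(totals.max()),
        "min_p": float(graph.pairs["p"].min()),
    }


def trajectory_recovery(seed: int) -> dict:
    """Linear differentiation design: Spearman agreement of MST pseudotime
    with the planted depth."""
    import scipy.stats

    rng = np.random.default_rng(seed)
    depths = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    centroids = np.column_stack([depths * 3.0, np.zeros(5)])
    coords, labels, true_depth = [], [], []
    for d, c in zip(depths, centroids):
        pts = c + rng.normal(0, 0.7, size=(60, 2))
        coords.append(pts)
        labels.extend([f"S{int(d)}"] * 60)
        true_depth.extend(d + rng.normal(0, 0.05, size=60))
    coords = np.vstack(coords)
    labels = np.asarray(labels)
    model = tj.fit_mst(coords, labels)
    pt = tj.pseudotime(model, coords, labels, root="S0")
    rho = float(scipy.stats.spearmanr(pt, np.asarray(true_depth)).statistic)
    return {"seed": seed, "spearman": rho, "n_decision_points": len(tj.decision_points(model))}


def full_recovery(
    seed: int,
    n_cells_per_group: int = 1000,
    n_perm: int = 1000,
) -> tuple[RecoveryResult, dict]:
    """Classification and module recovery from a single simulated
    experiment (shared preparation)."""
    prep = _prepare(seed, n_cells_per_group)
    return (
        _classification_from(prep, seed, n_perm),
        _module_from(prep, seed),
    )
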