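"""Pseudo-bulk aggregation and differential expression.

Single-cell counts are summed per (sample, state) into bulk-like columns;
contrasts between column groups use counts-per-million normalization, a
two-sided Wilcoxon rank-sum test on log2 CPM across replicate columns, and
Benjamini-Hochberg adjustment.  A gene is flagged differential when
|log2FC| > 1 and adjusted p < 0.05.  This rank-based test deliberately
replaces a parametric negative-binomial model: real-data DEG counts will
agree in spirit, not number, with analyses built on such models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .deathstate import benjamini_hochberg
from .io_qc import CountMatrix


class PseudoBulkError(ValueError):
    pass


@dataclass
class PseudoBulkMatrix:
    genes: np.ndarray
    columns: pd.MultiIndex            # (sample, state)
    counts: np.ndarray                # genes x columns, integer sums
    n_cells: np.ndarray               # cells per column
    min_cells_flag: int = 10

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def flagged(self) -> np.ndarray:
        """Columns backed by fewer than ``min_cells_flag`` cells."""
        return self.n_cells < self.min_cells_flag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.columns)


def make_pseudobulk(
    m: CountMatrix,
    states: pd.Series | np.ndarray,
    sample_col: str = "sample",
    min_cells_flag: int = 10,
) -> PseudoBulkMatrix:
    """Sum UMIs per (sample, state) column.

    ``states`` aligns with the matrix barcodes (a Series indexed by barcode
    or a bare vector).  Column sums equal the summed counts of their member
    cells exactly.
    """
    if isinstance(states, pd.Series):
        states = states.reindex(m.barcodes).to_numpy()
    states = np.asarray(states).astype(str)
    if len(states) != m.n_cells:
        raise PseudoBulkError("state vector does not align with cells")
    samples = m.cell_meta[sample_col].to_numpy().astype(str)
    keys = pd.MultiIndex.from_arrays([samples, states], names=["sample", "state"])
    uniq = keys.unique().sort_values()
    counts = np.zeros((m.n_genes, len(uniq)), dtype=np.int64)
    n_cells = np.zeros(len(uniq), dtype=int)
    csc = m.counts.tocsc()
    lookup = {key: i for i, key in enumerate(uniq)}
    col_of_cell = np.array([lookup[k] for k in keys])
    for j in range(len(uniq)):
        sel = np.flatnonzero(col_of_cell == j)
        n_cells[j] = len(sel)
        counts[:, j] = np.asarray(csc[:, sel].sum(axis=1)).ravel()
    return PseudoBulkMatrix(
        genes=m.genes, columns=uniq, counts=counts, n_cells=n_cells,
        min_cells_flag=min_cells_flag,
    )


def log_cpm(pb: PseudoBulkMatrix, prior: float = 1.0) -> np.ndarray:
    lib = pb.library_sizes.astype(float)
    if np.any(lib == 0):
        raise PseudoBulkError("pseudo-bulk column with zero total counts")
    cpm = pb.counts / lib[None, :] * 1e6
    return np.log2(cpm + prior)


def de_contrast(
    pb: PseudoBulkMatrix,
    group_a: np.ndarray | list[bool] | list[int],
    group_b: np.ndarray | list[bool] | list[int],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential expression between two sets of pseudo-bulk columns.

    log2FC is the difference of mean log2 CPM (prior 1); p from a two-sided
    Wilcoxon rank-sum across replicate columns (exact when both sides have
    <= 10 columns); BH across genes; DEG flag per the |log2FC| > 1 and
    p_adj < 0.05 rule.
    """
    a_idx = np.asarray(group_a)
    b_idx = np.asarray(group_b)
    if a_idx.dtype == bool:
        a_idx = np.flatnonzero(a_idx)
    if b_idx.dtype == bool:
        b_idx = np.flatnonzero(b_idx)
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise PseudoBulkError("each side needs at least 2 replicate columns")
    lc = log_cpm(pb)
    la, lb = lc[:, a_idx], lc[:, b_idx]
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    method = "exact" if (len(a_idx) <= 10 and len(b_idx) <= 10) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(
            la, lb, axis=-1, alternative="two-sided", method=method
        )
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant rows have undefined ranksum p; no evidence either way
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "gene": pb.genes,
            "log2FC": log2fc,
            "p": p,
            "p_adj": p_adj,
        }
    ).set_index("gene")
    out["deg"] = (np.abs(out["log2FC"]) > lfc_threshold) & (out["p_adj"] < alpha)
    return out


def state_contrasts(
    pb: PseudoBulkMatrix,
    mode: str = "one_vs_rest",
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """DE tables per state: each state's columns vs all other states pooled
    (``one_vs_rest``), or every ordered pair (``one_vs_one``)."""
    states = pb.columns.get_level_values("state").to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    uniq = sorted(set(states))
    if mode == "one_vs_rest":
        for s in uniq:
            mask = states == s
            if mask.sum() < 2 or (~mask).sum() < 2:
                warnings.warn(f"state {s!r} lacks replicate columns; skipped")
                continue
            tables[s] = de_contrast(pb, mask, ~mask, **kwargs)
    elif mode == "one_vs_one":
        for sa in uniq:
            for sb in uniq:
                if sa >= sb:
                    continue
                ma, mb = states == sa, states == sb
                if ma.sum() < 2 or mb.sum() < 2:
                    continue
                tables[f"{sa}_vs_{sb}"] = de_contrast(pb, ma, mb, **kwargs)
    else:
        raise PseudoBulkError(f"unknown contrast mode {mode!r}")
    return tables
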