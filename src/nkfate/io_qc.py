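"""Ingestion, quality control, normalization, feature selection, PCA and a
simplified batch correction for 10x-style UMI count matrices.

The processing contract follows the common droplet-based workflow: cells are
kept if they have 200–2500 detected genes, 800–10,000 total UMIs and under 5%
mitochondrial UMIs; counts are library-size normalized to a fixed scale
factor and natural-log transformed; 2000 highly variable genes feed a
center/unit-variance scaling (clipped at +/-10) and an exact PCA of which the
top 10 components are used by every downstream stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample", "group", "batch")


class FormatError(ValueError):
    """Inconsistent on-disk matrix."""


class QCError(ValueError):
    """Quality control removed everything, or inputs violate a contract."""


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with per-cell metadata.

    ``counts`` is gene-major (rows = genes) to match the on-disk MTX layout.
    """

    genes: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        self.counts = self.counts.tocsr()
        ng, nc = self.counts.shape
        if len(self.genes) != ng or len(self.barcodes) != nc:
            raise FormatError(
                f"dimension mismatch: counts {self.counts.shape}, "
                f"{len(self.genes)} genes, {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise FormatError("non-integral counts")
        self.counts.data = self.counts.data.astype(np.int64)
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        self.cell_meta = self.cell_meta.reindex(pd.Index(self.barcodes, name="barcode"))
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = ""
        self.cell_meta = self.cell_meta.fillna("")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return CountMatrix(
            genes=self.genes,
            barcodes=self.barcodes[idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return CountMatrix(
            genes=self.genes[idx],
            barcodes=self.barcodes,
            counts=self.counts[idx],
            cell_meta=self.cell_meta.copy(),
        )


@dataclass
class QCParams:
    min_features: int = 200
    max_features: int = 2500
    min_counts: int = 800
    max_counts: int = 10_000
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (self.min_features < self.max_features):
            raise QCError("min_features must be < max_features")
        if not (self.min_counts < self.max_counts):
            raise QCError("min_counts must be < max_counts")
        if not (0.0 <= self.max_mito_frac <= 1.0):
            raise QCError("max_mito_frac must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_features: int
    removed_counts: int
    removed_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


@dataclass
class NormParams:
    scale_factor: float = 1e4


@dataclass
class ExpressionMatrix:
    """Dense log-normalized gene x cell expression."""

    genes: np.ndarray
    barcodes: np.ndarray
    x: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError("expression dims inconsistent with gene/barcode lists")

    @property
    def n_genes(self) -> int:
        return self.x.shape[0]

    @property
    def n_cells(self) -> int:
        return self.x.shape[1]

    def subset_genes(self, names) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([pos[g] for g in names], dtype=int)
        return ExpressionMatrix(self.genes[idx], self.barcodes, self.x[idx], self.cell_meta)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return ExpressionMatrix(
            self.genes, self.barcodes[idx], self.x[:, idx], self.cell_meta.iloc[idx].copy()
        )


@dataclass
class Embedding:
    """PCA scores, loadings and explained-variance shares for k components."""

    coords: np.ndarray            # cells x k
    loadings: np.ndarray          # hvg genes x k
    explained_variance_ratio: np.ndarray
    k: int
    hvgs: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_10x(dir_path: str | Path) -> CountMatrix:
    """Read an MTX-triplet directory (matrix.mtx, genes.tsv, barcodes.tsv and
    an optional cell_metadata.tsv joined on barcode).

    A missing metadata file is tolerated (empty group/sample/batch columns,
    warning logged).  Duplicate gene symbols are resolved by keeping the row
    with the highest total count.
    """
    dir_path = Path(dir_path)
    mtx_path = dir_path / "matrix.mtx"
    genes_path = dir_path / "genes.tsv"
    barcodes_path = dir_path / "barcodes.tsv"
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    genes = genes_df.iloc[:, -1].to_numpy(dtype=object)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy(
        dtype=object
    )
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"matrix declares {counts.shape[0]} genes but genes.tsv has {len(genes)}"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix declares {counts.shape[1]} cells but barcodes.tsv has {len(barcodes)}"
        )
    meta_path = dir_path / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
    else:
        logger.warning("no cell_metadata.tsv in %s; group/sample/batch left empty", dir_path)
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))

    genes_u, first = np.unique(genes, return_index=True)
    if len(genes_u) < len(genes):
        totals = np.asarray(counts.sum(axis=1)).ravel()
        keep = []
        for g in genes_u:
            rows = np.flatnonzero(genes == g)
            keep.append(rows[np.argmax(totals[rows])])
        keep = np.sort(np.array(keep))
        logger.warning(
            "%d duplicate gene symbols resolved by keeping the highest-total row",
            len(genes) - len(genes_u),
        )
        counts = counts[keep]
        genes = genes[keep]
    return CountMatrix(genes=genes, barcodes=barcodes, counts=counts, cell_meta=meta)


def qc_filter(m: CountMatrix, p: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Keep cells inside the detected-feature and total-count windows with a
    mitochondrial UMI fraction strictly below the cap."""
    p = p or QCParams()
    mito_mask = np.array([str(g).upper().startswith(p.mito_prefix.upper()) for g in m.genes])
    counts = m.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    ok_features = (detected >= p.min_features) & (detected <= p.max_features)
    ok_counts = (totals >= p.min_counts) & (totals <= p.max_counts)
    ok_mito = mito_frac < p.max_mito_frac
    keep = ok_features & ok_counts & ok_mito
    report = QCReport(
        n_input=m.n_cells,
        n_retained=int(keep.sum()),
        removed_features=int((~ok_features).sum()),
        removed_counts=int((~ok_counts).sum()),
        removed_mito=int((~ok_mito).sum()),
    )
    if not keep.any():
        raise QCError("QC removed every cell")
    return m.subset_cells(keep), report


def lognormalize(m: CountMatrix, p: NormParams | None = None) -> ExpressionMatrix:
    """x_gc = ln(1 + c_gc * s / T_c) with T_c the per-cell total count."""
    p = p or NormParams()
    counts = m.counts.tocsc().astype(np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = m.barcodes[np.flatnonzero(totals == 0)[0]]
        raise QCError(f"cell {bad!r} has zero total counts; run qc_filter first")
    scaled = counts.multiply(p.scale_factor / totals)
    x = np.log1p(np.asarray(scaled.todense()))
    return ExpressionMatrix(genes=m.genes, barcodes=m.barcodes, x=x, cell_meta=m.cell_meta.copy())


def select_hvg(x: ExpressionMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-n genes by dispersion standardized within equal-frequency mean bins.

    Dispersion is variance/mean of the log-normalized values; genes with zero
    variance are never selected.  Ranking is deterministic (score, then gene
    name).
    """
    means = x.x.mean(axis=1)
    var = x.x.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    order_by_mean = np.argsort(means, kind="stable")
    n_genes = x.n_genes
    # a bin needs enough members for its dispersion z-scores to mean anything
    n_bins = max(1, min(n_bins, n_genes // 20))
    bins = np.empty(n_genes, dtype=int)
    bins[order_by_mean] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    z = np.zeros(n_genes)
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf
    eligible = np.flatnonzero(var > 0)
    if n >= len(eligible):
        if n > len(eligible):
            warnings.warn(
                f"requested {n} HVGs but only {len(eligible)} non-constant genes; returning all"
            )
        return [x.genes[i] for i in eligible]
    order = np.lexsort((x.genes.astype(str), -z))
    return [x.genes[i] for i in order[:n]]


def scale_and_pca(
    x: ExpressionMatrix,
    hvgs: list[str] | None = None,
    k: int = 10,
    clip: float = 10.0,
) -> Embedding:
    """Per-gene center/unit-variance scaling (clipped at +/-clip) followed by
    exact PCA; scores are reproducible up to a fixed sign convention."""
    sub = x.subset_genes(hvgs) if hvgs is not None else x
    if k > sub.n_genes:
        raise QCError(f"k={k} exceeds number of features {sub.n_genes}")
    mat = sub.x
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    scaled = np.clip((mat - mu) / sd, -clip, clip)
    cells = scaled.T  # cells x genes
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(cells)
    sv = pca.singular_values_
    tol = max(cells.shape) * np.finfo(float).eps * (sv[0] if sv[0] > 0 else 1.0)
    if sv[-1] <= tol:
        rank = int((sv > tol).sum())
        raise QCError(f"k={k} exceeds data rank {rank}")
    comps = pca.components_  # k x genes
    # deterministic sign: largest-|loading| entry positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1
            coords[:, i] *= -1
    return Embedding(
        coords=coords,
        loadings=comps.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        k=k,
        hvgs=np.asarray(sub.genes, dtype=object),
        barcodes=sub.barcodes,
        cell_meta=sub.cell_meta,
    )


def integrate_batches(
    emb: Embedding,
    batches: np.ndarray | None = None,
    k_anchor: int = 5,
    sigma: float | None = None,
    n_iter: int = 5,
) -> Embedding:
    """Simplified mutual-nearest-neighbor batch correction in PC space.

    The largest batch is the reference.  Each moving cell's closest mutual
    kNN pair with the reference defines a correction vector; all cells of
    the batch receive a Gaussian-kernel-weighted average of those vectors.
    The correction is applied iteratively (a single pass under-corrects when
    the batch shift exceeds the cloud spread, because mutual pairs then
    connect facing boundaries) until the corrections become negligible or
    ``n_iter`` rounds are done.  Single-batch input is returned unchanged.
    This is a lightweight stand-in for anchor-based integration and is off
    by default in the pipeline.
    """
    if batches is None:
        batches = emb.cell_meta["batch"].to_numpy()
    batches = np.asarray(batches)
    levels, counts = np.unique(batches, return_counts=True)
    if len(levels) < 2:
        return emb
    if counts.min() < k_anchor:
        raise QCError(f"a batch has fewer than k_anchor={k_anchor} cells")
    ref = levels[np.argmax(counts)]
    coords = emb.coords.copy()
    ref_idx = np.flatnonzero(batches == ref)
    scale = max(float(np.linalg.norm(coords[ref_idx].std(axis=0))), 1e-12)
    for lev in levels:
        if lev == ref:
            continue
        mov_idx = np.flatnonzero(batches == lev)
        for _ in range(max(n_iter, 1)):
            a, b = coords[mov_idx], coords[ref_idx]
            nn_ab = NearestNeighbors(n_neighbors=k_anchor).fit(b)
            nn_ba = NearestNeighbors(n_neighbors=k_anchor).fit(a)
            _, ab = nn_ab.kneighbors(a)
            _, ba = nn_ba.kneighbors(b)
            ba_sets = [set(row) for row in ba]
            # per moving cell, the closest mutual pair (ab rows are
            # distance-ordered, so the first mutual hit is the closest)
            anchor_src, anchor_vec = [], []
            for i in range(len(a)):
                for j in ab[i]:
                    if i in ba_sets[j]:
                        anchor_src.append(i)
                        anchor_vec.append(b[j] - a[i])
                        break
            if not anchor_src:
                warnings.warn(
                    f"no MNN pairs between batch {lev!r} and reference; left uncorrected"
                )
                break
            src = a[np.array(anchor_src)]
            vec = np.array(anchor_vec)
            d = np.linalg.norm(a[:, None, :] - src[None, :, :], axis=2)
            if sigma is None:
                nn_d = np.partition(d, 0, axis=1)[:, 0]
                sig = max(float(np.median(nn_d)), 1e-12)
            else:
                sig = sigma
            w = np.exp(-0.5 * (d / sig) ** 2)
            w_sum = w.sum(axis=1, keepdims=True)
            w_sum[w_sum == 0] = 1.0
            correction = (w @ vec) / w_sum
            coords[mov_idx] = a + correction
            if np.linalg.norm(correction, axis=1).mean() < 1e-6 * scale:
                break
    return Embedding(
        coords=coords,
        loadings=emb.loadings,
        explained_variance_ratio=emb.explained_variance_ratio,
        k=emb.k,
        hvgs=emb.hvgs,
        barcodes=emb.barcodes,
        cell_meta=emb.cell_meta,
    )


def annotate_cell_types(
    x: ExpressionMatrix,
    markers: dict[str, list[str]],
    clusters: np.ndarray | None = None,
    expr_threshold: float = 0.5,
) -> np.ndarray:
    """Label cells (or clusters of cells) by their best-scoring canonical
    marker program.

    Each marker gene is z-scored across cells; a type's score is the mean z
    of its markers.  With ``clusters`` given, scores are averaged per cluster
    and a cluster whose cells express two or more conflicting marker programs
    (>= 2 type scores above ``expr_threshold``) is flagged ``"ambiguous"``.
    Cells (clusters) with no positive score are ``"unassigned"``.
    """
    types = list(markers)
    present = {t: [g for g in gs if g in set(x.genes)] for t, gs in markers.items()}
    if not any(present.values()):
        raise QCError("no marker gene overlaps the expression matrix")
    pos = {g: i for i, g in enumerate(x.genes)}
    scores = np.zeros((len(types), x.n_cells))
    for ti, t in enumerate(types):
        genes = present[t]
        if not genes:
            scores[ti] = -np.inf
            continue
        sub = x.x[[pos[g] for g in genes]]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        scores[ti] = ((sub - mu) / sd).mean(axis=0)

    def decide(score_vec: np.ndarray) -> str:
        expressed = np.flatnonzero(score_vec > expr_threshold)
        if len(expressed) >= 2:
            return "ambiguous"
        best = int(np.argmax(score_vec))
        if score_vec[best] <= 0:
            return "unassigned"
        return types[best]

    if clusters is None:
        return np.array([decide(scores[:, c]) for c in range(x.n_cells)], dtype=object)
    clusters = np.asarray(clusters)
    labels = np.empty(x.n_cells, dtype=object)
    for cid in np.unique(clusters):
        mask = clusters == cid
        labels[mask] = decide(scores[:, mask].mean(axis=1))
    return labels
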