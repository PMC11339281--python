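"""Weighted co-expression network analysis: soft-thresholded adjacency,
topological overlap, module detection, eigengenes, module-trait correlation,
over-representation analysis and loess trend fits.

The network is unsigned: a_ij = |cor(x_i, x_j)|^beta with the soft threshold
beta chosen for approximate scale-free topology (the published analysis used
beta = 6).  Modules are cut from an average-linkage dendrogram of the
topological overlap dissimilarity 1 - TOM; each module is summarized by its
eigengene (first principal component of the standardized module submatrix)
and correlated with traits (latent trends, death-state scores, pseudotime)
by Spearman's rho with the Student-t p approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .deathstate import benjamini_hochberg
from .genesets import GeneSet


class CoexpError(ValueError):
    pass


@dataclass
class CoexpParams:
    beta: float = 6.0
    min_module_size: int = 30
    #: static dendrogram cut on 1 - TOM; 0.9 is the cutreeStatic convention.
    #: None requests permutation calibration (cut at ``cut_quantile`` of the
    #: shuffled-gene null dissimilarity), which is sharper for small sample
    #: counts but collapses once weak systematic factors beat chance.
    cut_height: float | None = 0.9
    cut_quantile: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise CoexpError("beta must be >= 1")


@dataclass
class ModuleResult:
    """Gene -> module map (module 0 = unassigned), eigengenes and shares."""

    modules: pd.Series                 # index gene, value module id
    eigengenes: pd.DataFrame           # obs x module columns "M1", ...
    explained_variance: dict[str, float] = field(default_factory=dict)
    cut_height: float | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.modules.unique() if m != 0)

    def genes_in(self, module_id: int) -> list[str]:
        return list(self.modules.index[self.modules == module_id])


def _corrcoef_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise CoexpError(f"constant gene at row {int(np.flatnonzero(sd == 0)[0])}")
    return np.clip(np.corrcoef(x), -1.0, 1.0)


def adjacency(x: np.ndarray, beta: float = 6.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency a_ij = |cor|^beta, a_ii = 1."""
    a = np.abs(_corrcoef_rows(np.asarray(x, dtype=float))) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def adjacency_tom(x: np.ndarray, params: CoexpParams | None = None) -> np.ndarray:
    """Topological overlap matrix.

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k excluding the self-edge; t_ii = 1.  Entries lie in [0, 1]
    and the matrix is symmetric.
    """
    params = params or CoexpParams()
    a = adjacency(np.asarray(x, dtype=float), params.beta)
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    a0 = a - np.eye(n)
    # a0 has zero diagonal, so (a0 @ a0)_ij already sums over u != i, j
    num = a0 @ a0 + a0
    den = np.minimum(k[:, None], k[None, :]) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return t


def pick_soft_threshold(
    x: np.ndarray,
    candidate_betas: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Scale-free-topology fit across candidate soft thresholds.

    For each beta the connectivity distribution p(k) is binned (log-spaced,
    >= 5 occupied bins required) and R^2 of log10 p(k) on log10 k computed;
    the smallest beta reaching ``r2_threshold`` is returned, or the argmax
    with a warning when none does.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 50:
        raise CoexpError("need at least 50 genes to assess scale-free fit")
    if len(candidate_betas) == 1:
        b = float(candidate_betas[0])
        return b, pd.DataFrame({"beta": [b], "r2": [np.nan], "mean_k": [np.nan]})
    abscor = np.abs(_corrcoef_rows(x))
    rows = []
    for b in candidate_betas:
        a = abscor ** b
        k = a.sum(axis=1) - 1.0
        k = k[k > 0]
        edges = np.logspace(np.log10(k.min() + 1e-12), np.log10(k.max() + 1e-9), n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        ks, ps = [], []
        for i in range(n_bins):
            sel = which == i
            if sel.sum() == 0:
                continue
            ks.append(k[sel].mean())
            ps.append(sel.mean())
        r2 = np.nan
        if len(ks) >= 5:
            res = scipy.stats.linregress(np.log10(ks), np.log10(ps))
            r2 = res.rvalue**2
        rows.append({"beta": float(b), "r2": r2, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_threshold]
    if len(ok):
        return float(ok["beta"].iloc[0]), table
    best = table.loc[table["r2"].idxmax()]
    warnings.warn(
        f"no candidate beta reaches scale-free R^2 >= {r2_threshold}; "
        f"returning argmax beta={best['beta']} (R^2={best['r2']:.2f})"
    )
    return float(best["beta"]), table


def _calibrate_cut(
    x: np.ndarray, params: CoexpParams
) -> float:
    """Permutation-calibrated static cut height: each gene's profile is
    shuffled independently (destroying co-expression, keeping marginals) and
    the cut is placed at the ``cut_quantile`` of the null 1 - TOM values, a
    dissimilarity chance co-variation rarely attains."""
    rng = np.random.default_rng(params.seed)
    xp = np.array([rng.permutation(row) for row in np.asarray(x, dtype=float)])
    t_null = adjacency_tom(xp, params)
    iu = np.triu_indices_from(t_null, k=1)
    return float(np.quantile(1.0 - t_null[iu], params.cut_quantile))


def detect_modules(
    tom: np.ndarray,
    params: CoexpParams | None = None,
    gene_names: list[str] | None = None,
    x: np.ndarray | None = None,
) -> ModuleResult:
    """Average-linkage hierarchical clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` fall into module 0 (grey).
    When ``cut_height`` is None the cut is permutation-calibrated, which
    requires the expression matrix ``x``.  Module ids are 1..M ordered by
    decreasing size; eigengenes are computed when ``x`` is given.
    """
    params = params or CoexpParams()
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    names = list(gene_names) if gene_names is not None else [f"G{i}" for i in range(n)]
    if len(names) != n:
        raise CoexpError("gene_names length mismatch")
    cut = params.cut_height
    if cut is None:
        if x is None:
            raise CoexpError("cut_height=None needs the expression matrix for calibration")
        cut = _calibrate_cut(x, params)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(ssd.squareform(diss, checks=False), method="average")
    raw = sch.fcluster(link, t=cut, criterion="distance")
    modules = np.zeros(n, dtype=int)
    ids, counts = np.unique(raw, return_counts=True)
    kept = [
        (cid, cnt) for cid, cnt in zip(ids, counts) if cnt >= params.min_module_size
    ]
    kept.sort(key=lambda ic: (-ic[1], ic[0]))
    for new_id, (cid, _) in enumerate(kept, start=1):
        modules[raw == cid] = new_id
    if not kept:
        warnings.warn("all genes unassigned (module 0); no cluster reached min_module_size")
    series = pd.Series(modules, index=pd.Index(names, name="gene"), name="module")
    eig = pd.DataFrame()
    ev: dict[str, float] = {}
    if x is not None:
        x = np.asarray(x, dtype=float)
        cols = {}
        for mid in sorted(set(modules) - {0}):
            e, share = module_eigengene(x[modules == mid])
            cols[f"M{mid}"] = e
            ev[f"M{mid}"] = share
        eig = pd.DataFrame(cols)
    return ModuleResult(modules=series, eigengenes=eig, explained_variance=ev, cut_height=cut)


def module_eigengene(x_module: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of the standardized module submatrix
    (genes x observations), unit-norm, sign-oriented to correlate positively
    with the module's mean expression profile.  Returns (eigengene over
    observations, explained-variance share)."""
    x_module = np.asarray(x_module, dtype=float)
    if x_module.ndim != 2 or x_module.shape[0] < 2:
        raise CoexpError("module needs at least 2 genes")
    mu = x_module.mean(axis=1, keepdims=True)
    sd = x_module.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise CoexpError("rank-0 module submatrix (all genes constant)")
    sd[sd == 0] = 1.0
    z = (x_module - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise CoexpError("rank-0 module submatrix")
    e = vt[0]
    share = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e, share


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of every module eigengene with a trait; p from
    the Student-t approximation t = rho sqrt((n-2)/(1-rho^2))."""
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if n < 4:
        raise CoexpError("need at least 4 aligned observations")
    if len(eigengenes) != n:
        raise CoexpError("eigengene rows do not align with trait")
    rows = []
    for col in eigengenes.columns:
        rho = scipy.stats.spearmanr(eigengenes[col].to_numpy(), trait).statistic
        rho = float(np.clip(rho, -1.0, 1.0))
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
        rows.append({"module": col, "rho": rho, "p": p})
    return pd.DataFrame(rows).set_index("module")


def ora(
    gene_list: list[str],
    sets: list[GeneSet] | GeneSet,
    universe: list[str],
) -> pd.DataFrame:
    """Over-representation of a gene list in each set: upper-tail
    hypergeometric P(X >= k) over the universe, BH-adjusted across sets."""
    if isinstance(sets, GeneSet):
        sets = [sets]
    universe_set = set(universe)
    gene_list = [g for g in dict.fromkeys(gene_list)]
    if not gene_list:
        raise CoexpError("empty gene list")
    if not set(gene_list) <= universe_set:
        raise CoexpError("gene list must be a subset of the universe")
    n_u = len(universe_set)
    n_l = len(gene_list)
    rows = []
    for s in sets:
        members = set(s.genes) & universe_set
        k = len(members & set(gene_list))
        m = len(members)
        p = float(scipy.stats.hypergeom.sf(k - 1, n_u, m, n_l)) if m else 1.0
        expected = n_l * m / n_u if n_u else 0.0
        rows.append(
            {
                "set": s.name,
                "overlap": k,
                "set_size": m,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def loess_trend(
    xvals: np.ndarray,
    yvals: np.ndarray,
    span: float = 0.75,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Locally weighted (tricube) linear regression with a residual-bootstrap
    confidence band.

    Returns a frame indexed by sorted unique x with columns fit, lo, hi.
    """
    xvals = np.asarray(xvals, dtype=float)
    yvals = np.asarray(yvals, dtype=float)
    if len(xvals) != len(yvals):
        raise CoexpError("x and y lengths differ")
    if len(xvals) < 10:
        raise CoexpError("need at least 10 points")
    n_local = int(np.ceil(span * len(xvals)))
    if n_local < 3:
        raise CoexpError(f"span {span} leaves fewer than 3 points per local fit")
    fit = lowess(yvals, xvals, frac=span, it=0, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    # collapse duplicate x (lowess already averages; be safe)
    xu, inv = np.unique(xs, return_inverse=True)
    yu = np.zeros_like(xu)
    for i in range(len(xu)):
        yu[i] = ys[inv == i].mean()
    order = np.argsort(xvals, kind="stable")
    fitted_at_x = np.interp(xvals, xu, yu)
    resid = yvals - fitted_at_x
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(xu)))
    for b in range(n_boot):
        yb = fitted_at_x + rng.choice(resid, size=len(resid), replace=True)
        fb = lowess(yb, xvals, frac=span, it=0, return_sorted=True)
        xb, inv_b = np.unique(fb[:, 0], return_inverse=True)
        ybu = np.zeros_like(xb)
        for i in range(len(xb)):
            ybu[i] = fb[inv_b == i, 1].mean()
        boots[b] = np.interp(xu, xb, ybu)
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return pd.DataFrame({"x": xu, "fit": yu, "lo": lo, "hi": hi}).set_index("x")
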