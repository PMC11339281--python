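"""Death-paradigm classification of NK cells.

The classifier follows a two-step clustering (k-means vector quantization,
then modularity community detection on a shared-nearest-neighbor graph over
the micro-cluster centroids), ranks each cluster's genes by log2 fold change
against all other NK cells, scores the twelve regulated-cell-death signatures
with a weighted Kolmogorov-Smirnov-like running-sum statistic, and assesses
significance with an empirical phenotype-permutation test.  Each cluster is
assigned the paradigm with the highest normalized enrichment score (NES)
among signatures with NES > 0 and BH-adjusted p < alpha; clusters in which no
paradigm is enriched are called healthy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import igraph as ig
import leidenalg
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .genesets import (
    CANONICAL_PARADIGMS,
    HEALTHY_LABEL,
    GeneSet,
    GeneSetCollection,
    aggregate_state,
    restrict_to_universe,
)
from .io_qc import Embedding, ExpressionMatrix

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9


class ClassificationError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    params: dict = field(default_factory=dict)


@dataclass
class RankedList:
    """Genes in descending ranking-metric order for one cluster."""

    genes: np.ndarray
    metric: np.ndarray
    cluster_id: int
    pvalues: np.ndarray | None = None


@dataclass
class EnrichmentResult:
    cluster_id: int
    paradigm: str
    es: float
    nes: float
    p: float
    p_adj: float
    n_perm: int
    flagged: bool = False


@dataclass
class DeathStateTable:
    """Per-cell paradigm/state labels plus the per-cluster evidence."""

    cells: pd.DataFrame            # barcode, cluster, paradigm, state
    cluster_evidence: pd.DataFrame # cluster, paradigm, es, nes, p, p_adj, n_perm
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# two-step clustering


def two_step_cluster(
    emb: Embedding,
    k_micro: int | None = None,
    n_neighbors: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means micro-clusters on the PC scores, then modularity communities
    on the shared-nearest-neighbor (Jaccard) graph of the centroids; cells
    inherit their micro-cluster's community.  Deterministic given the seed.
    """
    coords = emb.coords
    n = coords.shape[0]
    if k_micro is None:
        k_micro = max(2, min(200, n // 10))
    if not (2 <= k_micro < n):
        raise ClassificationError(f"need #cells > k_micro >= 2, got n={n}, k_micro={k_micro}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trigger convergence warnings
        km = KMeans(n_clusters=k_micro, init="k-means++", n_init=10, random_state=seed)
        micro = km.fit_predict(coords)
    centroids = km.cluster_centers_
    k_nn = min(n_neighbors, k_micro - 1)
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(centroids)
    _, idx = nn.kneighbors(centroids)  # includes self at position 0
    neigh = np.zeros((k_micro, k_micro), dtype=bool)
    for i in range(k_micro):
        neigh[i, idx[i]] = True
        neigh[i, i] = True
    inter = (neigh.astype(np.int32) @ neigh.T.astype(np.int32)).astype(float)
    sizes = neigh.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    jac = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(jac, 0.0)
    # shared-nearest-neighbor edges only between MUTUAL kNN centroid pairs:
    # at centroid granularity a small population contributes few nodes, and
    # one-directional forced links would wire it into its nearest large
    # neighborhood
    mutual = neigh & neigh.T
    np.fill_diagonal(mutual, False)
    jac = np.where(mutual, jac, 0.0)
    src, dst = np.nonzero(np.triu(jac > 0, k=1))
    g = ig.Graph(n=k_micro, edges=list(zip(src.tolist(), dst.tolist())))
    weights = jac[src, dst].tolist()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    comm_of_micro = np.array(part.membership)
    cell_comm = comm_of_micro[micro]
    # relabel communities 1..C by decreasing size, ties by old id
    ids, counts = np.unique(cell_comm, return_counts=True)
    order = np.lexsort((ids, -counts))
    remap = {old: new + 1 for new, old in enumerate(ids[order])}
    labels = np.array([remap[c] for c in cell_comm])
    return ClusterAssignment(
        labels=labels,
        n_clusters=len(ids),
        params={
            "k_micro": k_micro,
            "n_neighbors": n_neighbors,
            "resolution": resolution,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# marker ranking


def _log2fc(expm1_x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mean_in = expm1_x[:, mask].mean(axis=1)
    mean_out = expm1_x[:, ~mask].mean(axis=1)
    return np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))


def rank_cluster_genes(
    x: ExpressionMatrix,
    clusters: np.ndarray,
    cluster_id: int,
    min_cells: int = 10,
    metric: str = "log2fc",
) -> RankedList:
    """Rank genes for one cluster against all remaining cells.

    The ranking metric is the log2 fold change of mean un-logged expression
    (cluster vs rest, epsilon-regularized); ties are broken by the two-sided
    Wilcoxon rank-sum p-value, then by gene name.  ``metric="snr"`` uses the
    signal-to-noise ratio instead.
    """
    clusters = np.asarray(clusters)
    mask = clusters == cluster_id
    if mask.sum() < min_cells:
        raise ClassificationError(
            f"cluster {cluster_id} has {int(mask.sum())} cells (<{min_cells})"
        )
    if (~mask).sum() < 1:
        raise ClassificationError("cluster covers all cells; no complement to rank against")
    expm1_x = np.expm1(x.x)
    if metric == "log2fc":
        vals = _log2fc(expm1_x, mask)
    elif metric == "snr":
        mi, mo = x.x[:, mask].mean(axis=1), x.x[:, ~mask].mean(axis=1)
        si, so = x.x[:, mask].std(axis=1), x.x[:, ~mask].std(axis=1)
        vals = (mi - mo) / (si + so + LOG2FC_EPS)
    else:
        raise ClassificationError(f"unknown ranking metric {metric!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(
            x.x[:, mask], x.x[:, ~mask], axis=-1, alternative="two-sided", method="asymptotic"
        )
    pvals = np.asarray(res.pvalue)
    order = np.lexsort((x.genes.astype(str), pvals, -vals))
    return RankedList(
        genes=x.genes[order], metric=vals[order], cluster_id=int(cluster_id), pvalues=pvals[order]
    )


# ---------------------------------------------------------------------------
# weighted KS-like enrichment statistic


def gsea_es(ranked: RankedList, gene_set: GeneSet, weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted Kolmogorov-Smirnov-like
    running sum.

    Walking the ranked list, hits add |r_i|^w / N_R (N_R the sum of |r|^w
    over the set's genes) and misses subtract 1/(N - N_hit); the enrichment
    score is the running sum's most extreme value.
    """
    genes = np.asarray(ranked.genes, dtype=object)
    metric = np.asarray(ranked.metric, dtype=float)
    members = set(gene_set.genes)
    hit = np.array([g in members for g in genes])
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ClassificationError(f"gene set {gene_set.name!r} has no gene in the ranking")
    if n_hit == n:
        raise ClassificationError(
            f"gene set {gene_set.name!r} covers the entire ranking; empty complement"
        )
    return float(_es_single(hit, np.abs(metric) ** weight, n_hit))


def _es_single(hit: np.ndarray, absr_w: np.ndarray, n_hit: int) -> float:
    n = len(hit)
    n_r = absr_w[hit].sum()
    if n_r > 0:
        inc = np.where(hit, absr_w / n_r, -1.0 / (n - n_hit))
    else:  # all hit metrics exactly zero: fall back to unweighted steps
        inc = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    run = np.cumsum(inc)
    return run[np.argmax(np.abs(run))]


def _es_columns(hit_cols: np.ndarray, absr_cols: np.ndarray) -> np.ndarray:
    """ES per column: hit_cols and absr_cols are (N, P) arrays already in
    ranked order per column."""
    n, p = hit_cols.shape
    n_hit = hit_cols.sum(axis=0)
    n_r = (absr_cols * hit_cols).sum(axis=0)
    miss_step = -1.0 / (n - n_hit)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(
            hit_cols,
            np.where(n_r > 0, absr_cols / np.where(n_r > 0, n_r, 1.0), 1.0 / n_hit),
            miss_step[None, :],
        )
    run = np.cumsum(inc, axis=0)
    pick = np.argmax(np.abs(run), axis=0)
    return run[pick, np.arange(p)]


# ---------------------------------------------------------------------------
# permutation test


def _permuted_es(
    expm1_x32: np.ndarray,
    mask: np.ndarray,
    sets_membership: np.ndarray,
    n_r_exponent_w: float,
    n_perm: int,
    rng: np.random.Generator,
    block: int = 250,
) -> np.ndarray:
    """ES under cluster-vs-rest label permutation for several gene sets at
    once; the ranking (log2 fold change) is recomputed for every permutation.

    Returns an (n_sets, n_perm) array.
    """
    g, n = expm1_x32.shape
    k = int(mask.sum())
    total = expm1_x32.sum(axis=1, dtype=np.float64)
    n_sets = sets_membership.shape[1]
    out = np.empty((n_sets, n_perm), dtype=np.float64)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        member = np.zeros((n, b), dtype=np.float32)
        for j in range(b):
            member[rng.choice(n, size=k, replace=False), j] = 1.0
        cs = (expm1_x32 @ member).astype(np.float64)
        mean_in = cs / k
        # float32 accumulation can push cs a hair past the exact total
        mean_out = np.maximum((total[:, None] - cs) / (n - k), 0.0)
        lfc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
        order = np.argsort(-lfc, axis=0, kind="stable")
        absr = np.abs(np.take_along_axis(lfc, order, axis=0)) ** n_r_exponent_w
        for s in range(n_sets):
            hit = sets_membership[:, s][order]
            out[s, done : done + b] = _es_columns(hit, absr)
        done += b
    return out


def _p_and_nes(es_obs: float, es_perm: np.ndarray) -> tuple[float, float, bool]:
    same_sign = es_perm * np.sign(es_obs) > 0 if es_obs != 0 else np.zeros_like(es_perm, bool)
    n_same = int(same_sign.sum())
    if n_same == 0:
        return 1.0, float("nan"), True
    extreme = int((np.abs(es_perm[same_sign]) >= abs(es_obs)).sum())
    p = (1.0 + extreme) / (1.0 + n_same)
    nes = es_obs / np.abs(es_perm[same_sign]).mean()
    return p, nes, False


def gsea_permutation(
    x: ExpressionMatrix,
    clusters: np.ndarray,
    cluster_id: int,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_cells: int = 10,
    exhaustive: bool = False,
) -> EnrichmentResult:
    """Empirical phenotype-permutation enrichment of one gene set in one
    cluster: cluster-vs-rest labels are shuffled, the ranking recomputed and
    the ES re-scored for every permutation.  p is the one-tailed frequency of
    same-sign permuted ES at least as extreme as the observed ES (add-one
    corrected); NES divides the observed ES by the mean |permuted ES| of the
    same sign.

    ``exhaustive=True`` enumerates every cluster-vs-rest split of the same
    size instead of sampling; the observed split is part of the enumeration,
    so p needs no add-one correction.
    """
    if not exhaustive and n_perm < 10:
        raise ClassificationError("n_perm must be >= 10")
    clusters = np.asarray(clusters)
    mask = clusters == cluster_id
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ClassificationError("cluster and complement must each have >= 3 cells")
    ranked = rank_cluster_genes(x, clusters, cluster_id, min_cells=min(min_cells, int(mask.sum())))
    es_obs = gsea_es(ranked, gene_set, weight=weight)
    membership = np.array([[g in set(gene_set.genes)] for g in x.genes], dtype=bool)
    expm1_x = np.expm1(x.x)
    if exhaustive:
        import itertools

        n, k = len(clusters), int(mask.sum())
        es_list = []
        total = expm1_x.sum(axis=1)
        for idx in itertools.combinations(range(n), k):
            msk = np.zeros(n, dtype=bool)
            msk[list(idx)] = True
            mi = expm1_x[:, msk].mean(axis=1)
            mo = np.maximum((total - expm1_x[:, msk].sum(axis=1)) / (n - k), 0.0)
            lfc = np.log2((mi + LOG2FC_EPS) / (mo + LOG2FC_EPS))
            order = np.lexsort((x.genes.astype(str), -lfc))
            hit = membership[order, 0]
            es_list.append(_es_single(hit, np.abs(lfc[order]) ** weight, int(hit.sum())))
        es_perm = np.asarray(es_list)
        n_perm = len(es_perm)
        same = es_perm * np.sign(es_obs) > 0
        if not same.any():
            p, nes, flagged = 1.0, float("nan"), True
        else:
            p = float((np.abs(es_perm[same]) >= abs(es_obs) - 1e-12).sum() / same.sum())
            nes = float(es_obs / np.abs(es_perm[same]).mean())
            flagged = False
    else:
        rng = np.random.default_rng(seed)
        es_perm = _permuted_es(
            expm1_x.astype(np.float32), mask, membership, weight, n_perm, rng
        )[0]
        p, nes, flagged = _p_and_nes(es_obs, es_perm)
    return EnrichmentResult(
        cluster_id=int(cluster_id),
        paradigm=gene_set.name,
        es=float(es_obs),
        nes=float(nes),
        p=float(p),
        p_adj=float(p),
        n_perm=n_perm,
        flagged=flagged,
    )


def enrich_cluster(
    x: ExpressionMatrix,
    clusters: np.ndarray,
    cluster_id: int,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_cells: int = 10,
) -> list[EnrichmentResult]:
    """Permutation enrichment of every set in the collection against one
    cluster, sharing the permuted rankings across sets, with BH adjustment
    across the collection."""
    clusters = np.asarray(clusters)
    mask = clusters == cluster_id
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ClassificationError("cluster and complement must each have >= 3 cells")
    ranked = rank_cluster_genes(x, clusters, cluster_id, min_cells=min_cells)
    es_obs = np.array([gsea_es(ranked, s, weight=weight) for s in collection])
    membership = np.zeros((x.n_genes, len(collection)), dtype=bool)
    for si, s in enumerate(collection):
        members = set(s.genes)
        membership[:, si] = [g in members for g in x.genes]
    rng = np.random.default_rng(seed)
    es_perm = _permuted_es(
        np.expm1(x.x).astype(np.float32), mask, membership, weight, n_perm, rng
    )
    results = []
    p_enrich = []
    for si, s in enumerate(collection):
        p, nes, flagged = _p_and_nes(es_obs[si], es_perm[si])
        # the assignment rule is one-sided (only positive enrichment can be
        # selected), so the multiplicity family is the enrichment direction:
        # depleted sets enter BH with p=1 rather than with their depletion
        # tail, which would otherwise shrink the family and anti-conservatively
        # promote weak positive scores
        p_enrich.append(p if (es_obs[si] > 0 and not flagged) else 1.0)
        results.append(
            EnrichmentResult(
                cluster_id=int(cluster_id),
                paradigm=s.name,
                es=float(es_obs[si]),
                nes=float(nes),
                p=float(p),
                p_adj=float("nan"),
                n_perm=n_perm,
                flagged=flagged,
            )
        )
    p_adj = benjamini_hochberg(np.array(p_enrich))
    for r, q in zip(results, p_adj):
        r.p_adj = float(max(q, r.p))
    return results


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.clip(adj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# paradigm assignment


def assign_paradigms(
    results: dict[int, list[EnrichmentResult]],
    cluster_labels: np.ndarray,
    barcodes: np.ndarray,
    alpha: float = 0.05,
    paradigm_order: tuple[str, ...] = CANONICAL_PARADIGMS,
) -> DeathStateTable:
    """Per-cluster max-NES paradigm assignment with healthy fallback.

    A cluster's label is the paradigm with the largest NES among results
    with NES > 0 and adjusted p < alpha; if none qualifies the cluster is
    healthy.  NES ties are broken by the canonical paradigm order.
    """
    order_rank = {p: i for i, p in enumerate(paradigm_order)}
    cluster_paradigm: dict[int, str] = {}
    rows = []
    for cid, res in results.items():
        got = {r.paradigm for r in res}
        missing = [p for p in paradigm_order if p not in got]
        if missing:
            raise ClassificationError(f"cluster {cid}: missing paradigm results {missing}")
        qualifying = [
            r for r in res if (not r.flagged) and r.nes > 0 and r.p_adj < alpha
        ]
        if not qualifying:
            label = HEALTHY_LABEL
        else:
            best_nes = max(r.nes for r in qualifying)
            top = [r for r in qualifying if r.nes == best_nes]
            if len(top) > 1:
                logger.info(
                    "cluster %s: NES tie between %s; canonical order breaks it",
                    cid,
                    [r.paradigm for r in top],
                )
            label = min(top, key=lambda r: order_rank[r.paradigm]).paradigm
        cluster_paradigm[cid] = label
        for r in res:
            rows.append(
                {
                    "cluster": cid,
                    "paradigm": r.paradigm,
                    "es": r.es,
                    "nes": r.nes,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "n_perm": r.n_perm,
                    "flagged": r.flagged,
                }
            )
    cluster_labels = np.asarray(cluster_labels)
    paradigms = np.array(
        [cluster_paradigm.get(int(c), HEALTHY_LABEL) for c in cluster_labels], dtype=object
    )
    states = np.array(
        [aggregate_state(p) if p != HEALTHY_LABEL else HEALTHY_LABEL for p in paradigms],
        dtype=object,
    )
    cells = pd.DataFrame(
        {
            "barcode": np.asarray(barcodes, dtype=object),
            "cluster": cluster_labels,
            "paradigm": paradigms,
            "state": states,
        }
    )
    return DeathStateTable(
        cells=cells, cluster_evidence=pd.DataFrame(rows), alpha=alpha
    )


# ---------------------------------------------------------------------------
# end-to-end classification


def classify_death_states(
    x: ExpressionMatrix,
    emb: Embedding,
    collection: GeneSetCollection,
    k_micro: int | None = None,
    n_neighbors: int = 10,
    resolution: float = 1.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    weight: float = 1.0,
    min_cells: int = 10,
    seed: int = 0,
    paradigm_override: list[str] | None = None,
    min_detect_frac: float = 0.05,
) -> DeathStateTable:
    """Cluster the (NK) cells and classify every cluster into one of the
    twelve paradigms or healthy.

    Before ranking, the tested universe is restricted to genes detected in
    at least ``min_detect_frac`` of the cells (and the signatures intersected
    with it): genes at the detection limit produce epsilon-dominated fold
    changes that only add rank noise to the running-sum statistic.  Clusters
    smaller than ``min_cells`` cannot be ranked and default to healthy with
    a warning."""
    collection.validate_paradigms(paradigm_override)
    if min_detect_frac > 0:
        detected = (x.x > 0).mean(axis=1) >= min_detect_frac
        if not detected.any():
            raise ClassificationError("no gene passes the detection filter")
        x = ExpressionMatrix(x.genes[detected], x.barcodes, x.x[detected], x.cell_meta)
    collection = restrict_to_universe(collection, x.genes)
    assignment = two_step_cluster(
        emb, k_micro=k_micro, n_neighbors=n_neighbors, resolution=resolution, seed=seed
    )
    results: dict[int, list[EnrichmentResult]] = {}
    paradigm_order = tuple(paradigm_override) if paradigm_override else CANONICAL_PARADIGMS
    tiny: list[int] = []
    for i, cid in enumerate(np.unique(assignment.labels)):
        size = int((assignment.labels == cid).sum())
        if size < max(min_cells, 3) or (len(assignment.labels) - size) < 3:
            tiny.append(int(cid))
            results[int(cid)] = [
                EnrichmentResult(int(cid), s.name, 0.0, float("nan"), 1.0, 1.0, 0, flagged=True)
                for s in collection
            ]
            continue
        results[int(cid)] = enrich_cluster(
            x,
            assignment.labels,
            cid,
            collection,
            n_perm=n_perm,
            seed=seed + int(cid),
            weight=weight,
            min_cells=min_cells,
        )
    if tiny:
        warnings.warn(f"clusters {tiny} too small to rank; defaulted to healthy")
    table = assign_paradigms(
        results, assignment.labels, emb.barcodes, alpha=alpha, paradigm_order=paradigm_order
    )
    table.cells.attrs["cluster_params"] = assignment.params
    return table
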