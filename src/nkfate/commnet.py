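"""Ligand-receptor communication scoring between death-state NK groups and
other immune cell populations.

The model follows the mass-action communication framework: ligands and
receptors must be over-expressed in their source/target populations
(one-sided Wilcoxon vs the other cells, detection in >= 10% of the group);
group expression is summarized by Tukey's trimean; the interaction
probability of a pair is p = (L*R)/(Kh + L*R); significance comes from a
group-label permutation test; and significant pair probabilities are summed
into pathway-level weights per (source, target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .io_qc import ExpressionMatrix


class CommError(ValueError):
    pass


@dataclass
class LRPair:
    ligand: str
    receptor: tuple[str, ...] | str   # all subunits required
    pathway: str

    def __post_init__(self) -> None:
        if isinstance(self.receptor, str):
            self.receptor = tuple(s for s in self.receptor.split(";") if s)
        else:
            self.receptor = tuple(self.receptor)
        if not self.ligand or not self.receptor:
            raise CommError("ligand and receptor must be non-empty")
        if not self.pathway:
            raise CommError("pathway must be named")


@dataclass
class CommGraph:
    """Pathway-aggregated communication weights between populations."""

    table: pd.DataFrame  # source, target, pathway, weight, n_pairs
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def weight(self, source: str, target: str, pathway: str | None = None) -> float:
        sel = (self.table["source"] == source) & (self.table["target"] == target)
        if pathway is not None:
            sel &= self.table["pathway"] == pathway
        return float(self.table.loc[sel, "weight"].sum())


def read_lr_database(path: str | Path) -> list[LRPair]:
    """TSV with columns ligand, receptor (subunits ';'-separated), pathway."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"ligand", "receptor", "pathway"}
    if not required <= set(df.columns):
        raise CommError(f"LR database needs columns {sorted(required)}")
    return [
        LRPair(ligand=r.ligand, receptor=r.receptor, pathway=r.pathway)
        for r in df.itertuples()
    ]


def packaged_lr_database() -> list[LRPair]:
    """Minimal packaged ligand-receptor table (placeholder memberships for
    the pathways highlighted in the trauma NK analysis; supply a full
    database for real studies)."""
    ref = resources.files("nkfate") / "data" / "lr_pairs_minimal.tsv"
    with resources.as_file(ref) as p:
        return read_lr_database(p)


def detect_overexpressed(
    x: ExpressionMatrix,
    groups: np.ndarray,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    min_frac: float = 0.10,
    min_cells: int = 10,
) -> dict[str, set[str]]:
    """Genes over-expressed per population: one-sided Wilcoxon rank-sum
    (group vs all other cells) p < alpha and detection in >= min_frac of the
    group's cells.  Groups below ``min_cells`` are skipped with a warning."""
    groups = np.asarray(groups).astype(str)
    sub = x.subset_genes(genes) if genes is not None else x
    out: dict[str, set[str]] = {}
    for grp in np.unique(groups):
        mask = groups == grp
        if mask.sum() < min_cells:
            warnings.warn(f"population {grp!r} has {int(mask.sum())} cells (<{min_cells}); skipped")
            continue
        a, b = sub.x[:, mask], sub.x[:, ~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scipy.stats.mannwhitneyu(
                a, b, axis=-1, alternative="greater", method="asymptotic"
            )
        pvals = np.asarray(res.pvalue)
        frac = (a > 0).mean(axis=1)
        hits = (pvals < alpha) & (frac >= min_frac)
        out[grp] = {g for g, h in zip(sub.genes, hits) if h}
    return out


def trimean_expression(
    x: ExpressionMatrix, groups: np.ndarray, group: str, gene: str
) -> float:
    """Tukey trimean (Q1 + 2*Q2 + Q3)/4 of the gene's normalized expression
    in the population; quartiles by linear interpolation (type-7)."""
    groups = np.asarray(groups).astype(str)
    mask = groups == str(group)
    if mask.sum() == 0:
        raise CommError(f"population {group!r} is empty")
    gi = np.flatnonzero(x.genes == gene)
    if len(gi) == 0:
        raise CommError(f"gene {gene!r} not in matrix")
    vals = x.x[gi[0], mask]
    return _trimean(vals)


def _trimean(vals: np.ndarray) -> float:
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # numpy default = type-7
    return float((q1 + 2.0 * q2 + q3) / 4.0)


def interaction_probability(
    ligand_trimean: float, receptor_trimean: float, kh: float = 0.5
) -> float:
    """Mass-action communication probability p = L*R / (Kh + L*R)."""
    if ligand_trimean < 0 or receptor_trimean < 0:
        raise CommError("trimean expression must be non-negative")
    lr = ligand_trimean * receptor_trimean
    return float(lr / (kh + lr))


def _pair_probability(
    x: ExpressionMatrix, groups: np.ndarray, pair: LRPair, source: str, target: str, kh: float
) -> float:
    lig = trimean_expression(x, groups, source, pair.ligand)
    subunits = [trimean_expression(x, groups, target, r) for r in pair.receptor]
    rec = float(np.exp(np.mean(np.log(np.maximum(subunits, 1e-300))))) if min(subunits) > 0 else 0.0
    return interaction_probability(lig, rec, kh)


def permutation_significance(
    x: ExpressionMatrix,
    groups: np.ndarray,
    pair: LRPair,
    source: str,
    target: str,
    n_perm: int = 100,
    seed: int = 0,
    kh: float = 0.5,
) -> tuple[float, float]:
    """Label-permutation p-value for one pair and channel.

    Group labels are shuffled across all cells n_perm times; p is the
    add-one-corrected frequency of permuted probabilities >= observed.
    Returns (observed probability, p).
    """
    if n_perm < 10:
        raise CommError("n_perm must be >= 10")
    groups = np.asarray(groups).astype(str)
    obs = _pair_probability(x, groups, pair, source, target, kh)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _pair_probability(x, perm, pair, source, target, kh) >= obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return obs, p


def score_communication(
    x: ExpressionMatrix,
    groups: np.ndarray,
    pairs: list[LRPair],
    n_perm: int = 100,
    seed: int = 0,
    kh: float = 0.5,
    alpha: float = 0.05,
    min_cells: int = 10,
) -> CommGraph:
    """Full communication scoring.

    Candidate (pair, source, target) channels require the ligand
    over-expressed in the source AND every receptor subunit over-expressed in
    the target; candidates are scored by mass-action probability and tested
    by label permutation; significant channels aggregate into pathway
    weights."""
    groups = np.asarray(groups).astype(str)
    lr_genes = sorted(
        {p.ligand for p in pairs} | {s for p in pairs for s in p.receptor}
    )
    lr_genes = [g for g in lr_genes if g in set(x.genes)]
    if not lr_genes:
        raise CommError("no ligand/receptor gene is present in the matrix")
    xs = x.subset_genes(lr_genes)
    over = detect_overexpressed(xs, groups, alpha=alpha, min_cells=min_cells)
    rows = []
    k = 0
    for pair in pairs:
        if pair.ligand not in set(xs.genes) or not set(pair.receptor) <= set(xs.genes):
            continue
        for source, src_over in over.items():
            if pair.ligand not in src_over:
                continue
            for target, tgt_over in over.items():
                if not set(pair.receptor) <= tgt_over:
                    continue
                prob, p = permutation_significance(
                    xs, groups, pair, source, target,
                    n_perm=n_perm, seed=seed + k, kh=kh,
                )
                k += 1
                rows.append(
                    {
                        "ligand": pair.ligand,
                        "receptor": ";".join(pair.receptor),
                        "pathway": pair.pathway,
                        "source": source,
                        "target": target,
                        "probability": prob,
                        "p": p,
                        "significant": p < alpha,
                    }
                )
    pair_table = pd.DataFrame(rows)
    return aggregate_pathways(pair_table)


def aggregate_pathways(pair_table: pd.DataFrame) -> CommGraph:
    """Sum significant pair probabilities into (source, target, pathway)
    weights with pair counts.  An empty graph is allowed with a warning."""
    if len(pair_table) == 0 or not pair_table["significant"].any():
        warnings.warn("no significant ligand-receptor pair; communication graph is empty")
        return CommGraph(
            table=pd.DataFrame(columns=["source", "target", "pathway", "weight", "n_pairs"]),
            pairs=pair_table,
        )
    sig = pair_table[pair_table["significant"]]
    agg = (
        sig.groupby(["source", "target", "pathway"])
        .agg(weight=("probability", "sum"), n_pairs=("probability", "size"))
        .reset_index()
    )
    return CommGraph(table=agg, pairs=pair_table)
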