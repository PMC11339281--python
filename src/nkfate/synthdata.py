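"""Synthetic single-cell experiments with planted ground truth.

The generator emulates the structure of a post-trauma PBMC time course:
negative-binomial UMI counts with log-normal library sizes, several immune
cell types distinguished by marker programs, NK subpopulations carrying
planted death-signature programs whose mixing proportions shift across five
time-point groups, a hypoxia-like correlated gene module whose latent
activation rises then falls over the time course, a two-batch design, and
ligand-receptor pairs over-expressed in specific populations.

Counts are drawn as Gamma-Poisson (negative binomial) per gene per cell;
programs act additively in log-mean space on the cell's baseline.  Healthy
NK cells carry no death program.  All randomness flows from a single seed,
so the same configuration reproduces bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genesets import (
    CANONICAL_PARADIGMS,
    HEALTHY_LABEL,
    GeneSet,
    GeneSetCollection,
    aggregate_state,
    write_gmt,
)
from .io_qc import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("control", "PT-4h", "PT-6h", "PT-24h", "PT-72h")

#: Depth of each reported death state along the planted differentiation
#: (healthy root -> necrotic -> ferroptosis/pyroptosis -> apoptosis ->
#: immunogenic/autophagy), mirroring the decision-point ordering of the
#: trajectory analysis.
STATE_DEPTH = {
    HEALTHY_LABEL: 0.0,
    "necrotic": 1.0,
    "ferroptosis": 2.0,
    "pyroptosis": 2.0,
    "apoptosis": 3.0,
    "immunogenic": 4.0,
    "autophagy": 4.0,
    "parthanatos": 2.0,
    "entotic": 2.0,
    "netotic": 2.0,
    "lysosome_dependent": 2.0,
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CellTypeProfile:
    markers: tuple[str, ...]
    proportion: float
    marker_log_boost: float = 3.0


@dataclass
class ParadigmProgram:
    genes: tuple[str, ...]
    log_activation: float = 2.0


@dataclass
class HypoxiaModule:
    genes: tuple[str, ...]
    group_trend: dict[str, float]
    loading_low: float = 0.6
    loading_high: float = 1.0
    cell_sd: float = 0.3


@dataclass
class LRPairSpec:
    ligand: str
    receptor: str
    source: str
    target: str
    pathway: str
    log_boost: float = 2.5


@dataclass
class SimulationConfig:
    genes: tuple[str, ...]
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_cells_per_group: int = 1000
    cell_type_profiles: dict[str, CellTypeProfile] = field(default_factory=dict)
    paradigm_programs: dict[str, ParadigmProgram] = field(default_factory=dict)
    paradigm_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    hypoxia: HypoxiaModule | None = None
    lr_pairs: list[LRPairSpec] = field(default_factory=list)
    type_baseline_sd: float = 0.4
    nb_dispersion: float = 10.0
    libsize_lognorm_params: tuple[float, float] = (np.log(3000.0), 0.3)
    mito_gene_count: int = 10
    mito_frac_target: float = 0.02
    batch_effect_sd: float = 0.1
    n_samples_per_group: int = 4
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        universe = set(self.genes)
        if len(universe) != len(self.genes):
            raise SimulationError("duplicate gene names in universe")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        if self.batch_effect_sd < 0:
            raise SimulationError("batch_effect_sd must be non-negative")
        marker_genes: set[str] = set()
        for t, prof in self.cell_type_profiles.items():
            for g in prof.markers:
                if g not in universe:
                    raise SimulationError(f"marker {g!r} of type {t!r} not in gene universe")
            marker_genes |= set(prof.markers)
        props = [p.proportion for p in self.cell_type_profiles.values()]
        if props and abs(sum(props) - 1.0) > 1e-9:
            raise SimulationError("cell type proportions must sum to 1")
        for name, prog in self.paradigm_programs.items():
            for g in prog.genes:
                if g not in universe:
                    raise SimulationError(f"signature gene {g!r} of {name!r} not in universe")
            if set(prog.genes) & marker_genes:
                raise SimulationError(
                    f"signature of {name!r} overlaps cell-type marker genes"
                )
        for group, fr in self.paradigm_fractions.items():
            if group not in self.groups:
                raise SimulationError(f"fractions given for unknown group {group!r}")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise SimulationError(f"paradigm fractions of {group!r} do not sum to 1")
            for p in fr:
                if p != HEALTHY_LABEL and p not in self.paradigm_programs:
                    raise SimulationError(f"fraction names unknown paradigm {p!r}")
        if self.hypoxia is not None:
            for g in self.hypoxia.genes:
                if g not in universe:
                    raise SimulationError(f"hypoxia module gene {g!r} not in universe")
            for grp in self.groups:
                if grp not in self.hypoxia.group_trend:
                    raise SimulationError(f"hypoxia trend missing group {grp!r}")
        for pair in self.lr_pairs:
            for g in (pair.ligand, pair.receptor):
                if g not in universe:
                    raise SimulationError(f"LR gene {g!r} not in universe")


@dataclass
class GroundTruth:
    """Per-cell truth plus the planted structures."""

    cells: pd.DataFrame          # barcode, group, sample, batch, cell_type, paradigm, state, depth, hypoxia_latent
    module_genes: tuple[str, ...]
    group_trend: dict[str, float]
    paradigm_fractions: dict[str, dict[str, float]]

    def save(self, dir_path: str | Path) -> None:
        dir_path = Path(dir_path)
        dir_path.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(dir_path / "ground_truth_cells.tsv", sep="\t", index=False)
        with open(dir_path / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "module_genes": list(self.module_genes),
                    "group_trend": self.group_trend,
                    "paradigm_fractions": self.paradigm_fractions,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, dir_path: str | Path) -> "GroundTruth":
        dir_path = Path(dir_path)
        cells = pd.read_csv(dir_path / "ground_truth_cells.tsv", sep="\t", dtype={"barcode": str})
        with open(dir_path / "ground_truth.json") as fh:
            extra = json.load(fh)
        return cls(
            cells=cells,
            module_genes=tuple(extra["module_genes"]),
            group_trend=extra["group_trend"],
            paradigm_fractions=extra["paradigm_fractions"],
        )


# ---------------------------------------------------------------------------
# default study conditions


def _signature_names(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i:02d}" for i in range(1, n + 1))


DEFAULT_MARKERS = {
    "NK": ("GNLY", "NKG7", "KLRD1", "PRF1"),
    "T_CD4": ("IL7R", "CCR7", "CD4", "LTB"),
    "T_CD8": ("CD8A", "CD8B", "GZMK", "CD3D"),
    "B": ("MS4A1", "CD79A", "CD79B", "IGHM"),
    "monocyte": ("CD14", "LYZ", "S100A8", "FCN1"),
    "dendritic": ("FCER1A", "CST3", "CLEC10A", "ITGAX"),
    "neutrophil": ("FCGR3B", "CSF3R", "S100A4", "CXCR2"),
}

DEFAULT_TYPE_PROPORTIONS = {
    "NK": 0.40,
    "T_CD4": 0.15,
    "T_CD8": 0.12,
    "B": 0.08,
    "monocyte": 0.12,
    "dendritic": 0.05,
    "neutrophil": 0.08,
}

_SIG_PREFIX = {
    "intrinsic_apoptosis": "INTAPO",
    "extrinsic_apoptosis": "EXTAPO",
    "mpt_driven_necrosis": "MPTNEC",
    "necroptosis": "NECPTO",
    "ferroptosis": "FERRO",
    "pyroptosis": "PYRO",
    "parthanatos": "PARTH",
    "entotic_cell_death": "ENTO",
    "netotic_cell_death": "NETO",
    "lysosome_dependent_cell_death": "LYSO",
    "autophagy_dependent_cell_death": "AUTPH",
    "immunogenic_cell_death": "ICD",
}

#: Planted per-group mixing of paradigms among NK cells.  The dominant-state
#: pattern follows the published post-trauma time course (apoptosis 63%/84%
#: at 4h/6h; pyroptosis 80%/78% at 24h/72h; minor states around 5%).
DEFAULT_PARADIGM_FRACTIONS = {
    "control": {HEALTHY_LABEL: 0.90, "intrinsic_apoptosis": 0.05, "pyroptosis": 0.05},
    "PT-4h": {
        "intrinsic_apoptosis": 0.63,
        HEALTHY_LABEL: 0.22,
        "ferroptosis": 0.05,
        "autophagy_dependent_cell_death": 0.05,
        "immunogenic_cell_death": 0.05,
    },
    "PT-6h": {
        "intrinsic_apoptosis": 0.84,
        "ferroptosis": 0.06,
        "autophagy_dependent_cell_death": 0.05,
        "immunogenic_cell_death": 0.05,
    },
    "PT-24h": {"pyroptosis": 0.80, "necroptosis": 0.05, HEALTHY_LABEL: 0.15},
    "PT-72h": {
        "pyroptosis": 0.78,
        "necroptosis": 0.07,
        "intrinsic_apoptosis": 0.05,
        HEALTHY_LABEL: 0.10,
    },
}

#: Latent hypoxia activation per group: rises into the hyperacute phase and
#: falls back under resuscitation.
DEFAULT_HYPOXIA_TREND = {
    "control": 0.0,
    "PT-4h": 0.8,
    "PT-6h": 1.2,
    "PT-24h": 0.5,
    "PT-72h": 0.2,
}

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3",
    "MT-ATP6", "MT-CYB", "MT-ND4", "MT-ND5", "MT-RNR1",
)

DEFAULT_LR_PAIRS = [
    LRPairSpec("LGCXCL1", "RCCXCL1", "NK_apoptosis", "neutrophil", "CXCL"),
    LRPairSpec("LGCXCL2", "RCCXCL2", "NK_apoptosis", "neutrophil", "CXCL"),
    LRPairSpec("LGNOTCH1", "RCNOTCH1", "dendritic", "NK_pyroptosis", "NOTCH"),
    LRPairSpec("LGTGFB1", "RCTGFB1", "NK_ferroptosis", "T_CD8", "TGFB"),
]


def default_config(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells_per_group: int = 1000,
    activation: float = 2.0,
    signature_size: int = 25,
    **overrides,
) -> SimulationConfig:
    """The default study conditions: 2000 genes, 5 groups x 1000 cells."""
    genes: list[str] = []
    profiles = {
        t: CellTypeProfile(markers=DEFAULT_MARKERS[t], proportion=DEFAULT_TYPE_PROPORTIONS[t])
        for t in DEFAULT_MARKERS
    }
    for prof in profiles.values():
        genes.extend(prof.markers)
    programs: dict[str, ParadigmProgram] = {}
    for paradigm in CANONICAL_PARADIGMS:
        sig = _signature_names(_SIG_PREFIX[paradigm], signature_size)
        programs[paradigm] = ParadigmProgram(genes=sig, log_activation=activation)
        genes.extend(sig)
    hyp_genes = ("HIF1A", "HIF1AN", "EGLN1", "KDM3A") + _signature_names("HYPOX", 36)
    genes.extend(hyp_genes)
    for pair in DEFAULT_LR_PAIRS:
        genes.extend([pair.ligand, pair.receptor])
    genes.extend(MITO_GENES)
    n_bg = n_genes - len(genes)
    if n_bg < 0:
        raise SimulationError(f"n_genes={n_genes} too small for the structured genes ({len(genes)})")
    genes.extend(f"BG{i:04d}" for i in range(1, n_bg + 1))
    cfg = SimulationConfig(
        genes=tuple(genes),
        n_cells_per_group=n_cells_per_group,
        cell_type_profiles=profiles,
        paradigm_programs=programs,
        paradigm_fractions={g: dict(v) for g, v in DEFAULT_PARADIGM_FRACTIONS.items()},
        hypoxia=HypoxiaModule(genes=hyp_genes, group_trend=dict(DEFAULT_HYPOXIA_TREND)),
        lr_pairs=list(DEFAULT_LR_PAIRS),
        seed=seed,
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise SimulationError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation


def _population_label(cell_type: str, paradigm: str) -> str:
    """Population label used for communication: death-state NK subgroups
    (NK_apoptosis, ..., NK_healthy) plus the other cell types as-is."""
    if cell_type != "NK":
        return cell_type
    if paradigm in ("", HEALTHY_LABEL):
        return f"NK_{HEALTHY_LABEL}"
    return f"NK_{aggregate_state(paradigm)}"


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth, GeneSetCollection]:
    """Draw a full synthetic experiment.

    Returns the UMI count matrix with per-cell metadata, the ground truth
    (true type, paradigm, batch, planted module and pseudotime depth) and the
    planted paradigm signatures as a GeneSetCollection.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(config.genes, dtype=object)
    gpos = {g: i for i, g in enumerate(genes)}
    G = config.n_genes

    # --- baseline gene weights (relative expression propensities)
    base_w = rng.gamma(shape=0.4, scale=1.0, size=G) + 1e-4
    marker_all: set[str] = set()
    for prof in config.cell_type_profiles.values():
        marker_all |= set(prof.markers)
    for g in marker_all:
        base_w[gpos[g]] = 0.5
    # death-signature genes follow the same heterogeneous baseline law as
    # the rest of the transcriptome: a planted program shifts its genes in
    # log-mean space without granting them a privileged expression tier
    if config.hypoxia is not None:
        for g in config.hypoxia.genes:
            base_w[gpos[g]] = 1.0
    for pair in config.lr_pairs:
        base_w[gpos[pair.ligand]] = 0.8
        base_w[gpos[pair.receptor]] = 0.8
    mito_idx = np.array([gpos[g] for g in genes if str(g).upper().startswith("MT-")], dtype=int)
    if len(mito_idx):
        non_mito_sum = base_w.sum() - base_w[mito_idx].sum()
        base_w[mito_idx] = config.mito_frac_target * non_mito_sum / len(mito_idx)

    # --- per-type baseline log-mean vectors: each cell type carries a
    # transcriptome-wide expression identity on top of the shared baseline,
    # in addition to its boosted canonical markers.  Ligand/receptor genes
    # are exempt so the planted communication channels stay the only
    # population-differential LR signal.
    lr_idx = np.array(
        sorted({gpos[p.ligand] for p in config.lr_pairs} | {gpos[p.receptor] for p in config.lr_pairs}),
        dtype=int,
    )
    type_offsets = {}
    for t in config.cell_type_profiles:
        off = rng.normal(0.0, config.type_baseline_sd, size=G)
        if len(lr_idx):
            off[lr_idx] = 0.0
        type_offsets[t] = off

    # --- per-gene batch offsets (applied in log-mean space to batch "B")
    batch_delta = rng.normal(0.0, config.batch_effect_sd, size=G)

    # --- hypoxia loadings
    if config.hypoxia is not None:
        hyp_idx = np.array([gpos[g] for g in config.hypoxia.genes], dtype=int)
        hyp_load = rng.uniform(config.hypoxia.loading_low, config.hypoxia.loading_high, size=len(hyp_idx))
    else:
        hyp_idx = np.array([], dtype=int)
        hyp_load = np.array([])

    types = list(config.cell_type_profiles)
    type_p = np.array([config.cell_type_profiles[t].proportion for t in types])

    records = []
    count_blocks = []
    mu_lib, sd_lib = config.libsize_lognorm_params
    n_samples = max(config.n_samples_per_group, 1)

    for group in config.groups:
        n = config.n_cells_per_group
        cell_types = rng.choice(types, size=n, p=type_p) if types else np.array(["cell"] * n)
        fr = config.paradigm_fractions.get(group, {HEALTHY_LABEL: 1.0})
        fr_names = list(fr)
        fr_p = np.array([fr[k] for k in fr_names])
        paradigms = np.where(
            cell_types == "NK",
            rng.choice(fr_names, size=n, p=fr_p),
            "",
        )
        sample_idx = np.arange(n) % n_samples
        samples = np.array([f"{group}_s{i + 1}" for i in sample_idx], dtype=object)
        batches = np.where(sample_idx < (n_samples + 1) // 2, "A", "B")
        trend = config.hypoxia.group_trend[group] if config.hypoxia is not None else 0.0
        hyp_latent = trend + (
            rng.normal(0.0, config.hypoxia.cell_sd, size=n) if config.hypoxia is not None else np.zeros(n)
        )
        libsize = rng.lognormal(mu_lib, sd_lib, size=n)

        # log-weight per cell, built from the shared baseline
        logw = np.tile(np.log(base_w)[:, None], (1, n))
        for t in types:
            prof = config.cell_type_profiles[t]
            cols = np.flatnonzero(cell_types == t)
            if len(cols) == 0:
                continue
            rows = np.array([gpos[g] for g in prof.markers], dtype=int)
            logw[np.ix_(rows, cols)] += prof.marker_log_boost
            logw[:, cols] += type_offsets[t][:, None]
        for name, prog in config.paradigm_programs.items():
            cols = np.flatnonzero(paradigms == name)
            if len(cols) == 0:
                continue
            rows = np.array([gpos[g] for g in prog.genes], dtype=int)
            logw[np.ix_(rows, cols)] += prog.log_activation
        if len(hyp_idx):
            logw[hyp_idx, :] += hyp_load[:, None] * hyp_latent[None, :]
        bcols = np.flatnonzero(batches == "B")
        if len(bcols):
            logw[:, bcols] += batch_delta[:, None]
        pops = np.array(
            [_population_label(t, p) for t, p in zip(cell_types, paradigms)], dtype=object
        )
        for pair in config.lr_pairs:
            src_cols = np.flatnonzero(pops == pair.source)
            tgt_cols = np.flatnonzero(pops == pair.target)
            if len(src_cols):
                logw[gpos[pair.ligand], src_cols] += pair.log_boost
            if len(tgt_cols):
                logw[gpos[pair.receptor], tgt_cols] += pair.log_boost

        w = np.exp(logw)
        p = w / w.sum(axis=0, keepdims=True)
        mean = p * libsize[None, :]
        r = config.nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts = rng.poisson(lam)
        count_blocks.append(sp.csr_matrix(counts))

        states = np.array(
            [
                aggregate_state(p_) if p_ not in ("", HEALTHY_LABEL) else (HEALTHY_LABEL if p_ == HEALTHY_LABEL else "")
                for p_ in paradigms
            ],
            dtype=object,
        )
        depth = np.array(
            [STATE_DEPTH.get(s, 0.0) if s else 0.0 for s in states]
        )
        records.append(
            pd.DataFrame(
                {
                    "group": group,
                    "sample": samples,
                    "batch": batches,
                    "cell_type": cell_types,
                    "paradigm": paradigms,
                    "population": pops,
                    "state": states,
                    "depth": depth,
                    "hypoxia_latent": hyp_latent,
                }
            )
        )

    cells = pd.concat(records, ignore_index=True)
    barcodes = np.array([f"CELL{i:06d}" for i in range(len(cells))], dtype=object)
    cells.insert(0, "barcode", barcodes)
    counts = sp.hstack(count_blocks, format="csr")
    meta = cells.set_index("barcode")[["sample", "group", "batch"]]
    matrix = CountMatrix(genes=genes, barcodes=barcodes, counts=counts, cell_meta=meta)
    truth = GroundTruth(
        cells=cells,
        module_genes=tuple(config.hypoxia.genes) if config.hypoxia is not None else (),
        group_trend=dict(config.hypoxia.group_trend) if config.hypoxia is not None else {},
        paradigm_fractions={g: dict(v) for g, v in config.paradigm_fractions.items()},
    )
    collection = GeneSetCollection(
        sets=[
            GeneSet(name=name, genes=prog.genes, source="synthetic planted signature")
            for name, prog in config.paradigm_programs.items()
        ]
    )
    return matrix, truth, collection


def write_10x(matrix: CountMatrix, dir_path: str | Path) -> Path:
    """Write MTX + genes.tsv + barcodes.tsv + cell_metadata.tsv."""
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise SimulationError("refusing to write an empty matrix")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dir_path / "matrix.mtx", matrix.counts.tocoo(), field="integer")
    with open(dir_path / "genes.tsv", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")
    meta = matrix.cell_meta.reset_index()
    meta.columns = ["barcode"] + list(matrix.cell_meta.columns)
    meta.to_csv(dir_path / "cell_metadata.tsv", sep="\t", index=False)
    return dir_path


__all__ = [
    "SimulationConfig",
    "SimulationError",
    "CellTypeProfile",
    "ParadigmProgram",
    "HypoxiaModule",
    "LRPairSpec",
    "GroundTruth",
    "default_config",
    "simulate_experiment",
    "write_10x",
    "write_gmt",
    "DEFAULT_GROUPS",
    "DEFAULT_MARKERS",
    "DEFAULT_PARADIGM_FRACTIONS",
    "DEFAULT_HYPOXIA_TREND",
    "STATE_DEPTH",
]
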