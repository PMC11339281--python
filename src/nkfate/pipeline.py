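"""End-to-end pipeline: QC -> normalize -> HVG -> PCA -> (integrate) ->
annotate -> NK subset -> death-state classification -> composition ->
pseudo-bulk DE -> co-expression modules -> trajectory -> communication.

Every run writes plain TSV/JSON stage outputs plus a manifest (parameters,
seed, input checksums, package version) into the run directory, so any stage
can be audited or rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import commnet as cn
from . import composition as comp
from . import coexpnet as cx
from . import deathstate as ds
from . import io_qc
from . import pseudobulk as pbk
from . import synthdata as sdt
from . import trajectory as tj
from .genesets import HEALTHY_LABEL, GeneSetCollection, read_gmt

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    counts_dir: str | None = None       # None -> simulate
    gmt: str | None = None              # None -> planted/packaged signatures
    lr_database: str | None = None      # None -> packaged minimal table
    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    n_cells_per_group: int = 1000
    qc: io_qc.QCParams = field(default_factory=io_qc.QCParams)
    norm: io_qc.NormParams = field(default_factory=io_qc.NormParams)
    n_hvg: int = 2000
    n_pcs: int = 10
    integrate: bool = False
    k_anchor: int = 5
    markers: dict = field(default_factory=lambda: {t: list(g) for t, g in sdt.DEFAULT_MARKERS.items()})
    nk_label: str = "NK"
    k_micro: int | None = None
    n_neighbors: int = 10
    resolution: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    gsea_weight: float = 1.0
    # 25-gene planted signatures should be detectable at pseudo-bulk scale
    coexp: cx.CoexpParams = field(default_factory=lambda: cx.CoexpParams(min_module_size=20))
    coexp_n_genes: int = 1500
    comm_n_perm: int = 100
    kh: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub in (("qc", io_qc.QCParams), ("norm", io_qc.NormParams), ("coexp", cx.CoexpParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                bad = set(kwargs[key]) - sub_known
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Any stage error aborts with the stage name; a ``PARTIAL`` marker file
    records how far the run got.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "PARTIAL"
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "inputs": {},
    }
    stage = "setup"

    def tick(name):
        nonlocal stage
        timings[stage] = round(time.time() - tick.t0, 2)
        logger.info("stage %s done (%.1fs); starting %s", stage, timings[stage], name)
        stage = name
        tick.t0 = time.time()

    tick.t0 = time.time()
    marker.write_text(stage)
    truth = None
    try:
        # ------------------------------------------------ input / simulate
        stage = "input"
        planted_pairs = None
        if config.counts_dir is None:
            if not config.simulate:
                raise ValueError("no counts_dir and simulate=False")
            cfg = sdt.default_config(
                seed=config.seed, n_cells_per_group=config.n_cells_per_group
            )
            matrix, truth, planted = sdt.simulate_experiment(cfg)
            planted_pairs = [
                cn.LRPair(p.ligand, (p.receptor,), p.pathway) for p in cfg.lr_pairs
            ]
            truth.save(out / "ground_truth")
        else:
            matrix = io_qc.read_10x(config.counts_dir)
            for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
                p = Path(config.counts_dir) / f
                if p.exists():
                    manifest["inputs"][f] = _checksum(p)
            planted = None
        tick("genesets")
        if config.gmt is not None:
            collection = read_gmt(config.gmt)
            manifest["inputs"]["gmt"] = _checksum(Path(config.gmt))
        elif planted is not None:
            collection = planted
        else:
            from .genesets import packaged_death_paradigms

            collection = packaged_death_paradigms()
        collection.validate_paradigms()

        # ------------------------------------------------ qc / normalize
        tick("qc")
        matrix, qc_report = io_qc.qc_filter(matrix, config.qc)
        qc_report.to_tsv(out / "qc_report.tsv")
        tick("normalize")
        x = io_qc.lognormalize(matrix, config.norm)
        tick("hvg")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hvgs = io_qc.select_hvg(x, config.n_hvg)
        tick("pca")
        emb = io_qc.scale_and_pca(x, hvgs, k=config.n_pcs)
        if config.integrate:
            tick("integrate")
            emb = io_qc.integrate_batches(emb, k_anchor=config.k_anchor)

        # ------------------------------------------------ annotate / NK subset
        tick("annotate")
        pbmc_clusters = ds.two_step_cluster(
            emb, n_neighbors=config.n_neighbors, resolution=config.resolution,
            seed=config.seed,
        )
        cell_types = io_qc.annotate_cell_types(x, config.markers, clusters=pbmc_clusters.labels)
        pd.DataFrame(
            {"barcode": x.barcodes, "cluster": pbmc_clusters.labels, "cell_type": cell_types}
        ).to_csv(out / "cell_types.tsv", sep="\t", index=False)
        nk_mask = cell_types == config.nk_label
        if nk_mask.sum() < 50:
            raise ValueError(f"only {int(nk_mask.sum())} NK cells identified")
        x_nk = x.subset_cells(nk_mask)

        # ------------------------------------------------ classify
        tick("classify")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hv_nk = io_qc.select_hvg(x_nk, config.n_hvg)
            emb_nk = io_qc.scale_and_pca(x_nk, hv_nk, k=config.n_pcs)
            table = ds.classify_death_states(
                x_nk, emb_nk, collection,
                k_micro=config.k_micro, n_neighbors=config.n_neighbors,
                resolution=config.resolution, n_perm=config.n_perm,
                alpha=config.alpha, weight=config.gsea_weight, seed=config.seed,
            )
        table.cells.to_csv(out / "death_states.tsv", sep="\t", index=False)
        table.cluster_evidence.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)

        # ------------------------------------------------ composition
        tick("composition")
        nk_meta = x_nk.cell_meta
        composition = comp.state_fractions(table.cells, nk_meta, by=["group"])
        composition.to_tsv(out / "composition_by_group.tsv")
        comp_sample = comp.state_fractions(table.cells, nk_meta, by=["group", "sample"])
        comp_sample.to_tsv(out / "composition_by_sample.tsv")

        # ------------------------------------------------ pseudobulk + DE
        tick("pseudobulk")
        nk_counts = matrix.subset_cells(nk_mask)
        states = table.cells.set_index("barcode")["state"]
        pb = pbk.make_pseudobulk(nk_counts, states)
        pb.to_frame().to_csv(out / "pseudobulk_counts.tsv", sep="\t")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de_tables = pbk.state_contrasts(pb)
        de_summary = pd.DataFrame(
            [{"state": s, "n_deg": int(t["deg"].sum())} for s, t in de_tables.items()]
        )
        de_summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
        for s, t in de_tables.items():
            t.to_csv(out / f"de_{s}.tsv", sep="\t")

        # ------------------------------------------------ co-expression
        tick("coexpression")
        # sample x state aggregates of the NK cells; drop thin columns
        pb_keep = ~pb.flagged
        pb_all = pbk.PseudoBulkMatrix(
            genes=pb.genes,
            columns=pb.columns[pb_keep],
            counts=pb.counts[:, pb_keep],
            n_cells=pb.n_cells[pb_keep],
        )
        lc = pbk.log_cpm(pb_all)
        var = lc.var(axis=1)
        top = np.argsort(-var, kind="stable")[: config.coexp_n_genes]
        lc_top, genes_top = lc[top], [str(g) for g in matrix.genes[top]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tom = cx.adjacency_tom(lc_top, config.coexp)
            modules = cx.detect_modules(
                tom, config.coexp, gene_names=genes_top, x=lc_top
            )
        modules.modules.to_csv(out / "gene_modules.tsv", sep="\t")
        trait_corr = pd.DataFrame()
        if len(modules.eigengenes.columns):
            # traits: per pseudo-bulk sample, the fraction of that sample's
            # NK cells in each death state (plus total dying burden)
            samples = pb_all.columns.get_level_values("sample")
            frac_by_sample = comp_sample.fractions.reset_index().set_index("sample")
            frac_by_sample = frac_by_sample.drop(columns=["group"], errors="ignore")
            frames = []
            for state in frac_by_sample.columns:
                trait = frac_by_sample[state].reindex(samples).to_numpy()
                if np.ptp(trait[~np.isnan(trait)]) == 0:
                    continue
                tc = cx.module_trait_correlation(modules.eigengenes, trait)
                tc.insert(0, "trait", f"frac_{state}")
                frames.append(tc.reset_index())
            dying = 1.0 - frac_by_sample[HEALTHY_LABEL] if HEALTHY_LABEL in frac_by_sample else None
            if dying is not None:
                tc = cx.module_trait_correlation(
                    modules.eigengenes, dying.reindex(samples).to_numpy()
                )
                tc.insert(0, "trait", "dying_burden")
                frames.append(tc.reset_index())
            trait_corr = pd.concat(frames, ignore_index=True)
            trait_corr.to_csv(out / "module_trait_correlation.tsv", sep="\t", index=False)
            ora_tables = {}
            for mid in modules.module_ids:
                ora_tables[f"M{mid}"] = cx.ora(
                    modules.genes_in(mid), list(collection), genes_top
                )
            pd.concat(ora_tables, names=["module"]).to_csv(out / "module_ora.tsv", sep="\t")

        # ------------------------------------------------ trajectory
        tick("trajectory")
        state_per_cell = table.cells["state"].to_numpy()
        n_states = len(set(state_per_cell))
        traj_info = {}
        if n_states >= 2:
            model = tj.fit_mst(emb_nk.coords, state_per_cell)
            root = HEALTHY_LABEL if HEALTHY_LABEL in model.nodes else model.nodes[0]
            pt = tj.pseudotime(model, emb_nk.coords, state_per_cell, root)
            model.to_json(out / "trajectory.json")
            pd.DataFrame(
                {"barcode": x_nk.barcodes, "state": state_per_cell, "pseudotime": pt}
            ).to_csv(out / "pseudotime.tsv", sep="\t", index=False)
            traj_info = {
                "root": root,
                "decision_points": tj.decision_points(model),
                "n_nodes": len(model.nodes),
            }
        else:
            warnings.warn("fewer than 2 states; trajectory skipped")

        # ------------------------------------------------ communication
        tick("communication")
        if config.lr_database is not None:
            pairs = cn.read_lr_database(config.lr_database)
        elif planted_pairs is not None:
            pairs = planted_pairs
        else:
            pairs = cn.packaged_lr_database()
        if config.lr_database is not None:
            manifest["inputs"]["lr_database"] = _checksum(Path(config.lr_database))
        populations = np.where(
            nk_mask,
            np.array([f"NK_{s}" for s in _states_for_all(x, table)], dtype=object),
            cell_types,
        )
        keep = populations != "ambiguous"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = cn.score_communication(
                x.subset_cells(keep), populations[keep], pairs,
                n_perm=config.comm_n_perm, seed=config.seed, kh=config.kh,
            )
        graph.table.to_csv(out / "communication_weights.tsv", sep="\t", index=False)
        graph.pairs.to_csv(out / "communication_pairs.tsv", sep="\t", index=False)

        tick("finish")
        manifest["timings_s"] = timings
        manifest["trajectory"] = traj_info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        marker.unlink(missing_ok=True)
        return out
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        marker.write_text(stage)
        raise PipelineError(stage, str(exc)) from exc


def _states_for_all(x: io_qc.ExpressionMatrix, table: ds.DeathStateTable) -> np.ndarray:
    lut = table.cells.set_index("barcode")["state"]
    return np.array([lut.get(b, "") for b in x.barcodes], dtype=object)


SECTIONS = (
    ("qc_report.tsv", "Quality control"),
    ("cell_types.tsv", "Cell type annotation"),
    ("composition_by_group.tsv", "Death-state composition"),
    ("cluster_enrichment.tsv", "Cluster enrichment evidence"),
    ("module_trait_correlation.tsv", "Co-expression modules vs dying-NK burden"),
    ("trajectory.json", "MST trajectory"),
    ("communication_weights.tsv", "Cell-cell communication"),
)


def report(run_dir: str | Path) -> str:
    """Assemble a plain-text summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = [f"# nkfate run report: {run_dir}"]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        man = json.loads(manifest_path.read_text())
        lines.append(f"version {man.get('version')} seed {man.get('seed')}")
    partial = run_dir / "PARTIAL"
    if partial.exists():
        lines.append(f"WARNING: incomplete run (stopped in stage {partial.read_text().strip()!r})")
    n = 0
    for fname, title in SECTIONS:
        p = run_dir / fname
        lines.append(f"\n## {title}")
        if not p.exists():
            lines.append("WARNING: missing")
            continue
        n += 1
        if p.suffix == ".json":
            lines.append(p.read_text().strip())
        else:
            df = pd.read_csv(p, sep="\t")
            lines.append(df.head(25).to_string(index=False))
            if len(df) > 25:
                lines.append(f"... ({len(df)} rows)")
    lines.append(f"\nsections present: {n}/{len(SECTIONS)}")
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    return text
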