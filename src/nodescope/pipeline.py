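"""End-to-end pipeline orchestration from a single YAML configuration.

Stages run in dependency order (simulate -> qc -> cluster -> project ->
ica -> stats -> correlate), each writing plain-text outputs plus
provenance metadata into the run directory.  One global seed is offset
per stage, so a rerun with the same configuration reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import merge_clusters_to_nodes
from .ica import fit_ica, identify_differentiation_ic, score_cell_cycle
from .impute import ancova_interaction, build_diffusion_operator, correlate, impute
from .matrix import CountMatrix, read_dge, write_dge
from .projection import build_reference, knn_place, project_into_reference
from .qc import QCThresholds, run_qc
from .resources import load_marker_config
from .simulate import default_config, simulate_cohort
from .stats import compare_arms, fractional_populations, marker_positive_fraction
from .workflow import ClusteringBundle, reduce_and_cluster

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

STAGES = ("simulate", "qc", "cluster", "project", "ica", "stats", "correlate")

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {name: 1000 + 17 * i for i, name in enumerate(STAGES)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    input_dir: str | None = None        # read a cohort instead of simulating
    cohort_scale: float = 1.0           # multiplies per-animal cell counts
    qc: dict = field(default_factory=dict)            # QCThresholds fields
    cluster: dict = field(default_factory=dict)       # reduce_and_cluster kwargs
    n_nodes: int = 3
    tumor_cell_type: str = "cgnp_tumor"
    projection: dict = field(default_factory=lambda: {
        "reference_arm": "vehicle", "query_arm": "treated", "K": 5,
    })
    ica: dict = field(default_factory=lambda: {"n_components": 4})
    lineage_marker: str = "Yfp"
    lineage_threshold: float = 0.5
    correlate: dict = field(default_factory=lambda: {
        "gene_x": "Sufu", "gene_y": "Gli1", "k": 12, "t": 3,
    })
    markers_file: str | None = None

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]


def validate_config(path: str) -> tuple[PipelineConfig, list[str], list[str]]:
    """Parse and validate a YAML pipeline configuration.

    Returns (config with defaults filled, errors, warnings); all problems
    are collected rather than failing at the first.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return PipelineConfig(), [f"cannot parse {path}: {exc}"], []
    if not raw:
        warnings_.append("empty configuration: running with defaults only")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown configuration key {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for stage in cfg.stages:
        if stage not in STAGES:
            errors.append(f"unknown stage {stage!r}")
    sd = cfg.qc.get("sd_multiplier")
    if sd is not None and not (4.0 <= float(sd) <= 5.0):
        warnings_.append(
            f"sd_multiplier {sd} departs from the conventional 4-5 band"
        )
    if cfg.markers_file and not os.path.exists(cfg.markers_file):
        errors.append(f"markers_file {cfg.markers_file!r} does not exist")
    if cfg.input_dir and not os.path.exists(cfg.input_dir):
        errors.append(f"input_dir {cfg.input_dir!r} does not exist")
    return cfg, errors, warnings_


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute the configured stages; returns a manifest of outputs.

    The run directory is append-only within a run; every stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "log.jsonl")
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    state: dict = {}

    def log(stage: str, **payload):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **payload}) + "\n")

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrapped with stage context
            log(stage, status="failed", error=str(exc))
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = outputs
        log(stage, status="ok", seconds=round(time.time() - t0, 3))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, outdir: str, state: dict) -> dict:
    seed = config.stage_seed("simulate")
    if config.input_dir:
        matrix = read_dge(os.path.join(config.input_dir, "dge.tsv"), "tsv")
        truth_path = os.path.join(config.input_dir, "truth.tsv")
        truth = (
            pd.read_csv(truth_path, sep="\t", index_col=0)
            if os.path.exists(truth_path)
            else None
        )
    else:
        sim = default_config(seed=seed)
        if config.cohort_scale != 1.0:
            for p in sim.populations + sim.trajectories:
                p.n_cells_per_animal = max(
                    1, int(round(p.n_cells_per_animal * config.cohort_scale))
                )
        matrix, truth = simulate_cohort(sim)
    state["matrix"], state["truth"] = matrix, truth
    write_dge(matrix, os.path.join(outdir, "dge.tsv"), "tsv")
    if truth is not None:
        _write_tsv(truth, os.path.join(outdir, "truth.tsv"))
    return {"barcodes": matrix.n_barcodes, "genes": matrix.n_genes}


def _stage_qc(config: PipelineConfig, outdir: str, state: dict) -> dict:
    thresholds = QCThresholds(**config.qc)
    filtered, report = run_qc(state["matrix"], thresholds)
    state["qc_matrix"] = filtered
    report.to_json(os.path.join(outdir, "qc_report.json"))
    return {"kept_barcodes": filtered.n_barcodes, "kept_genes": filtered.n_genes}


def _stage_cluster(config: PipelineConfig, outdir: str, state: dict) -> dict:
    matrix = state.get("qc_matrix") or state["matrix"]
    markers = (
        yaml.safe_load(open(config.markers_file))
        if config.markers_file
        else load_marker_config()
    )
    bundle = reduce_and_cluster(
        matrix,
        seed=config.stage_seed("cluster"),
        with_tsne=True,
        marker_config=markers["cell_types"],
        min_marker_fraction=markers.get("min_fraction", 0.5),
        **config.cluster,
    )
    state["bundle"] = bundle
    cells = pd.DataFrame(
        {
            "cluster": bundle.clusters.labels,
            "cell_type": [
                bundle.cell_types.get(c, "unassigned") for c in bundle.clusters.labels
            ],
            "tsne_1": bundle.layout.coordinates[:, 0],
            "tsne_2": bundle.layout.coordinates[:, 1],
        },
        index=bundle.norm.barcodes.index,
    )
    # node merging over the tumor multi-cluster complex
    tumor_clusters = [
        c for c, t in bundle.cell_types.items() if t == config.tumor_cell_type
    ]
    node_col = np.full(len(cells), -1)
    if len(tumor_clusters) >= max(2, config.n_nodes):
        tree = merge_clusters_to_nodes(
            bundle.pca, bundle.clusters, config.n_nodes, subset=tumor_clusters
        )
        node_col = np.array(
            [tree.node_assignment.get(c, -1) for c in bundle.clusters.labels]
        )
        with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        state["node_tree"] = tree
    cells["node"] = node_col
    _write_tsv(cells, os.path.join(outdir, "clusters.tsv"))
    state["cells"] = cells
    return {
        "n_clusters": bundle.clusters.n_clusters,
        "significant_pcs": bundle.pca.significant,
        "cell_types": bundle.cell_types,
    }


def _stage_project(config: PipelineConfig, outdir: str, state: dict) -> dict:
    bundle: ClusteringBundle = state["bundle"]
    matrix = state.get("qc_matrix") or state["matrix"]
    arms = matrix.barcodes["arm"].to_numpy()
    ref_arm = config.projection.get("reference_arm", "vehicle")
    query_arm = config.projection.get("query_arm", "treated")
    K = int(config.projection.get("K", 5))
    ref_mask = arms == ref_arm
    query_mask = arms == query_arm
    if not ref_mask.any() or not query_mask.any():
        raise ValueError(f"arms {ref_arm!r}/{query_arm!r} not present")
    ref_matrix = matrix.subset_barcodes(ref_mask)
    # reference PCA must not residualize covariates: self-projection of the
    # reference through its own loadings has to reproduce its embeddings
    cluster_kwargs = {
        k: v for k, v in config.cluster.items() if k != "regress_library_size"
    }
    ref_bundle = reduce_and_cluster(
        ref_matrix,
        seed=config.stage_seed("project"),
        with_tsne=True,
        regress_library_size=False,
        **cluster_kwargs,
    )
    labels = np.array(
        [
            state["cells"]["cell_type"].to_numpy()[i]
            for i in np.flatnonzero(ref_mask)
        ]
    )
    reference = build_reference(ref_bundle.pca, ref_bundle.layout, labels)
    query_norm = bundle.norm.subset_barcodes(query_mask)
    emb = project_into_reference(reference, query_norm)
    result = knn_place(reference, emb, K=K)
    out = pd.DataFrame(
        {
            "placed_1": result.placed[:, 0],
            "placed_2": result.placed[:, 1],
            "label": result.labels,
            "confidence": result.confidence,
        },
        index=query_norm.barcodes.index,
    )
    _write_tsv(out, os.path.join(outdir, "projection.tsv"))
    return {"n_projected": len(out), "K": K, **result.metadata}


def _tumor_mask(config: PipelineConfig, state: dict) -> np.ndarray:
    bundle: ClusteringBundle = state["bundle"]
    tumor_clusters = {
        c for c, t in bundle.cell_types.items() if t == config.tumor_cell_type
    }
    return np.isin(bundle.clusters.labels, list(tumor_clusters))


def _stage_ica(config: PipelineConfig, outdir: str, state: dict) -> dict:
    bundle: ClusteringBundle = state["bundle"]
    mask = _tumor_mask(config, state)
    if mask.sum() < 50:
        raise ValueError("too few tumor cells for ICA")
    sub = bundle.norm.subset_barcodes(mask)
    model = fit_ica(
        sub,
        n_components=config.ica.get("n_components", "auto"),
        seed=config.stage_seed("ica"),
    )
    state["ica"], state["ica_mask"] = model, mask
    comp, orient = identify_differentiation_ic(model)
    phases = score_cell_cycle(bundle.norm)
    scores = pd.DataFrame(
        model.scores,
        index=sub.barcodes.index,
        columns=list(model.weights.columns),
    )
    scores["differentiation_score"] = orient * model.scores[:, comp]
    _write_tsv(scores, os.path.join(outdir, "ica_scores.tsv"))
    phase_df = phases.scores.copy()
    phase_df["phase"] = phases.assignment
    _write_tsv(phase_df, os.path.join(outdir, "cell_cycle.tsv"))
    state["phases"] = phases
    return {
        "n_components": model.n_components,
        "differentiation_ic": int(comp),
        "orientation": int(orient),
    }


def _stage_stats(config: PipelineConfig, outdir: str, state: dict) -> dict:
    bundle: ClusteringBundle = state["bundle"]
    cells = state["cells"]
    barcodes = bundle.norm.barcodes
    group = np.where(
        cells["node"].to_numpy() >= 0,
        "node_" + cells["node"].astype(str),
        cells["cell_type"],
    )
    table = fractional_populations(
        group, barcodes["animal"].to_numpy(), barcodes["arm"].to_numpy()
    )
    _write_tsv(table, os.path.join(outdir, "population_fractions.tsv"))
    results = {}
    for col in table.columns:
        if col == "arm":
            continue
        try:
            res = compare_arms(table, col, "one_way_anova")
            results[col] = {"F": res.statistic, "p": res.p}
        except ValueError as exc:
            results[col] = {"error": str(exc)}
    lineage = marker_positive_fraction(
        bundle.norm,
        group,
        barcodes["animal"].to_numpy(),
        config.lineage_marker,
        config.lineage_threshold,
    )
    _write_tsv(lineage.set_index(["animal", "group"]), os.path.join(outdir, "lineage_fractions.tsv"))
    with open(os.path.join(outdir, "arm_comparisons.json"), "w") as fh:
        json.dump(results, fh, indent=2)
    return {"groups_tested": len(results)}


def _stage_correlate(config: PipelineConfig, outdir: str, state: dict) -> dict:
    bundle: ClusteringBundle = state["bundle"]
    mask = _tumor_mask(config, state)
    gx = config.correlate.get("gene_x", "Sufu")
    gy = config.correlate.get("gene_y", "Gli1")
    k = int(config.correlate.get("k", 12))
    t = int(config.correlate.get("t", 3))
    arms = bundle.norm.barcodes["arm"].to_numpy()
    records = []
    imputed_frames = []
    for arm in pd.unique(arms):
        sel = mask & (arms == arm)
        if sel.sum() <= max(k, 3):
            continue
        emb = bundle.pca.significant_embeddings()[sel]
        op = build_diffusion_operator(emb, k=k)
        sub = bundle.norm.subset_barcodes(sel)
        vals = np.column_stack([sub.gene_vector(gx), sub.gene_vector(gy)])
        imp = impute(op, vals, t=t)
        res = correlate(imp[:, 0], imp[:, 1], gx, gy, arm=arm)
        records.append(res.to_dict())
        imputed_frames.append(
            pd.DataFrame(
                {f"{gx}_imputed": imp[:, 0], f"{gy}_imputed": imp[:, 1], "arm": arm},
                index=sub.barcodes.index,
            )
        )
    if not imputed_frames:
        raise ValueError("no arm had enough tumor cells for imputation")
    imputed = pd.concat(imputed_frames)
    _write_tsv(imputed, os.path.join(outdir, "imputed_expression.tsv"))
    anc = ancova_interaction(
        imputed[f"{gx}_imputed"].to_numpy(),
        imputed[f"{gy}_imputed"].to_numpy(),
        imputed["arm"].to_numpy(),
    )
    payload = {
        "correlations": records,
        "ancova": {
            "slopes": anc.slopes,
            "interaction_F": anc.interaction_f,
            "interaction_p": anc.interaction_p,
            "caveat": anc.caveat,
        },
        "k": k,
        "t": t,
    }
    with open(os.path.join(outdir, "correlation.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"arms": [r["arm"] for r in records]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "project": _stage_project,
    "ica": _stage_ica,
    "stats": _stage_stats,
    "correlate": _stage_correlate,
}
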