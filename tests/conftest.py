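"""Shared fixtures: generated cohorts and derived analysis bundles.

Everything is produced programmatically by the simulator; heavy objects
are session-scoped so recovery tests share one cohort per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nodescope.qc import run_qc
from nodescope.resources import load_marker_config
from nodescope.simulate import default_config, simulate_cohort
from nodescope.workflow import reduce_and_cluster


def small_discrete_config(seed: int, names=("astrocyte", "oligodendrocyte", "microglia"),
                          n_cells: int = 80, animals: int = 1):
    """Compact single-arm discrete-population cohort (no trajectory,
    doublets, spike-ins or chimeras)."""
    cfg = default_config(seed=seed)
    cfg.populations = [p for p in cfg.populations if p.name in names]
    for p in cfg.populations:
        p.n_cells_per_animal = n_cells
    cfg.trajectories = []
    cfg.n_animals_per_arm = animals
    cfg.arms = ("vehicle",)
    cfg.effects = {"vehicle": cfg.effects["vehicle"]}
    cfg.doublet_rate = 0.0
    cfg.spikein_rate = 0.0
    cfg.chimera_rate = 0.0
    return cfg


def stromal_config(seed: int, n_cells: int = 60, animals: int = 2):
    """All six stromal populations, one arm; the doublet-detection fixture."""
    cfg = default_config(seed=seed)
    for p in cfg.populations:
        p.n_cells_per_animal = n_cells
    cfg.trajectories = []
    cfg.n_animals_per_arm = animals
    cfg.arms = ("vehicle",)
    cfg.effects = {"vehicle": cfg.effects["vehicle"]}
    cfg.doublet_rate = 0.0
    cfg.spikein_rate = 0.0
    cfg.chimera_rate = 0.0
    return cfg


def truth_class_labels(truth: pd.DataFrame) -> pd.Series:
    """Ground-truth class per cell: population name, with trajectory cells
    labeled by pseudotime tier."""
    lab = truth["population"].copy()
    traj = truth["tier"] >= 0
    lab[traj] = "tier" + truth.loc[traj, "tier"].astype(str)
    return lab


@pytest.fixture(scope="session")
def cohort():
    """Default two-arm cohort (seed 1): raw matrix + truth."""
    cfg = default_config(seed=1)
    matrix, truth = simulate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def qc_cohort(cohort):
    """QC'd default cohort plus the QC report and truth restricted to
    surviving barcodes."""
    _, matrix, truth = cohort
    filtered, report = run_qc(matrix)
    return filtered, report, truth


@pytest.fixture(scope="session")
def clustered_cohort(qc_cohort):
    """Clustering bundle (with cell types) over the QC'd default cohort."""
    filtered, _, truth = qc_cohort
    bundle = reduce_and_cluster(
        filtered, seed=1, marker_config=load_marker_config()["cell_types"]
    )
    kept = truth.loc[bundle.norm.barcodes.index]
    return bundle, kept


@pytest.fixture(scope="session")
def tumor_subset(clustered_cohort):
    """Normalized tumor-cluster subset of the default cohort."""
    bundle, kept = clustered_cohort
    tumor_clusters = [c for c, t in bundle.cell_types.items() if t == "cgnp_tumor"]
    mask = np.isin(bundle.clusters.labels, tumor_clusters)
    return bundle.norm.subset_barcodes(mask), kept[mask], bundle, mask
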