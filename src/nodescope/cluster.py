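"""Dimensionality reduction, graph clustering and cluster-level analyses.

The reduction backbone follows the standard single-cell recipe: binned
dispersion z-scoring for variable-gene selection, SVD PCA on centered and
unit-scaled variable genes, significant-component selection by z-scoring
each component's share of the variance (z > 2), shared-nearest-neighbor
graph construction with Jaccard edge weights and modularity-maximizing
community detection at resolution 0.8, and t-SNE for 2-D layout.

Cluster-level analyses: a zero-inflated log-normal ("bimodal") likelihood
ratio test for differential expression, a doublet-cluster heuristic (many
significant genes of low fold-change and high detection against a pair of
parent clusters), hierarchical merging of cluster centroids into nodes,
and marker-threshold cell-type labeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariableGeneSelection",
    "PCAModel",
    "ClusterResult",
    "TSNELayout",
    "DEResult",
    "NodeTree",
    "select_variable_genes",
    "fit_pca",
    "select_significant_pcs",
    "build_snn_cluster",
    "embed_tsne",
    "de_bimod_lrt",
    "detect_doublet_clusters",
    "merge_clusters_to_nodes",
    "classify_cell_types",
]


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------


@dataclass
class VariableGeneSelection:
    table: pd.DataFrame  # per-gene: mean, dispersion, bin, z
    selected: pd.Index
    mean_low: float
    mean_high: float
    z_min: float
    n_bins: int


def select_variable_genes(
    norm: NormalizedMatrix,
    mean_low: float = 0.125,
    mean_high: float = 3.0,
    z_min: float = 0.5,
    n_bins: int = 20,
) -> VariableGeneSelection:
    """Binned-dispersion variable-gene selection.

    Per gene: mean expression and dispersion (variance/mean) over cells;
    genes are sorted into ``n_bins`` equal-width bins of mean expression and
    dispersion is z-scored within each bin.  Selected genes have mean in
    (mean_low, mean_high) and dispersion z-score >= z_min.
    """
    values = norm.values
    means = values.mean(axis=1)
    variances = values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, variances / np.maximum(means, 1e-300), 0.0)
    if len(np.unique(means)) < n_bins:
        raise ValueError(f"need at least {n_bins} distinct gene means")
    edges = np.linspace(means.min(), means.max(), n_bins + 1)
    bins = np.clip(np.digitize(means, edges[1:-1]), 0, n_bins - 1)
    z = np.zeros_like(dispersion)
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        mu, sd = dispersion[sel].mean(), dispersion[sel].std()
        z[sel] = (dispersion[sel] - mu) / sd if sd > 0 else 0.0
    table = pd.DataFrame(
        {"mean": means, "dispersion": dispersion, "bin": bins, "z": z},
        index=norm.genes.index,
    )
    keep = (means > mean_low) & (means < mean_high) & (z >= z_min)
    selected = norm.genes.index[keep]
    if len(selected) == 0:
        raise ValueError("no variable genes selected; relax the cutoffs")
    return VariableGeneSelection(table, selected, mean_low, mean_high, z_min, n_bins)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """SVD PCA over centered, unit-scaled variable genes.

    ``loadings`` (genes x components) are the gene-side singular vectors;
    ``embeddings`` (cells x components) are the cell scores weighted by
    each component's singular value when ``weight_by_var`` (so per-column
    spread reflects component variance).  ``gene_means``/``gene_sds`` are
    the scaling constants, retained for reference projection.
    """

    genes: pd.Index
    gene_means: np.ndarray
    gene_sds: np.ndarray
    loadings: np.ndarray
    embeddings: np.ndarray
    variances: np.ndarray
    z_scores: np.ndarray
    significant: list[int]
    excluded: list[int]
    weight_by_var: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def significant_embeddings(self) -> np.ndarray:
        return self.embeddings[:, self.significant]


def fit_pca(
    norm: NormalizedMatrix,
    genes: pd.Index | None = None,
    n_components: int = 50,
    weight_by_var: bool = True,
    covariate: np.ndarray | None = None,
) -> PCAModel:
    """Exact SVD PCA on the selected genes; deterministic up to the fixed
    sign convention (the largest-|loading| gene of each component is
    positive).

    ``covariate`` (one value per cell, e.g. log library size) is
    residualized out of each scaled gene before decomposition — the
    standard guard against a total-count gradient masquerading as a
    biological axis.
    """
    genes = norm.genes.index if genes is None else pd.Index(genes)
    X = norm.values[norm.genes.index.get_indexer(genes), :].T  # cells x genes
    n_cells, n_genes = X.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components {n_components} exceeds min(cells, genes) = "
            f"{min(n_cells, n_genes)}"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    if covariate is not None:
        x = np.asarray(covariate, dtype=float)
        if x.shape != (n_cells,):
            raise ValueError("covariate must have one value per cell")
        x = x - x.mean()
        denom = float(x @ x)
        if denom > 0:
            Z = Z - np.outer(x, (x @ Z) / denom)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| gene positive per component
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip = np.where(flip == 0, 1.0, flip)
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    loadings = Vt.T
    embeddings = U * S[None, :] if weight_by_var else U
    variances = S**2 / max(n_cells - 1, 1)
    sd = variances.std()
    z = (variances - variances.mean()) / sd if sd > 0 else np.zeros_like(variances)
    model = PCAModel(
        genes=genes, gene_means=means, gene_sds=sds, loadings=loadings,
        embeddings=embeddings, variances=variances, z_scores=z,
        significant=[], excluded=[], weight_by_var=weight_by_var,
    )
    try:
        model.significant = select_significant_pcs(model)
    except ValueError:
        model.significant = list(range(min(10, n_components)))
    return model


def select_significant_pcs(
    model: PCAModel, z_threshold: float = 2.0, exclusions: set[int] | None = None
) -> list[int]:
    """Components whose variance z-score (over the per-component variance
    vector) exceeds ``z_threshold``, minus any manually excluded components
    (e.g. batch-effect axes), in component order.  Exclusions are 0-based
    component indices."""
    exclusions = exclusions or set()
    sig = [
        int(c)
        for c in range(model.n_components)
        if model.z_scores[c] > z_threshold and c not in exclusions
    ]
    if not sig:
        raise ValueError("no significant components at this threshold")
    return sig


# ---------------------------------------------------------------------------
# SNN clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: np.ndarray
    snn: sp.csr_matrix
    resolution: float
    modularity: float
    seed: int
    k_neighbors: int
    method: str = "leiden"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cluster_cells(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def _snn_graph(embeddings: np.ndarray, k: int, prune: float) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: kNN by Euclidean distance, edges
    weighted by the Jaccard index of the two cells' neighbor lists
    (self-inclusive), pruned below ``prune``."""
    n = embeddings.shape[0]
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(embeddings)
    _, idx = nn.kneighbors(embeddings)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    adj[np.arange(n), np.arange(n)] = 1.0  # self-inclusive neighbor sets
    shared = adj @ adj.T
    shared = shared.tocoo()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    union = sizes[shared.row] + sizes[shared.col] - shared.data
    jaccard = shared.data / union
    keep = (jaccard >= prune) & (shared.row != shared.col)
    return sp.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def build_snn_cluster(
    embeddings: np.ndarray,
    k_neighbors: int = 30,
    resolution: float = 0.8,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> ClusterResult:
    """SNN graph + modularity-maximizing community detection.

    Communities are found on the Jaccard-weighted SNN graph with a
    configurable resolution parameter (RB-configuration modularity, Leiden
    refinement of the Louvain scheme); deterministic for a fixed seed.
    Labels are re-indexed to contiguous integers ordered by cluster size.
    """
    n = embeddings.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least {k_neighbors + 1} cells")
    if np.allclose(embeddings, embeddings[0]):
        warnings.warn("degenerate embeddings: all cells identical", stacklevel=2)
        snn = sp.csr_matrix((n, n))
        return ClusterResult(
            np.zeros(n, dtype=int), snn, resolution, 0.0, seed, k_neighbors
        )
    snn = _snn_graph(embeddings, k_neighbors, prune)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    # contiguous labels, largest cluster first (stable tie-break by raw label)
    order = pd.Series(raw).value_counts(sort=True).index.to_numpy()
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(v)] for v in raw])
    return ClusterResult(
        labels, snn, resolution, float(part.quality()), seed, k_neighbors
    )


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------


@dataclass
class TSNELayout:
    coordinates: np.ndarray
    perplexity: float
    seed: int


def embed_tsne(
    embeddings: np.ndarray, perplexity: float = 30.0, seed: int = 0
) -> TSNELayout:
    """Barnes-Hut t-SNE of the (significant-component) embeddings;
    deterministic for a fixed seed."""
    n = embeddings.shape[0]
    if embeddings.ndim != 2 or embeddings.shape[1] < 2:
        raise ValueError("t-SNE needs at least 2 input dimensions")
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        n_jobs=1,
    )
    coords = ts.fit_transform(np.asarray(embeddings, dtype=np.float64))
    return TSNELayout(np.asarray(coords, dtype=np.float64), perplexity, seed)


# ---------------------------------------------------------------------------
# bimodal likelihood-ratio differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: log_fc, pct_a, pct_b, lrt, p, p_adj

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def _bimod_loglik(n: np.ndarray, k: np.ndarray, s1: np.ndarray, s2: np.ndarray):
    """Maximized log-likelihood of the zero-inflated log-normal model per
    gene, from sufficient statistics: n cells, k positive, sum and
    sum-of-squares of positive values.  Variance floored to keep the
    degenerate single-positive-value case finite."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = k / n
        binom = np.where(k > 0, k * np.log(np.maximum(p, 1e-300)), 0.0) + np.where(
            n - k > 0, (n - k) * np.log(np.maximum(1 - p, 1e-300)), 0.0
        )
        mu = np.where(k > 0, s1 / np.maximum(k, 1), 0.0)
        var = np.where(k > 0, s2 / np.maximum(k, 1) - mu**2, 0.0)
        var = np.maximum(var, 1e-6)
        normal = np.where(
            k > 0, -0.5 * k * (np.log(2 * np.pi * var) + 1.0), 0.0
        )
    return binom + normal


def de_bimod_lrt(
    norm: NormalizedMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
) -> DEResult:
    """Likelihood-ratio test for single-cell differential expression.

    Expression of each gene is modeled as a point mass at zero mixed with a
    log-scale normal component; the LRT compares a pooled fit against
    independent per-group fits (detection probability, positive-component
    mean and variance; 3 df).  Log fold-change is the difference of group
    means of normalized expression; p-values are Benjamini-Hochberg
    adjusted.  Genes with no expression in either group get p = 1.
    """
    a = norm.values[:, np.asarray(cells_a)]
    b = norm.values[:, np.asarray(cells_b)]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")

    def suff(x):
        pos = x > 0
        k = pos.sum(axis=1).astype(float)
        s1 = np.where(pos, x, 0.0).sum(axis=1)
        s2 = np.where(pos, x**2, 0.0).sum(axis=1)
        return k, s1, s2

    ka, s1a, s2a = suff(a)
    kb, s1b, s2b = suff(b)
    na, nb = float(a.shape[1]), float(b.shape[1])
    ll_a = _bimod_loglik(np.full_like(ka, na), ka, s1a, s2a)
    ll_b = _bimod_loglik(np.full_like(kb, nb), kb, s1b, s2b)
    ll_pool = _bimod_loglik(
        np.full_like(ka, na + nb), ka + kb, s1a + s1b, s2a + s2b
    )
    lrt = np.maximum(2.0 * (ll_a + ll_b - ll_pool), 0.0)
    p = stats.chi2.sf(lrt, df=3)
    allzero = (ka + kb) == 0
    p[allzero] = 1.0
    lrt[allzero] = 0.0
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    log_fc[allzero] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "pct_a": ka / na,
            "pct_b": kb / nb,
            "lrt": lrt,
            "p": p,
            "p_adj": np.maximum(p_adj, p),
        },
        index=norm.genes.index,
    )
    return DEResult(table)


# ---------------------------------------------------------------------------
# doublet-cluster detection
# ---------------------------------------------------------------------------


@dataclass
class DoubletFlag:
    cluster: int
    parents: tuple[int, int]
    n_low_fc_genes: tuple[int, int]


def detect_doublet_clusters(
    norm: NormalizedMatrix,
    clusters: ClusterResult,
    n_min: int = 50,
    alpha: float = 0.05,
    fc_max: float = 0.5,
    pct_min: float = 0.25,
) -> list[DoubletFlag]:
    """Flag clusters bearing the transcriptomic signature of co-captured
    cell pairs: against both members of some candidate parent pair, at
    least ``n_min`` significantly differential genes with low fold-change
    (|logFC| < fc_max) and high detection in both groups
    (min pct > pct_min)."""
    if clusters.n_clusters < 3:
        raise ValueError("need at least 3 clusters")
    ids = range(clusters.n_clusters)
    counts: dict[tuple[int, int], int] = {}
    for c in ids:
        cells_c = clusters.cluster_cells(c)
        for o in ids:
            if o == c:
                continue
            de = de_bimod_lrt(norm, cells_c, clusters.cluster_cells(o)).table
            qual = (
                (de["p_adj"] < alpha)
                & (de["log_fc"].abs() < fc_max)
                & (np.minimum(de["pct_a"], de["pct_b"]) > pct_min)
            )
            counts[(c, o)] = int(qual.sum())
    flags = []
    for c in ids:
        best = None
        for i in ids:
            for j in ids:
                if len({c, i, j}) < 3 or i >= j:
                    continue
                qi, qj = counts[(c, i)], counts[(c, j)]
                if qi >= n_min and qj >= n_min:
                    if best is None or min(qi, qj) > min(best[1], best[2]):
                        best = ((i, j), qi, qj)
        if best is not None:
            flags.append(DoubletFlag(c, best[0], (best[1], best[2])))
    return flags


# ---------------------------------------------------------------------------
# node merging
# ---------------------------------------------------------------------------


@dataclass
class NodeTree:
    linkage_matrix: np.ndarray
    cluster_ids: list[int]
    node_assignment: dict[int, int]
    linkage_method: str

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage_matrix)

        def rec(node):
            if node.is_leaf():
                return f"c{self.cluster_ids[node.id]}"
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def merge_clusters_to_nodes(
    model: PCAModel,
    clusters: ClusterResult,
    n_nodes: int,
    subset: list[int] | None = None,
    linkage_method: str = "average",
) -> NodeTree:
    """Hierarchically cluster the cluster centroids in significant-PC space
    and cut the dendrogram into ``n_nodes`` groups.

    ``subset`` restricts the tree to a designated set of clusters (e.g. the
    multi-cluster differentiation complex); other clusters are not assigned
    a node.
    """
    ids = sorted(subset) if subset is not None else list(range(clusters.n_clusters))
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters to merge")
    if n_nodes > len(ids):
        raise ValueError(f"n_nodes {n_nodes} exceeds {len(ids)} clusters")
    emb = model.significant_embeddings()
    centroids = np.vstack([emb[clusters.labels == c].mean(axis=0) for c in ids])
    Z = sch.linkage(centroids, method=linkage_method, metric="euclidean")
    cut = sch.fcluster(Z, t=n_nodes, criterion="maxclust")
    assignment = {c: int(g) - 1 for c, g in zip(ids, cut)}
    return NodeTree(Z, ids, assignment, linkage_method)


# ---------------------------------------------------------------------------
# marker-based cell-type labeling
# ---------------------------------------------------------------------------


def classify_cell_types(
    norm: NormalizedMatrix,
    clusters: ClusterResult,
    marker_config: dict[str, dict[str, float]],
    min_fraction: float = 0.5,
) -> dict[int, str]:
    """Label each cluster with the cell type whose marker set has the
    highest mean positive fraction (expression > per-gene threshold),
    provided it exceeds ``min_fraction``; otherwise "unassigned".  Markers
    absent from the matrix are skipped with a warning."""
    if not marker_config:
        raise ValueError("marker_config is empty")
    gene_index = norm.genes.index
    usable: dict[str, list[tuple[int, float]]] = {}
    for ctype, markers in marker_config.items():
        rows = []
        for gene, thr in markers.items():
            if gene in gene_index:
                rows.append((gene_index.get_loc(gene), float(thr)))
            else:
                warnings.warn(f"marker gene {gene!r} absent; skipped", stacklevel=2)
        if rows:
            usable[ctype] = rows
    labels: dict[int, str] = {}
    for c in range(clusters.n_clusters):
        cells = clusters.cluster_cells(c)
        best, best_frac = "unassigned", min_fraction
        for ctype, rows in usable.items():
            fracs = [
                (norm.values[i, cells] > thr).mean() for i, thr in rows
            ]
            f = float(np.mean(fracs))
            if f > best_frac:
                best, best_frac = ctype, f
        labels[c] = best
    return labels
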