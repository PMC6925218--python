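"""Chained analysis steps over a QC'd count matrix.

Convenience layer tying the module surfaces together in the standard
order: log normalization -> variable genes -> PCA (with optional
library-size residualization) -> significant-component selection -> SNN
community detection -> optional t-SNE and cell-type labels.  The pipeline
runner, the command-line interface and the recovery tests all go through
this entry point so they share identical defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import (
    ClusterResult,
    PCAModel,
    TSNELayout,
    VariableGeneSelection,
    build_snn_cluster,
    classify_cell_types,
    embed_tsne,
    fit_pca,
    select_significant_pcs,
    select_variable_genes,
)
from .matrix import CountMatrix, NormalizedMatrix
from .qc import normalize_log

__all__ = ["ClusteringBundle", "reduce_and_cluster"]


@dataclass
class ClusteringBundle:
    norm: NormalizedMatrix
    variable_genes: VariableGeneSelection
    pca: PCAModel
    clusters: ClusterResult
    layout: TSNELayout | None = None
    cell_types: dict[int, str] = field(default_factory=dict)

    def used_components(self) -> list[int]:
        return self.pca.significant


def reduce_and_cluster(
    matrix: CountMatrix,
    seed: int = 0,
    scale_total: float = 10_000.0,
    n_components: int = 50,
    pcs: str | int = "significant",
    exclude_pcs: set[int] | None = None,
    regress_library_size: bool = True,
    k_neighbors: int = 30,
    resolution: float = 0.8,
    with_tsne: bool = False,
    perplexity: float = 30.0,
    marker_config: dict | None = None,
    min_marker_fraction: float = 0.5,
) -> ClusteringBundle:
    """Normalize, reduce and cluster a QC'd matrix with shared defaults.

    ``pcs`` is either "significant" (variance z > 2, minus ``exclude_pcs``)
    or an explicit component count (the first N components), mirroring
    manual component curation.  ``regress_library_size`` residualizes log
    total counts out of each scaled gene before the SVD, so that depth
    gradients do not masquerade as structure.
    """
    norm = normalize_log(matrix, scale_total)
    selection = select_variable_genes(norm)
    covariate = (
        np.log(matrix.barcode_totals().astype(float)) if regress_library_size else None
    )
    n_components = min(
        n_components, len(selection.selected) - 1, matrix.n_barcodes - 1
    )
    pca = fit_pca(norm, selection.selected, n_components=n_components, covariate=covariate)
    if pcs == "significant":
        try:
            pca.significant = select_significant_pcs(pca, exclusions=exclude_pcs)
        except ValueError:
            pca.significant = [
                c for c in range(min(10, pca.n_components))
                if c not in (exclude_pcs or set())
            ]
    else:
        pca.significant = [
            c for c in range(int(pcs)) if c not in (exclude_pcs or set())
        ]
    pca.excluded = sorted(exclude_pcs) if exclude_pcs else []
    clusters = build_snn_cluster(
        pca.significant_embeddings(),
        k_neighbors=k_neighbors,
        resolution=resolution,
        seed=seed,
    )
    bundle = ClusteringBundle(norm, selection, pca, clusters)
    if with_tsne:
        bundle.layout = embed_tsne(
            pca.significant_embeddings(), perplexity=perplexity, seed=seed
        )
    if marker_config:
        bundle.cell_types = classify_cell_types(
            norm, clusters, marker_config, min_fraction=min_marker_fraction
        )
    return bundle
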