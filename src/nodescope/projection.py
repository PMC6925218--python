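"""Cross-dataset reference projection.

A fitted reference (typically the wild-type developmental dataset) exposes
its variable-gene scaling constants, PCA gene loadings and 2-D layout.
Query cells (e.g. tumor cells) are embedded into the reference PC space by
multiplying their rescaled expression with the reference gene loadings,
then placed and labeled by k-nearest-neighbor averaging among reference
cells: the placed coordinate is the arithmetic mean of the K neighbors'
layout coordinates, the transferred label is the neighbor majority vote.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import PCAModel, TSNELayout
from .matrix import NormalizedMatrix

__all__ = [
    "ReferenceModel",
    "ProjectionResult",
    "build_reference",
    "project_into_reference",
    "knn_place",
    "transfer_labels",
]


@dataclass
class ReferenceModel:
    """Frozen reference: scaling constants, loadings, embeddings, layout,
    labels.  ``components`` is the ordered significant-component list used
    for neighbor search."""

    genes: pd.Index
    gene_means: np.ndarray
    gene_sds: np.ndarray
    loadings: np.ndarray
    variances: np.ndarray
    components: list[int]
    embeddings: np.ndarray
    layout: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        pd.DataFrame(
            np.column_stack([self.gene_means, self.gene_sds, self.loadings]),
            index=self.genes,
            columns=["mean", "sd"] + [f"PC{i}" for i in range(self.loadings.shape[1])],
        ).to_csv(os.path.join(path, "loadings.tsv"), sep="\t")
        np.savetxt(os.path.join(path, "embeddings.tsv"), self.embeddings, delimiter="\t")
        np.savetxt(os.path.join(path, "layout.tsv"), self.layout, delimiter="\t")
        pd.Series(self.labels).to_csv(
            os.path.join(path, "labels.tsv"), sep="\t", header=False
        )
        with open(os.path.join(path, "metadata.json"), "w") as fh:
            json.dump(
                {
                    "variances": self.variances.tolist(),
                    "components": list(self.components),
                    **self.metadata,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str) -> "ReferenceModel":
        df = pd.read_csv(os.path.join(path, "loadings.tsv"), sep="\t", index_col=0)
        with open(os.path.join(path, "metadata.json")) as fh:
            meta = json.load(fh)
        variances = np.array(meta.pop("variances"))
        components = list(meta.pop("components"))
        return cls(
            genes=df.index,
            gene_means=df["mean"].to_numpy(),
            gene_sds=df["sd"].to_numpy(),
            loadings=df.drop(columns=["mean", "sd"]).to_numpy(),
            variances=variances,
            components=components,
            embeddings=np.loadtxt(os.path.join(path, "embeddings.tsv"), ndmin=2),
            layout=np.loadtxt(os.path.join(path, "layout.tsv"), ndmin=2),
            labels=pd.read_csv(
                os.path.join(path, "labels.tsv"), sep="\t", header=None, index_col=0
            )[1].to_numpy(),
            metadata=meta,
        )


@dataclass
class ProjectionResult:
    embeddings: np.ndarray           # queries x components (full)
    neighbor_indices: np.ndarray     # queries x K
    neighbor_distances: np.ndarray   # queries x K
    placed: np.ndarray               # queries x 2
    labels: np.ndarray               # queries
    confidence: np.ndarray           # queries, vote fraction in (0, 1]
    K: int
    metadata: dict = field(default_factory=dict)


def build_reference(
    model: PCAModel, layout: TSNELayout, labels: np.ndarray, **metadata
) -> ReferenceModel:
    """Assemble a ReferenceModel from a fitted PCA, a 2-D layout and
    per-cell labels of the reference dataset."""
    labels = np.asarray(labels)
    if not (len(labels) == model.embeddings.shape[0] == layout.coordinates.shape[0]):
        raise ValueError("embeddings, layout and labels must align per cell")
    return ReferenceModel(
        genes=model.genes,
        gene_means=model.gene_means,
        gene_sds=model.gene_sds,
        loadings=model.loadings,
        variances=model.variances,
        components=list(model.significant),
        embeddings=model.embeddings,
        layout=layout.coordinates,
        labels=labels,
        metadata=dict(metadata),
    )


def project_into_reference(
    ref: ReferenceModel,
    query: NormalizedMatrix,
    min_gene_overlap: float = 0.5,
) -> np.ndarray:
    """Embed query cells into the reference PC space via the reference gene
    loadings.

    Query expression is restricted to the reference variable genes and
    transformed with the *reference* centering/scaling constants; genes the
    query lacks contribute the centered value of a zero count.  The
    embedding is the rescaled expression times the loadings, which
    reproduces the reference's own (variance-weighted) scores exactly for
    reference cells.
    """
    shared = ref.genes.intersection(query.genes.index)
    overlap = len(shared) / len(ref.genes)
    if overlap < min_gene_overlap:
        raise ValueError(
            f"only {overlap:.0%} of reference variable genes present in query "
            f"(floor {min_gene_overlap:.0%})"
        )
    n_query = query.n_barcodes
    X = np.zeros((n_query, len(ref.genes)))
    pos_ref = ref.genes.get_indexer(shared)
    pos_query = query.genes.index.get_indexer(shared)
    X[:, pos_ref] = query.values[pos_query, :].T
    Z = (X - ref.gene_means) / ref.gene_sds
    return Z @ ref.loadings


def knn_place(
    ref: ReferenceModel, query_embeddings: np.ndarray, K: int = 5
) -> ProjectionResult:
    """Place queries at the mean layout coordinates of their K nearest
    reference cells (Euclidean distance over the reference's significant
    components; ties broken by reference cell index) and transfer labels by
    majority vote.

    Both K = 5 and K = 3 are common conventions for this step; the default
    is 5 and the value actually used is recorded in the result metadata.
    """
    n_ref = ref.embeddings.shape[0]
    if not (1 <= K <= n_ref):
        raise ValueError(f"K must lie in [1, {n_ref}]")
    comps = ref.components
    refE = ref.embeddings[:, comps]
    qE = np.asarray(query_embeddings)[:, comps]
    n_query = qE.shape[0]
    idx = np.empty((n_query, K), dtype=int)
    dist = np.empty((n_query, K))
    chunk = max(1, int(2e7 // max(n_ref, 1)))
    for start in range(0, n_query, chunk):
        block = qE[start : start + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            - 2.0 * block @ refE.T
            + np.sum(refE**2, axis=1)[None, :]
        )
        order = np.argsort(d2, axis=1, kind="stable")[:, :K]
        idx[start : start + chunk] = order
        dist[start : start + chunk] = np.sqrt(
            np.maximum(np.take_along_axis(d2, order, axis=1), 0.0)
        )
    placed = ref.layout[idx].mean(axis=1)
    labels, confidence = transfer_labels(idx, ref.labels)
    return ProjectionResult(
        embeddings=np.asarray(query_embeddings),
        neighbor_indices=idx,
        neighbor_distances=dist,
        placed=placed,
        labels=labels,
        confidence=confidence,
        K=K,
        metadata={
            "K": K,
            "note": "K=5 default; K=3 is an equally common convention for this placement",
        },
    )


def transfer_labels(
    neighbor_indices: np.ndarray, ref_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority label among each query's neighbors with the vote fraction
    as confidence; vote ties resolve to the nearest neighbor's label."""
    ref_labels = np.asarray(ref_labels)
    n, K = neighbor_indices.shape
    out = np.empty(n, dtype=ref_labels.dtype)
    conf = np.empty(n)
    for i in range(n):
        votes = pd.Series(ref_labels[neighbor_indices[i]]).value_counts()
        top = votes.max()
        winners = set(votes.index[votes == top])
        if len(winners) > 1:
            label = next(
                ref_labels[j] for j in neighbor_indices[i] if ref_labels[j] in winners
            )
        else:
            label = votes.idxmax()
        out[i] = label
        conf[i] = top / K
    return out, conf
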