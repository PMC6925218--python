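"""ICA decomposition of the tumor compartment and cell-cycle scoring.

After stromal cells are removed, variable genes are re-selected on the
tumor subset and an independent component analysis is run on the z-scaled
variable-gene x cell matrix.  The number of components defaults to the
number of significant PCA dimensions (variance z > 2) of the same subset.
The differentiation component is identified by marker enrichment in the
top-weighted gene tails; cell-cycle phases are scored from phase gene
lists (mean z-scored expression, argmax assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import FastICA

from .cluster import TSNELayout, embed_tsne, fit_pca, select_variable_genes
from .matrix import NormalizedMatrix
from .resources import load_cell_cycle_genes

__all__ = [
    "ICAModel",
    "PhaseScores",
    "fit_ica",
    "identify_differentiation_ic",
    "score_cell_cycle",
    "ic_tsne",
    "DIFFERENTIATION_MARKERS",
    "PROLIFERATION_MARKERS",
]

#: Canonical neuronal-differentiation markers used to orient the
#: differentiation component on murine cerebellar data.
DIFFERENTIATION_MARKERS = [
    "Rbfox3", "Cntn2", "Grin2b", "Neurod1", "Nhlh1", "Gabra6", "Cntn1",
]

#: Proliferation/progenitor markers (mitogenic program + cycle drivers).
PROLIFERATION_MARKERS = [
    "Atoh1", "Sfrp1", "Ptch1", "Mycn", "Mki67", "Ccnb1", "Cdk1", "Top2a",
]


@dataclass
class ICAModel:
    n_components: int
    scores: np.ndarray       # cells x components, ~unit variance
    weights: pd.DataFrame    # genes x components
    top_tail_n: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def top_genes(self, component: int, tail: str = "positive", n: int | None = None):
        """The n most heavily weighted genes in one tail of a component."""
        n = n or self.top_tail_n
        w = self.weights.iloc[:, component]
        ordered = w.sort_values(ascending=(tail == "negative"))
        return ordered.index[:n]


def fit_ica(
    norm: NormalizedMatrix,
    n_components: int | str = "auto",
    seed: int = 0,
    top_tail_n: int = 50,
    max_components: int = 30,
    reselect_variable_genes: bool = True,
) -> ICAModel:
    """Fixed-point ICA (deflation, logcosh contrast) on z-scaled variable
    genes of the (stroma-free) subset.

    Variable genes are re-selected on the subset itself (disable with
    ``reselect_variable_genes=False`` to use every gene).  With
    ``n_components="auto"`` the component count equals the number of
    significant PCA dimensions (variance z > 2) of the same matrix.
    Components are sign-oriented so the heavier weight tail is positive,
    and ordered by decreasing score kurtosis (most non-Gaussian first).
    """
    if reselect_variable_genes:
        selection = select_variable_genes(norm)
        sub = norm.subset_genes(selection.selected)
    else:
        sub = norm
    if n_components == "auto":
        pca = fit_pca(
            norm, sub.genes.index,
            n_components=min(max_components, sub.n_genes, sub.n_barcodes),
        )
        n_components = len(pca.significant)
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = sub.values.T  # cells x genes
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        random_state=seed,
        max_iter=500,
    )
    scores = ica.fit_transform(Z)
    weights = ica.components_.T  # genes x components

    # orientation: heavier tail of gene weights positive
    for c in range(n_components):
        w = weights[:, c]
        k = min(top_tail_n, len(w))
        pos = np.sort(w)[-k:]
        neg = np.sort(w)[:k]
        if np.abs(neg).sum() > np.abs(pos).sum():
            weights[:, c] = -w
            scores[:, c] = -scores[:, c]
    order = np.argsort(-_stats.kurtosis(scores, axis=0))
    scores = scores[:, order]
    weights = weights[:, order]
    wdf = pd.DataFrame(
        weights, index=sub.genes.index,
        columns=[f"IC{i + 1}" for i in range(n_components)],
    )
    return ICAModel(
        n_components=n_components,
        scores=scores,
        weights=wdf,
        top_tail_n=top_tail_n,
        seed=seed,
        metadata={"n_variable_genes": int(sub.n_genes)},
    )


def identify_differentiation_ic(
    model: ICAModel,
    differentiation_markers: list[str] | None = None,
    proliferation_markers: list[str] | None = None,
) -> tuple[int, int]:
    """Locate the differentiation axis among the components.

    For each component and orientation the enrichment score counts
    differentiation markers in the top-``n`` positive tail minus those in
    the negative tail; the proliferation markers act only as a tie-break
    (a differentiation axis should carry them at its negative end).
    Returns (component index, orientation in {+1, -1}); remaining ties
    resolve to the lower component index.
    """
    diff = differentiation_markers or DIFFERENTIATION_MARKERS
    prol = proliferation_markers or PROLIFERATION_MARKERS
    genes = model.weights.index
    diff = [g for g in diff if g in genes]
    prol = [g for g in prol if g in genes]
    if not diff:
        raise ValueError("no differentiation markers present in the weight matrix")
    best: tuple[int, int] | None = None
    best_key: tuple[float, float] = (-np.inf, -np.inf)
    for c in range(model.n_components):
        w = model.weights.iloc[:, c]
        for orient in (1, -1):
            ordered = (w * orient).sort_values(ascending=False)
            top_pos = set(ordered.index[: model.top_tail_n])
            top_neg = set(ordered.index[-model.top_tail_n:])
            enrich = sum(g in top_pos for g in diff) - sum(g in top_neg for g in diff)
            tiebreak = sum(g in top_neg for g in prol) - sum(g in top_pos for g in prol)
            if (enrich, tiebreak) > best_key:
                best_key, best = (enrich, tiebreak), (c, orient)
    if best_key[0] <= 0:
        raise ValueError("no component carries the differentiation markers")
    return best


@dataclass
class PhaseScores:
    scores: pd.DataFrame  # cells x phases
    assignment: np.ndarray  # per-cell phase, "low-cycling" when all < 0

    @property
    def phases(self) -> list[str]:
        return list(self.scores.columns)


def score_cell_cycle(
    norm: NormalizedMatrix,
    phase_gene_sets: dict[str, list[str]] | None = None,
) -> PhaseScores:
    """Mean z-scored expression of each phase gene list per cell; the
    assigned phase is the argmax, or "low-cycling" when every score is
    negative."""
    phase_gene_sets = phase_gene_sets or load_cell_cycle_genes()
    gene_index = norm.genes.index
    cols = {}
    for phase, genes in phase_gene_sets.items():
        present = [g for g in genes if g in gene_index]
        if not present:
            raise ValueError(f"phase list {phase!r} has no genes in the matrix")
        vals = norm.values[gene_index.get_indexer(present), :]
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        cols[phase] = ((vals - mu) / sd).mean(axis=0)
    scores = pd.DataFrame(cols, index=norm.barcodes.index)
    arr = scores.to_numpy()
    assignment = np.asarray(scores.columns)[arr.argmax(axis=1)].astype(object)
    assignment[(arr <= 0).all(axis=1)] = "low-cycling"
    return PhaseScores(scores, np.asarray(assignment))


def ic_tsne(model: ICAModel, perplexity: float = 30.0, seed: int = 0) -> TSNELayout:
    """t-SNE of the IC score matrix (needs >= 2 components)."""
    if model.scores.shape[1] < 2:
        raise ValueError(
            "t-SNE needs at least 2 components; refit with n_components >= 2"
        )
    return embed_tsne(model.scores, perplexity=perplexity, seed=seed)
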