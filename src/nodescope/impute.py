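"""Diffusion-based expression imputation and gene-gene correlation.

Dropout obscures gene-gene relationships in Drop-seq data; sharing
information across transcriptomically similar cells recovers them.  A
row-stochastic cell-cell transition matrix is built from a k-nearest-
neighbor graph in significant-PC space (k = 12 by default) with an
adaptive Gaussian kernel, and expression vectors are diffused by
multiplying with its powers.  Downstream: Pearson correlation with a
t-distribution test and an ANCOVA treatment-interaction model
(``target ~ regulator * arm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DiffusionOperator",
    "CorrelationResult",
    "AncovaResult",
    "build_diffusion_operator",
    "impute",
    "correlate",
    "ancova_interaction",
]


@dataclass
class DiffusionOperator:
    """Row-stochastic cell-cell transition matrix over a kNN kernel."""

    transition: sp.csr_matrix
    k: int
    bandwidth_rank: int

    @property
    def n_cells(self) -> int:
        return self.transition.shape[0]


def build_diffusion_operator(embeddings: np.ndarray, k: int = 12) -> DiffusionOperator:
    """kNN graph in PC space -> adaptive Gaussian kernel -> symmetrized,
    row-normalized transition matrix.

    The kernel bandwidth of each cell is its distance to the
    ``ceil(k/3)``-th neighbor (excluding self); identical points fall back
    to uniform affinity over the neighborhood.  Every row of the result
    sums to one.
    """
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if not (0 < k < n):
        raise ValueError(f"k must lie in (0, {n})")
    rank = max(1, int(np.ceil(k / 3)))
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(X)
    dist, idx = nn.kneighbors(X)  # includes self at distance 0
    sigma = dist[:, rank]
    sigma = np.where(sigma <= 0, 1.0, sigma)
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k + 1)
    W = sp.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n))
    W = (W + W.T) * 0.5
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = sp.diags(1.0 / np.where(rowsum == 0, 1.0, rowsum))
    P = (inv @ W).tocsr()
    return DiffusionOperator(P, k, rank)


def impute(
    operator: DiffusionOperator, values: np.ndarray, t: int = 3
) -> np.ndarray:
    """Diffuse expression ``t`` steps: ``imputed = P^t @ values``.

    ``values`` is (cells,) or (cells, genes); ``t = 0`` returns the input
    unchanged.  Row-stochasticity preserves constant vectors and makes the
    per-gene variance non-increasing in ``t``.
    """
    if t < 0 or int(t) != t:
        raise ValueError("t must be a nonnegative integer")
    out = np.asarray(values, dtype=float)
    squeeze = out.ndim == 1
    if squeeze:
        out = out[:, None]
    if out.shape[0] != operator.n_cells:
        raise ValueError("values must have one row per cell")
    for _ in range(int(t)):
        out = operator.transition @ out
    return out[:, 0] if squeeze else out


@dataclass
class CorrelationResult:
    gene_x: str
    gene_y: str
    r: float
    t_statistic: float
    p: float
    n: int
    arm: str | None = None
    flagged: bool = False  # zero-variance input; r undefined

    def to_dict(self) -> dict:
        return {
            "gene_x": self.gene_x, "gene_y": self.gene_y, "r": self.r,
            "t": self.t_statistic, "p": self.p, "n": self.n,
            "arm": self.arm, "flagged": self.flagged,
        }


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    gene_x: str = "x",
    gene_y: str = "y",
    arm: str | None = None,
) -> CorrelationResult:
    """Pearson correlation with the t-distribution test:
    ``t = r * sqrt((n - 2) / (1 - r^2))``, two-sided p on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two aligned vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(gene_x, gene_y, np.nan, np.nan, np.nan, n, arm, True)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(gene_x, gene_y, r, np.inf, 0.0, n, arm)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(gene_x, gene_y, r, float(t), float(p), n, arm)


@dataclass
class AncovaResult:
    slopes: dict[str, float]
    interaction_f: float
    interaction_p: float
    n: int
    caveat: str = field(
        default="cells treated as independent observations; cells within an "
        "animal are not independent (pseudo-replication)"
    )


def ancova_interaction(
    x: np.ndarray, y: np.ndarray, arms: np.ndarray
) -> AncovaResult:
    """Linear model ``y ~ x * arm``: per-arm slopes plus the F-test of the
    slope-by-arm interaction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arms = np.asarray(arms)
    levels = pd.unique(arms)
    if len(levels) < 2:
        raise ValueError("need at least two arms")
    for lv in levels:
        if (arms == lv).sum() < 3:
            raise ValueError(f"arm {lv!r} has fewer than 3 cells")
    df = pd.DataFrame({"x": x, "y": y, "arm": pd.Categorical(arms)})
    model = smf.ols("y ~ x * C(arm)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = anova.loc["x:C(arm)"]
    slopes = {
        str(lv): float(
            np.polyfit(df.loc[df["arm"] == lv, "x"], df.loc[df["arm"] == lv, "y"], 1)[0]
        )
        for lv in levels
    }
    return AncovaResult(
        slopes=slopes,
        interaction_f=float(inter["F"]),
        interaction_p=float(inter["PR(>F)"]),
        n=len(df),
    )
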