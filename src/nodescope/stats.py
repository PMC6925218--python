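"""Cohort-level statistics with the animal as the unit of replication.

Per-cell labels are first collapsed to per-animal fractional population
tables (each animal's cells sum to one), and all treatment comparisons are
run on those fractions: one-way ANOVA / two-sample t-tests between arms,
two-way ANOVA of marker-positive rates across cluster groups and animals,
Fisher's exact test, the hypergeometric signature-overlap test, and fold
changes (both ratio-of-means and mean-of-ratios variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .matrix import NormalizedMatrix

__all__ = [
    "fractional_populations",
    "compare_arms",
    "marker_positive_fraction",
    "two_way_anova_rates",
    "fisher_exact_2x2",
    "hypergeom_overlap",
    "fold_change",
    "fold_change_bound",
]


def fractional_populations(
    labels: np.ndarray | pd.Series,
    animals: np.ndarray | pd.Series,
    arms: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Animal x group table of fractions (group count / animal total).

    Rows sum to one over the exhaustive grouping.  When ``arms`` is given
    the arm label is attached as the first column (one label per animal).
    Animals with zero cells are simply absent.
    """
    df = pd.DataFrame({"label": np.asarray(labels), "animal": np.asarray(animals)})
    counts = df.groupby(["animal", "label"], sort=True).size().unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    if arms is not None:
        arm_of = (
            pd.DataFrame({"animal": np.asarray(animals), "arm": np.asarray(arms)})
            .drop_duplicates("animal")
            .set_index("animal")["arm"]
        )
        fractions.insert(0, "arm", arm_of.reindex(fractions.index))
    return fractions


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    df: tuple | None = None


def compare_arms(
    table: pd.DataFrame, group: str, test: str = "one_way_anova"
) -> TestResult:
    """Compare one group's per-animal fractions between arms.

    ``table`` must carry an ``arm`` column (see
    :func:`fractional_populations`).  With two arms the one-way ANOVA F
    equals the square of the two-sample t statistic.  Degenerate inputs
    (zero variance, equal means) report p = 1 by convention.
    """
    if "arm" not in table.columns:
        raise ValueError("table must have an 'arm' column")
    groups = [
        table.loc[table["arm"] == a, group].dropna().to_numpy()
        for a in pd.unique(table["arm"])
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 animals per arm")
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return TestResult(test, 0.0, 1.0)
    if test == "one_way_anova":
        with np.errstate(invalid="ignore"):
            f, p = stats.f_oneway(*groups)
        return TestResult(test, float(f), float(p))
    if test == "two_sample_t":
        if len(groups) != 2:
            raise ValueError("two_sample_t needs exactly 2 arms")
        t, p = stats.ttest_ind(groups[0], groups[1])
        return TestResult(test, float(t), float(p))
    raise ValueError(f"unknown test {test!r}")


def marker_positive_fraction(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    animals: np.ndarray,
    marker: str,
    threshold: float,
) -> pd.DataFrame:
    """Per (animal, group): fraction of cells with normalized ``marker``
    expression above ``threshold``, with the backing counts.

    Groups absent in an animal yield missing values, not zeros.
    """
    if marker not in norm.genes.index:
        raise ValueError(f"marker {marker!r} absent from matrix")
    expr = norm.gene_vector(marker)
    df = pd.DataFrame(
        {
            "animal": np.asarray(animals),
            "group": np.asarray(labels),
            "positive": expr > threshold,
        }
    )
    agg = df.groupby(["animal", "group"], sort=True)["positive"].agg(["sum", "count"])
    agg["fraction"] = agg["sum"] / agg["count"]
    out = agg.reset_index().rename(columns={"sum": "n_positive", "count": "n_cells"})
    out["marker"] = marker
    return out


def two_way_anova_rates(
    table: pd.DataFrame,
    response: str = "fraction",
    factor_a: str = "group",
    factor_b: str = "animal",
) -> dict:
    """Two-factor fixed-effects ANOVA on per-animal rates plus pairwise
    Bonferroni-adjusted contrasts between levels of ``factor_a``.

    ``table`` is long-form (one row per animal x group), e.g. the output of
    :func:`marker_positive_fraction`.
    """
    df = table.dropna(subset=[response]).copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    if np.allclose(df[response], df[response].iloc[0]):
        # constant response: no effects by convention
        effects = {
            f"C({factor_a})": {"F": 0.0, "p": 1.0, "df": float(df[factor_a].nunique() - 1)},
            f"C({factor_b})": {"F": 0.0, "p": 1.0, "df": float(df[factor_b].nunique() - 1)},
        }
        levels = sorted(df[factor_a].unique())
        contrasts = {
            f"{a} vs {b}": {"t": 0.0, "p": 1.0, "p_bonferroni": 1.0}
            for i, a in enumerate(levels)
            for b in levels[i + 1 :]
        }
        return {"effects": effects, "contrasts": contrasts, "n": len(df)}
    formula = f"{response} ~ C({factor_a}) + C({factor_b})"
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    effects = {
        str(idx): {
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
            "df": float(row["df"]),
        }
        for idx, row in anova.iterrows()
        if idx != "Residual"
    }
    levels = sorted(df[factor_a].unique())
    contrasts = {}
    raw = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            xa = df.loc[df[factor_a] == a, response]
            xb = df.loc[df[factor_a] == b, response]
            if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore"):
                    t, p = stats.ttest_ind(xa, xb)
            raw.append(((str(a), str(b)), float(t), float(p)))
    m = len(raw)
    for (pair, t, p) in raw:
        contrasts[f"{pair[0]} vs {pair[1]}"] = {
            "t": t,
            "p": p,
            "p_bonferroni": min(1.0, p * m),
        }
    return {"effects": effects, "contrasts": contrasts, "n": len(df)}


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums the probabilities of all tables (with the observed
    margins) whose hypergeometric probability does not exceed the observed
    table's; the conditional-MLE odds ratio is reported.  A zero margin
    gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        odds = stats.contingency.odds_ratio(t, kind="conditional").statistic
    return float(odds), float(res.pvalue)


def hypergeom_overlap(
    set_a: set | list, set_b: set | list, universe: set | list
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the overlap between two gene sets
    within a universe: P(X >= observed overlap)."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return k, min(1.0, p)


def fold_change(
    frac_a: float | np.ndarray, frac_b: float | np.ndarray, paired: bool = False
) -> float | tuple[float, float]:
    """Fold change of a over b.

    Scalars give the simple ratio of means.  With ``paired=True`` and
    per-animal vectors, returns (mean of per-animal ratios, SEM).
    """
    a = np.atleast_1d(np.asarray(frac_a, dtype=float))
    b = np.atleast_1d(np.asarray(frac_b, dtype=float))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired fold change needs aligned vectors")
        if (b == 0).any():
            raise ValueError("zero denominator; use fold_change_bound")
        ratios = a / b
        return float(ratios.mean()), float(ratios.std(ddof=1) / np.sqrt(len(ratios)))
    denom = b.mean()
    if denom == 0:
        raise ValueError("zero denominator; use fold_change_bound")
    return float(a.mean() / denom)


def fold_change_bound(frac_a: float, n_denominator_cells: int) -> float:
    """Lower bound on the fold change when the denominator fraction is an
    observed zero: compares against the one-count fraction 1/n."""
    if n_denominator_cells <= 0:
        raise ValueError("need a positive denominator cell count")
    return float(frac_a * n_denominator_cells)
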