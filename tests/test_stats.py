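"""Cohort statistics: fractional tables, arm comparisons, two-way ANOVA,
exact tests and fold changes."""

import numpy as np
import pandas as pd
import pytest
from math import comb
from scipy import stats as sps

from nodescope.stats import (
    compare_arms,
    fisher_exact_2x2,
    fold_change,
    fold_change_bound,
    fractional_populations,
    hypergeom_overlap,
    marker_positive_fraction,
    two_way_anova_rates,
)


# ---------------------------------------------------------------------------
# fractional populations
# ---------------------------------------------------------------------------


def test_fraction_arithmetic():
    labels = ["A", "A", "B", "C"]
    animals = ["m1"] * 4
    table = fractional_populations(labels, animals)
    assert table.loc["m1", "A"] == pytest.approx(0.5)
    assert table.loc["m1"].sum() == pytest.approx(1.0)


def test_single_group_all_ones():
    table = fractional_populations(["A"] * 6, ["m1"] * 3 + ["m2"] * 3)
    assert (table["A"] == 1.0).all()


def test_rows_sum_to_one_with_arm_column(clustered_cohort):
    bundle, kept = clustered_cohort
    table = fractional_populations(
        bundle.clusters.labels,
        bundle.norm.barcodes["animal"].to_numpy(),
        bundle.norm.barcodes["arm"].to_numpy(),
    )
    sums = table.drop(columns="arm").sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_cohort_arm_fractions_reflect_depletion(clustered_cohort):
    """The treated arm's tumor fraction is depleted roughly by the
    programmed multiplier."""
    bundle, kept = clustered_cohort
    tumor = kept["population"].eq("cgnp_tumor").to_numpy()
    table = fractional_populations(
        np.where(tumor, "tumor", "other"),
        bundle.norm.barcodes["animal"].to_numpy(),
        bundle.norm.barcodes["arm"].to_numpy(),
    )
    v = table.loc[table["arm"] == "vehicle", "tumor"]
    t = table.loc[table["arm"] == "treated", "tumor"]
    # programmed: 150/300 vehicle vs 0.45 multiplier (renormalized) treated
    assert v.mean() > t.mean()
    sem = np.sqrt(v.sem() ** 2 + t.sem() ** 2)
    programmed_v, programmed_t = 0.5, 0.45 * 150 / (150 + 0.45 * 150 - 0 + 150 * 0)
    # renormalized treated fraction: 0.45*150 / (150 + 0.45*150) = 0.3103
    assert abs(t.mean() - 0.45 * 150 / (150 + 67.5)) < 4 * sem + 0.05


# ---------------------------------------------------------------------------
# arm comparisons
# ---------------------------------------------------------------------------


def arm_table(vals_a, vals_b):
    return pd.DataFrame(
        {
            "arm": ["vehicle"] * len(vals_a) + ["treated"] * len(vals_b),
            "g": list(vals_a) + list(vals_b),
        },
        index=[f"m{i}" for i in range(len(vals_a) + len(vals_b))],
    )


def test_identical_arms_f_zero_p_one():
    res = compare_arms(arm_table([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]), "g")
    assert res.statistic == 0.0 and res.p == 1.0


def test_separated_arms_significant():
    rng = np.random.default_rng(0)
    a = 0.1 + rng.normal(0, 1e-3, 3)
    b = 0.5 + rng.normal(0, 1e-3, 3)
    res = compare_arms(arm_table(a, b), "g")
    assert res.p < 0.01


def test_anova_matches_hand_computed_mean_squares():
    a, b = np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.6, 0.5])
    res = compare_arms(arm_table(a, b), "g")
    grand = np.concatenate([a, b]).mean()
    ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f_hand = (ss_between / 1) / (ss_within / 4)
    assert res.statistic == pytest.approx(f_hand, abs=1e-10)


def test_t_squared_equals_f_for_two_arms():
    a, b = [0.12, 0.18, 0.25], [0.3, 0.42, 0.38]
    f = compare_arms(arm_table(a, b), "g", "one_way_anova")
    t = compare_arms(arm_table(a, b), "g", "two_sample_t")
    assert t.statistic**2 == pytest.approx(f.statistic, rel=1e-10)
    assert t.p == pytest.approx(f.p, rel=1e-10)


def test_too_few_animals_rejected():
    with pytest.raises(ValueError, match="2 animals"):
        compare_arms(arm_table([0.1], [0.2, 0.3]), "g")


# ---------------------------------------------------------------------------
# marker fractions
# ---------------------------------------------------------------------------


def make_norm_for_marker():
    from nodescope.matrix import NormalizedMatrix

    vals = np.array([[2.0, 2.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
    genes = pd.DataFrame(
        {"species": "mouse", "mito": False, "transgene": [True, False]},
        index=pd.Index(["Yfp", "Gfap"], name="gene"),
    )
    barcodes = pd.DataFrame(
        {"animal": ["m1", "m1", "m1", "m2"], "arm": "vehicle"},
        index=pd.Index([f"bc{i}" for i in range(4)], name="barcode"),
    )
    return NormalizedMatrix(vals, genes, barcodes)


def test_marker_fraction_thresholds():
    norm = make_norm_for_marker()
    labels = np.array(["A", "A", "B", "B"])
    animals = norm.barcodes["animal"].to_numpy()
    t = marker_positive_fraction(norm, labels, animals, "Gfap", 0.0)
    assert (t["fraction"] == 1.0).all()  # every cell above threshold 0
    t2 = marker_positive_fraction(norm, labels, animals, "Gfap", 99.0)
    assert (t2["fraction"] == 0.0).all()
    t3 = marker_positive_fraction(norm, labels, animals, "Yfp", 0.5)
    m1A = t3[(t3["animal"] == "m1") & (t3["group"] == "A")]
    assert m1A["fraction"].iloc[0] == pytest.approx(1.0)
    # group A absent in animal m2 -> no row, not a zero
    assert t3[(t3["animal"] == "m2") & (t3["group"] == "A")].empty


def test_cohort_lineage_fraction_recovers_programmed_rate(clustered_cohort):
    bundle, kept = clustered_cohort
    singlet = ~kept["is_doublet"].to_numpy()
    labels = kept["population"].to_numpy()
    frac = kept.loc[singlet & (labels == "cgnp_tumor"), "lineage"].mean()
    n = (singlet & (labels == "cgnp_tumor")).sum()
    sd = np.sqrt(0.8 * 0.2 / n)
    assert abs(frac - 0.8) < 2 * sd + 0.01


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


def rate_table(group_effects, n_animals=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in group_effects.items():
        for a in range(n_animals):
            rows.append(
                {"group": g, "animal": f"m{a}", "fraction": mu + rng.normal(0, noise)}
            )
    return pd.DataFrame(rows)


def test_two_way_all_equal_f_zero():
    table = rate_table({"glial": 0.3, "vascular": 0.3})
    res = two_way_anova_rates(table)
    assert res["effects"]["C(group)"]["F"] == pytest.approx(0.0, abs=1e-20)


def test_two_way_programmed_group_effect():
    table = rate_table({"astro": 0.31, "oligo": 0.29, "endo": 0.0, "fibro": 0.005},
                       noise=0.02, seed=1)
    res = two_way_anova_rates(table)
    assert res["effects"]["C(group)"]["p"] < 0.001
    for pair in ("astro vs endo", "astro vs fibro", "endo vs oligo", "fibro vs oligo"):
        assert res["contrasts"][pair]["p_bonferroni"] < 0.001


def test_two_way_factor_swap_symmetry():
    table = rate_table({"a": 0.2, "b": 0.4}, noise=0.03, seed=2)
    res1 = two_way_anova_rates(table, factor_a="group", factor_b="animal")
    res2 = two_way_anova_rates(table, factor_a="animal", factor_b="group")
    assert res1["effects"]["C(group)"]["p"] == pytest.approx(
        res2["effects"]["C(group)"]["p"], rel=1e-9
    )
    assert res1["effects"]["C(animal)"]["p"] == pytest.approx(
        res2["effects"]["C(animal)"]["p"], rel=1e-9
    )


def test_two_way_single_level_factor_rejected():
    table = rate_table({"only": 0.2})
    with pytest.raises(ValueError, match="single level"):
        two_way_anova_rates(table)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def enumerate_fisher_p(table):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def test_fisher_worked_diagonal_case():
    odds, p = fisher_exact_2x2(np.array([[5, 0], [0, 5]]))
    assert p == pytest.approx(2 / 252, rel=1e-9)


def test_fisher_balanced_table_p_one():
    _, p = fisher_exact_2x2(np.array([[3, 3], [3, 3]]))
    assert p == 1.0


def test_fisher_row_swap_invariance():
    t = np.array([[7, 2], [3, 8]])
    odds1, p1 = fisher_exact_2x2(t)
    odds2, p2 = fisher_exact_2x2(t[::-1].copy())
    assert p1 == pytest.approx(p2, rel=1e-12)
    assert odds1 == pytest.approx(1 / odds2, rel=1e-6)


def test_fisher_zero_margin_p_one():
    _, p = fisher_exact_2x2(np.array([[0, 0], [3, 5]]))
    assert p == 1.0


def test_fisher_matches_enumeration_small_margins():
    rng = np.random.default_rng(0)
    for _ in range(50):
        t = rng.integers(0, 9, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        _, p = fisher_exact_2x2(t)
        assert p == pytest.approx(enumerate_fisher_p(t), rel=1e-9), t


def test_hypergeom_identical_sets_closed_form():
    universe = [f"g{i}" for i in range(10)]
    a = universe[:5]
    k, p = hypergeom_overlap(a, a, universe)
    assert k == 5
    assert p == pytest.approx(1 / comb(10, 5), rel=1e-12)


def test_hypergeom_disjoint_and_full_universe():
    universe = [f"g{i}" for i in range(10)]
    k, p = hypergeom_overlap(universe[:5], universe[5:], universe)
    assert k == 0 and p == 1.0
    k, p = hypergeom_overlap(universe[:5], universe, universe)
    assert k == 5 and p == pytest.approx(1.0)


def test_hypergeom_monotone_in_overlap():
    universe = [f"g{i}" for i in range(40)]
    ps = []
    for overlap in range(0, 11):
        a = universe[:10]
        b = universe[10 - overlap : 20 - overlap]
        ps.append(hypergeom_overlap(a, b, universe)[1])
    assert all(ps[i + 1] <= ps[i] + 1e-15 for i in range(10))


def test_hypergeom_subset_violation():
    with pytest.raises(ValueError):
        hypergeom_overlap(["x"], ["g0"], ["g0", "g1"])


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def test_fold_change_basics():
    assert fold_change(0.2, 0.2) == pytest.approx(1.0)
    assert fold_change(8.73, 0.04) == pytest.approx(218.25)
    assert fold_change(8.73, 0.04) * fold_change(0.04, 8.73) == pytest.approx(1.0)


def test_fold_change_paired_variant():
    a = np.array([2.0, 4.0, 6.0])
    b = np.array([1.0, 1.0, 2.0])
    mean_ratio, sem = fold_change(a, b, paired=True)
    assert mean_ratio == pytest.approx(np.mean([2, 4, 3]))
    assert sem == pytest.approx(np.std([2, 4, 3], ddof=1) / np.sqrt(3))


def test_fold_change_zero_denominator():
    with pytest.raises(ValueError, match="denominator"):
        fold_change(0.5, 0.0)
    assert fold_change_bound(0.5, 200) == pytest.approx(100.0)
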