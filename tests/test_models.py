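"""Wilks statistics, Type-III SSCPs, pruning, site-level tests, EMMs."""

import numpy as np
import pandas as pd
import pytest

from sulfidiv import models
from sulfidiv.models import ModelSpec


# ---------------------------------------------------------------------------
# Trait transformations


def test_transform_values_and_standardization():
    df = pd.DataFrame(
        {
            "sl_mm": [10.0, 20.0, 30.0, 40.0],
            "fecundity": [0.0, 4.0, 9.0, 16.0],
            "fat_content": [0.0, 0.25, 0.5, 1.0],
        }
    )
    out, rec = models.transform_traits(df, zscore=False)
    assert out["sl_mm"].iloc[0] == pytest.approx(1.0)  # log10(10)
    assert out["fat_content"].iloc[0] == pytest.approx(0.0)
    assert out["fat_content"].iloc[3] == pytest.approx(np.pi / 2)
    assert out["fecundity"].tolist() == [0.0, 2.0, 3.0, 4.0]

    z, rec = models.transform_traits(df)
    for col in ["sl_mm", "fecundity", "fat_content"]:
        assert z[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    back = rec.invert(z)
    pd.testing.assert_frame_equal(back, df, check_dtype=False, atol=1e-10)


@pytest.mark.parametrize(
    "col,vals,match",
    [
        ("sl_mm", [0.0, 1.0], "log10"),
        ("fat_content", [-0.1, 0.5], "arcsine"),
        ("fat_content", [0.5, 1.5], "arcsine"),
    ],
)
def test_transform_domain_errors(col, vals, match):
    df = pd.DataFrame({col: vals})
    with pytest.raises(ValueError, match=match):
        models.transform_traits(df)


# ---------------------------------------------------------------------------
# Wilks statistics


def test_wilks_toy_sscp_determinant_oracle():
    """Lambda, Rao F and partial eta^2 on a hand-computable SSCP pair."""
    H = np.array([[2.0, 0.0], [0.0, 0.0]])
    E = np.array([[2.0, 0.0], [0.0, 2.0]])
    res = models.wilks_stats(H, E, dfh=1, dfe=4)
    assert res.wilks_lambda == pytest.approx(0.5)  # det(E)/det(H+E) = 4/8
    assert res.F == pytest.approx(1.5)
    assert (res.df1, res.df2) == (2.0, 3.0)
    assert res.partial_eta_sq == pytest.approx(0.5)


def test_wilks_null_effect():
    E = np.eye(3) * 2.0
    res = models.wilks_stats(np.zeros((3, 3)), E, dfh=2, dfe=10)
    assert res.wilks_lambda == pytest.approx(1.0)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-12)


def test_wilks_univariate_reduces_to_anova_f():
    H = np.array([[6.0]])
    E = np.array([[8.0]])
    dfh, dfe = 2, 12
    res = models.wilks_stats(H, E, dfh, dfe)
    expected = (6.0 / dfh) / (8.0 / dfe)
    assert res.F == pytest.approx(expected, rel=1e-12)
    assert (res.df1, res.df2) == (2.0, 12.0)


def test_wilks_singular_E_errors():
    E = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(np.linalg.LinAlgError, match="responses"):
        models.wilks_stats(np.eye(2), E, 1, 4)


# ---------------------------------------------------------------------------
# fit_mglm


def test_residual_sscp_matches_hand_least_squares():
    """4 observations, 2 responses, one centred covariate."""
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0],
                       "y1": [1.0, 2.0, 2.0, 4.0],
                       "y2": [0.0, 1.0, 3.0, 3.0]})
    fit = models.fit_mglm(df, ModelSpec(dependents=["y1", "y2"], covariates=["x"]))
    X = np.column_stack([np.ones(4), df["x"] - df["x"].mean()])
    Y = df[["y1", "y2"]].to_numpy()
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    R = Y - X @ B
    np.testing.assert_allclose(fit.E, R.T @ R, atol=1e-10)
    assert fit.dfe == 2


def test_balanced_design_type3_equals_sequential():
    """In a balanced orthogonal 2x2 design the SSCPs are order-free."""
    rng = np.random.default_rng(5)
    a = np.repeat([0, 0, 1, 1], 8)
    b = np.tile(np.repeat([0, 1], 4), 4)
    Y = rng.normal(size=(32, 2)) + np.column_stack([a, b])
    df = pd.DataFrame({"A": a.astype(str), "B": b.astype(str),
                       "y1": Y[:, 0], "y2": Y[:, 1]})
    spec = ModelSpec(dependents=["y1", "y2"], fixed_factors=["A", "B"],
                     interactions=[("A", "B")])
    fit = models.fit_mglm(df, spec)
    # sequential: fit A alone, then A+B, compare SSCP increments
    E0 = models.fit_mglm(df, ModelSpec(["y1", "y2"], fixed_factors=["A"])).E
    EA = models.fit_mglm(df, ModelSpec(["y1", "y2"], fixed_factors=["A", "B"])).E
    H_B_seq = E0 - EA
    H_B_t3, _ = fit.hypothesis_sscp("B")
    np.testing.assert_allclose(H_B_t3, H_B_seq, atol=1e-8)
    for term in ["A", "B", "A:B"]:
        H, _ = fit.hypothesis_sscp(term)
        np.testing.assert_allclose(H, H.T, atol=1e-10)
        assert np.linalg.eigvalsh(H).min() > -1e-8
    np.testing.assert_allclose(fit.E, fit.E.T, atol=1e-10)


def test_rank_deficiency_names_aliased_columns():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                       "z": [2.0, 4.0, 6.0, 8.0],
                       "y": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="aliased"):
        models.fit_mglm(df, ModelSpec(["y"], covariates=["x", "z"]))


def test_statsmodels_manova_cross_check(two_group_frame):
    """Wilks lambda agrees with the independent statsmodels implementation."""
    sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
    df = two_group_frame
    fit = models.fit_mglm(
        df, ModelSpec(["y1", "y2", "y3"], fixed_factors=["sulfidic"])
    )
    res = fit.term_test("sulfidic")
    mv = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ C(sulfidic)", data=df)
    tab = mv.mv_test().results["C(sulfidic)"]["stat"]
    assert res.wilks_lambda == pytest.approx(
        float(tab.loc["Wilks' lambda", "Value"]), rel=1e-8
    )
    assert res.F == pytest.approx(
        float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-6
    )


# ---------------------------------------------------------------------------
# Pruning


def _prune_frame(rng, strong_three_way=False):
    n = 160
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    c = rng.integers(0, 2, n)
    y = rng.normal(0, 1, n) + a + b + c
    if strong_three_way:
        # pure three-way contrast: orthogonal to mains and two-ways
        y = y + 1.5 * (2 * a - 1) * (2 * b - 1) * (2 * c - 1)
    return pd.DataFrame({"A": a.astype(str), "B": b.astype(str),
                         "C": c.astype(str), "y1": y,
                         "y2": rng.normal(0, 1, n)})


def test_prune_keeps_all_significant_terms(rng):
    n = 120
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = rng.normal(0, 0.3, n) + a + b + 1.5 * a * b
    df = pd.DataFrame({"A": a.astype(str), "B": b.astype(str), "y": y})
    spec = ModelSpec(["y"], fixed_factors=["A", "B"], interactions=[("A", "B")])
    fit0 = models.fit_mglm(df, spec)
    assert fit0.term_test("A:B").p < 0.1  # precondition
    pruned, _ = models.prune_model(df, spec)
    assert pruned.interactions == [("A", "B")]


def test_prune_removes_highest_order_first(rng):
    df = _prune_frame(rng)
    spec = ModelSpec(["y1", "y2"], fixed_factors=["A", "B", "C"],
                     interactions=models.all_interactions(["A", "B", "C"]))
    fit0 = models.fit_mglm(df, spec)
    assert fit0.term_test("A:B:C").p > 0.1  # precondition: null 3-way
    pruned, fit = models.prune_model(df, spec)
    assert ("A", "B", "C") not in pruned.interactions
    # main effects and the nested structure are never dropped
    assert pruned.fixed_factors == ["A", "B", "C"]


def test_prune_hierarchy_exception_protects_contained_term(rng):
    """A null 2-way survives when a significant 3-way contains it."""
    for attempt in range(10):
        df = _prune_frame(rng, strong_three_way=True)
        spec = ModelSpec(["y1"], fixed_factors=["A", "B", "C"],
                         interactions=models.all_interactions(["A", "B", "C"]))
        fit0 = models.fit_mglm(df, spec)
        if fit0.term_test("A:B:C").p < 0.1 and fit0.term_test("A:B").p > 0.1:
            pruned, _ = models.prune_model(df, spec)
            assert ("A", "B", "C") in pruned.interactions
            assert ("A", "B") in pruned.interactions
            return
    pytest.fail("could not construct the protected configuration in 10 draws")


# ---------------------------------------------------------------------------
# Site-level nested test


def _site_frame(habitat_shift=0.0, seed=9, sites_per_cell=3, n=6):
    rng = np.random.default_rng(seed)
    rows = []
    for clade in ["c1", "c2"]:
        for sulf in [True, False]:
            for s in range(sites_per_cell):
                site = f"{clade}_{'S' if sulf else 'N'}{s}"
                site_eff = rng.normal(0, 0.5)
                for i in range(n):
                    rows.append(
                        {
                            "clade": clade,
                            "sulfidic": sulf,
                            "site_id": site,
                            "y1": rng.normal(0, 1)
                            + site_eff
                            + habitat_shift * sulf,
                            "y2": rng.normal(0, 1),
                        }
                    )
    return pd.DataFrame(rows)


def test_site_level_univariate_matches_nested_anova_closed_form():
    df = _site_frame(habitat_shift=1.0)
    spec = ModelSpec(["y1"], fixed_factors=["clade", "sulfidic"],
                     nested_random=("site_id", ("clade", "sulfidic")),
                     interactions=[("clade", "sulfidic")])
    fit = models.fit_mglm(df, spec)
    res = models.site_level_test(fit, "sulfidic")
    # classical nested ANOVA on site means: MS_term / MS_site(cell)
    sm = df.groupby(["clade", "sulfidic", "site_id"])["y1"].mean().reset_index()
    cell_means = sm.groupby(["clade", "sulfidic"])["y1"].transform("mean")
    ss_site = ((sm["y1"] - cell_means) ** 2).sum()
    df_site = len(sm) - 4
    hab_means = sm.groupby("sulfidic")["y1"].mean()
    # balanced design: SS for habitat on site means
    ss_h = len(sm) / 2 * ((hab_means - sm["y1"].mean()) ** 2).sum() * 2 / 2
    n_per = sm.groupby("sulfidic").size()
    grand = sm["y1"].mean()
    ss_h = float((n_per * (hab_means - grand) ** 2).sum())
    F_expected = (ss_h / 1) / (ss_site / df_site)
    assert res.F == pytest.approx(F_expected, rel=1e-10)
    assert res.df2 == df_site


def test_site_level_null_and_df_bookkeeping():
    df = _site_frame(habitat_shift=0.0, seed=3)
    spec = ModelSpec(["y1", "y2"], fixed_factors=["clade", "sulfidic"],
                     nested_random=("site_id", ("clade", "sulfidic")),
                     interactions=[("clade", "sulfidic")])
    fit = models.fit_mglm(df, spec)
    res = models.site_level_test(fit, "sulfidic")
    assert res.p > 0.05
    # denominator df = sites - cells (univariate case shown exactly above);
    # for p = 2 responses Rao's df2 reflects the multivariate correction
    n_sites, n_cells = 12, 4
    assert res.df2 == pytest.approx(n_sites - n_cells - 1)


def test_site_level_single_site_cell_warns():
    df = _site_frame(sites_per_cell=1)
    extra = _site_frame(sites_per_cell=2, seed=11)
    extra = extra[extra["clade"] == "c1"]
    both = pd.concat([df[df["clade"] == "c2"], extra], ignore_index=True)
    spec = ModelSpec(["y1"], fixed_factors=["clade", "sulfidic"],
                     nested_random=("site_id", ("clade", "sulfidic")),
                     interactions=[("clade", "sulfidic")])
    fit = models.fit_mglm(both, spec)
    with pytest.warns(UserWarning, match="single site"):
        models.site_level_test(fit, "sulfidic")


# ---------------------------------------------------------------------------
# Estimated marginal means


def test_emm_balanced_oneway_equals_group_means(rng):
    g = np.repeat(["a", "b", "c"], 10)
    y = rng.normal(0, 1, 30) + np.repeat([0.0, 1.0, 2.0], 10)
    df = pd.DataFrame({"g": g, "y": y})
    fit = models.fit_mglm(df, ModelSpec(["y"], fixed_factors=["g"]))
    emm = models.estimated_marginal_means(fit, "g")
    for lvl, grp in df.groupby("g"):
        got = emm.loc[emm["level"] == lvl, "emm"].iloc[0]
        assert got == pytest.approx(grp["y"].mean(), abs=1e-10)


def test_emm_ancova_closed_form():
    """Two groups with a covariate: EMMs at the covariate mean by hand."""
    df = pd.DataFrame(
        {
            "g": ["A", "A", "B", "B"],
            "x": [0.0, 2.0, 1.0, 3.0],
            "y": [0.0, 2.0, 3.0, 5.0],
        }
    )
    fit = models.fit_mglm(df, ModelSpec(["y"], fixed_factors=["g"],
                                        covariates=["x"]))
    emm = models.estimated_marginal_means(fit, "g")
    vals = dict(zip(emm["level"], emm["emm"]))
    assert vals["A"] == pytest.approx(1.5, abs=1e-10)
    assert vals["B"] == pytest.approx(3.5, abs=1e-10)


def test_emm_differences_invariant_to_covariate_shift(rng):
    n = 40
    g = np.repeat(["A", "B"], n // 2)
    x = rng.normal(0, 1, n)
    y = rng.normal(0, 1, n) + (g == "B") + 0.5 * x
    df = pd.DataFrame({"g": g, "x": x, "y": y})
    df2 = df.assign(x=df["x"] + 100.0)
    spec = ModelSpec(["y"], fixed_factors=["g"], covariates=["x"])
    e1 = models.estimated_marginal_means(models.fit_mglm(df, spec), "g")
    e2 = models.estimated_marginal_means(models.fit_mglm(df2, spec), "g")
    d1 = np.diff(e1["emm"].to_numpy())
    d2 = np.diff(e2["emm"].to_numpy())
    np.testing.assert_allclose(d1, d2, atol=1e-8)


def test_emm_extrapolation_warns(rng):
    df = pd.DataFrame({"g": ["A", "A", "B", "B"], "x": [0.0, 1.0, 0.5, 1.5],
                       "y": [0.0, 1.0, 1.0, 2.0]})
    fit = models.fit_mglm(df, ModelSpec(["y"], fixed_factors=["g"],
                                        covariates=["x"]))
    with pytest.warns(UserWarning, match="outside"):
        models.estimated_marginal_means(fit, "g", at={"x": 10.0})


# ---------------------------------------------------------------------------
# Post-hoc ANCOVA on scores


def test_ancova_homogeneous_slopes_give_small_interaction_f(rng):
    n = 60
    site = np.repeat(["s1", "s2", "s3"], n // 3)
    x = rng.normal(0, 1, n)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
    tab = models.ancova_slopes(y, x, site)
    inter = tab.loc[tab["term"] == "site:shape"]
    assert inter["p"].iloc[0] > 0.05


def test_ancova_interaction_matches_extra_sum_of_squares_oracle(rng):
    n = 30
    site = np.repeat(["s1", "s2"], n)
    x = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
    y = np.concatenate(
        [rng.normal(0, 0.4, n), x[n:] + rng.normal(0, 0.4, n)]
    )  # slopes 0 and 1
    tab = models.ancova_slopes(y, x, site)
    inter = tab.loc[tab["term"] == "site:shape"].iloc[0]

    # oracle: explicit SSE of the separate-slopes vs common-slope fits
    def sse(X, yv):
        b, *_ = np.linalg.lstsq(X, yv, rcond=None)
        r = yv - X @ b
        return float(r @ r)

    g = (site == "s2").astype(float)
    X_full = np.column_stack([np.ones(2 * n), g, x, g * x])
    X_red = np.column_stack([np.ones(2 * n), g, x])
    sse_full = sse(X_full, y)
    sse_red = sse(X_red, y)
    F_oracle = (sse_red - sse_full) / 1 / (sse_full / (2 * n - 4))
    assert inter["F"] == pytest.approx(F_oracle, abs=1e-8)


def test_ancova_invariant_to_covariate_zscaling(rng):
    n = 45
    site = np.repeat(["s1", "s2", "s3"], n // 3)
    x = rng.normal(0, 2, n)
    y = rng.normal(0, 1, n) + x * (site == "s2")
    t1 = models.ancova_slopes(y, x, site)
    t2 = models.ancova_slopes(y, (x - x.mean()) / x.std(), site)
    np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-8)


def test_ancova_excludes_tiny_sites(rng):
    site = np.array(["s1"] * 10 + ["s2"] * 10 + ["s3"] * 2)
    x = rng.normal(0, 1, 22)
    y = rng.normal(0, 1, 22)
    with pytest.warns(UserWarning, match="s3"):
        tab = models.ancova_slopes(y, x, site)
    assert not tab.empty
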