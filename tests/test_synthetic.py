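"""Generator contracts: design shape, effects, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

from sulfidiv import models, morphometrics, popgen, synthetic
from sulfidiv.models import ModelSpec
from sulfidiv.synthetic import EffectConfig, StudyDesign


# ---------------------------------------------------------------------------
# Sites


def test_site_counts_small_design():
    design = StudyDesign(n_clades=2, systems_per_clade=2, nonsulfidic_per_system=1)
    sites = synthetic.generate_sites(design, seed=0)
    assert len(sites) == 8
    assert sites["sulfidic"].sum() == 4


def test_default_design_has_ten_systems():
    sites = synthetic.generate_sites(seed=0)
    assert sites["sulfidic"].sum() == 10
    assert sites["system_id"].nunique() == 10


def test_site_invariants_and_h2s_range():
    design = StudyDesign(h2s_range=(30.0, 60.0))
    sites = synthetic.generate_sites(design, seed=5)
    # exhaustive scan: sulfidic <=> h2s > 0, h2s within range
    for row in sites.itertuples():
        if row.sulfidic:
            assert 30.0 <= row.h2s_um <= 60.0
        else:
            assert row.h2s_um == 0.0
    per_system = sites.groupby("system_id")["sulfidic"].agg(["sum", "count"])
    assert (per_system["sum"] == 1).all()
    assert (per_system["count"] - per_system["sum"] >= 1).all()


def test_rejects_system_without_nonsulfidic_partner():
    with pytest.raises(ValueError, match="non-sulfidic"):
        synthetic.generate_sites(StudyDesign(nonsulfidic_per_system=0), seed=0)


# ---------------------------------------------------------------------------
# Traits


def test_traits_deterministic_given_seed(small_sites):
    a = synthetic.generate_traits(small_sites, n_per_site=8, seed=7)
    b = synthetic.generate_traits(small_sites, n_per_site=8, seed=7)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = synthetic.generate_traits(small_sites, n_per_site=8, seed=8)
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_default_effects_match_configured_trait_targets():
    """Sulfidic-minus-non-sulfidic targets: +1.52 mg embryo mass, fewer
    offspring (14.98 -> 9.09), realized at reference H2S."""
    eff = EffectConfig()
    assert eff.embryo_mass_effect == pytest.approx(3.04 - 1.52)
    assert eff.fecundity_effect == pytest.approx(9.09 - 14.98)
    design = StudyDesign(n_clades=2, systems_per_clade=2,
                         h2s_range=(100.0, 100.0))  # reference concentration
    sites = synthetic.generate_sites(design, seed=1)
    eff = EffectConfig(site_effect_sd=0.0)
    traits = synthetic.generate_traits(sites, eff, n_per_site=400, seed=1)
    fem = traits[traits.sex == "F"]
    emb = fem.groupby("sulfidic")["embryo_lean_weight_mg"].mean()
    fec = fem.groupby("sulfidic")["fecundity"].mean()
    assert emb[True] - emb[False] == pytest.approx(1.52, abs=0.12)
    assert fec[False] == pytest.approx(14.98, abs=0.8)
    assert fec[True] == pytest.approx(9.09, abs=0.8)


def test_null_configuration_equalizes_habitat_means(small_sites):
    traits = synthetic.generate_traits(
        small_sites, EffectConfig.null(), n_per_site=200, seed=2
    )
    fem = traits[traits.sex == "F"]
    for col in ["embryo_lean_weight_mg", "fecundity", "sl_mm"]:
        g = fem.groupby("sulfidic")[col]
        diff = abs(g.mean()[True] - g.mean()[False])
        se = np.sqrt((g.sem() ** 2).sum())
        assert diff < 3 * se


def test_allometry_correlation_matches_configuration(small_sites):
    eff = EffectConfig(site_effect_sd=0.0)
    # ~1000 females across sites
    traits = synthetic.generate_traits(small_sites, eff, n_per_site=250, seed=3)
    fem = traits[traits.sex == "F"]
    # within-site correlation (between-site structure held out)
    rs = []
    for _, grp in fem.groupby("site_id"):
        rs.append(np.corrcoef(grp["sl_mm"], grp["fecundity"])[0, 1])
    assert 0.60 <= np.mean(rs) <= 0.74


def test_tradeoff_latent_negative_correlation(small_sites):
    """Offspring size and number trade off through the latent allocation."""
    eff = EffectConfig(site_effect_sd=0.0)
    traits = synthetic.generate_traits(small_sites, eff, n_per_site=600, seed=3)
    fem = traits[traits.sex == "F"].copy()
    # pooled within-site correlation (site means removed)
    for col in ["fecundity", "embryo_lean_weight_mg"]:
        fem[col] -= fem.groupby("site_id")[col].transform("mean")
    r = np.corrcoef(fem["fecundity"], fem["embryo_lean_weight_mg"])[0, 1]
    assert r < -0.04  # configured tradeoff_r = -0.3 implies r ~= -0.09


def test_trait_generation_errors(small_sites):
    with pytest.raises(ValueError, match="n_per_site"):
        synthetic.generate_traits(small_sites, n_per_site=1, seed=0)
    with pytest.raises(ValueError, match="noise"):
        synthetic.generate_traits(
            small_sites, EffectConfig(fecundity_sd=-1.0), n_per_site=4, seed=0
        )


# ---------------------------------------------------------------------------
# Landmarks


def test_landmarks_shape_contract(small_sites):
    shapes = synthetic.generate_landmarks(small_sites, n_per_site=4, seed=0)
    assert shapes.coords.shape == (len(small_sites) * 4, 13, 2)
    assert len(shapes.metadata) == shapes.n_specimens


def test_zero_noise_zero_effect_configurations_identical(small_sites):
    eff = EffectConfig.null()
    eff.landmark_noise_sd = 0.0
    shapes = synthetic.generate_landmarks(small_sites, eff, n_per_site=3, seed=0)
    females = [
        i for i, sid in enumerate(shapes.specimen_ids)
        if shapes.metadata.iloc[i]["sex"] == "F"
    ]
    ref = shapes.coords[females[0]]
    for i in females[1:4]:
        assert morphometrics.procrustes_distance(ref, shapes.coords[i]) < 1e-10


def test_head_effect_recovered_downstream():
    """Injected head enlargement is recovered by the shape divergence axis."""
    design = StudyDesign(n_clades=2, systems_per_clade=2,
                         nonsulfidic_per_system=1,
                         h2s_range=(100.0, 100.0))  # known effect magnitude
    sites = synthetic.generate_sites(design, seed=4)
    eff = EffectConfig(head_shape_effect=0.05, site_effect_sd=0.0)
    shapes = synthetic.generate_landmarks(sites, eff, n_per_site=25, seed=4)
    aligned = morphometrics.gpa(shapes)
    rw = morphometrics.relative_warps(aligned, n_keep=7)
    df = rw.to_frame().join(aligned.metadata)
    spec = ModelSpec([f"rw{i+1}" for i in range(7)], fixed_factors=["sulfidic"])
    fit = models.fit_mglm(df.reset_index(), spec)
    vec = models.divergence_vector(fit, "sulfidic")
    sulf = fit.data["sulfidic"].astype(float).to_numpy()
    r = np.corrcoef(sulf, vec.scores)[0, 1]
    assert r > 0.9


def test_bad_mean_configuration_rejected(small_sites):
    with pytest.raises(ValueError, match="13 x 2"):
        synthetic.generate_landmarks(
            small_sites, n_per_site=3, seed=0,
            mean_configuration=np.zeros((12, 2)),
        )


# ---------------------------------------------------------------------------
# Genotypes


def test_balding_nichols_zero_F_returns_ancestral():
    rng = np.random.default_rng(0)
    p = np.array([0.2, 0.3, 0.5])
    np.testing.assert_array_equal(
        synthetic.balding_nichols_frequencies(p, 0.0, rng), p
    )


def test_balding_nichols_variance_scales_with_F():
    rng = np.random.default_rng(1)
    p = np.array([0.3, 0.7])
    draws = np.array(
        [synthetic.balding_nichols_frequencies(p, 0.2, rng)[0] for _ in range(4000)]
    )
    assert draws.mean() == pytest.approx(0.3, abs=0.01)
    assert draws.var() == pytest.approx(0.2 * 0.3 * 0.7, rel=0.1)


def test_genotype_domain_contract(small_sites):
    gt = synthetic.generate_genotypes(small_sites, n_per_site=6, n_loci=4, seed=0)
    labels = set(100 + 2 * np.arange(6))
    assert set(gt.calls.ravel().tolist()) <= labels
    assert gt.calls.shape == (len(small_sites) * 6, 4, 2)


def test_divergence_F_out_of_range_rejected(small_sites):
    with pytest.raises(ValueError, match="divergence_F"):
        synthetic.generate_genotypes(
            small_sites, EffectConfig(divergence_F=1.0), n_per_site=4, seed=0
        )


def test_theta_recovers_balding_nichols_F(small_sites):
    """theta-hat within [0.12, 0.28] in >= 90 % of seeds at F = 0.2."""
    eff = EffectConfig(divergence_F=0.2, scale_F_with_h2s=False)
    two_sites = small_sites.iloc[:2]
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        gt = synthetic.generate_genotypes(
            two_sites, eff, n_per_site=25, n_loci=10, seed=seed
        )
        theta, _ = popgen.pairwise_fst(gt, gt.sites[0], gt.sites[1])
        hits += 0.12 <= theta <= 0.28
    assert hits >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# Downstream monotonicity


def _mean_divergence(slope: float, seed: int) -> float:
    design = StudyDesign(n_clades=2, systems_per_clade=2, nonsulfidic_per_system=1)
    sites = synthetic.generate_sites(design, seed=seed)
    eff = EffectConfig(effect_vs_h2s_slope=slope, site_effect_sd=0.02)
    traits = synthetic.generate_traits(sites, eff, n_per_site=16, seed=seed)
    t, _ = models.transform_traits(traits)
    fem = t[t.sex == "F"]
    spec = ModelSpec(
        ["fecundity", "embryo_lean_weight_mg", "embryo_fat"],
        fixed_factors=["clade", "sulfidic"],
        covariates=["sl_mm"],
        nested_random=("site_id", ("clade", "sulfidic")),
    )
    fit = models.fit_mglm(fem, spec)
    vec = models.divergence_vector(fit, "sulfidic")
    sulf = fit.data["sulfidic"].to_numpy()
    return float(vec.scores[sulf].mean() - vec.scores[~sulf].mean())


def test_mean_divergence_monotone_in_h2s_slope():
    grid = [0.0, 0.5, 1.5]
    means = [
        np.mean([_mean_divergence(s, seed) for seed in range(20)]) for s in grid
    ]
    assert means[0] <= means[1] <= means[2]
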