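"""Generator behavior: determinism, conservation, neutrality, dose response,
closed-form expectations, and efficiency-from-matrix wiring."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import dropscreen as ds
from dropscreen.simdata import guide_21mers, pwm_scores


def test_invalid_config_names_offending_field():
    with pytest.raises(ds.ConfigError, match="frac_essential"):
        ds.SimConfig(frac_essential=1.5).validate()
    with pytest.raises(ds.ConfigError, match="guides_per_gene"):
        ds.SimConfig(guides_per_gene=0).validate()
    with pytest.raises(ds.ConfigError, match="pwm"):
        ds.SimConfig(pwm=np.zeros((20, 4))).validate()
    with pytest.raises(ds.ConfigError, match="cn_spec"):
        ds.SimConfig(cn_spec=ds.CnSpec(fractions={2: 0.5})).validate()


def test_library_size_arithmetic():
    cfg = ds.SimConfig(n_genes=100, guides_per_gene=6,
                       n_intergenic_controls=50, n_nontargeting_controls=50, seed=0)
    guides, truth = ds.simulate_library(cfg)
    assert len(guides) == 700
    assert (guides["control_class"] == "targeting").sum() == 600
    # control guides map to no gene and carry no effect
    ctl = guides[guides["control_class"] != "targeting"]
    assert ctl["gene_id"].isna().all()
    # every targeting guide's gene exists in the truth
    assert set(guides["gene_id"].dropna()) <= set(truth.beta.index)


def test_true_fitness_genes_are_expressed():
    cfg = ds.SimConfig(n_genes=400, frac_unexpressed=0.4, seed=2)
    _, truth = ds.simulate_library(cfg)
    ess = truth.beta < 0
    assert (truth.rpkm[ess] >= 1.0).all()
    neutral = truth.beta == 0
    frac = (truth.rpkm[neutral] < 1.0).mean()
    assert frac == pytest.approx(0.4, abs=0.01)


def test_zero_matrix_and_no_noise_gives_half_efficiency():
    cfg = ds.SimConfig(n_genes=30, efficiency_noise_sd=0.0, seed=3)
    _, truth = ds.simulate_library(cfg)
    assert np.allclose(truth.efficiency, 0.5)


def test_efficiency_recomputable_from_emitted_sequences():
    # +2 weight for G at position 1 raises efficiency of G-starting guides,
    # and the emitted efficiencies equal the logistic recomputed by hand
    pwm = np.zeros((21, 4))
    pwm[0, 2] = 2.0  # G at protospacer position 1
    cfg = ds.SimConfig(n_genes=200, pwm=pwm, efficiency_noise_sd=0.0, seed=4)
    guides, truth = ds.simulate_library(cfg)
    seq21 = guide_21mers(guides)
    recomputed = expit(pwm_scores(seq21.tolist(), pwm))
    assert np.allclose(truth.efficiency.to_numpy(), recomputed)
    has_g = seq21.str[0] == "G"
    assert truth.efficiency[has_g.to_numpy()].mean() > truth.efficiency[(~has_g).to_numpy()].mean()


def test_determinism_identical_seed_identical_outputs():
    cfg = ds.SimConfig(n_genes=80, seed=7)
    g1, t1 = ds.simulate_library(cfg)
    g2, t2 = ds.simulate_library(cfg)
    pd.testing.assert_frame_equal(g1, g2)
    pd.testing.assert_series_equal(t1.efficiency, t2.efficiency)
    s1 = ds.simulate_screen(g1, t1, cfg)
    s2 = ds.simulate_screen(g2, t2, cfg)
    pd.testing.assert_frame_equal(s1.counts, s2.counts)
    c1 = ds.simulate_companions(t1, cfg)
    c2 = ds.simulate_companions(t2, cfg)
    pd.testing.assert_frame_equal(c1.orthology, c2.orthology)
    pd.testing.assert_frame_equal(c1.ceres, c2.ceres)


def test_counts_sum_to_configured_depth(small_screen):
    cfg = small_screen["config"]
    counts = small_screen["table"].counts
    n_guides = len(small_screen["guides"])
    expected = int(round(cfg.read_depth_per_guide * n_guides))
    assert (counts.sum(axis=0) == expected).all()


def test_neutral_screen_lfc_centered_at_zero():
    # all beta = 0, no CN damage: per-seed mean log2FC scatters around 0
    # the SE is that of the per-guide log2FC distribution: log of noisy
    # counts carries a small O(CV^2) Jensen bias (~ -0.004 at default
    # depth) that is negligible at the distribution scale asserted here
    means, sds, n_guides = [], [], 0
    for seed in range(20):
        cfg = ds.SimConfig(n_genes=60, frac_essential=0.0, seed=seed,
                           cn_spec=ds.CnSpec(delta=0.0))
        guides, truth = ds.simulate_library(cfg)
        table = ds.simulate_screen(guides, truth, cfg)
        norm = ds.normalize(table.counts, "total")
        lfc = ds.log2_fold_change(norm, "t0", table.final_samples()[0])
        means.append(lfc.mean())
        sds.append(lfc.std())
        n_guides = len(lfc)
    grand = np.mean(means)
    se = np.mean(sds) / np.sqrt(n_guides)
    assert abs(grand) < 3 * se


def test_expected_mode_matches_closed_form_total_dropout():
    # one fully edited gene with beta = -1 does not grow: after 45
    # doublings its abundance ratio vs a neutral guide is exactly 2^-45
    cfg = ds.SimConfig(n_genes=2, frac_essential=0.5, beta_range=(-1.0, -1.0),
                       guides_per_gene=1, n_intergenic_controls=1,
                       n_nontargeting_controls=0, efficiency_noise_sd=0.0,
                       t0_abundance_cv=0.0, seed=3)
    guides, truth = ds.simulate_library(cfg)
    truth.efficiency[:] = 1.0
    table = ds.simulate_screen(guides, truth, cfg, mode="expected")
    ess = truth.essential_genes[0]
    g_ess = guides.loc[guides.gene_id == ess, "guide_id"].iloc[0]
    g_neu = guides.loc[(guides.gene_id != ess) &
                       (guides.control_class == "targeting"), "guide_id"].iloc[0]
    c, fin = table.counts, table.final_samples()[0]
    ratio = (c.loc[g_ess, fin] / c.loc[g_ess, "t0"]) / (c.loc[g_neu, fin] / c.loc[g_neu, "t0"])
    assert ratio == pytest.approx(2.0 ** -45, rel=1e-9)


def test_dose_response_monotone_in_effect_and_efficiency():
    # expected-value mode on a beta x efficiency grid: depletion deepens
    # with |beta| and with efficiency
    betas = [0.0, -0.2, -0.5, -1.0]
    effs = [0.2, 0.5, 0.9]
    cfg = ds.SimConfig(n_genes=len(betas) * len(effs), frac_essential=0.0,
                       guides_per_gene=2, n_intergenic_controls=5,
                       n_nontargeting_controls=0, t0_abundance_cv=0.0, seed=9)
    guides, truth = ds.simulate_library(cfg)
    genes = list(truth.beta.index)
    grid = {}
    for i, b in enumerate(betas):
        for j, e in enumerate(effs):
            g = genes[i * len(effs) + j]
            truth.beta[g] = b
            truth.efficiency[guides.loc[guides.gene_id == g, "guide_id"]] = e
            grid[(b, e)] = g
    table = ds.simulate_screen(guides, truth, cfg, mode="expected")
    norm = ds.normalize(table.counts, "total")
    lfc = ds.log2_fold_change(norm, "t0", table.final_samples()[0])
    gof = guides.set_index("guide_id")["gene_id"]
    gene_lfc = lfc.groupby(gof).mean()
    for e in effs:  # more negative beta => deeper depletion
        vals = [gene_lfc[grid[(b, e)]] for b in betas]
        assert all(x > y for x, y in zip(vals, vals[1:]))
    for b in betas[1:]:  # higher efficiency => deeper depletion
        vals = [gene_lfc[grid[(b, e)]] for e in effs]
        assert all(x > y for x, y in zip(vals, vals[1:]))


def test_extreme_copy_number_depletes_neutral_genes():
    # function-independent dropout: delta binds only at >= 8 copies
    cfg = ds.SimConfig(n_genes=60, frac_essential=0.0, seed=5,
                       cn_spec=ds.CnSpec(fractions={2: 0.8, 8: 0.2}, delta=0.05,
                                         damage_min_copies=8))
    guides, truth = ds.simulate_library(cfg)
    table = ds.simulate_screen(guides, truth, cfg, mode="expected")
    norm = ds.normalize(table.counts, "total")
    lfc = ds.log2_fold_change(norm, "t0", table.final_samples()[0])
    gof = guides.set_index("guide_id")["gene_id"]
    gene_lfc = lfc.groupby(gof).mean()
    amp = truth.copy_number[truth.copy_number >= 8].index
    normal = truth.copy_number[truth.copy_number < 8].index
    assert gene_lfc[amp].mean() < gene_lfc[normal].mean() - 1.0


def test_companions_unexpressed_fraction_zero_means_no_possible_errors(small_screen):
    cfg = ds.SimConfig(n_genes=100, frac_unexpressed=0.0, seed=6)
    guides, truth = ds.simulate_library(cfg)
    comp = ds.simulate_companions(truth, cfg)
    assert (comp.expression >= 1.0).all()
    scores = small_screen["scores"].head(50).copy()
    scores.index = comp.expression.index[:50]
    curve = ds.rankwise_fdr(scores, comp.expression)
    assert (curve.table["fdr"] == 0).all()


def test_buffered_family_members_get_weak_scores():
    cfg = ds.SimConfig(n_genes=400, seed=8)
    _, truth = ds.simulate_library(cfg)
    comp = ds.simulate_companions(truth, cfg)
    orth = comp.orthology
    ess = set(truth.essential_genes)
    buffered = orth[(orth["buffered"]) & (orth["fly_gene"].isin(ess))]
    singles = orth[(~orth["buffered"]) & (orth["confidence"] != "low") &
                   (orth["fly_gene"].isin(ess))]
    assert len(buffered) > 0 and len(singles) > 0
    assert comp.human_fitness[buffered["human_gene"]].mean() < 5.0
    assert comp.human_fitness[singles["human_gene"]].mean() > 5.0


def test_ceres_panel_width_matches_config():
    cfg = ds.SimConfig(n_genes=50, n_cell_lines=436, seed=1)
    _, truth = ds.simulate_library(cfg)
    comp = ds.simulate_companions(truth, cfg)
    assert comp.ceres.shape[1] == 436


def test_screen_rejects_unknown_condition_and_uncovered_guides():
    cfg = ds.SimConfig(n_genes=10, seed=0)
    guides, truth = ds.simulate_library(cfg)
    with pytest.raises(ValueError, match="condition"):
        ds.simulate_screen(guides, truth, cfg, conditions=("tra",))
    extra = guides.copy()
    extra.loc[len(extra)] = ["rogue", "A" * 20, "AGG", "g00001", "group1", "targeting"]
    with pytest.raises(ValueError, match="cover"):
        ds.simulate_screen(extra, truth, cfg)


def test_drug_arms_shift_context_genes():
    spec = ds.DrugSpec(name="tra", n_resistance=3, n_synergy=3,
                       resistance_shift=0.8, synergy_shift=-0.8)
    cfg = ds.SimConfig(n_genes=60, frac_essential=0.1, drug_spec=spec,
                       t0_abundance_cv=0.0, seed=10)
    guides, truth = ds.simulate_library(cfg)
    table = ds.simulate_screen(guides, truth, cfg, mode="expected",
                               conditions=("none", "tra"))
    norm = ds.normalize(table.counts, "total")
    t0 = table.t0_sample
    gof = guides.set_index("guide_id")["gene_id"]
    arm = {c: ds.log2_fold_change(norm, t0, table.final_samples(c)[0]).groupby(gof).mean()
           for c in ("none", "tra")}
    delta = arm["tra"] - arm["none"]
    shift = truth.drug_effects["tra"]
    res, syn = shift[shift > 0].index, shift[shift < 0].index
    neu = shift[shift == 0].index
    assert delta[res].min() > delta[neu].max()
    assert delta[syn].max() < delta[neu].min()


def test_premix_noise_widens_neutral_spread():
    base = dict(n_genes=80, frac_essential=0.0, seed=14)
    quiet = ds.SimConfig(**base)
    noisy = ds.SimConfig(**base, t0_premix_noise_sd=0.8)
    sds = {}
    for name, cfg in (("quiet", quiet), ("noisy", noisy)):
        guides, truth = ds.simulate_library(cfg)
        table = ds.simulate_screen(guides, truth, cfg)
        norm = ds.normalize(table.counts, "total")
        lfc = ds.log2_fold_change(norm, "t0", table.final_samples()[0])
        sds[name] = lfc.std()
    assert sds["noisy"] > sds["quiet"] * 1.5
    with pytest.raises(ds.ConfigError, match="premix"):
        ds.SimConfig(t0_premix_noise_sd=-1).validate()
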