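import numpy as np
import pytest

from trialmed import (LmmFit, MediationModelPair, draw_parameters, estimate_effects,
                      modality_difference_p, ci_nonoverlap, backtransform,
                      fit_mediation_models, generate_dataset, true_standardized_effects)

from conftest import preprocess


def _fake_fit(terms, beta, vcov=None):
    beta = np.asarray(beta, float)
    if vcov is None:
        vcov = np.zeros((len(beta), len(beta)))
    return LmmFit(term_names=tuple(terms), beta=beta, vcov_beta=np.asarray(vcov, float),
                  sigma2_resid=1.0, random_effect_variances={"intercept": 0.1},
                  loglik=0.0, converged=True, n_obs=100, n_subjects=10)


MED_TERMS = ("intercept", "X", "W", "X:W")
OUT_TERMS = ("intercept", "X", "W", "X:W", "M", "M:W")


def _zero_vcov_pair(a_t, a_p, b_t, b_p, cp_t, cp_p, direction="behavior_perception"):
    """Hand-set paths at touch (w=0) and pain (w=1)."""
    med = _fake_fit(MED_TERMS, [0.0, a_t, 0.0, a_p - a_t])
    out = _fake_fit(OUT_TERMS, [0.0, cp_t, 0.0, cp_p - cp_t, b_t, b_p - b_t])
    return MediationModelPair(direction=direction, mediator_fit=med, outcome_fit=out)


def test_zero_uncertainty_closed_form_product_of_coefficients():
    pair = _zero_vcov_pair(a_t=0.5, a_p=0.5, b_t=0.4, b_p=0.4, cp_t=0.3, cp_p=0.3)
    est = estimate_effects(pair, n_sims=50, seed=1)
    for lvl in ("pain", "touch"):
        assert est.points[("me", lvl)] == pytest.approx(0.20, abs=1e-10)
        assert est.points[("de", lvl)] == pytest.approx(0.30, abs=1e-10)
        assert est.points[("te", lvl)] == pytest.approx(0.50, abs=1e-10)
        assert est.points[("prop", lvl)] == pytest.approx(0.40, abs=1e-10)
        lo, hi = est.cis[("me", lvl)]
        assert lo == pytest.approx(hi) == pytest.approx(0.20, abs=1e-10)


def test_no_mediation_when_b_is_zero():
    pair = _zero_vcov_pair(a_t=0.5, a_p=0.5, b_t=0.0, b_p=0.0, cp_t=0.3, cp_p=0.3)
    est = estimate_effects(pair, n_sims=10, seed=0)
    assert est.points[("me", "pain")] == 0.0
    assert est.points[("prop", "pain")] == 0.0
    assert est.points[("de", "pain")] == est.points[("te", "pain")]


def test_per_draw_additivity_te_equals_me_plus_de(small_preprocessed):
    df = small_preprocessed.df
    sub = small_preprocessed
    pair = fit_mediation_models(
        type(sub)(df[df.group == "patient"].reset_index(drop=True), dict(sub.meta)),
        "behavior_perception")
    est = estimate_effects(pair, n_sims=200, seed=5)
    for lvl in ("pain", "touch"):
        np.testing.assert_allclose(
            est.draws[("te", lvl)],
            est.draws[("me", lvl)] + est.draws[("de", lvl)], rtol=0, atol=0)


def test_draws_deterministic_and_match_moments():
    beta = np.array([0.2, -0.1])
    V = np.array([[0.04, 0.01], [0.01, 0.09]])
    fit = _fake_fit(("intercept", "X"), beta, V)
    d1 = draw_parameters(fit, 1000, seed=42)
    d2 = draw_parameters(fit, 1000, seed=42)
    np.testing.assert_array_equal(d1, d2)
    big = draw_parameters(fit, 100_000, seed=7)
    np.testing.assert_allclose(big.mean(0), beta, atol=0.005)
    np.testing.assert_allclose(np.cov(big.T), V, rtol=0.05)
    # zero covariance: every draw equals beta
    d0 = draw_parameters(_fake_fit(("intercept", "X"), beta), 10, seed=0)
    assert np.all(d0 == beta)


def test_draws_reject_non_psd_vcov():
    V = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.raises(ValueError, match="positive semidefinite"):
        draw_parameters(_fake_fit(("a", "b"), [0.0, 0.0], V), 10, seed=0)


def test_modality_difference_p_degenerate_cases():
    pair = _zero_vcov_pair(a_t=0.5, a_p=0.5, b_t=0.4, b_p=0.4, cp_t=0.3, cp_p=0.3)
    est = estimate_effects(pair, n_sims=1000, seed=1)
    res = modality_difference_p(est, "me")  # identical draws -> all zeros
    assert res["p"] == 1.0
    # every pain draw above every touch draw -> floored p
    pair2 = _zero_vcov_pair(a_t=0.1, a_p=0.9, b_t=0.5, b_p=0.5, cp_t=0.1, cp_p=0.1)
    est2 = estimate_effects(pair2, n_sims=1000, seed=1)
    res2 = modality_difference_p(est2, "me")
    assert res2["p"] == pytest.approx(0.002)
    assert res2["p_str"] == "< 0.002"
    assert ci_nonoverlap(est2, "me")


def test_modality_p_null_distribution_roughly_uniform():
    """With pain and touch paths equal, the difference p over replicates
    should be approximately uniform."""
    from scipy import stats
    rng = np.random.default_rng(0)
    pvals = []
    for r in range(300):
        se = 0.05
        beta_med = [0.0, 0.3 + rng.normal(0, se), 0.0, rng.normal(0, se * np.sqrt(2))]
        beta_out = [0.0, 0.2 + rng.normal(0, se), 0.0, rng.normal(0, se * np.sqrt(2)),
                    0.4 + rng.normal(0, se), rng.normal(0, se * np.sqrt(2))]
        Vm = np.zeros((4, 4)); Vm[1, 1] = se**2; Vm[3, 3] = 2 * se**2
        Vo = np.zeros((6, 6)); Vo[1, 1] = se**2; Vo[3, 3] = 2 * se**2
        Vo[4, 4] = se**2; Vo[5, 5] = 2 * se**2
        pair = MediationModelPair(
            direction="behavior_perception",
            mediator_fit=_fake_fit(MED_TERMS, beta_med, Vm),
            outcome_fit=_fake_fit(OUT_TERMS, beta_out, Vo))
        est = estimate_effects(pair, n_sims=400, seed=int(rng.integers(2**31)))
        pvals.append(modality_difference_p(est, "me")["p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_backtransform_scales_by_stratum_sd_and_inverts():
    pair = _zero_vcov_pair(a_t=0.5, a_p=0.5, b_t=0.0, b_p=0.0, cp_t=-0.15, cp_p=-0.15,
                           direction="perception_behavior")
    est = estimate_effects(pair, n_sims=10, seed=0)
    meta = {"zscore_stats": {
        "rt_ms|patient|pain": (450.0, 100.0), "rt_ms|patient|touch": (430.0, 80.0)}}
    rep = backtransform(est, meta, "patient", "z_rt")
    assert rep.unit == "ms"
    assert rep.effects[("de", "pain")] == pytest.approx(-15.0)
    assert rep.effects[("de", "touch")] == pytest.approx(-12.0)
    assert rep.effects[("me", "pain")] == 0.0
    # algebraic inverse: dividing by the same SD restores the z-scale value
    assert rep.effects[("de", "pain")] / 100.0 == pytest.approx(
        est.points[("de", "pain")], abs=1e-12)
    with pytest.raises(ValueError, match="zscore_stats"):
        backtransform(est, {}, "patient", "z_rt")


def test_recovers_generator_truth_at_scale(strong_mediation_config):
    """Fitted standardized ME/DE approach the closed-form population values."""
    import dataclasses
    from conftest import standardize_only
    cfg = dataclasses.replace(strong_mediation_config, n_subjects_per_group=40,
                              seed=99)
    t = standardize_only(generate_dataset(cfg))
    sub = type(t)(t.df[t.df.group == "patient"].reset_index(drop=True), dict(t.meta))
    pair = fit_mediation_models(sub, "behavior_perception")
    est = estimate_effects(pair, n_sims=1000, seed=3)
    truth = true_standardized_effects(cfg, "patient", "pain", "behavior_perception")
    lo, hi = est.cis[("me", "pain")]
    assert lo < truth["me"] < hi
    lo, hi = est.cis[("prop", "pain")]
    assert lo < truth["prop"] < hi
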