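import numpy as np
import pandas as pd
import pytest

from trialmed import LmmSpec, fit_lmm, moderator_coding, generate_dataset
from trialmed.mixed_models import coding_values

from conftest import preprocess


def _toy_df(n_subj=2, n_per=6, seed=0, u_sd=0.0, e_sd=0.0, slope=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, u_sd)
        x = np.tile([-1.0, 0.0, 1.0], n_per // 3)
        y = slope * x + u + rng.normal(0, e_sd, n_per)
        rows.append(pd.DataFrame({
            "subject_id": f"S{s}", "modality": ["pain", "touch"] * (n_per // 2),
            "centered_intensity": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_noiseless_fixed_slope_recovered_exactly():
    df = _toy_df(n_subj=3, n_per=12)
    spec = LmmSpec(outcome="y", fixed_terms=("intercept", "X"))
    fit = fit_lmm(df, spec)
    assert fit.coef("X") == pytest.approx(0.3, abs=1e-10)
    assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-10)
    assert fit.sigma2_resid < 1e-12


def test_beta_equals_hand_built_gls_on_12_row_toy():
    """With the engine's own variance estimates, beta must equal the dense
    GLS solution (X'V^-1 X)^-1 X'V^-1 y computed by direct inversion."""
    df = _toy_df(n_subj=2, n_per=6, u_sd=0.5, e_sd=0.4, seed=3)
    spec = LmmSpec(outcome="y", fixed_terms=("intercept", "X"), random_slope=False)
    fit = fit_lmm(df, spec)
    X = np.column_stack([np.ones(12), df["centered_intensity"]])
    y = df["y"].to_numpy()
    tau2 = fit.random_effect_variances["intercept"]
    V = fit.sigma2_resid * np.eye(12)
    for s, sub in df.groupby("subject_id"):
        idx = np.ix_(sub.index, sub.index)
        V[idx] += tau2
    Vi = np.linalg.inv(V)
    beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    np.testing.assert_allclose(fit.beta, beta_gls, atol=1e-6)
    vcov_gls = np.linalg.inv(X.T @ Vi @ X)
    np.testing.assert_allclose(fit.vcov_beta, vcov_gls, atol=1e-6)


def test_matches_statsmodels_mixedlm():
    """Independent oracle: statsmodels MixedLM (REML) on a well-conditioned
    dataset with clearly nonzero variance components."""
    smf = pytest.importorskip("statsmodels.formula.api")
    from trialmed import GeneratorConfig
    cfg = GeneratorConfig(n_subjects_per_group=20, n_blocks=2,
                          sd_subject_intercept_m=0.4, sd_subject_slope_m=0.15,
                          sd_subject_intercept_y=0.4, sd_subject_slope_y=0.15,
                          order_trials=False, seed=31)
    t = preprocess(generate_dataset(cfg))
    df = t.df[t.df.group == "patient"].copy()
    spec = LmmSpec(outcome="z_rating",
                   fixed_terms=("intercept", "X", "W", "X:W", "M", "M:W"),
                   mediator="z_rt")
    fit = fit_lmm(df, spec)
    df["w"] = df["modality"].map(coding_values())
    sm_fit = smf.mixedlm("z_rating ~ centered_intensity*w + z_rt*w", df,
                         groups=df.subject_id,
                         re_formula="~centered_intensity").fit(reml=True)
    # statsmodels orders terms differently; compare by construction
    sm = {"intercept": "Intercept", "X": "centered_intensity", "W": "w",
          "X:W": "centered_intensity:w", "M": "z_rt", "M:W": "z_rt:w"}
    for term, sm_name in sm.items():
        assert fit.coef(term) == pytest.approx(sm_fit.fe_params[sm_name], abs=2e-3)
    my_se = np.sqrt(np.diag(fit.vcov_beta))
    sm_se = np.array([sm_fit.bse_fe[sm[t]] for t in spec.fixed_terms])
    np.testing.assert_allclose(my_se, sm_se, rtol=0.02)


def test_moderated_slope_recovery_at_large_n(strong_mediation_config):
    """W coded 0/1 with a(touch)=0.1, a(pain)=0.5: beta_X ~ 0.1, beta_X:W ~ 0.4."""
    import dataclasses
    from trialmed import PathSet
    paths = {(g, "pain"): PathSet(0.5, 0.0, 0.0) for g in ("patient", "control")}
    paths.update({(g, "touch"): PathSet(0.1, 0.0, 0.0) for g in ("patient", "control")})
    cfg = dataclasses.replace(
        strong_mediation_config, paths=paths, n_subjects_per_group=60,
        sd_subject_intercept_m=0.05, sd_subject_slope_m=0.02,
        sd_resid_m=0.5, seed=21)
    t = preprocess(generate_dataset(cfg))
    df = t.df[t.df.group == "patient"]
    # behavior_mediates: the mediator latent is RT (sign-flipped); a_z = -a/sd_M
    spec = LmmSpec(outcome="z_rt", fixed_terms=("intercept", "X", "W", "X:W"))
    fit = fit_lmm(df, spec)
    se_x = np.sqrt(fit.vcov_beta[1, 1])
    se_xw = np.sqrt(fit.vcov_beta[3, 3])
    from trialmed.synthetic import _latent_sds
    sd_touch = _latent_sds(cfg, "patient", "touch")[0]
    sd_pain = _latent_sds(cfg, "patient", "pain")[0]
    assert fit.coef("X") == pytest.approx(-0.1 / sd_touch, abs=2.5 * se_x)
    assert fit.coef("X") + fit.coef("X:W") == pytest.approx(
        -0.5 / sd_pain, abs=2.5 * np.sqrt(se_x**2 + se_xw**2))


def test_moderator_coding_values_and_contrast_invariance(small_preprocessed):
    assert moderator_coding("touch") == 0.0
    assert moderator_coding("pain") == 1.0
    assert moderator_coding("touch", "effect") == -0.5
    assert moderator_coding("pain", "effect") == 0.5
    df = small_preprocessed.df[small_preprocessed.df.group == "patient"]
    spec = LmmSpec(outcome="z_rating", fixed_terms=("intercept", "X", "W", "X:W"))
    a = {}
    for scheme in ("reference", "effect"):
        fit = fit_lmm(df, spec, coding=scheme)
        w = coding_values(scheme)
        a[scheme] = {m: fit.coef("X") + fit.coef("X:W") * w[m]
                     for m in ("pain", "touch")}
    for m in ("pain", "touch"):
        assert a["reference"][m] == pytest.approx(a["effect"][m], abs=1e-8)


def test_duplicating_data_keeps_beta_and_shrinks_vcov(small_preprocessed):
    df = small_preprocessed.df[small_preprocessed.df.group == "control"]
    spec = LmmSpec(outcome="z_rt", fixed_terms=("intercept", "X", "W", "X:W"))
    fit1 = fit_lmm(df, spec)
    fit2 = fit_lmm(pd.concat([df, df], ignore_index=True), spec)
    # beta is invariant up to the (slight) REML re-estimation of variances
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=2e-3)
    assert np.all(np.diag(fit2.vcov_beta) < np.diag(fit1.vcov_beta))


def test_spec_validation_errors():
    with pytest.raises(ValueError, match="intercept"):
        LmmSpec(outcome="y", fixed_terms=("X",))
    with pytest.raises(ValueError, match="mediator"):
        LmmSpec(outcome="y", fixed_terms=("intercept", "M"))
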