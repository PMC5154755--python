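"""Likelihood, model comparison machinery, and the auxiliary estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from confbound.ddm import mean_decision_time, p_choice_positive
from confbound.fitting import (
    FitParams,
    ModelSpec,
    bic_of,
    classify_majority_choice,
    combine_bic,
    empirical_rt_sd,
    fit_model,
    fit_quantile_bounds,
    logistic_interaction_fit,
    neg_log_likelihood,
    second_decision_table,
    zero_coherence_bound_estimate,
)


def _toy_table(sessions, cohs, choices, rts, confs):
    return pd.DataFrame({
        "session": sessions, "coh2": cohs, "choice2": choices,
        "rt2_s": rts, "conf": confs,
    })


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

def test_six_models_vary_bound_or_kappa_as_documented():
    assert ModelSpec(1).bound_by_session and not ModelSpec(1).kappa_by_session
    assert ModelSpec(2).kappa_by_session and not ModelSpec(2).bound_by_session
    assert ModelSpec(3).bound_by_session and ModelSpec(3).bound_conf_slope
    assert ModelSpec(4).kappa_by_session and ModelSpec(4).kappa_conf_slope
    assert ModelSpec(5).bound_by_session and ModelSpec(5).kappa_conf_slope
    assert ModelSpec(6).kappa_by_session and ModelSpec(6).bound_conf_slope
    # per-session parameter + shared parameter + optional slope + C0 + tnd
    assert ModelSpec(1).n_free(9) == 12
    assert ModelSpec(3).n_free(9) == 13
    with pytest.raises(ValueError):
        ModelSpec(7)


# ---------------------------------------------------------------------------
# majority classification and RT SDs
# ---------------------------------------------------------------------------

def test_majority_flags_coincide_with_correct_for_unbiased_choices(second_table):
    flags = classify_majority_choice(second_table)
    nonzero = second_table["coh2"] != 0
    objective = np.sign(second_table.loc[nonzero, "choice2"]) == np.sign(
        second_table.loc[nonzero, "coh2"]
    )
    assert (flags[nonzero.to_numpy()] == objective.to_numpy()).mean() > 0.999


def test_majority_flags_follow_the_shifted_subjective_equality_point():
    """With a C0 bias the PSE moves to -C0 and the flags move with it."""
    rng = np.random.default_rng(2)
    cohs = np.repeat([-0.512, -0.256, -0.128, -0.064, -0.032, 0.0,
                      0.032, 0.064, 0.128, 0.256, 0.512], 600)
    p = p_choice_positive(10.0 * (cohs + 0.05), 1.0)
    choices = np.where(rng.uniform(size=len(cohs)) < p, 1.0, -1.0)
    tab = _toy_table(0, cohs, choices, np.ones(len(cohs)), np.ones(len(cohs)))
    flags = classify_majority_choice(tab)
    # every coherence above the shifted PSE (-0.05) has majority "positive"
    above = cohs > -0.04
    np.testing.assert_array_equal(flags[above], choices[above] > 0)
    below = cohs < -0.06
    np.testing.assert_array_equal(flags[below], choices[below] < 0)


def test_single_coherence_is_rejected():
    tab = _toy_table(0, np.zeros(10), np.r_[np.ones(5), -np.ones(5)],
                     np.ones(10), np.ones(10))
    with pytest.raises(ValueError):
        classify_majority_choice(tab)


def test_rt_sd_hand_arithmetic_and_undersized_cell():
    tab = _toy_table([0] * 3 + [0], [0.1] * 3 + [0.2],
                     [1.0] * 4, [0.8, 1.0, 1.2, 0.9], [1.0] * 4)
    sds = empirical_rt_sd(tab, np.array([True, True, True, False]))
    assert sds[(0, 0.1)] == pytest.approx(0.2)
    with pytest.raises(ValueError, match="0.2"):
        empirical_rt_sd(tab, np.ones(4, dtype=bool))


def test_rt_sds_fall_with_coherence(second_table):
    flags = classify_majority_choice(second_table)
    sds = empirical_rt_sd(second_table, flags)
    lo = np.mean([v for (s, c), v in sds.items() if c == 0.0])
    hi = np.mean([v for (s, c), v in sds.items() if c == 0.512])
    assert hi < lo


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_single_trial_contribution_matches_closed_form():
    s = 0.17
    tab = _toy_table([0, 0], [0.0, 0.0], [1.0, -1.0], [1.35, 1.35], [1.0, 1.0])
    params = FitParams(kappa=10.0, B=1.0, beta_conf=0.0, C0=0.0, tnd_s=0.35)
    rt_sds = {(0, 0.0): s}
    # choice p=0.5 -> ln 2 each; RT at the predicted mean (B^2 + tnd = 1.35)
    # contributes only the Gaussian normalizer
    val = neg_log_likelihood(tab, ModelSpec(1), params, rt_sds,
                             flags=np.array([True, False]))
    expected = 2 * np.log(2) + 0.5 * np.log(2 * np.pi * s**2)
    assert val == pytest.approx(expected, rel=1e-12)


def test_model3_with_zero_slope_reduces_to_model1(second_table):
    flags = classify_majority_choice(second_table)
    rt_sds = empirical_rt_sd(second_table, flags)
    p1 = FitParams(kappa=9.0, B=np.full(9, 1.1), beta_conf=0.0, C0=0.01, tnd_s=0.34)
    a = neg_log_likelihood(second_table, ModelSpec(1), p1, rt_sds, flags)
    b = neg_log_likelihood(second_table, ModelSpec(3), p1, rt_sds, flags)
    assert a == pytest.approx(b, rel=1e-12)


def test_likelihood_matches_naive_trialwise_summation():
    """Independent oracle: loop over trials with scipy distributions."""
    rng = np.random.default_rng(8)
    n = 50
    sessions = rng.integers(0, 3, n)
    cohs = rng.choice([-0.256, -0.064, 0.0, 0.064, 0.256], n)
    choices = rng.choice([-1.0, 1.0], n)
    rts = rng.uniform(0.6, 1.8, n)
    confs = rng.uniform(0.5, 1.0, n)
    tab = _toy_table(sessions, cohs, choices, rts, confs)
    flags = rng.uniform(size=n) < 0.8
    rt_sds = {(s, c): 0.3 for s in range(3) for c in [0.0, 0.064, 0.256]}
    kappas = np.array([8.0, 10.0, 12.0])
    params = FitParams(kappa=kappas, B=1.2, beta_conf=0.4, C0=0.02, tnd_s=0.3)
    spec = ModelSpec(4)  # kappa by session + kappa slope

    conf_c = confs - confs.mean()
    expected = 0.0
    for i in range(n):
        kap = kappas[sessions[i]] + 0.4 * conf_c[i]
        mu = kap * (cohs[i] + 0.02)
        p_pos = 1.0 / (1.0 + np.exp(-2 * mu * 1.2))
        p = p_pos if choices[i] > 0 else 1 - p_pos
        expected -= np.log(p)
        if flags[i]:
            pred = mean_decision_time(mu, 1.2) + 0.3
            expected -= norm.logpdf(rts[i], pred, 0.3)
    got = neg_log_likelihood(tab, spec, params, rt_sds, flags)
    assert got == pytest.approx(expected, rel=1e-10)


def test_rt_terms_separate_from_choice_terms():
    rng = np.random.default_rng(9)
    n = 200
    cohs = rng.choice([-0.256, 0.0, 0.256], n)
    tab = _toy_table(0, cohs, rng.choice([-1.0, 1.0], n),
                     rng.uniform(0.5, 2.0, n), np.ones(n))
    params = FitParams(kappa=10.0, B=1.0, beta_conf=0.0, C0=0.0, tnd_s=0.3)
    base = {(0, c): 0.3 for c in [0.0, 0.256]}
    doubled = {k: 2 * v for k, v in base.items()}
    no_rt_a = neg_log_likelihood(tab, ModelSpec(1), params, base, include_rt=False)
    no_rt_b = neg_log_likelihood(tab, ModelSpec(1), params, doubled, include_rt=False)
    assert no_rt_a == pytest.approx(no_rt_b)  # choice part blind to RT SDs
    with_rt = neg_log_likelihood(tab, ModelSpec(1), params, base)
    assert with_rt != pytest.approx(no_rt_a)


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def test_bic_arithmetic_and_combination():
    assert bic_of(2000.0, 5, 1000) == pytest.approx(5 * np.log(1000) + 4000)

    class R:  # minimal stand-in with the summed fields
        def __init__(s, df, n, nll):
            s.df, s.n_trials, s.neg_log_likelihood = df, n, nll

    combined = combine_bic([R(5, 100, 300.0), R(5, 200, 500.0)])
    assert combined == pytest.approx(bic_of(800.0, 10, 300))


def test_bic_ranking_invariant_to_constant_likelihood_shift():
    nlls = np.array([100.0, 90.0, 120.0])
    dfs = np.array([5, 6, 5])
    b1 = [bic_of(nll, df, 500) for nll, df in zip(nlls, dfs)]
    b2 = [bic_of(nll - 30, df, 500) for nll, df in zip(nlls, dfs)]
    assert np.argsort(b1).tolist() == np.argsort(b2).tolist()


# ---------------------------------------------------------------------------
# quantile fit / zero-coherence estimator / logistic interaction
# ---------------------------------------------------------------------------

def test_one_quantile_reduces_to_the_plain_session_model(second_table):
    sub = second_table.iloc[:1500]
    flags = classify_majority_choice(sub)
    rt_sds = empirical_rt_sd(sub, flags)
    q1 = fit_quantile_bounds(sub, n_quantiles=1, flags=flags, rt_sds=rt_sds,
                             n_restarts=2, seed=0)
    assert len(q1) == 1 and q1["bound_offset"].iloc[0] == 0.0


def test_constant_confidence_cannot_define_quantiles():
    tab = _toy_table(0, [0.1] * 20, [1.0] * 20, [1.0] * 20, [0.8] * 20)
    with pytest.raises(ValueError):
        fit_quantile_bounds(tab, n_quantiles=7)


def test_zero_coherence_bound_closed_form():
    tab = _toy_table(0, [0.0] * 4, [1.0] * 4, [1.4] * 4, [0.9] * 4)
    out = zero_coherence_bound_estimate(tab, tnd_s=0.4, n_groups=1)
    assert out["bound_hat"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        zero_coherence_bound_estimate(tab, tnd_s=1.5, n_groups=1)


def _simulate_logistic(k1, k2, k3, n, rng):
    coh1 = rng.choice([0.0, 0.032, 0.064, 0.128, 0.256, 0.512], n)
    coh2 = rng.choice([-0.512, -0.256, -0.128, -0.064, -0.032, 0.0,
                       0.032, 0.064, 0.128, 0.256, 0.512], n)
    p = 1.0 / (1.0 + np.exp(-(k1 + k2 * coh2 + k3 * coh2 * coh1)))
    choice = np.where(rng.uniform(size=n) < p, 1.0, -1.0)
    return pd.DataFrame({
        "trial_type": "double", "coh1": coh1, "coh2": coh2, "choice2": choice,
    })


def test_interaction_test_controls_type_one_error():
    """k3 = 0 data: |z| < 2 in at least 90% of replicates."""
    rng = np.random.default_rng(11)
    hits = 0
    reps = 50
    for _ in range(reps):
        fit = logistic_interaction_fit(_simulate_logistic(0.1, 8.0, 0.0, 1200, rng))
        hits += abs(fit.z[2]) < 2.0
    assert hits >= int(0.9 * reps)


def test_interaction_test_detects_a_real_modulation():
    rng = np.random.default_rng(12)
    detected = 0
    reps = 20
    for _ in range(reps):
        fit = logistic_interaction_fit(_simulate_logistic(0.1, 8.0, 8.0, 4000, rng))
        detected += fit.z[2] > 2.0
    assert detected >= int(0.7 * reps)


def test_rescaling_coherence_rescales_the_slope_not_the_fit():
    rng = np.random.default_rng(13)
    tab = _simulate_logistic(0.1, 8.0, 5.0, 4000, rng)
    fit = logistic_interaction_fit(tab)
    scaled = tab.copy()
    scaled["coh2"] = scaled["coh2"] * 2.0
    fit2 = logistic_interaction_fit(scaled)
    assert fit2.k[1] == pytest.approx(fit.k[1] / 2.0, rel=1e-4)
    assert fit2.k[0] == pytest.approx(fit.k[0], abs=1e-4)


def test_second_decision_table_requires_conf_hat(dataset):
    with pytest.raises(ValueError):
        second_decision_table(dataset)  # no conf_hat column yet
    cov = second_decision_table(dataset, covariate="coherence")
    assert len(cov) == 4752
    assert cov["conf"].max() == pytest.approx(0.512)
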