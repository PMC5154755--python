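"""Trial schedule, delay distribution, agent confidence, and simulator."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from confbound.ddm import mean_decision_time, p_choice_positive
from confbound.task import (
    AgentParams,
    ConfigurationError,
    DesignSpec,
    TrialSpec,
    _truncexp_rate,
    agent_confidence,
    generate_block,
    generate_session,
    mirror_block,
    sample_delay,
    simulate_dataset,
    simulate_trial,
)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 17])
def test_block_composition_holds_for_every_seed(design, seed):
    block = generate_block(design, seed)
    assert len(block) == 154
    doubles = [t for t in block if t.trial_type == "double"]
    singles = [t for t in block if t.trial_type != "double"]
    assert len(doubles) == 121 and len(singles) == 33
    # full factorial coverage of ordered coherence pairs
    pairs = Counter((t.coh1, t.coh2) for t in doubles)
    assert len(pairs) == 121 and set(pairs.values()) == {1}
    for ttype, axis in [("D1star", "coh1"), ("D2star", "coh2"), ("D1catch", "coh1")]:
        cohs = sorted(getattr(t, axis) for t in block if t.trial_type == ttype)
        assert cohs == sorted(design.coherence_set)


def test_block_order_is_seed_determined(design):
    assert generate_block(design, 5) == generate_block(design, 5)
    assert generate_block(design, 5) != generate_block(design, 6)


def test_mirror_flips_signs_and_is_an_involution(design):
    block = generate_block(design, 3)
    mirrored = mirror_block(block)
    assert mirror_block(mirrored) == block
    for t, m in zip(block, mirrored):
        if t.trial_type != "D2star":
            assert m.coh1 == pytest.approx(-t.coh1)
            # zero-coherence trials keep coherence but flip the rewarded coin
            if t.coh1 == 0:
                assert m.coh1 == 0 and m.rewarded_dir1 == -t.rewarded_dir1


def test_session_has_four_blocks_with_repeated_stimuli(design):
    sess = generate_session(design, 11)
    assert len(sess) == 616
    blocks = {b: [t for t in sess if t.block == b] for b in range(4)}
    stim = lambda ts: Counter((t.trial_type, t.coh1, t.coh2) for t in ts)
    assert stim(blocks[2]) == stim(blocks[0])
    assert stim(blocks[3]) == stim(blocks[1])
    # block 2 is the mirror of block 1 at the stimulus level
    mirrored = Counter(
        (t, -c1 if not np.isnan(c1) else c1, -c2 if not np.isnan(c2) else c2)
        for (t, c1, c2) in stim(blocks[0])
    )
    assert stim(blocks[1]) == mirrored


def test_invalid_designs_are_rejected():
    with pytest.raises(ConfigurationError):
        DesignSpec(coherence_set=(0.0, 0.1, 0.2))  # not sign-symmetric
    with pytest.raises(ConfigurationError):
        DesignSpec(delay_mean_s=2.0)


# ---------------------------------------------------------------------------
# delays
# ---------------------------------------------------------------------------

def test_delay_samples_match_range_and_calibrated_mean(design):
    rng = np.random.default_rng(0)
    d = sample_delay(design, rng, size=1_000_000)
    assert d.min() >= design.delay_range_s[0]
    assert d.max() <= design.delay_range_s[1]
    assert d.mean() == pytest.approx(design.delay_mean_s, abs=1e-3)


def test_truncated_exponential_rate_reproduces_mean(design):
    lam = _truncexp_rate(design)
    lo, hi = design.delay_range_s
    c = hi - lo
    mean = lo + 1.0 / lam - c / np.expm1(lam * c)
    assert mean == pytest.approx(design.delay_mean_s, abs=1e-10)


# ---------------------------------------------------------------------------
# agent confidence
# ---------------------------------------------------------------------------

def test_confidence_degenerate_and_limit_priors():
    assert agent_confidence(1, 0.5, 0.0, {0.0: 1.0}, 10.0, 1.0) == 0.5
    # all mass on the strongest coherence with huge sensitivity: any
    # crossing is near-conclusive
    c = agent_confidence(1, 0.2, 0.0, {0.512: 0.5, -0.512: 0.5}, 60.0, 1.0)
    assert c > 0.999
    # symmetric prior, zero-coherence-only beliefs stay at 1/2
    assert agent_confidence(-1, 1.3, 0.0, {0.0: 1.0}, 10.0, 1.0) == 0.5
    with pytest.raises(ValueError):
        agent_confidence(1, 0.0, 0.0, {0.0: 1.0}, 10.0, 1.0)


def _brute_force_confidence(choice, t_query, prior, kappa, B, dt=2e-3, nx=241):
    """Bayes over a discretized evidence-path likelihood (independent oracle).

    For each coherence, a Markov chain on an evidence grid tracks the
    probability of being absorbed at the chosen bound in the time bin
    containing ``t_query``; Bayes' rule over those absorption masses gives
    the posterior probability the choice was correct.
    """
    from scipy.stats import norm

    x = np.linspace(-B, B, nx)
    step_sd = np.sqrt(dt)
    k_query = int(round(t_query / dt))
    f = {}
    for C in prior:
        mu = kappa * C
        centers = x + mu * dt
        p_up = norm.sf((B - centers) / step_sd)
        p_down = norm.cdf((-B - centers) / step_sd)
        T = norm.pdf((x[None, :] - centers[:, None]) / step_sd)
        stay = np.maximum(1.0 - p_up - p_down, 0.0)
        T *= (stay / np.maximum(T.sum(axis=1), 1e-300))[:, None]
        m = np.zeros(nx)
        m[nx // 2] = 1.0
        absorbed = 0.0
        for _ in range(k_query):
            absorbed = float(m @ (p_up if choice > 0 else p_down))
            m = m @ T
        f[C] = absorbed
    w = np.array([prior[C] * f[C] for C in prior])
    w /= w.sum()
    cohs = np.array(list(prior))
    return float(w[np.sign(cohs) == np.sign(choice)].sum() + 0.5 * w[cohs == 0].sum())


def test_confidence_matches_discretized_bayes_oracle():
    prior = {-0.256: 0.5, 0.256: 0.5}
    kappa, B = 10.0, 1.0
    for t, choice in [(0.3, 1), (0.8, 1), (0.3, -1)]:
        closed = agent_confidence(choice, t, 0.0, prior, kappa, B)
        brute = _brute_force_confidence(choice, t, prior, kappa, B)
        assert closed == pytest.approx(brute, abs=0.02)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def test_trial_record_fields_follow_trial_type(agent, design):
    star2 = TrialSpec("D2star", np.nan, 0.128, np.nan, 1.0)
    rec = simulate_trial(star2, agent, 7, design)
    assert np.isfinite(rec["choice2"]) and np.isfinite(rec["rt2_s"])
    assert np.isfinite(rec["confidence"]) and np.isnan(rec["choice1"])
    assert np.isnan(rec["conf_true"])  # no first decision to be confident about

    catch = TrialSpec("D1catch", -0.064, np.nan, -1.0, np.nan)
    rec = simulate_trial(catch, agent, 8, design)
    assert np.isfinite(rec["choice1"]) and np.isfinite(rec["rt1_s"])
    assert np.isfinite(rec["confidence"]) and np.isnan(rec["choice2"])
    assert rec["rt1_s"] >= agent.tnd_s


def test_dataset_shape_and_reproducibility(design, agent, dataset):
    assert len(dataset) == 9 * 616 == 5544
    again = simulate_dataset(design, agent, 20160915)
    pd.testing.assert_frame_equal(dataset, again)
    assert (dataset.groupby("trial_type").size()["double"]) == 4356
    # every recorded RT exceeds the non-decision time
    assert dataset["rt1_s"].dropna().min() >= agent.tnd_s
    assert dataset["rt2_s"].dropna().min() >= agent.tnd_s
    # rating present exactly where the design solicits one
    assert dataset["confidence"].notna().all()


def test_simulated_first_decisions_match_analytic_psychometrics(agent):
    """Engine accuracy/RT agree with the closed forms per coherence."""
    from confbound.ddm import simulate_first_passage_batch

    for coh in (0.0, 0.128, 0.512):
        mu = agent.kappa * coh
        n = 100_000
        signs, times = simulate_first_passage_batch(
            mu, agent.B1, 1e-3, np.random.default_rng(coh.__hash__() % 2**31), n=n
        )
        p = p_choice_positive(mu, agent.B1)
        se = np.sqrt(p * (1 - p) / n)
        assert np.mean(signs > 0) == pytest.approx(p, abs=max(3 * se, 1e-4))
        se_t = times.std() / np.sqrt(n)
        assert times.mean() == pytest.approx(
            mean_decision_time(mu, agent.B1), abs=3 * se_t + 2e-3
        )


def test_confidence_higher_on_correct_first_decisions(dataset):
    first = dataset.dropna(subset=["coh1", "correct1", "conf_true"])
    for coh in (0.032, 0.064, 0.128):
        cell = first[np.abs(first["coh1"]) == coh]
        by_acc = cell.groupby("correct1")["conf_true"].mean()
        assert by_acc[1.0] > by_acc[0.0]


def test_rt2_increases_with_confidence_when_bound_tracks_it(dataset):
    dd = dataset[dataset["trial_type"] == "double"]
    q = pd.qcut(dd["conf_true"], 4, labels=False)
    means = dd.groupby(q)["rt2_s"].mean()
    assert np.all(np.diff(means.to_numpy()) > 0)


def test_zero_bound_slope_decouples_rt2_from_confidence(design):
    flat = AgentParams(b_conf=0.0, b0=1.2)
    df = simulate_dataset(replace(design, n_sessions=3), flat, 99)
    dd = df[df["trial_type"] == "double"]
    rho, _ = spearmanr(dd["conf_true"], dd["rt2_s"])
    assert abs(rho) < 3.5 / np.sqrt(len(dd))


def test_nonpositive_second_bound_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        AgentParams(b0=0.2, b_conf=-0.5)
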