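"""Trial schedule and generative agent for the two-stage motion-discrimination task.

The task interleaves four trial types in each block:

* ``double`` -- a left/right motion decision (D1st) followed by an up/down
  decision (D2nd) at the chosen target; all 121 ordered pairs of the 11
  signed coherences appear once per block.
* ``D1star`` -- a single first decision with a confidence rating.
* ``D2star`` -- the first decision is bypassed; only the second decision is
  made (with a confidence rating).
* ``D1catch`` -- looks like a double-decision trial but ends after the
  first decision and its confidence rating.

Each block holds the 121 double trials plus 11 trials of each single type
(154 trials).  A session is four blocks: the second mirrors the first
(signed coherences and rewarded directions flipped), the third and fourth
repeat the stimuli of the first two, and every block is independently
shuffled.

The simulated agent is a drift-diffusion process with drift
``kappa * (C + C0)``, flat bound ``B1`` (scaled per session) on the first
decision, and a second-decision bound that varies linearly with the agent's
confidence in the first decision: ``B2 = b0 + b_conf * conf``.  Confidence
is the Bayesian posterior probability that the chosen direction is correct
given the bound crossed, the decision time, and a short sample of
post-decision evidence, under the known uniform prior over the 11 signed
coherences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ddm import simulate_first_passage_batch

__all__ = [
    "COHERENCE_SET",
    "DesignSpec",
    "TrialSpec",
    "AgentParams",
    "generate_block",
    "mirror_block",
    "generate_session",
    "sample_delay",
    "agent_confidence",
    "simulate_trial",
    "simulate_dataset",
]

#: The 11 signed motion coherences used for every decision.
COHERENCE_SET: tuple[float, ...] = (
    -0.512, -0.256, -0.128, -0.064, -0.032, 0.0,
    0.032, 0.064, 0.128, 0.256, 0.512,
)

TRIAL_TYPES = ("double", "D1star", "D2star", "D1catch")
SINGLE_TYPES = ("D1star", "D2star", "D1catch")


class ConfigurationError(ValueError):
    """Raised for invalid design or agent configurations."""


@dataclass(frozen=True)
class DesignSpec:
    """Trial-schedule parameters of the experiment."""

    coherence_set: tuple[float, ...] = COHERENCE_SET
    n_sessions: int = 9
    blocks_per_session: int = 4
    delay_range_s: tuple[float, float] = (0.3, 1.0)
    delay_mean_s: float = 0.57
    n_singles_per_type: int = 11

    def __post_init__(self) -> None:
        cohs = sorted(self.coherence_set)
        if len(cohs) != len(set(cohs)):
            raise ConfigurationError("coherence_set contains duplicates")
        if sorted(-c for c in cohs) != cohs:
            raise ConfigurationError("coherence_set must be symmetric about zero")
        lo, hi = self.delay_range_s
        if not (lo < self.delay_mean_s < hi):
            raise ConfigurationError("delay mean must lie inside delay range")

    @property
    def n_coherences(self) -> int:
        return len(self.coherence_set)

    @property
    def trials_per_block(self) -> int:
        n = self.n_coherences
        return n * n + 3 * self.n_singles_per_type


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial before simulation.

    ``coh1``/``coh2`` are signed coherences (NaN when that decision axis is
    absent); rewarded directions are +-1 (for zero coherence an independent
    fair coin).
    """

    trial_type: str
    coh1: float
    coh2: float
    rewarded_dir1: float
    rewarded_dir2: float
    session: int = 0
    block: int = 0
    index: int = 0


@dataclass(frozen=True)
class AgentParams:
    """Generative drift-diffusion agent.

    The defaults describe a competent observer: sensitivity ``kappa = 10``
    gives ~65% accuracy at 3.2% coherence and near-ceiling accuracy at
    51.2%; the second-decision bound rises by roughly 25% over the range of
    confidence estimates the interpolation recovers (the k-NN estimates
    compress the latent confidence range, so the slope on the latent scale
    is steeper), and bounds drift by a few percent from session to session.
    """

    kappa: float = 10.0
    C0: float = 0.0
    tnd_s: float = 0.35
    B1: float = 1.0
    b0: float = 0.5
    b_conf: float = 0.85
    session_bound_scale: tuple[float, ...] = (
        1.00, 0.94, 1.05, 0.97, 1.08, 0.92, 1.03, 0.96, 1.06,
    )
    rating_noise_sd: float = 0.08
    pde_duration_s: float = 0.2

    def __post_init__(self) -> None:
        if self.B1 <= 0:
            raise ConfigurationError("B1 must be positive")
        if self.b0 + min(0.0, self.b_conf) <= 0:
            raise ConfigurationError(
                "second-decision bound b0 + b_conf*conf must stay positive on [0, 1]"
            )
        if any(s <= 0 for s in self.session_bound_scale):
            raise ConfigurationError("session bound scales must be positive")


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------

def _base_trials(design: DesignSpec, rng: np.random.Generator) -> list[TrialSpec]:
    cohs = design.coherence_set
    trials: list[TrialSpec] = []

    def rewarded(coh: float) -> float:
        if coh == 0.0:
            return float(rng.choice([-1.0, 1.0]))
        return float(np.sign(coh))

    for c1 in cohs:
        for c2 in cohs:
            trials.append(TrialSpec("double", c1, c2, rewarded(c1), rewarded(c2)))
    reps = design.n_singles_per_type // design.n_coherences
    if reps * design.n_coherences != design.n_singles_per_type:
        raise ConfigurationError(
            "n_singles_per_type must be a multiple of the coherence-set size"
        )
    for _ in range(reps):
        for c in cohs:
            trials.append(TrialSpec("D1star", c, np.nan, rewarded(c), np.nan))
        for c in cohs:
            trials.append(TrialSpec("D2star", np.nan, c, np.nan, rewarded(c)))
        for c in cohs:
            trials.append(TrialSpec("D1catch", c, np.nan, rewarded(c), np.nan))
    return trials


def generate_block(design: DesignSpec, seed: int) -> list[TrialSpec]:
    """Generate one shuffled block of 154 trials.

    Every ordered coherence pair appears exactly once among the double
    trials and each single type covers each coherence exactly once; the
    presentation order is a seed-determined permutation.
    """
    rng = np.random.default_rng(seed)
    trials = _base_trials(design, rng)
    order = rng.permutation(len(trials))
    return [replace(trials[j], index=i) for i, j in enumerate(order)]


def mirror_block(block: list[TrialSpec]) -> list[TrialSpec]:
    """Sign-flip coherences and rewarded directions on both decision axes.

    Zero-coherence trials keep coherence 0 but flip the rewarded coin, so
    ``mirror(mirror(block))`` restores the original block exactly.
    """
    out = []
    for t in block:
        out.append(
            replace(
                t,
                coh1=-t.coh1 if not np.isnan(t.coh1) else np.nan,
                coh2=-t.coh2 if not np.isnan(t.coh2) else np.nan,
                rewarded_dir1=-t.rewarded_dir1 if not np.isnan(t.rewarded_dir1) else np.nan,
                rewarded_dir2=-t.rewarded_dir2 if not np.isnan(t.rewarded_dir2) else np.nan,
            )
        )
    return out


def _reorder(block: list[TrialSpec], rng: np.random.Generator) -> list[TrialSpec]:
    order = rng.permutation(len(block))
    return [replace(block[j], index=i) for i, j in enumerate(order)]


def generate_session(design: DesignSpec, seed: int, session: int = 0) -> list[TrialSpec]:
    """Four blocks: base, mirrored, and re-shuffled repeats of both (616 trials)."""
    ss = np.random.SeedSequence(seed)
    block_seed, *shuffle_seeds = [int(s) for s in ss.generate_state(4)]
    b1 = generate_block(design, block_seed)
    b2 = mirror_block(b1)
    rngs = [np.random.default_rng(s) for s in shuffle_seeds]
    blocks = [b1, _reorder(b2, rngs[0]), _reorder(b1, rngs[1]), _reorder(b2, rngs[2])]
    out = []
    for bi, blk in enumerate(blocks):
        for t in blk:
            out.append(replace(t, session=session, block=bi))
    return out


def _truncexp_rate(design: DesignSpec) -> float:
    """Rate of the truncated exponential whose mean matches the design."""
    lo, hi = design.delay_range_s
    c = hi - lo
    target = design.delay_mean_s - lo

    def mean_minus_target(lam: float) -> float:
        return 1.0 / lam - c / np.expm1(lam * c) - target

    return brentq(mean_minus_target, 1e-8, 1e3)


def sample_delay(design: DesignSpec, rng: np.random.Generator, size=None):
    """Sample inter-event delays from the calibrated truncated exponential."""
    lo, hi = design.delay_range_s
    lam = _truncexp_rate(design)
    c = hi - lo
    u = rng.uniform(size=size)
    return lo - np.log1p(-u * (-np.expm1(-lam * c))) / lam


# ---------------------------------------------------------------------------
# agent confidence
# ---------------------------------------------------------------------------

def _confidence_batch(choice, t, pde, B, coherences, probs, kappa, tau, C0=0.0):
    """Posterior P(chosen direction rewarded) for arrays of decisions.

    For a flat-bound diffusion the likelihood of hitting bound ``s*B`` at
    time ``t`` under drift ``mu`` factorises as
    ``exp(s*mu*B - mu^2 t/2) * f0(t, B)`` where ``f0`` does not depend on
    ``mu``, so the drift-independent factor cancels in the posterior over
    coherences.  A post-decision evidence sample ``y ~ N(mu*tau, tau)``
    multiplies in ``exp(y*mu - mu^2 tau/2)``.
    """
    choice = np.atleast_1d(np.asarray(choice, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pde = np.atleast_1d(np.asarray(pde, dtype=float))
    B = np.broadcast_to(np.atleast_1d(np.asarray(B, dtype=float)), choice.shape)
    mu = kappa * (np.asarray(coherences, dtype=float) + C0)  # (m,)
    logw = (
        np.log(np.asarray(probs, dtype=float))[None, :]
        + choice[:, None] * mu[None, :] * B[:, None]
        - 0.5 * mu[None, :] ** 2 * t[:, None]
    )
    if tau > 0:
        logw = logw + pde[:, None] * mu[None, :] - 0.5 * mu[None, :] ** 2 * tau
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    cohs = np.asarray(coherences, dtype=float)
    match = np.sign(cohs)[None, :] == choice[:, None]
    conf = (w * match).sum(axis=1) + 0.5 * (w * (cohs == 0.0)[None, :]).sum(axis=1)
    return conf


def agent_confidence(
    choice: int,
    decision_time_s: float,
    post_decision_evidence: float,
    coherence_prior: dict[float, float],
    kappa: float,
    bound: float,
    pde_duration_s: float = 0.0,
) -> float:
    """Posterior probability that the chosen direction is correct.

    Parameters
    ----------
    choice
        Sign of the crossed bound (+1 or -1).
    decision_time_s
        Time of the bound crossing (seconds, > 0).
    post_decision_evidence
        Accumulated evidence observed after commitment, in evidence units
        over ``pde_duration_s`` seconds (0 if none).
    coherence_prior
        Mapping from signed coherence to prior probability.
    kappa, bound
        The agent's drift sensitivity and the bound that was crossed.
    """
    if decision_time_s <= 0:
        raise ValueError("decision_time_s must be positive")
    cohs = np.array(list(coherence_prior.keys()), dtype=float)
    probs = np.array(list(coherence_prior.values()), dtype=float)
    probs = probs / probs.sum()
    if len(cohs) == 1 and cohs[0] == 0.0:
        return 0.5
    conf = _confidence_batch(
        [choice], [decision_time_s], [post_decision_evidence], [bound],
        cohs, probs, kappa, pde_duration_s,
    )
    return float(conf[0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_COLUMNS = [
    "session", "block", "trial_index", "trial_type",
    "coh1", "coh2", "rewarded_dir1", "rewarded_dir2",
    "choice1", "rt1_s", "correct1",
    "choice2", "rt2_s", "correct2",
    "confidence", "conf_true",
]


def _specs_to_frame(specs: list[TrialSpec]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "session": [t.session for t in specs],
            "block": [t.block for t in specs],
            "trial_index": [t.index for t in specs],
            "trial_type": [t.trial_type for t in specs],
            "coh1": [t.coh1 for t in specs],
            "coh2": [t.coh2 for t in specs],
            "rewarded_dir1": [t.rewarded_dir1 for t in specs],
            "rewarded_dir2": [t.rewarded_dir2 for t in specs],
        }
    )
    return df


def _simulate_frame(
    df: pd.DataFrame,
    agent: AgentParams,
    design: DesignSpec,
    ss: np.random.SeedSequence,
    dt_s: float,
) -> pd.DataFrame:
    n = len(df)
    scales = np.asarray(agent.session_bound_scale, dtype=float)
    if df["session"].max() >= len(scales):
        raise ConfigurationError("session_bound_scale shorter than the number of sessions")
    scale = scales[df["session"].to_numpy()]
    prior_cohs = np.asarray(design.coherence_set, dtype=float)
    prior_p = np.full(len(prior_cohs), 1.0 / len(prior_cohs))

    s_fp1, s_pde, s_rate, s_fp2 = ss.spawn(4)
    rng_pde = np.random.default_rng(s_pde)
    rng_rate = np.random.default_rng(s_rate)

    for col in _COLUMNS:
        if col not in df:
            df[col] = np.nan

    # --- first decisions -------------------------------------------------
    m1 = df["trial_type"].isin(["double", "D1star", "D1catch"]).to_numpy()
    mu1 = agent.kappa * (df.loc[m1, "coh1"].to_numpy() + agent.C0)
    B1 = agent.B1 * scale[m1]
    sign1, t1 = simulate_first_passage_batch(mu1, B1, dt_s, np.random.default_rng(s_fp1))
    tau = agent.pde_duration_s
    pde = rng_pde.normal(mu1 * tau, np.sqrt(tau)) if tau > 0 else np.zeros(mu1.shape)
    conf1 = _confidence_batch(sign1, t1, pde, B1, prior_cohs, prior_p, agent.kappa, tau)
    df.loc[m1, "choice1"] = sign1.astype(float)
    df.loc[m1, "rt1_s"] = t1 + agent.tnd_s
    df.loc[m1, "correct1"] = (sign1 == df.loc[m1, "rewarded_dir1"].to_numpy()).astype(float)
    df.loc[m1, "conf_true"] = conf1

    # --- second decisions -------------------------------------------------
    m2 = df["trial_type"].isin(["double", "D2star"]).to_numpy()
    conf_for_bound = np.where(
        df.loc[m2, "trial_type"].to_numpy() == "D2star", 1.0,
        df.loc[m2, "conf_true"].to_numpy(),
    )
    B2 = (agent.b0 + agent.b_conf * conf_for_bound) * scale[m2]
    if np.any(B2 <= 0):
        raise ConfigurationError("non-positive effective second-decision bound")
    mu2 = agent.kappa * (df.loc[m2, "coh2"].to_numpy() + agent.C0)
    sign2, t2 = simulate_first_passage_batch(mu2, B2, dt_s, np.random.default_rng(s_fp2))
    pde2 = rng_pde.normal(mu2 * tau, np.sqrt(tau)) if tau > 0 else np.zeros(mu2.shape)
    conf2 = _confidence_batch(sign2, t2, pde2, B2, prior_cohs, prior_p, agent.kappa, tau)
    df.loc[m2, "choice2"] = sign2.astype(float)
    df.loc[m2, "rt2_s"] = t2 + agent.tnd_s
    df.loc[m2, "correct2"] = (sign2 == df.loc[m2, "rewarded_dir2"].to_numpy()).astype(float)

    # --- confidence ratings ----------------------------------------------
    # Singles rate the decision just made; double trials rate the final
    # target, i.e. that BOTH decisions were correct.
    rating = np.full(n, np.nan)
    tt = df["trial_type"].to_numpy()
    conf_true_all = df["conf_true"].to_numpy()
    conf2_all = np.full(n, np.nan)
    conf2_all[m2] = conf2
    single1 = (tt == "D1star") | (tt == "D1catch")
    rating[single1] = conf_true_all[single1]
    rating[tt == "D2star"] = conf2_all[tt == "D2star"]
    dd = tt == "double"
    rating[dd] = conf_true_all[dd] * conf2_all[dd]
    noisy = rating + rng_rate.normal(0.0, agent.rating_noise_sd, size=n)
    df["confidence"] = np.clip(noisy, 0.0, 1.0)
    df.loc[~(single1 | (tt == "D2star") | dd), "confidence"] = np.nan

    return df[_COLUMNS]


def simulate_trial(
    spec: TrialSpec, agent: AgentParams, rng, design: DesignSpec | None = None,
    dt_s: float = 1e-3,
) -> pd.Series:
    """Simulate a single trial; returns one TrialRecord row."""
    design = design or DesignSpec()
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    else:
        seed = rng if isinstance(rng, (int, np.integer)) else rng.integers(0, 2**31 - 1)
        ss = np.random.SeedSequence(int(seed))
    df = _specs_to_frame([spec])
    return _simulate_frame(df, agent, design, ss, dt_s).iloc[0]


def simulate_dataset(
    design: DesignSpec, agent: AgentParams, seed: int, dt_s: float = 1e-3,
) -> pd.DataFrame:
    """Simulate the full multi-session experiment (9 x 616 trials by default)."""
    ss = np.random.SeedSequence(seed)
    sess_seeds = ss.spawn(design.n_sessions + 1)
    specs: list[TrialSpec] = []
    for s in range(design.n_sessions):
        specs.extend(
            generate_session(design, int(sess_seeds[s].generate_state(1)[0]), session=s)
        )
    df = _specs_to_frame(specs)
    return _simulate_frame(df, agent, design, sess_seeds[-1], dt_s)
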