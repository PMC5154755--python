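"""Normative time-dependent bounds for the second decision via dynamic programming.

The decision maker observes a diffusion with drift ``kappa * C`` where the
signed coherence ``C`` is drawn from a known prior.  The sufficient
statistic is (accumulated evidence x, elapsed time t); stopping yields the
trial reward only if *both* decisions are correct, so the stop value is
``conf1 * R * P(sign(x) correct | x, t)`` where ``conf1`` is the
(fixed, given) confidence that the first decision was correct.  Continuing
costs time.  Two cost structures are supported:

* ``reward_rate`` (default): time is charged at the reward rate rho
  (points/s), and rho is solved self-consistently so that the expected net
  value of a trial cycle -- decision time plus non-decision and
  inter-trial time -- is zero (average-reward formulation).
* ``per_second``: a fixed cost per second of deliberation.

Backward induction on a (time x evidence) grid yields the optimal policy,
summarized as a time-dependent symmetric bound: the smallest |x| at which
stopping is optimal.  The bounds collapse with elapsed time and, centrally,
their offset grows with ``conf1``: the more likely the first decision was
correct, the more a correct second decision is worth, and the longer it is
worth deliberating.

Because everything in the stopped value scales with ``conf1`` while the
time charge does not, comparing bounds across ``conf1`` levels is only
meaningful at a *common* reward rate: the rate is a property of the whole
task environment, not of one confidence level.  ``solve_bound_family``
therefore calibrates rho once (on the mixture of confidence levels) and
derives each level's bounds at that shared rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ddm import _BGK_BETA
from .task import COHERENCE_SET

__all__ = [
    "DPConfig",
    "BoundPolicy",
    "HorizonError",
    "posterior_correct",
    "solve_optimal_bounds",
    "solve_bound_family",
    "simulate_policy",
]


class HorizonError(RuntimeError):
    """The continuation region is still open at the time horizon."""


@dataclass(frozen=True)
class DPConfig:
    """Grid, prior, and economics of the dynamic program."""

    dt_s: float = 0.005
    t_max_s: float = 5.0
    x_max: float = 5.0
    nx: int = 201
    coherences: tuple[float, ...] = COHERENCE_SET
    prior: tuple[float, ...] | None = None  # uniform if None
    kappa: float = 10.0
    reward_R: float = 1.0
    tnd_s: float = 0.35
    iti_s: float = 2.0
    conf1: float = 1.0
    cost_mode: str = "reward_rate"  # or "per_second"
    cost_per_s: float = 0.1
    rho: float | None = None  # fix the time charge instead of solving for it

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.t_max_s <= self.dt_s:
            raise ValueError("need 0 < dt_s < t_max_s")
        if self.cost_mode not in ("reward_rate", "per_second"):
            raise ValueError("cost_mode must be 'reward_rate' or 'per_second'")
        if self.nx % 2 == 0:
            raise ValueError("nx must be odd so the grid contains x = 0")

    @property
    def prior_probs(self) -> np.ndarray:
        if self.prior is None:
            return np.full(len(self.coherences), 1.0 / len(self.coherences))
        p = np.asarray(self.prior, dtype=float)
        return p / p.sum()

    @property
    def x_grid(self) -> np.ndarray:
        return np.linspace(-self.x_max, self.x_max, self.nx)

    @property
    def t_grid(self) -> np.ndarray:
        n_t = int(round(self.t_max_s / self.dt_s))
        return np.arange(n_t + 1) * self.dt_s


@dataclass
class BoundPolicy:
    """Symmetric time-dependent termination bound and its reward rate."""

    times: np.ndarray
    bound: np.ndarray
    rho: float
    value0: float  # value of the evidence-free start state
    config: DPConfig = field(repr=False, default=None)


def _log_posterior_weights(x, t, coherences, probs, kappa):
    """log P(C | x, t) up to the per-x normalizer; shape (len(x), len(C))."""
    mu = kappa * np.asarray(coherences, dtype=float)
    x = np.asarray(x, dtype=float)
    return (
        np.log(probs)[None, :] + x[:, None] * mu[None, :]
        - 0.5 * mu[None, :] ** 2 * t
    )


def _posterior(x, t, coherences, probs, kappa):
    logw = _log_posterior_weights(x, t, coherences, probs, kappa)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def posterior_correct(x, t, coherences=COHERENCE_SET, prior=None, kappa=10.0):
    """P(direction matching sign(x) is correct | evidence x at time t).

    Zero-coherence trials reward a fair coin, so their posterior mass
    contributes 1/2 regardless of x; at x = 0 the best guess is correct
    with probability 1/2 under a symmetric prior.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cohs = np.asarray(coherences, dtype=float)
    probs = (np.full(len(cohs), 1.0 / len(cohs)) if prior is None
             else np.asarray(prior, dtype=float) / np.sum(prior))
    w = _posterior(x, t, cohs, probs, kappa)
    p_pos = (w * (cohs > 0)[None, :]).sum(axis=1) + 0.5 * (w * (cohs == 0)[None, :]).sum(axis=1)
    out = np.where(x > 0, p_pos, np.where(x < 0, 1.0 - p_pos, np.maximum(p_pos, 1.0 - p_pos)))
    return out if out.shape != (1,) else float(out[0])


def _best_stop_prob(x, t, cohs, probs, kappa):
    """P(correct | x, t) for the better of the two choices (vectorized)."""
    w = _posterior(x, t, cohs, probs, kappa)
    p_pos = (w * (cohs > 0)[None, :]).sum(axis=1) + 0.5 * (w * (cohs == 0)[None, :]).sum(axis=1)
    return np.maximum(p_pos, 1.0 - p_pos)


def _transition_stack(config: DPConfig) -> np.ndarray:
    """Row-stochastic one-step kernels, one per coherence: (nC*nx, nx)."""
    x = config.x_grid
    mu = config.kappa * np.asarray(config.coherences, dtype=float)
    sd = np.sqrt(config.dt_s)
    # destination j given source i: N(x_i + mu*dt, dt) discretized on the grid
    diff = x[None, None, :] - (x[None, :, None] + mu[:, None, None] * config.dt_s)
    T = np.exp(-0.5 * (diff / sd) ** 2)
    T /= T.sum(axis=2, keepdims=True)
    return np.ascontiguousarray(T.reshape(len(mu) * config.nx, config.nx))


def _backward(config: DPConfig, charge: float):
    """One backward-induction sweep at a fixed time charge (points/s).

    Returns (value at x=0 t=0, bound array over the time grid, values V0).
    """
    x = config.x_grid
    t_grid = config.t_grid
    n_t = len(t_grid) - 1
    cohs = np.asarray(config.coherences, dtype=float)
    probs = config.prior_probs
    scale = config.conf1 * config.reward_R
    T = _transition_stack(config)
    nC = len(cohs)

    bound = np.empty(n_t + 1)
    V = scale * _best_stop_prob(x, t_grid[-1], cohs, probs, config.kappa)
    bound[n_t] = 0.0
    pos = x >= 0
    for k in range(n_t - 1, -1, -1):
        t = t_grid[k]
        v_stop = scale * _best_stop_prob(x, t, cohs, probs, config.kappa)
        w = _posterior(x, t, cohs, probs, config.kappa)  # (nx, nC)
        tv = (T @ V).reshape(nC, config.nx)              # E[V' | x, C]
        v_cont = np.einsum("xc,cx->x", w, tv) - charge * config.dt_s
        stop = v_stop >= v_cont
        V = np.where(stop, v_stop, v_cont)
        stopped_pos = stop[pos]
        bound[k] = x[pos][stopped_pos].min() if stopped_pos.any() else np.inf
    i0 = config.nx // 2
    return float(V[i0]), bound, V


def solve_optimal_bounds(config: DPConfig) -> BoundPolicy:
    """Backward-induction solution for one confidence level.

    In ``reward_rate`` mode with ``rho`` unset, the rate is found by root
    finding on the average-reward fixed point: the value of starting a
    trial equals the opportunity cost ``rho * (tnd_s + iti_s)`` of the
    dead time it entails.
    """
    dead = config.tnd_s + config.iti_s
    if config.cost_mode == "per_second":
        charge = config.cost_per_s
        v0, bound, _ = _backward(config, charge)
        rho = charge
    elif config.rho is not None:
        rho = config.rho
        v0, bound, _ = _backward(config, rho)
    else:
        if config.reward_R == 0:
            rho = 0.0
            v0, bound, _ = _backward(config, 0.0)
        else:
            def gap(r):
                v, _, _ = _backward(config, r)
                return v - r * dead

            hi = config.reward_R / dead
            if gap(hi) > 0:  # pragma: no cover - defensive
                raise RuntimeError("reward-rate fixed point not bracketed")
            rho = brentq(gap, 0.0, hi, xtol=1e-6)
            v0, bound, _ = _backward(config, rho)
    if config.reward_R > 0 and rho > 0:
        if not np.isfinite(bound).all():
            raise HorizonError(
                "continuation region unbounded in evidence; increase x_max"
            )
        surv = _survival_at_horizon(config, bound)
        if surv > 1e-4:
            raise HorizonError(
                f"continuation region effectively open at t_max "
                f"(survival mass {surv:.2e}); increase t_max_s"
            )
    return BoundPolicy(times=config.t_grid, bound=bound, rho=float(rho),
                       value0=v0, config=config)


def _survival_at_horizon(config: DPConfig, bound: np.ndarray) -> float:
    """Probability (under the prior) that a path is still unabsorbed at t_max."""
    x = config.x_grid
    T = _transition_stack(config).reshape(len(config.coherences), config.nx, config.nx)
    probs = config.prior_probs
    i0 = config.nx // 2
    m = np.zeros((len(probs), config.nx))
    m[:, i0] = probs
    for k in range(1, len(bound)):
        m = np.einsum("cj,cji->ci", m, T)
        m[:, np.abs(x) >= bound[k]] = 0.0
    return float(m.sum())


def solve_bound_family(config: DPConfig, conf1_levels=(0.6, 0.8, 1.0)) -> dict[float, BoundPolicy]:
    """Optimal bounds per first-decision confidence level at a shared rate.

    In ``reward_rate`` mode the rate is calibrated once on the equal
    mixture of the given levels (the environment's trials span all of
    them), then each level's policy is derived at that common rho.  In
    ``per_second`` mode the charge is already shared.
    """
    if config.cost_mode == "per_second" or config.rho is not None:
        return {c: solve_optimal_bounds(replace(config, conf1=c)) for c in conf1_levels}
    dead = config.tnd_s + config.iti_s

    def gap(r):
        vals = [_backward(replace(config, conf1=c), r)[0] for c in conf1_levels]
        return float(np.mean(vals)) - r * dead

    hi = config.reward_R / dead
    rho = brentq(gap, 0.0, hi, xtol=1e-6)
    return {
        c: solve_optimal_bounds(replace(config, conf1=c, rho=rho))
        for c in conf1_levels
    }


def simulate_policy(policy: BoundPolicy, kappa: float, coherences,
                    n_per_coherence: int, tnd_s: float, seed: int,
                    ) -> pd.DataFrame:
    """Diffusion paths absorbed at the time-varying bound.

    Returns one row per signed coherence with choice frequencies, accuracy
    (scored against sign(C); 0.5 by convention at C = 0), and mean RT.
    The absorbing boundary is continuity-corrected exactly as in the
    flat-bound simulator.
    """
    rng = np.random.default_rng(seed)
    dt = float(policy.times[1] - policy.times[0])
    corr = _BGK_BETA * np.sqrt(dt)
    b = np.maximum(policy.bound - corr, 0.0)
    rows = []
    for C in coherences:
        mu = kappa * C
        n = int(n_per_coherence)
        xpos = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        t_dec = np.full(n, policy.times[-1])
        sgn = np.zeros(n)
        for k in range(1, len(policy.times)):
            na = int(alive.sum())
            if na == 0:
                break
            xpos[alive] += mu * dt + np.sqrt(dt) * rng.standard_normal(na)
            hit = alive & (np.abs(xpos) >= b[k])
            t_dec[hit] = policy.times[k]
            sgn[hit] = np.sign(xpos[hit])
            alive &= ~hit
        if alive.any():  # forced stop at the horizon
            sgn[alive] = np.sign(xpos[alive])
        ties = sgn == 0
        if ties.any():
            sgn[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        acc = 0.5 if C == 0 else float(np.mean(sgn == np.sign(C)))
        rows.append({
            "coherence": C,
            "n": n,
            "p_positive": float(np.mean(sgn > 0)),
            "accuracy": acc,
            "mean_rt_s": float(np.mean(t_dec) + tnd_s),
        })
    return pd.DataFrame(rows)
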