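"""Flat-bound drift-diffusion fits to second-decision choices and RTs.

The likelihood combines a Bernoulli term for every choice with a Gaussian
term for the reaction time of "majority" trials, using the model's
predicted mean RT and the empirical per-(session, coherence) RT standard
deviation.  Six model variants let the bound B and/or the sensitivity kappa
vary by session and/or linearly with interpolated first-decision
confidence:

====== ============================ ===========================
model  bound B                      sensitivity kappa
====== ============================ ===========================
1      by session                   shared
2      shared                       by session
3      by session + conf slope      shared
4      shared                       by session + conf slope
5      by session                   shared + conf slope
6      by session + conf slope*     by session
====== ============================ ===========================

(*model 6: the session-varying parameter is kappa, the confidence slope is
on the shared bound.)  Models are compared by BIC; the confidence covariate
can be swapped for the unsigned first-decision coherence with one flag.
The bias C0 and the non-decision time are shared across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ddm import mean_decision_time

__all__ = [
    "ModelSpec",
    "FitParams",
    "FitResult",
    "second_decision_table",
    "classify_majority_choice",
    "empirical_rt_sd",
    "neg_log_likelihood",
    "fit_model",
    "fit_all_models",
    "bic_of",
    "combine_bic",
    "fit_quantile_bounds",
    "zero_coherence_bound_estimate",
    "logistic_interaction_fit",
]

_PENALTY = 1e10

_MODEL_TABLE = {
    # model_id: (bound_by_session, kappa_by_session, bound_slope, kappa_slope)
    1: (True, False, False, False),
    2: (False, True, False, False),
    3: (True, False, True, False),
    4: (False, True, False, True),
    5: (True, False, False, True),
    6: (False, True, True, False),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six bound/kappa variation schemes."""

    model_id: int
    covariate: str = "confidence"  # or "coherence"

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TABLE:
            raise ValueError(f"model_id must be 1-6, got {self.model_id}")
        if self.covariate not in ("confidence", "coherence"):
            raise ValueError("covariate must be 'confidence' or 'coherence'")

    @property
    def bound_by_session(self) -> bool:
        return _MODEL_TABLE[self.model_id][0]

    @property
    def kappa_by_session(self) -> bool:
        return _MODEL_TABLE[self.model_id][1]

    @property
    def bound_conf_slope(self) -> bool:
        return _MODEL_TABLE[self.model_id][2]

    @property
    def kappa_conf_slope(self) -> bool:
        return _MODEL_TABLE[self.model_id][3]

    @property
    def has_slope(self) -> bool:
        return self.bound_conf_slope or self.kappa_conf_slope

    def n_free(self, n_sessions: int) -> int:
        nk = n_sessions if self.kappa_by_session else 1
        nb = n_sessions if self.bound_by_session else 1
        return nk + nb + int(self.has_slope) + 2  # + C0, tnd


@dataclass
class FitParams:
    """Unpacked parameter estimates (arrays where session-varying)."""

    kappa: np.ndarray | float
    B: np.ndarray | float
    beta_conf: float
    C0: float
    tnd_s: float

    @property
    def mean_B(self) -> float:
        return float(np.mean(self.B))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappa))


@dataclass
class FitResult:
    model_spec: ModelSpec
    params: FitParams
    neg_log_likelihood: float
    n_trials: int
    df: int
    bic: float
    x: np.ndarray = field(repr=False, default=None)
    success: bool = True
    conf_center: float = 0.0


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def second_decision_table(trials: pd.DataFrame, covariate: str = "confidence") -> pd.DataFrame:
    """Extract the second-decision rows (double D2nd + D2star) for fitting.

    Returns columns session, coh2, choice2, rt2_s, conf.  With the
    confidence covariate, double trials use their interpolated ``conf_hat``
    and D2star trials are assigned confidence 1 (the first decision was
    bypassed, so there is nothing to be uncertain about).  With the
    coherence covariate, double trials use |coh1| and D2star trials the
    strongest coherence.
    """
    mask = trials["trial_type"].isin(["double", "D2star"])
    sub = trials.loc[mask].dropna(subset=["coh2", "choice2", "rt2_s"]).copy()
    is_star = sub["trial_type"] == "D2star"
    if covariate == "confidence":
        if "conf_hat" not in sub or sub.loc[~is_star, "conf_hat"].isna().any():
            raise ValueError(
                "double trials need a conf_hat column (run annotate_conf_hat first)"
            )
        conf = np.where(is_star, 1.0, sub.get("conf_hat", np.nan))
    elif covariate == "coherence":
        cmax = np.nanmax(np.abs(trials["coh1"].to_numpy()))
        conf = np.where(is_star, cmax, np.abs(sub["coh1"].to_numpy()))
    else:
        raise ValueError("covariate must be 'confidence' or 'coherence'")
    out = sub[["session", "coh2", "choice2", "rt2_s"]].copy()
    out["conf"] = conf
    return out.reset_index(drop=True)


class _FitData:
    """Arrays + per-trial RT SDs for fast likelihood evaluation."""

    def __init__(self, table: pd.DataFrame, rt_sds: dict, flags: np.ndarray):
        self.sessions = np.unique(table["session"].to_numpy())
        self.n_sessions = len(self.sessions)
        self.sess_idx = np.searchsorted(self.sessions, table["session"].to_numpy())
        self.coh = table["coh2"].to_numpy(dtype=float)
        self.sign = np.sign(table["choice2"].to_numpy(dtype=float))
        self.rt = table["rt2_s"].to_numpy(dtype=float)
        self.conf = table["conf"].to_numpy(dtype=float)
        self.center = float(self.conf.mean())
        self.conf_c = self.conf - self.center
        self.n = len(table)
        self.flags = np.asarray(flags, dtype=bool)
        sd = np.full(self.n, np.nan)
        keys = list(zip(table["session"].to_numpy(), np.abs(self.coh)))
        for i, key in enumerate(keys):
            if key in rt_sds:
                sd[i] = rt_sds[key]
        self.sd = sd
        self.rt_mask = self.flags & np.isfinite(sd)
        if np.any(sd[self.rt_mask] <= 0):
            raise ValueError("RT standard deviations must be positive")
        # constant part of the Gaussian RT log-density
        self._rt_const = float(
            np.sum(0.5 * np.log(2 * np.pi * self.sd[self.rt_mask] ** 2))
        )


def classify_majority_choice(table: pd.DataFrame, choice_col: str = "choice2",
                             coh_col: str = "coh2") -> np.ndarray:
    """Flag trials whose choice falls on the majority side of a logistic fit.

    A 2-parameter logistic of choice on signed coherence locates the point
    of subjective equality; trials whose choice matches the side with
    fitted p > 0.5 at their coherence are flagged.  These flags select the
    trials whose RTs enter the Gaussian likelihood and the empirical SDs.
    Under perfect separation the sign-of-coherence rule is used instead
    (zero-coherence trials then go with the overall majority choice).
    """
    coh = table[coh_col].to_numpy(dtype=float)
    sign = np.sign(table[choice_col].to_numpy(dtype=float))
    y = (sign > 0).astype(float)
    if len(np.unique(coh)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need >= 2 distinct coherences with both choices represented")
    import statsmodels.api as sm

    X = sm.add_constant(coh)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params[1]) > 1e4:
            raise RuntimeError("separation")
        p = res.predict(X)
    except Exception:
        warnings.warn("logistic fit separated; falling back to sign-of-coherence rule")
        majority0 = 1.0 if y[coh == 0].mean() >= 0.5 else -1.0
        side = np.where(coh == 0, majority0, np.sign(coh))
        return sign == side
    return np.where(p > 0.5, sign > 0, sign < 0)


def empirical_rt_sd(table: pd.DataFrame, flags: np.ndarray,
                    rt_col: str = "rt2_s", coh_col: str = "coh2") -> dict:
    """Sample SD of majority-trial RTs per (session, unsigned coherence) cell."""
    sub = table.loc[np.asarray(flags, dtype=bool)]
    out = {}
    for (sess, coh), grp in sub.groupby(["session", np.abs(sub[coh_col])]):
        if len(grp) < 2:
            raise ValueError(
                f"cell (session={sess}, |coh|={coh}) has {len(grp)} majority "
                "trials; need >= 2 for a sample SD"
            )
        out[(sess, coh)] = float(grp[rt_col].std(ddof=1))
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _unpack(x: np.ndarray, spec: ModelSpec, n_sessions: int):
    nk = n_sessions if spec.kappa_by_session else 1
    nb = n_sessions if spec.bound_by_session else 1
    kap = x[:nk]
    B = x[nk:nk + nb]
    i = nk + nb
    beta = x[i] if spec.has_slope else 0.0
    i += int(spec.has_slope)
    C0, tnd = x[i], x[i + 1]
    return kap, B, beta, C0, tnd


def _nll_core(x: np.ndarray, spec: ModelSpec, data: _FitData,
              include_rt: bool = True) -> float:
    kap, B, beta, C0, tnd = _unpack(x, spec, data.n_sessions)
    kap_t = kap[data.sess_idx] if len(kap) > 1 else np.full(data.n, kap[0])
    B_t = B[data.sess_idx] if len(B) > 1 else np.full(data.n, B[0])
    if spec.bound_conf_slope:
        B_t = B_t + beta * data.conf_c
    if spec.kappa_conf_slope:
        kap_t = kap_t + beta * data.conf_c
    floor = min(B_t.min(), kap_t.min())
    if floor <= 1e-6:
        # smooth rejection: gradient points back toward the feasible region
        return _PENALTY * (1.0 + abs(floor))
    mu = kap_t * (data.coh + C0)
    nll = float(np.sum(np.logaddexp(0.0, -2.0 * data.sign * mu * B_t)))
    if include_rt:
        m = data.rt_mask
        pred = mean_decision_time(mu[m], B_t[m]) + tnd
        nll += data._rt_const + float(
            np.sum((data.rt[m] - pred) ** 2 / (2.0 * data.sd[m] ** 2))
        )
    return nll


def neg_log_likelihood(table: pd.DataFrame, model_spec: ModelSpec,
                       params: FitParams, rt_sds: dict,
                       flags: np.ndarray | None = None,
                       include_rt: bool = True,
                       conf_center: float | None = None) -> float:
    """Negative log likelihood of a second-decision table under one model.

    Bernoulli terms for every choice; Gaussian RT terms (model's predicted
    mean, data's SD) for majority-flagged trials only.
    """
    if flags is None:
        flags = classify_majority_choice(table)
    data = _FitData(table, rt_sds, flags)
    if conf_center is not None:
        data.conf_c = data.conf - conf_center
        data.center = conf_center
    n_sessions = data.n_sessions
    kap = np.atleast_1d(np.asarray(params.kappa, dtype=float))
    B = np.atleast_1d(np.asarray(params.B, dtype=float))
    x = np.concatenate([
        kap, B,
        [params.beta_conf] if model_spec.has_slope else [],
        [params.C0, params.tnd_s],
    ])
    return _nll_core(x, model_spec, data, include_rt=include_rt)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _start_and_bounds(spec: ModelSpec, data: _FitData):
    min_rt = data.rt.min()
    tnd0 = min(0.7 * min_rt, 0.35)
    # moment-based starts: bound from slow low-coherence RTs, kappa from
    # accuracy at the strongest coherence
    lo_coh = np.abs(data.coh) == np.min(np.abs(data.coh))
    B0 = float(np.sqrt(max(np.mean(data.rt[lo_coh]) - tnd0, 0.04)))
    cmax = np.max(np.abs(data.coh))
    hi = np.abs(data.coh) == cmax
    acc = np.mean(data.sign[hi] == np.sign(data.coh[hi]))
    acc = np.clip(acc, 0.55, 0.999)
    k0 = float(np.clip(np.log(acc / (1 - acc)) / (2 * cmax * B0), 0.5, 80.0))
    nk = data.n_sessions if spec.kappa_by_session else 1
    nb = data.n_sessions if spec.bound_by_session else 1
    x0 = np.concatenate([
        np.full(nk, k0), np.full(nb, B0),
        [0.0] if spec.has_slope else [],
        [0.0, tnd0],
    ])
    bounds = (
        [(1e-2, 100.0)] * nk + [(1e-2, 10.0)] * nb
        + ([(-60.0, 60.0)] if spec.has_slope else [])
        + [(-0.2, 0.2), (0.0, max(min_rt - 1e-3, 1e-3))]
    )
    return x0, bounds


def fit_model(table: pd.DataFrame, model_spec: ModelSpec,
              rt_sds: dict | None = None, flags: np.ndarray | None = None,
              n_restarts: int = 5, seed: int = 0,
              include_rt: bool = True) -> FitResult:
    """Maximum-likelihood fit of one model variant.

    Runs a box-constrained quasi-Newton optimization from a moment-based
    start plus ``n_restarts - 1`` dispersed starts and keeps the best
    optimum.  The confidence covariate is centered at its sample mean, so
    session bounds are bounds at average confidence.
    """
    if flags is None:
        flags = classify_majority_choice(table)
    if rt_sds is None:
        rt_sds = empirical_rt_sd(table, flags)
    data = _FitData(table, rt_sds, flags)
    x0, bounds = _start_and_bounds(model_spec, data)
    rng = np.random.default_rng(seed)
    best = None
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = x0
        else:
            jitter = rng.uniform(0.6, 1.6, size=len(x0))
            start = np.clip(x0 * jitter + rng.normal(0, 0.02, len(x0)), lo + 1e-3, hi - 1e-3)
        res = minimize(
            _nll_core, start, args=(model_spec, data, include_rt),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise RuntimeError(f"all restarts failed for model {model_spec.model_id}")
    kap, B, beta, C0, tnd = _unpack(best.x, model_spec, data.n_sessions)
    params = FitParams(
        kappa=kap.copy() if len(kap) > 1 else float(kap[0]),
        B=B.copy() if len(B) > 1 else float(B[0]),
        beta_conf=float(beta), C0=float(C0), tnd_s=float(tnd),
    )
    df = model_spec.n_free(data.n_sessions)
    nll = float(best.fun)
    return FitResult(
        model_spec=model_spec, params=params, neg_log_likelihood=nll,
        n_trials=data.n, df=df, bic=bic_of(nll, df, data.n),
        x=best.x.copy(), success=bool(best.success), conf_center=data.center,
    )


def fit_all_models(table: pd.DataFrame, covariate: str = "confidence",
                   n_restarts: int = 5, seed: int = 0,
                   model_ids=(1, 2, 3, 4, 5, 6)) -> dict[int, FitResult]:
    """Fit the six variants to one second-decision table (shared flags/SDs)."""
    flags = classify_majority_choice(table)
    rt_sds = empirical_rt_sd(table, flags)
    return {
        mid: fit_model(table, ModelSpec(mid, covariate), rt_sds, flags,
                       n_restarts=n_restarts, seed=seed + mid)
        for mid in model_ids
    }


def bic_of(neg_log_likelihood: float, df: int, n_trials: int) -> float:
    """BIC = df * ln(n) + 2 * NLL (lower is better)."""
    return df * np.log(n_trials) + 2.0 * neg_log_likelihood


def combine_bic(results: list[FitResult]) -> float:
    """Across-subject BIC from summed df, trial counts, and log likelihoods."""
    df = sum(r.df for r in results)
    n = sum(r.n_trials for r in results)
    nll = sum(r.neg_log_likelihood for r in results)
    return bic_of(nll, df, n)


# ---------------------------------------------------------------------------
# quantile bound fit, zero-coherence estimator, logistic interaction
# ---------------------------------------------------------------------------

def _numerical_hessian(f, x, rel_step=1e-4, abs_step=1e-5):
    """Central-difference Hessian (symmetrized)."""
    p = len(x)
    h = np.maximum(np.abs(x) * rel_step, abs_step)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_quantile_bounds(table: pd.DataFrame, n_quantiles: int = 7,
                        flags: np.ndarray | None = None,
                        rt_sds: dict | None = None,
                        n_restarts: int = 3, seed: int = 0) -> pd.DataFrame:
    """Session-bound fit with an additive bound offset per confidence quantile.

    Trials are grouped into ``n_quantiles`` quantiles of the confidence
    estimate; the lowest quantile is the reference (offset fixed at 0).
    Percent bound change is reported relative to the average session bound
    on lowest-quantile trials, with standard errors from the local
    curvature of the likelihood.
    """
    if table["conf"].nunique() < n_quantiles:
        raise ValueError("confidence estimates too coarse to form quantiles")
    if flags is None:
        flags = classify_majority_choice(table)
    if rt_sds is None:
        rt_sds = empirical_rt_sd(table, flags)
    data = _FitData(table, rt_sds, flags)
    qcodes = pd.qcut(data.conf, n_quantiles, labels=False, duplicates="drop")
    qcodes = np.asarray(qcodes, dtype=int)
    nq = qcodes.max() + 1
    S = data.n_sessions
    n_off = nq - 1

    def nll(x):
        kap = x[0]
        B_s = x[1:1 + S]
        offs = np.concatenate([[0.0], x[1 + S:1 + S + n_off]])
        C0, tnd = x[-2], x[-1]
        B_t = B_s[data.sess_idx] + offs[qcodes]
        if B_t.min() <= 1e-6 or kap <= 0:
            return _PENALTY * (1.0 + abs(min(B_t.min(), kap)))
        mu = kap * (data.coh + C0)
        out = float(np.sum(np.logaddexp(0.0, -2.0 * data.sign * mu * B_t)))
        m = data.rt_mask
        pred = mean_decision_time(mu[m], B_t[m]) + tnd
        out += data._rt_const + float(
            np.sum((data.rt[m] - pred) ** 2 / (2.0 * data.sd[m] ** 2))
        )
        return out

    min_rt = data.rt.min()
    tnd0 = min(0.7 * min_rt, 0.35)
    lo_coh = np.abs(data.coh) == np.min(np.abs(data.coh))
    B0 = float(np.sqrt(max(np.mean(data.rt[lo_coh]) - tnd0, 0.04)))
    x0 = np.concatenate([[10.0], np.full(S, B0), np.zeros(n_off), [0.0, tnd0]])
    bounds = ([(1e-2, 100.0)] + [(1e-2, 10.0)] * S + [(-5.0, 5.0)] * n_off
              + [(-0.2, 0.2), (0.0, max(min_rt - 1e-3, 1e-3))])
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        start = x0 if r == 0 else x0 * rng.uniform(0.8, 1.25, len(x0))
        start = np.clip(start, [b[0] + 1e-3 for b in bounds], [b[1] - 1e-3 for b in bounds])
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res

    x = best.x
    H = _numerical_hessian(nll, x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(x), np.nan)
    B_s = x[1:1 + S]
    offs = np.concatenate([[0.0], x[1 + S:1 + S + n_off]])
    se_offs = np.concatenate([[0.0], se[1 + S:1 + S + n_off]])
    low_mask = qcodes == 0
    ref = float(np.mean(B_s[data.sess_idx[low_mask]]))
    rows = []
    for q in range(nq):
        rows.append({
            "quantile": q + 1,
            "mean_conf": float(data.conf[qcodes == q].mean()),
            "n_trials": int(np.sum(qcodes == q)),
            "bound_offset": float(offs[q]),
            "se_offset": float(se_offs[q]),
            "pct_change": 100.0 * offs[q] / ref,
            "se_pct": 100.0 * se_offs[q] / ref,
        })
    return pd.DataFrame(rows)


def zero_coherence_bound_estimate(table: pd.DataFrame, tnd_s: float,
                                  n_groups: int = 4) -> pd.DataFrame:
    """Bound estimates from zero-coherence second decisions.

    At zero coherence the drift is ~0, so the mean decision time equals
    B**2 and the bound is recovered as ``sqrt(mean RT - tnd)`` within each
    confidence group (quartiles of the confidence estimate by default).
    """
    zero = table.loc[table["coh2"] == 0.0]
    if len(zero) == 0:
        raise ValueError("no zero-coherence second decisions in the table")
    if n_groups > 1:
        groups = pd.qcut(zero["conf"], n_groups, labels=False, duplicates="drop")
    else:
        groups = np.zeros(len(zero), dtype=int)
    rows = []
    for g, grp in zero.groupby(np.asarray(groups)):
        mean_rt = float(grp["rt2_s"].mean())
        if mean_rt <= tnd_s:
            raise ValueError(
                f"group {g}: mean RT {mean_rt:.3f} s <= tnd {tnd_s:.3f} s"
            )
        rows.append({
            "group": int(g) + 1,
            "mean_conf": float(grp["conf"].mean()),
            "n_trials": len(grp),
            "mean_rt_s": mean_rt,
            "bound_hat": float(np.sqrt(mean_rt - tnd_s)),
        })
    return pd.DataFrame(rows)


@dataclass
class LogisticInteractionFit:
    """ML estimates of P(up) = logistic(k1 + k2*coh2 + k3*coh2*|coh1|)."""

    k: np.ndarray          # (k1, k2, k3)
    se: np.ndarray
    n: int

    @property
    def z(self) -> np.ndarray:
        return self.k / self.se


def logistic_interaction_fit(trials: pd.DataFrame) -> LogisticInteractionFit:
    """Does first-decision coherence modulate second-decision accuracy?

    Fits the 3-parameter logistic of the D2nd choice on coh2 and the
    interaction coh2*|coh1| over double-decision trials; the null
    hypothesis of interest is k3 = 0.
    """
    import statsmodels.api as sm

    dd = trials.loc[trials["trial_type"] == "double"].dropna(
        subset=["coh1", "coh2", "choice2"]
    )
    coh1 = np.abs(dd["coh1"].to_numpy(dtype=float))
    coh2 = dd["coh2"].to_numpy(dtype=float)
    if len(np.unique(coh2)) < 2 or len(np.unique(coh1)) < 2:
        raise ValueError("need variation in both coh2 and |coh1|")
    y = (dd["choice2"].to_numpy(dtype=float) > 0).astype(float)
    X = np.column_stack([np.ones(len(dd)), coh2, coh2 * coh1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("perfect separation in logistic interaction fit")
    return LogisticInteractionFit(k=res.params, se=res.bse, n=len(dd))
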