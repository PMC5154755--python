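"""k-nearest-neighbor interpolation of first-decision confidence.

Double-decision trials carry no confidence report for the first decision,
so confidence is interpolated from the single-decision trials (``D1star``
and ``D1catch``) that do: for a first decision with a given unsigned
coherence, accuracy, and reaction time, the estimate is the mean rating of
the k single-decision trials in the same (coherence, accuracy) cell whose
RTs are closest.  Errors being rarer than correct responses, a smaller k is
used for error trials (defaults k=30 correct / k=15 error).  Zero-coherence
trials are grouped with the correct class.  Leave-one-out cross-validation
on the single-decision trials quantifies how predictable the ratings are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfidencePool",
    "InsufficientPoolError",
    "knn_confidence",
    "loo_variance_explained",
    "annotate_conf_hat",
]

K_CORRECT_DEFAULT = 30
K_ERROR_DEFAULT = 15


class InsufficientPoolError(ValueError):
    """A (coherence, accuracy) cell holds fewer entries than requested."""


def _as_correct_class(coh_unsigned, correct):
    """Zero-coherence decisions are conventionally scored as correct."""
    coh_unsigned = np.asarray(coh_unsigned, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    return np.where(coh_unsigned == 0.0, True, correct)


@dataclass
class ConfidencePool:
    """Rated single first decisions: (unsigned coherence, accuracy, RT, rating)."""

    coh_unsigned: np.ndarray
    correct: np.ndarray
    rt_s: np.ndarray
    rating: np.ndarray

    def __post_init__(self) -> None:
        self.coh_unsigned = np.asarray(self.coh_unsigned, dtype=float)
        self.correct = _as_correct_class(self.coh_unsigned, self.correct)
        self.rt_s = np.asarray(self.rt_s, dtype=float)
        self.rating = np.asarray(self.rating, dtype=float)
        if np.any(self.rt_s <= 0):
            raise ValueError("pool RTs must be positive")
        if np.any((self.rating < 0) | (self.rating > 1)):
            raise ValueError("pool ratings must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.rating)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "ConfidencePool":
        """Build the pool from the D1star and D1catch rows of a trial table."""
        sub = trials[trials["trial_type"].isin(["D1star", "D1catch"])]
        sub = sub.dropna(subset=["coh1", "rt1_s", "correct1", "confidence"])
        return cls(
            coh_unsigned=np.abs(sub["coh1"].to_numpy()),
            correct=sub["correct1"].to_numpy().astype(bool),
            rt_s=sub["rt1_s"].to_numpy(),
            rating=sub["confidence"].to_numpy(),
        )

    def cell(self, coh_unsigned: float, correct: bool):
        """Indices of entries matching a (coherence, accuracy) cell."""
        correct = bool(_as_correct_class(coh_unsigned, correct))
        return np.flatnonzero(
            (self.coh_unsigned == coh_unsigned) & (self.correct == correct)
        )


def _knn_cell_mean(rts, ratings, idx, query_rt: float, k: int) -> float:
    # stable tie-break: sort on (|rt - query|, rt, insertion index)
    d = np.abs(rts[idx] - query_rt)
    order = np.lexsort((idx, rts[idx], d))
    return float(ratings[idx[order[:k]]].mean())


def knn_confidence(
    query: tuple[float, bool, float],
    pool: ConfidencePool,
    k_correct: int = K_CORRECT_DEFAULT,
    k_error: int = K_ERROR_DEFAULT,
) -> float:
    """Mean rating of the k nearest (by RT) pool entries in the query's cell.

    ``query`` is (unsigned coherence, accuracy flag, rt_s).  Raises
    :class:`InsufficientPoolError` if the cell holds fewer than k entries.
    """
    coh, correct, rt = query
    correct = bool(_as_correct_class(coh, correct))
    k = k_correct if correct else k_error
    idx = pool.cell(coh, correct)
    if len(idx) < k:
        raise InsufficientPoolError(
            f"cell (|coh|={coh}, {'correct' if correct else 'error'}) has "
            f"{len(idx)} entries, fewer than k={k}"
        )
    return _knn_cell_mean(pool.rt_s, pool.rating, idx, rt, k)


def loo_variance_explained(
    pool: ConfidencePool,
    k_correct: int = K_CORRECT_DEFAULT,
    k_error: int = K_ERROR_DEFAULT,
    small_cell: str = "strict",
) -> float:
    """Leave-one-out fraction of rating variance explained by the k-NN rule.

    Each entry's rating is predicted from its own cell with the entry
    removed; returns ``1 - SS_res / SS_tot`` over all entries (at most 1,
    unbounded below).  ``small_cell="shrink"`` lets undersized cells use
    all their remaining entries (cells with a single entry are skipped);
    the default is to raise, since a cell below k changes what "k-NN"
    means for it.
    """
    if small_cell not in ("strict", "shrink"):
        raise ValueError("small_cell must be 'strict' or 'shrink'")
    preds = np.full(len(pool), np.nan)
    for coh in np.unique(pool.coh_unsigned):
        for correct in (True, False):
            idx = pool.cell(coh, correct)
            if len(idx) == 0:
                continue
            k = k_correct if bool(_as_correct_class(coh, correct)) else k_error
            if len(idx) <= k:
                if small_cell == "strict":
                    raise InsufficientPoolError(
                        f"cell (|coh|={coh}, {'correct' if correct else 'error'}) needs "
                        f"more than k={k} entries for leave-one-out, has {len(idx)}"
                    )
                if len(idx) < 2:
                    continue
                k = len(idx) - 1
            rts, ratings = pool.rt_s[idx], pool.rating[idx]
            d = np.abs(rts[:, None] - rts[None, :])
            np.fill_diagonal(d, np.inf)
            # vectorized analogue of _knn_cell_mean's (distance, rt, index) order
            rank = np.lexsort(
                (np.broadcast_to(idx, d.shape), np.broadcast_to(rts, d.shape), d),
                axis=1,
            )[:, :k]
            preds[idx] = ratings[rank].mean(axis=1)
    m = np.isfinite(preds)
    resid = pool.rating[m] - preds[m]
    ss_tot = np.sum((pool.rating[m] - pool.rating[m].mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / ss_tot)


def annotate_conf_hat(
    trials: pd.DataFrame,
    pool: ConfidencePool | None = None,
    k_correct: int = K_CORRECT_DEFAULT,
    k_error: int = K_ERROR_DEFAULT,
    small_cell: str = "shrink",
) -> pd.DataFrame:
    """Add a ``conf_hat`` column interpolating D1st confidence on double trials.

    ``small_cell`` governs cells with fewer than k entries: ``"strict"``
    raises, ``"shrink"`` uses every entry available in the cell and, for an
    empty cell, borrows the nearest unsigned coherence with the same
    accuracy class (high-coherence error cells can be empty simply because
    such errors are rare).
    """
    if small_cell not in ("strict", "shrink"):
        raise ValueError("small_cell must be 'strict' or 'shrink'")
    pool = pool if pool is not None else ConfidencePool.from_trials(trials)
    out = trials.copy()
    out["conf_hat"] = np.nan
    dd = out[(out["trial_type"] == "double")].dropna(subset=["coh1", "rt1_s", "correct1"])
    coh_u = np.abs(dd["coh1"].to_numpy())
    correct = _as_correct_class(coh_u, dd["correct1"].to_numpy().astype(bool))
    rt = dd["rt1_s"].to_numpy()
    preds = np.empty(len(dd))
    for coh in np.unique(coh_u):
        for corr in (True, False):
            qmask = (coh_u == coh) & (correct == corr)
            if not qmask.any():
                continue
            k = k_correct if corr else k_error
            idx = pool.cell(coh, corr)
            if len(idx) < k:
                if small_cell == "strict":
                    raise InsufficientPoolError(
                        f"cell (|coh|={coh}, {'correct' if corr else 'error'}) has "
                        f"{len(idx)} entries, fewer than k={k}"
                    )
                if len(idx) == 0:
                    cohs_avail = np.unique(
                        pool.coh_unsigned[pool.correct == corr]
                    )
                    if len(cohs_avail) == 0:
                        raise InsufficientPoolError(
                            f"no pool entries at all for the "
                            f"{'correct' if corr else 'error'} class"
                        )
                    nearest = cohs_avail[np.argmin(np.abs(cohs_avail - coh))]
                    idx = pool.cell(nearest, corr)
                k = min(k, len(idx))
            for qi in np.flatnonzero(qmask):
                preds[qi] = _knn_cell_mean(pool.rt_s, pool.rating, idx, rt[qi], k)
    out.loc[dd.index, "conf_hat"] = preds
    return out
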