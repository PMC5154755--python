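"""Summary figures: psychometric, chronometric, confidence, and bound panels.

Each figure's backing summary table is also written as CSV so the plotted
numbers are reproducible byte-for-byte from the same input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["plot_summaries"]


def _psychometric(trials: pd.DataFrame) -> pd.DataFrame:
    dd = trials.dropna(subset=["coh1", "correct1"])
    g = dd.groupby(np.abs(dd["coh1"]))
    return pd.DataFrame({
        "coh_unsigned": g.size().index,
        "p_correct": g["correct1"].mean().to_numpy(),
        "n": g.size().to_numpy(),
    })


def _chronometric(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    first = trials.dropna(subset=["coh1", "rt1_s"])
    second = trials.dropna(subset=["coh2", "rt2_s"])
    for name, sub, coh, rt in (
        ("first", first, "coh1", "rt1_s"),
        ("second", second, "coh2", "rt2_s"),
    ):
        g = sub.groupby(np.abs(sub[coh]))[rt]
        rows.append(pd.DataFrame({
            "decision": name,
            "coh_unsigned": g.mean().index,
            "mean_rt_s": g.mean().to_numpy(),
            "sem_rt_s": (g.std() / np.sqrt(g.size())).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def _confidence(trials: pd.DataFrame) -> pd.DataFrame:
    sub = trials[trials["trial_type"].isin(["D1star", "D1catch"])]
    sub = sub.dropna(subset=["coh1", "confidence", "correct1"])
    g = sub.groupby([np.abs(sub["coh1"]), sub["correct1"]])["confidence"]
    out = g.mean().rename("mean_confidence").reset_index()
    out.columns = ["coh_unsigned", "correct", "mean_confidence"]
    return out


def plot_summaries(trials: pd.DataFrame, outdir, quantile_fit: pd.DataFrame | None = None) -> list[Path]:
    """Write the standard behavioral panels (PNG + backing CSV) to ``outdir``.

    Panels with no supporting data are skipped with a log warning.
    Returns the figure paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    panels = {
        "psychometric": _psychometric,
        "chronometric": _chronometric,
        "confidence_vs_coherence": _confidence,
    }
    for name, builder in panels.items():
        summary = builder(trials) if len(trials) else pd.DataFrame()
        if summary.empty:
            log.warning("no data for %s panel; skipped", name)
            continue
        summary.to_csv(outdir / f"{name}.csv", index=False)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        if name == "psychometric":
            ax.plot(summary["coh_unsigned"], summary["p_correct"], "o-")
            ax.set_ylabel("proportion correct (first decision)")
        elif name == "chronometric":
            for dec, sub in summary.groupby("decision"):
                ax.errorbar(sub["coh_unsigned"], sub["mean_rt_s"],
                            yerr=sub["sem_rt_s"], fmt="o-", label=dec)
            ax.legend(frameon=False)
            ax.set_ylabel("mean RT (s)")
        else:
            for corr, sub in summary.groupby("correct"):
                ax.plot(sub["coh_unsigned"], sub["mean_confidence"], "o-",
                        label="correct" if corr else "error")
            ax.legend(frameon=False)
            ax.set_ylabel("mean confidence rating")
        ax.set_xlabel("unsigned coherence")
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if quantile_fit is not None and len(quantile_fit):
        quantile_fit.to_csv(outdir / "bound_vs_confidence_quantile.csv", index=False)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.errorbar(quantile_fit["mean_conf"], quantile_fit["pct_change"],
                    yerr=quantile_fit["se_pct"], fmt="o")
        ax.set_xlabel("first-decision confidence (quantile mean)")
        ax.set_ylabel("% change in bound vs lowest quantile")
        fig.tight_layout()
        path = outdir / "bound_vs_confidence_quantile.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
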