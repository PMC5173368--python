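"""Figures: multi-scale correlograms and indicator-vs-area summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_correlogram", "plot_indicator_areas"]


def plot_correlogram(profile, title: str = "", path=None, ax=None):
    """Estimate per distance band with its 95% CI band and null expectation."""
    frame = profile.to_frame()
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    km = frame["band_m"] / 1000.0
    ax.fill_between(km, frame["ci_lo"], frame["ci_hi"], color="0.8",
                    label="95% CI")
    ax.plot(km, frame["estimate"], "k-", lw=1.5, label="estimate")
    ax.plot(km, frame["expected"], "k--", lw=1.0, label="null expectation")
    ax.set_xlabel("distance band (km)")
    ax.set_ylabel("Moran's I" if profile.stat == "moran" else "BB join count")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax


def plot_indicator_areas(ranking, table: pd.DataFrame, path=None):
    """Cave area by indicator count, colored by reported relevance.

    The vertical dashed line marks the median area of caves with three or
    more biodiversity indicators.
    """
    merged = ranking.table.join(table[["area_m2", "reported_relevance"]],
                                rsuffix="_t")
    merged = merged.dropna(subset=["score", "area_m2"])
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"maximal": "#b2182b", "high": "#ef8a62", "mid": "#67a9cf",
              "low": "#2166ac"}
    rng = np.random.default_rng(0)
    for cat, col in colors.items():
        sub = merged[merged["reported_relevance"] == cat]
        if len(sub) == 0:
            continue
        jitter = rng.uniform(-0.18, 0.18, size=len(sub))
        ax.scatter(np.log(sub["area_m2"]), sub["score"] + jitter, s=8,
                   color=col, alpha=0.6, label=cat)
    sel = merged["score"] >= 3
    if sel.any():
        med = float(np.log(merged.loc[sel, "area_m2"]).median())
        ax.axvline(med, ls="--", color="k", lw=1,
                   label="median log-area, score ≥ 3")
    ax.set_xlabel("log cave area (m²)")
    ax.set_ylabel("number of biodiversity indicators")
    ax.legend(frameon=False, fontsize=7, title="reported relevance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
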