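"""Summary plots: dose-response, time course, stacked region shares."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_dose_response(summary: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for treatment, sub in summary.groupby("treatment"):
        sub = sub.sort_values("dose_nM")
        ax.errorbar(
            sub["dose_nM"], sub["mean_I_bar"], yerr=sub["sd_I_bar"],
            marker="o", capsize=3, label=str(treatment),
        )
    ax.set_xlabel("dose (nM)")
    ax.set_ylabel(r"mean $\bar{I}$ per cell (a.u./px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_time_course(summary: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for treatment, sub in summary.groupby("treatment"):
        sub = sub.sort_values("time_min")
        ax.errorbar(
            sub["time_min"], sub["mean_I_bar"], yerr=sub["sd_I_bar"],
            marker="o", capsize=3, label=str(treatment),
        )
    ax.set_xlabel("time post-transfection (min)")
    ax.set_ylabel(r"mean $\bar{I}$ per cell (a.u./px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_region_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Stacked per-region percentage bars, one bar per condition row."""
    perc_cols = sorted(
        [c for c in summary.columns if c.startswith("mean_Perc_R")],
        key=lambda c: int(c.rsplit("R", 1)[1]),
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = None
    x = range(len(summary))
    for col in perc_cols:
        vals = summary[col].fillna(0.0)
        ax.bar(x, vals, bottom=bottom, label=col.removeprefix("mean_Perc_"))
        bottom = vals if bottom is None else bottom + vals
    labels = [
        f"{r.treatment}\n{r.dose_nM:g} nM, {r.time_min:g} min"
        for r in summary.itertuples()
    ]
    ax.set_xticks(list(x), labels, fontsize=7)
    ax.set_ylabel("share of cytoplasmic signal (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
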