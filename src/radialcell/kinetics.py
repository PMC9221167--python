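"""Condition-level aggregation: dose-response, time courses, contrasts.

Works on the long-format per-cell table produced by the features stage
(one row per cell x region, plus the per-cell columns repeated).  Dead
cells are excluded from every aggregate, mirroring the exclusion strategy
the per-cell viability flag automates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frames import ConfigurationError

GROUP_KEYS = ["treatment", "dose_nM", "time_min"]


@dataclass
class Contrast:
    """Fold change and Welch two-sided p-value between two cell samples."""

    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float
    n_a: int
    n_b: int


def cells_table(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long (cell x region) table to one row per cell."""
    cols = [c for c in ["frame", *GROUP_KEYS] if c in df.columns]
    return df.drop_duplicates(subset=cols + ["cell_id"]) if cols else df.drop_duplicates(
        subset=["cell_id"]
    )


def aggregate(df: pd.DataFrame, keys: list[str] | None = None) -> pd.DataFrame:
    """Per-condition mean and sample SD (n-1) of I_bar, and of Perc_Ri.

    ``df`` is the long per-cell/per-region table with a boolean ``viable``
    column.  Dead (and unclassifiable) cells are dropped; groups emptied by
    the exclusion are dropped with a warning.  SD for n = 1 is reported as
    0.0 (flagged via ``n_cells == 1``).
    """
    keys = keys or GROUP_KEYS
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise ConfigurationError(f"missing grouping columns: {missing}")
    viable = df[df["viable"] == True]  # noqa: E712  (NaN-safe)
    if viable.empty:
        raise ConfigurationError("no viable cells to aggregate")

    cells = cells_table(viable)
    grouped = cells.groupby(keys, dropna=False)["I_bar"]
    summary = grouped.agg(
        n_cells="count", mean_I_bar="mean", sd_I_bar=lambda s: s.std(ddof=1)
    ).reset_index()
    summary["sd_I_bar"] = summary["sd_I_bar"].fillna(0.0)

    if "Ri" in viable.columns:
        reg = (
            viable.groupby(keys + ["Ri"], dropna=False)["Perc_Ri"]
            .agg(mean_Perc="mean", sd_Perc=lambda s: s.std(ddof=1))
            .reset_index()
        )
        reg["sd_Perc"] = reg["sd_Perc"].fillna(0.0)
        wide = reg.pivot_table(
            index=keys, columns="Ri", values=["mean_Perc", "sd_Perc"]
        )
        wide.columns = [f"{a}_R{int(b)}" for a, b in wide.columns]
        summary = summary.merge(wide.reset_index(), on=keys, how="left")
    return summary


def dose_response(summaries: pd.DataFrame) -> pd.DataFrame:
    """Order condition summaries by dose at fixed treatment/time.

    Requires >= 2 doses; a missing dose-0 control is tolerated but flagged
    in the ``has_control`` attribute column.
    """
    if summaries["dose_nM"].nunique() < 2:
        raise ConfigurationError("dose_response needs >= 2 doses")
    out = summaries.sort_values("dose_nM").reset_index(drop=True)
    out.attrs["has_control"] = bool((out["dose_nM"] == 0).any())
    return out


def time_course(summaries: pd.DataFrame) -> pd.DataFrame:
    """Order summaries by time and attach per-region monotone-trend signs.

    The trend statistic per region is the sign of the Theil-Sen slope of
    mean Perc_Ri against time (stored in ``attrs["region_trends"]``).
    """
    if summaries["time_min"].nunique() < 2:
        raise ConfigurationError("time_course needs >= 2 time points")
    out = summaries.sort_values("time_min").reset_index(drop=True)
    trends: dict[str, int] = {}
    for col in out.columns:
        if col.startswith("mean_Perc_R"):
            y = out[col].to_numpy(dtype=float)
            t = out["time_min"].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() >= 2:
                slope, *_ = stats.theilslopes(y[ok], t[ok])
                trends[col.removeprefix("mean_Perc_")] = int(np.sign(slope))
    out.attrs["region_trends"] = trends
    return out


def contrast(values_a: np.ndarray, values_b: np.ndarray) -> Contrast:
    """Fold change of means + Welch two-sample two-sided t-test.

    Operates on per-cell values (I_bar, or Perc_Ri for regional
    contrasts), viable cells only — filter before calling.  Degenerate
    case: both arms constant and equal -> p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("contrast needs >= 2 cells per arm")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    fold = mean_a / mean_b if mean_b != 0 else np.inf
    return Contrast(
        mean_a=mean_a,
        mean_b=mean_b,
        fold_change=float(fold),
        p_value=p,
        n_a=a.size,
        n_b=b.size,
    )


def permutation_pvalue(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_resamples: int | str = "exact",
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of means.

    Cross-check for :func:`contrast`; exact enumeration for small samples.
    """
    res = stats.permutation_test(
        (np.asarray(values_a, float), np.asarray(values_b, float)),
        lambda x, y: np.mean(x) - np.mean(y),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=np.inf if n_resamples == "exact" else n_resamples,
        rng=seed,
    )
    return float(res.pvalue)
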