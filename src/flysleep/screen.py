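"""Screen statistics: per-line sleep means and ±3 SD outlier calls.

A chemical-mutagenesis screen assays sleep in a handful of flies per
mutagenized line; line means are approximately normal across the screen, and
candidate sleep mutants are the lines falling beyond mean ± 3 SD.  The
histogram read-out uses 25-min bins anchored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenResult", "aggregate_line_sleep", "call_screen_outliers"]


@dataclass
class ScreenResult:
    grand_mean: float
    grand_sd: float
    k_sd: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    table: pd.DataFrame  # line_id, n_flies, mean_sleep_min, z_score, call
    low_outliers: list[str] = field(default_factory=list)
    high_outliers: list[str] = field(default_factory=list)

    @property
    def low_cutoff(self) -> float:
        return self.grand_mean - self.k_sd * self.grand_sd

    @property
    def high_cutoff(self) -> float:
        return self.grand_mean + self.k_sd * self.grand_sd


def aggregate_line_sleep(
    summaries: pd.DataFrame,
    line_of_fly: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse per-fly-per-day sleep summaries to per-line means.

    ``summaries`` is the concatenation of :func:`flysleep.sleep.summarize_sleep`
    outputs (needs columns fly_id, total_sleep_min, and line_id unless
    ``line_of_fly`` supplies the assignment).  A fly's mean is over its
    (surviving) days; a line's mean is the unweighted mean over its flies.
    Returns columns (line_id, n_flies, mean_sleep_min).
    """
    df = summaries.copy()
    if line_of_fly is not None:
        unknown = set(df["fly_id"]) - set(line_of_fly)
        if unknown:
            raise ValueError(f"flies without line assignment: {sorted(unknown)[:5]}")
        df["line_id"] = df["fly_id"].map(line_of_fly)
    if df["line_id"].isna().any():
        raise ValueError("every fly must be assigned to exactly one line")
    per_line_check = df.groupby("fly_id")["line_id"].nunique()
    if (per_line_check > 1).any():
        bad = per_line_check[per_line_check > 1].index[0]
        raise ValueError(f"fly {bad!r} assigned to multiple lines")

    fly_means = (
        df.groupby(["line_id", "fly_id"])["total_sleep_min"].mean().reset_index()
    )
    lines = (
        fly_means.groupby("line_id")["total_sleep_min"]
        .agg(mean_sleep_min="mean", n_flies="count")
        .reset_index()[["line_id", "n_flies", "mean_sleep_min"]]
    )
    odd = lines[(lines["n_flies"] < 4) | (lines["n_flies"] > 8)]
    if len(odd):
        warnings.warn(
            f"{len(odd)} line(s) outside the expected 4-8 flies per line",
            stacklevel=2,
        )
    return lines


def call_screen_outliers(
    lines: pd.DataFrame,
    bin_min: float = 25.0,
    k_sd: float = 3.0,
    *,
    robust: bool = False,
) -> ScreenResult:
    """Call candidate mutant lines beyond mean ± k·SD of the line means.

    ``lines`` needs columns line_id and mean_sleep_min (as produced by
    :func:`aggregate_line_sleep`).  By default the SD is the n−1 sample SD
    over line means, outliers included — the raw screen read-out.  With
    ``robust`` the centre/scale are the median and the normal-consistent
    MAD (×1.4826), insensitive to the outliers being hunted.  Lines strictly
    below centre − k·scale are low (short-sleep) outliers, strictly above
    centre + k·scale high outliers; exact boundary ties are not called.
    """
    if len(lines) < 2:
        raise ValueError("need at least 2 lines to form a screen distribution")
    if len(lines) < 10:
        warnings.warn("fewer than 10 lines: SD estimate is unstable", stacklevel=2)
    means = lines["mean_sleep_min"].to_numpy(dtype=float)
    if robust:
        grand_mean = float(np.median(means))
        grand_sd = float(1.4826 * np.median(np.abs(means - grand_mean)))
    else:
        grand_mean = float(means.mean())
        grand_sd = float(means.std(ddof=1))
    if grand_sd == 0:
        warnings.warn("degenerate screen: all line means identical", stacklevel=2)
        z = np.zeros_like(means)
    else:
        z = (means - grand_mean) / grand_sd

    lo_cut = grand_mean - k_sd * grand_sd
    hi_cut = grand_mean + k_sd * grand_sd
    low = (means < lo_cut) & (grand_sd > 0)
    high = (means > hi_cut) & (grand_sd > 0)

    edges = np.arange(0.0, np.ceil(means.max() / bin_min) * bin_min + bin_min, bin_min)
    hist, _ = np.histogram(means, bins=edges)

    table = lines.copy()
    table["z_score"] = z
    table["call"] = np.where(low, "low", np.where(high, "high", "none"))
    return ScreenResult(
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        k_sd=k_sd,
        hist_edges=edges,
        hist_counts=hist,
        table=table,
        low_outliers=list(table.loc[low, "line_id"]),
        high_outliers=list(table.loc[high, "line_id"]),
    )
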