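"""Daily expression profiles: qPCR fold changes and western densitometry.

Transcript abundance is quantified by the comparative-Ct (ΔΔCt) method with
a reference gene (e.g. actin) as loading control; protein abundance comes
from band densitometry normalised to a loading band and anchored so the
value at a chosen Zeitgeber time (canonically ZT0) equals 1.  Profiles over
the day are screened for circular local maxima — sleep-associated proteins
can show two daily peaks, one for the siesta and one for night sleep —
and genotypes are compared on their replicate-level daily means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedProfile",
    "GenotypeComparison",
    "ddct_relative_expression",
    "normalize_densitometry",
    "detect_daily_peaks",
    "compare_genotype_levels",
]


@dataclass(frozen=True)
class NormalizedProfile:
    """Loading-normalised, anchor-scaled expression over one day."""

    timepoints_zt: tuple[float, ...]
    values: tuple[float, ...]  # anchor timepoint == 1 exactly
    anchor_zt: float

    def __post_init__(self) -> None:
        if len(self.timepoints_zt) != len(self.values):
            raise ValueError("timepoints and values must have equal length")

    @property
    def daily_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def peak_times(self) -> tuple[float, ...]:
        idx = detect_daily_peaks(np.asarray(self.values))
        return tuple(self.timepoints_zt[i] for i in idx)


@dataclass(frozen=True)
class GenotypeComparison:
    mean_a: float
    mean_b: float
    difference: float  # mean_b - mean_a
    p_value: float | None
    n_a: int
    n_b: int


def ddct_relative_expression(
    samples: pd.DataFrame, calibrator_sample: str
) -> pd.Series:
    """Comparative-Ct fold changes relative to a calibrator sample.

    ``samples`` needs columns ``sample``, ``ct_target`` and ``ct_reference``
    (reference-gene Ct, e.g. actin).  ΔCt = Ct_target − Ct_reference per
    sample; fold = 2^−(ΔCt − ΔCt_calibrator), so the calibrator's fold is
    exactly 1.  Samples with a missing reference Ct are dropped with a
    warning.
    """
    import warnings

    df = samples.copy()
    missing = df["ct_reference"].isna() | df["ct_target"].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} sample(s) without finite Ct values",
            stacklevel=2,
        )
        df = df[~missing]
    if calibrator_sample not in set(df["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    dct = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    dct.index = df["sample"].to_numpy()
    ddct = dct - dct.loc[calibrator_sample]
    return np.power(2.0, -ddct).rename("fold_change")


def normalize_densitometry(
    timepoints_zt: Sequence[float],
    raw: Sequence[float],
    loading: Sequence[float],
    anchor_zt: float = 0.0,
    *,
    anchor_value: float | None = None,
) -> NormalizedProfile:
    """Band intensity / loading control, rescaled so the anchor ZT equals 1.

    When genotypes share one blot, pass the *calibrator* lane's
    loading-normalised intensity as ``anchor_value`` so all profiles are on
    the calibrator's scale (its ZT0 ≡ 1) and between-genotype level
    differences survive normalisation; with the default the profile is
    anchored to its own ``anchor_zt`` point.
    """
    t = np.asarray(timepoints_zt, dtype=float)
    r = np.asarray(raw, dtype=float)
    l = np.asarray(loading, dtype=float)
    if not (t.size == r.size == l.size):
        raise ValueError("timepoints, raw and loading must have equal length")
    if (r <= 0).any() or (l <= 0).any():
        raise ValueError("densitometry values must be strictly positive")
    where_anchor = np.nonzero(t == anchor_zt)[0]
    if where_anchor.size == 0:
        raise ValueError(f"anchor timepoint ZT{anchor_zt:g} not present")
    rel = r / l
    denom = anchor_value if anchor_value is not None else rel[where_anchor[0]]
    if denom <= 0:
        raise ValueError("anchor value must be strictly positive")
    rel = rel / denom
    return NormalizedProfile(tuple(t), tuple(rel), anchor_zt)


def detect_daily_peaks(values: np.ndarray) -> list[int]:
    """Indices of circular strict local maxima of a daily profile.

    The day wraps: the first and last timepoints are neighbours.  A peak is
    strictly greater than both circular neighbours, so constant profiles
    (and plateaus) yield no peaks.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 timepoints to call daily peaks")
    left = np.roll(v, 1)
    right = np.roll(v, -1)
    return [int(i) for i in np.nonzero((v > left) & (v > right))[0]]


def is_bimodal(values: np.ndarray, min_separation: int = 2) -> bool:
    """True when exactly two circular peaks are >= ``min_separation`` apart."""
    peaks = detect_daily_peaks(values)
    if len(peaks) != 2:
        return False
    n = len(values)
    gap = (peaks[1] - peaks[0]) % n
    return min(gap, n - gap) >= min_separation


def compare_genotype_levels(
    a: Sequence[NormalizedProfile], b: Sequence[NormalizedProfile]
) -> GenotypeComparison:
    """Compare overall expression between genotypes on replicate daily means.

    Each replicate contributes its mean over the day's timepoints; the test
    is a two-sample t-test on those replicate means (replicates, not
    timepoints, are the independent units).  With fewer than 2 replicates on
    either side only the descriptive difference is reported (p is None).
    """
    means_a = np.array([p.daily_mean for p in a], dtype=float)
    means_b = np.array([p.daily_mean for p in b], dtype=float)
    if means_a.size == 0 or means_b.size == 0:
        raise ValueError("both genotypes need at least one replicate")
    mean_a, mean_b = float(means_a.mean()), float(means_b.mean())
    p: float | None
    if means_a.size < 2 or means_b.size < 2:
        p = None
    elif np.ptp(means_a) == 0 and np.ptp(means_b) == 0:
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        p = float(stats.ttest_ind(means_a, means_b).pvalue)
    return GenotypeComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        difference=mean_b - mean_a,
        p_value=p,
        n_a=means_a.size,
        n_b=means_b.size,
    )
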