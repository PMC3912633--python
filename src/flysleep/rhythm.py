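"""Circadian rhythmicity in constant darkness via the periodogram.

Free-running rest:activity rhythms are scored from DD days of an activity
trace: counts are binned to 30 min, linearly detrended, and the discrete
Fourier power spectrum is computed on a zero-padded grid.  The rhythmicity
statistic ("FFT value") is the share of total non-DC spectral power carried
by the peak frequency inside the circadian band (periods 18–30 h); a fly is
called rhythmic when that share exceeds 0.01.  A secondary 10–14 h band
flags flies whose bimodal (morning/evening) activity persists in DD as an
apparent ~12 h rhythm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import detrend

from .dam import MINUTES_PER_DAY, ActivityTrace, rebin_counts

__all__ = [
    "RhythmResult",
    "CohortRhythm",
    "fft_rhythm",
    "cohort_rhythm_table",
    "plot_double_actogram",
]

CIRCADIAN_BAND_H = (18.0, 30.0)
TWELVE_HOUR_BAND_H = (10.0, 14.0)


@dataclass(frozen=True)
class RhythmResult:
    fly_id: str
    period_h: float | None
    fft_value: float
    rhythmic: bool
    twelve_hour: bool


@dataclass(frozen=True)
class CohortRhythm:
    n_total: int
    n_rhythmic: int
    percent_rhythmic: float
    mean_period_h: float | None
    sem_period_h: float | None
    mean_fft: float | None
    sem_fft: float | None

    def format_rhythmicity(self) -> str:
        """Render like a genotype table row, e.g. ``"93.8% (30/32)"``."""
        return f"{self.percent_rhythmic:.1f}% ({self.n_rhythmic}/{self.n_total})"


def _band_peak(power: np.ndarray, periods_h: np.ndarray, band: tuple[float, float]):
    """(peak power, peak period) within a period band; (0, None) if empty."""
    sel = (periods_h >= band[0]) & (periods_h <= band[1])
    if not sel.any():
        return 0.0, None
    idx = np.nonzero(sel)[0]
    best = idx[np.argmax(power[idx])]
    return float(power[best]), float(periods_h[best])


def fft_rhythm(
    trace: ActivityTrace,
    dd_day_range: tuple[int, int] = (3, 11),
    threshold: float = 0.01,
    analysis_bin_min: int = 30,
    pad_factor: int = 4,
) -> RhythmResult:
    """Classify one fly's DD rhythmicity and estimate its period.

    ``dd_day_range`` selects DD days (1-based, inclusive) counted from the
    first constant-darkness day of the trace's schedule; the default (3, 11)
    analyses nine days, skipping the first two DD days of transients.

    The spectrum is computed from 30-min bins after linear detrending, zero-
    padded to the next power of two at or above ``pad_factor`` times the
    sample count so the period grid near 24 h is finer than the Rayleigh
    resolution.  ``fft_value`` is invariant to scaling the counts.
    """
    lo, hi = dd_day_range
    if hi < lo:
        raise ValueError("dd_day_range must be (first, last) with first <= last")
    n_days = hi - lo + 1
    if n_days < 3:
        raise ValueError("need at least 3 days of DD data for a spectrum")
    dd0 = trace.schedule.first_dd_day()
    if dd0 is None:
        raise ValueError("trace schedule has no DD days")
    first_day = dd0 + (lo - 1)
    last_day = dd0 + (hi - 1)
    if last_day >= trace.n_days:
        raise ValueError(
            f"requested DD days {dd_day_range} extend past the trace "
            f"({trace.n_days} days recorded)"
        )

    binned = rebin_counts(trace, analysis_bin_min)
    per_day = MINUTES_PER_DAY // analysis_bin_min
    x = binned.counts[first_day * per_day : (last_day + 1) * per_day].astype(float)
    x = detrend(x, type="linear")

    n = x.size
    nfft = 1 << max(int(math.ceil(math.log2(pad_factor * n))), 1)
    spec = np.fft.rfft(x, n=nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=analysis_bin_min / 60.0)  # cycles per hour
    nonzero = freqs > 0
    total = float(power[nonzero].sum())
    periods_h = np.full_like(freqs, np.inf)
    periods_h[nonzero] = 1.0 / freqs[nonzero]

    circ_pow, circ_per = _band_peak(power, periods_h, CIRCADIAN_BAND_H)
    twelve_pow, twelve_per = _band_peak(power, periods_h, TWELVE_HOUR_BAND_H)

    fft_value = circ_pow / total if total > 0 else 0.0
    rhythmic = fft_value > threshold
    twelve_hour = twelve_pow > circ_pow
    if rhythmic:
        period = circ_per
    elif twelve_hour:
        period = twelve_per
    else:
        period = None
    return RhythmResult(trace.fly_id, period, fft_value, rhythmic, twelve_hour)


def cohort_rhythm_table(results: Sequence[RhythmResult]) -> CohortRhythm:
    """Summarise a genotype cohort: % rhythmic plus period/FFT means ± SEM.

    Period and FFT statistics are over rhythmic flies only; SEM uses the n−1
    sample SD.  With a single rhythmic fly the SEM is undefined (None).
    """
    results = list(results)
    if not results:
        raise ValueError("empty cohort")
    n_total = len(results)
    rhythmic = [r for r in results if r.rhythmic]
    n_r = len(rhythmic)

    def mean_sem(vals: list[float]):
        if not vals:
            return None, None
        m = float(np.mean(vals))
        if len(vals) < 2:
            return m, None
        return m, float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    mean_p, sem_p = mean_sem([r.period_h for r in rhythmic if r.period_h is not None])
    mean_f, sem_f = mean_sem([r.fft_value for r in rhythmic])
    return CohortRhythm(
        n_total=n_total,
        n_rhythmic=n_r,
        percent_rhythmic=100.0 * n_r / n_total,
        mean_period_h=mean_p,
        sem_period_h=sem_p,
        mean_fft=mean_f,
        sem_fft=sem_f,
    )


def plot_double_actogram(trace: ActivityTrace, ax=None, bin_min: int = 30):
    """Double-plotted actogram: each row shows two consecutive days.

    Plotting utility only; returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    binned = rebin_counts(trace, bin_min)
    per_day = MINUTES_PER_DAY // bin_min
    days = binned.counts.reshape(binned.n_days, per_day)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * max(binned.n_days - 1, 1)))
    peak = days.max() or 1
    for row in range(binned.n_days - 1):
        pair = np.concatenate([days[row], days[row + 1]]) / peak
        xs = np.arange(pair.size) * bin_min / 60.0
        ax.bar(xs, pair * 0.9, width=bin_min / 60.0, bottom=-row, align="edge",
               color="k")
    ax.set_xlim(0, 48)
    ax.set_xlabel("time (h, double-plotted)")
    ax.set_yticks([])
    ax.set_title(trace.fly_id)
    return ax
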