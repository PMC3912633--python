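"""Sleep scoring and architecture metrics from beam-break activity.

Fly sleep is operationally defined as a run of behavioral quiescence of at
least five consecutive minutes without a beam crossing.  This module finds
those runs (bouts), summarises per-day sleep architecture (total, daytime and
night-time sleep, episode counts and durations, activity index), builds
population sleep profiles, and quantifies mechanical sleep deprivation and
the morning rebound that follows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dam import MINUTES_PER_DAY, ActivityTrace, to_zeitgeber

__all__ = [
    "SleepBout",
    "DeprivationResult",
    "detect_sleep_bouts",
    "sleep_mask",
    "summarize_sleep",
    "activity_index",
    "sleep_profile",
    "deprivation_metrics",
]

DAY_PHASE = "daytime"
NIGHT_PHASE = "nighttime"


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= threshold consecutive zero-count minutes."""

    start_min: int
    duration_min: int
    day_index: int
    phase: str  # phase of the bout's *start*; minutes are re-split for accounting

    @property
    def end_min(self) -> int:  # exclusive
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class DeprivationResult:
    sleep_lost_min: float
    rebound_gain_min: float
    deprivation_efficacy: float | None  # None when baseline-window sleep is 0


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of zeros."""
    iszero = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    edges = np.diff(iszero)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_sleep_bouts(
    trace: ActivityTrace, min_inactive_min: int = 5
) -> list[SleepBout]:
    """Score sleep bouts: maximal zero-count runs of length >= the threshold.

    Requires minute-resolution bins — the 5-min rule is meaningless on
    coarser data.  Bouts are maximal: extending any bout by one minute in
    either direction hits a nonzero count or the trace edge.
    """
    if min_inactive_min < 1:
        raise ValueError("min_inactive_min must be >= 1")
    if trace.bin_minutes > 1:
        raise ValueError(
            f"bout detection needs <= 1-min bins, trace has {trace.bin_minutes}"
        )
    day_len = trace.schedule.lights_off_zt_min
    bouts = []
    for start, length in _zero_runs(trace.counts):
        if length < min_inactive_min:
            continue
        day, zt = to_zeitgeber(trace, start)
        phase = DAY_PHASE if zt < day_len else NIGHT_PHASE
        bouts.append(SleepBout(start, length, day, phase))
    return bouts


def sleep_mask(trace: ActivityTrace, bouts: Sequence[SleepBout]) -> np.ndarray:
    """Boolean minute mask: True where the fly is asleep (inside a bout)."""
    mask = np.zeros(trace.counts.size, dtype=bool)
    for b in bouts:
        mask[b.start_min : b.end_min] = True
    return mask


def _check_bouts_match(trace: ActivityTrace, bouts: Sequence[SleepBout]) -> None:
    for b in bouts:
        if b.end_min > trace.counts.size:
            raise ValueError("bouts do not fit the trace (mismatched inputs?)")
        if trace.counts[b.start_min : b.end_min].any():
            raise ValueError("bout covers nonzero counts; trace/bout mismatch")


def summarize_sleep(
    trace: ActivityTrace,
    bouts: Sequence[SleepBout],
    *,
    exclude_dead: bool = True,
) -> pd.DataFrame:
    """Per-day sleep architecture table.

    Columns: day, total_sleep_min, day_sleep_min, night_sleep_min,
    n_episodes_day, n_episodes_night, mean_episode_min_day,
    mean_episode_min_night, activity_index.  Sleep minutes are attributed to
    the phase they fall in (a bout crossing ZT12 is split), while the episode
    itself is counted once, in the phase of its start.  Episode means are NaN
    when the episode count is zero.  Days in ``trace.excluded_days`` — and,
    with ``exclude_dead``, days after the fly's last activity — are omitted.
    """
    _check_bouts_match(trace, bouts)
    mask = sleep_mask(trace, bouts)
    idx = np.arange(trace.counts.size)
    absolute = trace.zt_offset_min + idx * trace.bin_minutes
    day_of = absolute // MINUTES_PER_DAY
    zt_of = absolute % MINUTES_PER_DAY
    is_day_phase = zt_of < trace.schedule.lights_off_zt_min

    skip = set(trace.excluded_days)
    if exclude_dead:
        skip |= set(range(trace.alive_through + 1, trace.n_days))

    rows = []
    for day in range(trace.n_days):
        if day in skip:
            continue
        in_day = day_of == day
        asleep = mask & in_day
        day_sleep = int((asleep & is_day_phase).sum())
        night_sleep = int((asleep & ~is_day_phase).sum())
        day_eps = [b for b in bouts if b.day_index == day and b.phase == DAY_PHASE]
        night_eps = [b for b in bouts if b.day_index == day and b.phase == NIGHT_PHASE]
        waking = in_day & ~mask
        n_waking = int(waking.sum())
        rows.append(
            {
                "fly_id": trace.fly_id,
                "line_id": trace.line_id,
                "day": day,
                "total_sleep_min": day_sleep + night_sleep,
                "day_sleep_min": day_sleep,
                "night_sleep_min": night_sleep,
                "n_episodes_day": len(day_eps),
                "n_episodes_night": len(night_eps),
                "mean_episode_min_day": (
                    float(np.mean([b.duration_min for b in day_eps]))
                    if day_eps
                    else math.nan
                ),
                "mean_episode_min_night": (
                    float(np.mean([b.duration_min for b in night_eps]))
                    if night_eps
                    else math.nan
                ),
                "activity_index": (
                    float(trace.counts[waking].sum() / n_waking)
                    if n_waking
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def activity_index(trace: ActivityTrace, bouts: Sequence[SleepBout]) -> float:
    """Mean beam crossings per waking minute over the whole trace.

    Counts inside bouts are zero by construction, so the numerator equals the
    trace's total counts; the denominator is the number of non-bout minutes.
    NaN if the fly slept the entire span.
    """
    _check_bouts_match(trace, bouts)
    waking = ~sleep_mask(trace, bouts)
    n = int(waking.sum())
    if n == 0:
        return math.nan
    return float(trace.counts[waking].sum() / n)


def sleep_profile(
    traces: Iterable[ActivityTrace],
    profile_bin_min: int = 30,
    min_inactive_min: int = 5,
    *,
    exclude_dead: bool = True,
) -> pd.DataFrame:
    """Population sleep profile: per-ZT-bin mean sleep fraction ± SEM.

    Each fly-day contributes, per ZT bin, the fraction of its minutes spent
    asleep; mean and SEM (n−1 denominator) are over fly-days.  Returns
    columns (zt_bin_min, mean, sem, n).
    """
    if MINUTES_PER_DAY % profile_bin_min:
        raise ValueError("profile_bin_min must divide 1440")
    n_bins = MINUTES_PER_DAY // profile_bin_min
    flyday_rows = []
    for trace in traces:
        bouts = detect_sleep_bouts(trace, min_inactive_min)
        mask = sleep_mask(trace, bouts).astype(float)
        skip = set(trace.excluded_days)
        if exclude_dead:
            skip |= set(range(trace.alive_through + 1, trace.n_days))
        per_day = mask.reshape(trace.n_days, MINUTES_PER_DAY)
        for day in range(trace.n_days):
            if day in skip:
                continue
            frac = per_day[day].reshape(n_bins, profile_bin_min).mean(axis=1)
            flyday_rows.append(frac)
    if len(flyday_rows) < 2:
        raise ValueError("sleep_profile needs at least two fly-days")
    arr = np.vstack(flyday_rows)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
    return pd.DataFrame(
        {
            "zt_bin_min": np.arange(n_bins) * profile_bin_min,
            "mean": mean,
            "sem": sem,
            "n": arr.shape[0],
        }
    )


def _window_sleep_min(
    trace: ActivityTrace,
    day: int,
    window_zt_h: tuple[float, float],
    min_inactive_min: int,
) -> float:
    """Sleep minutes of ``trace`` on ``day`` within the ZT-hour window."""
    bouts = detect_sleep_bouts(trace, min_inactive_min)
    mask = sleep_mask(trace, bouts)
    lo = day * MINUTES_PER_DAY + int(window_zt_h[0] * 60) - trace.zt_offset_min
    hi = day * MINUTES_PER_DAY + int(window_zt_h[1] * 60) - trace.zt_offset_min
    lo, hi = max(lo, 0), min(hi, mask.size)
    return float(mask[lo:hi].sum())


def deprivation_metrics(
    baseline: ActivityTrace,
    deprived: ActivityTrace,
    sd_day: int,
    *,
    sd_window_zt_h: tuple[float, float] = (18.0, 24.0),
    rebound_window_zt_h: tuple[float, float] = (0.0, 5.0),
    min_inactive_min: int = 5,
) -> DeprivationResult:
    """Quantify mechanical sleep deprivation and the next-morning rebound.

    The stimulation window (default ZT18–24) is read on ``sd_day`` of the
    deprived trace; the rebound window (default ZT0–5) on ``sd_day + 1``.
    Baseline values are the per-day means of the same windows on the
    unperturbed baseline trace.

    ``sleep_lost_min`` = baseline window sleep − SD window sleep;
    ``rebound_gain_min`` = post-SD rebound sleep − baseline rebound sleep;
    ``deprivation_efficacy`` = lost / baseline window sleep (None if the
    baseline window had no sleep).
    """
    if sd_window_zt_h[1] <= sd_window_zt_h[0]:
        raise ValueError("sd window must be a forward ZT interval")
    if sd_day + 1 >= deprived.n_days:
        raise ValueError("deprived trace must include the day after SD")

    base_sd = float(
        np.mean(
            [
                _window_sleep_min(baseline, d, sd_window_zt_h, min_inactive_min)
                for d in range(baseline.n_days)
            ]
        )
    )
    base_reb = float(
        np.mean(
            [
                _window_sleep_min(baseline, d, rebound_window_zt_h, min_inactive_min)
                for d in range(baseline.n_days)
            ]
        )
    )
    sd_sleep = _window_sleep_min(deprived, sd_day, sd_window_zt_h, min_inactive_min)
    reb_sleep = _window_sleep_min(
        deprived, sd_day + 1, rebound_window_zt_h, min_inactive_min
    )
    lost = base_sd - sd_sleep
    gain = reb_sleep - base_reb
    efficacy = lost / base_sd if base_sd > 0 else None
    return DeprivationResult(lost, gain, efficacy)
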