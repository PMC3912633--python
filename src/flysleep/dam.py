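"""Trikinetics DAM (Drosophila Activity Monitor) ingestion and time arithmetic.

A DAM monitor records, once per minute, the number of infrared beam crossings
for each of 32 flies housed in activity tubes.  Everything downstream —
sleep scoring, the screen, rhythmicity — consumes :class:`ActivityTrace`
objects produced here.  Time is handled in Zeitgeber coordinates: ZT0 is
lights-on, ZT12 lights-off in a 12:12 light:dark (LD) cycle, and in constant
darkness (DD) the entrained schedule is projected forward so circadian time
stays aligned with the prior LD phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LightSchedule",
    "ActivityTrace",
    "ReadReport",
    "DamFormatError",
    "read_dam_monitor",
    "write_dam_monitor",
    "rebin_counts",
    "to_zeitgeber",
    "trace_to_tidy",
]

MINUTES_PER_DAY = 1440


class DamFormatError(ValueError):
    """Raised for malformed monitor files (bad timestamps, gaps, shape)."""


def _parse_clock(clock: str) -> int:
    """``"HH:MM"`` -> minutes after midnight."""
    hh, mm = clock.split(":")
    m = int(hh) * 60 + int(mm)
    if not 0 <= m < MINUTES_PER_DAY:
        raise ValueError(f"clock time out of range: {clock!r}")
    return m


@dataclass(frozen=True)
class LightSchedule:
    """Light regime of an experiment, day by day.

    Parameters
    ----------
    lights_on
        Clock time of ZT0 as ``"HH:MM"``.
    regime
        One label per experimental day, each ``"LD"`` or ``"DD"``.  Once DD
        starts it must persist: flies are not re-entrained mid-recording.
    photoperiod_h
        Hours of light per LD day; 12 in a standard 12:12 cycle.
    """

    lights_on: str = "08:00"
    regime: tuple[str, ...] = ("LD",) * 5
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        _parse_clock(self.lights_on)
        if not 0 < self.photoperiod_h < 24:
            raise ValueError("photoperiod_h must lie in (0, 24)")
        if not self.regime:
            raise ValueError("regime must name at least one day")
        seen_dd = False
        for label in self.regime:
            if label not in ("LD", "DD"):
                raise ValueError(f"regime labels must be 'LD' or 'DD', got {label!r}")
            if label == "DD":
                seen_dd = True
            elif seen_dd:
                raise ValueError("LD after DD is not allowed (no re-entrainment)")

    @property
    def lights_on_min(self) -> int:
        return _parse_clock(self.lights_on)

    @property
    def n_days(self) -> int:
        return len(self.regime)

    @property
    def lights_off_zt_min(self) -> int:
        return int(round(self.photoperiod_h * 60))

    def first_dd_day(self) -> int | None:
        """Index of the first DD day, or None if the experiment is all LD."""
        for i, label in enumerate(self.regime):
            if label == "DD":
                return i
        return None

    def with_days(self, n_ld: int, n_dd: int) -> "LightSchedule":
        return replace(self, regime=("LD",) * n_ld + ("DD",) * n_dd)


@dataclass
class ActivityTrace:
    """One fly's beam-crossing counts plus schedule metadata.

    ``counts`` holds non-negative integers, one per ``bin_minutes`` bin,
    spanning whole Zeitgeber days (the canonical bin is 1 minute).
    ``excluded_days`` marks ZT-days dropped by a gap policy or dead-fly
    truncation; summary code must skip them.
    """

    fly_id: str
    line_id: str
    start: datetime
    bin_minutes: int
    counts: np.ndarray
    schedule: LightSchedule
    excluded_days: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_minutes < 1:
            raise ValueError("bin_minutes must be >= 1")
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        span = self.counts.size * self.bin_minutes
        if span == 0 or span % MINUTES_PER_DAY:
            raise ValueError(
                f"trace must span whole days; got {span} minutes"
            )

    @property
    def n_days(self) -> int:
        return self.counts.size * self.bin_minutes // MINUTES_PER_DAY

    @property
    def zt_offset_min(self) -> int:
        """ZT minute of the first bin (0 when the trace starts at lights-on)."""
        start_min = self.start.hour * 60 + self.start.minute
        return (start_min - self.schedule.lights_on_min) % MINUTES_PER_DAY

    @property
    def alive_through(self) -> int:
        """Last day index with any beam crossings (-1 if the fly never moved)."""
        per_day = self.counts.reshape(self.n_days, -1).sum(axis=1)
        active = np.nonzero(per_day)[0]
        return int(active[-1]) if active.size else -1

    def flag_dead_days(self) -> "ActivityTrace":
        """Exclude trailing all-zero days (>= 24 h of silence == dead fly)."""
        last = self.alive_through
        if last >= self.n_days - 1:
            return self
        dead = frozenset(range(last + 1, self.n_days))
        return replace(self, excluded_days=self.excluded_days | dead)

    def day_slice(self, day: int) -> np.ndarray:
        per_day = MINUTES_PER_DAY // self.bin_minutes
        return self.counts[day * per_day : (day + 1) * per_day]


@dataclass(frozen=True)
class ReadReport:
    rows_parsed: int
    rows_dropped: int
    gaps_filled: int = 0
    days_dropped: tuple[int, ...] = ()


def to_zeitgeber(trace: ActivityTrace, minute_index: int) -> tuple[int, int]:
    """Map a bin index of ``trace`` to ``(day_index, ZT_minutes)``.

    ZT0 is lights-on; in DD the entrained cycle is projected forward, so the
    returned phase doubles as circadian time (CT).
    """
    if not 0 <= minute_index < trace.counts.size:
        raise IndexError(
            f"minute_index {minute_index} out of range [0, {trace.counts.size})"
        )
    absolute = trace.zt_offset_min + minute_index * trace.bin_minutes
    return absolute // MINUTES_PER_DAY, absolute % MINUTES_PER_DAY


def rebin_counts(trace: ActivityTrace, new_bin_minutes: int) -> ActivityTrace:
    """Sum counts into coarser bins; the total count is conserved exactly."""
    if new_bin_minutes == trace.bin_minutes:
        return trace
    if new_bin_minutes % trace.bin_minutes or MINUTES_PER_DAY % new_bin_minutes:
        raise ValueError(
            f"new bin {new_bin_minutes} must be a multiple of {trace.bin_minutes} "
            "and divide 1440"
        )
    factor = new_bin_minutes // trace.bin_minutes
    summed = trace.counts.reshape(-1, factor).sum(axis=1)
    return replace(trace, bin_minutes=new_bin_minutes, counts=summed)


# ---------------------------------------------------------------------------
# Monitor file dialect
#
# The common Trikinetics layout is tab-separated with a reading index, date
# ("1 Jan 14"), time ("HH:MM:SS"), a status code, further bookkeeping columns,
# and finally 32 count columns (channels 1..32).  We locate the counts as the
# trailing 32 columns so minor dialect variants parse unchanged.
# ---------------------------------------------------------------------------

N_CHANNELS = 32
_DATE_FMT = "%d %b %y"


def read_dam_monitor(
    path,
    channel_map: Mapping[int, tuple[str, str]],
    schedule: LightSchedule,
    *,
    gap_policy: str | None = None,
) -> tuple[list[ActivityTrace], ReadReport]:
    """Read a Trikinetics monitor file into per-fly :class:`ActivityTrace`.

    Parameters
    ----------
    channel_map
        ``{channel (1..32): (fly_id, line_id)}`` — only mapped channels
        produce traces.
    gap_policy
        ``None`` (gaps are a hard error), ``"zeros"`` (missing minutes are
        zero-filled) or ``"drop-day"`` (zero-filled, and the affected ZT-day
        is excluded from every trace).

    Returns the traces plus a :class:`ReadReport`.  Partial leading/trailing
    days (relative to lights-on) are trimmed so every trace spans whole
    Zeitgeber days.
    """
    bad = set(channel_map) - set(range(1, N_CHANNELS + 1))
    if bad:
        raise ValueError(f"channel_map keys must be in 1..32, got {sorted(bad)}")
    if gap_policy not in (None, "zeros", "drop-day"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")

    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < N_CHANNELS + 3:
        raise DamFormatError(
            f"expected >= {N_CHANNELS + 3} tab-separated columns, got {df.shape[1]}"
        )
    rows_parsed = len(df)
    stamps = pd.to_datetime(
        df.iloc[:, 1].str.strip() + " " + df.iloc[:, 2].str.strip(),
        format=_DATE_FMT + " %H:%M:%S",
    )
    counts = df.iloc[:, -N_CHANNELS:].astype(np.int64).to_numpy()

    deltas = stamps.diff().dt.total_seconds().iloc[1:] / 60.0
    nonpos = np.nonzero(deltas.to_numpy() <= 0)[0]
    if nonpos.size:
        row = int(nonpos[0]) + 1
        raise DamFormatError(
            f"non-monotonic timestamp at row {row + 1}: {stamps.iloc[row]}"
        )

    # Regularise onto a 1-min grid from first to last stamp.
    t0, t1 = stamps.iloc[0], stamps.iloc[-1]
    n_grid = int((t1 - t0).total_seconds() // 60) + 1
    grid_pos = ((stamps - t0).dt.total_seconds() // 60).astype(int).to_numpy()
    gaps_filled = n_grid - rows_parsed
    if gaps_filled and gap_policy is None:
        miss = np.setdiff1d(np.arange(n_grid), grid_pos)[0]
        raise DamFormatError(
            f"gap in recording at {t0 + timedelta(minutes=int(miss))}; "
            "set gap_policy='zeros' or 'drop-day'"
        )
    full = np.zeros((n_grid, N_CHANNELS), dtype=np.int64)
    full[grid_pos] = counts
    missing_mask = np.ones(n_grid, dtype=bool)
    missing_mask[grid_pos] = False

    # Trim to whole ZT days: first grid minute at ZT0.
    start_min = t0.hour * 60 + t0.minute
    offset = (schedule.lights_on_min - start_min) % MINUTES_PER_DAY
    usable = n_grid - offset
    n_days = usable // MINUTES_PER_DAY
    if n_days < 1:
        raise DamFormatError("fewer than one whole Zeitgeber day of data")
    lo, hi = offset, offset + n_days * MINUTES_PER_DAY
    full = full[lo:hi]
    missing_mask = missing_mask[lo:hi]
    rows_dropped = (lo) + (n_grid - hi)
    start = (t0 + timedelta(minutes=int(offset))).to_pydatetime()

    dropped_days: tuple[int, ...] = ()
    if gap_policy == "drop-day" and missing_mask.any():
        per_day = missing_mask.reshape(n_days, MINUTES_PER_DAY).any(axis=1)
        dropped_days = tuple(int(d) for d in np.nonzero(per_day)[0])

    traces = [
        ActivityTrace(
            fly_id=fly,
            line_id=line,
            start=start,
            bin_minutes=1,
            counts=full[:, ch - 1].copy(),
            schedule=schedule,
            excluded_days=frozenset(dropped_days),
        )
        for ch, (fly, line) in sorted(channel_map.items())
    ]
    report = ReadReport(rows_parsed, rows_dropped, gaps_filled, dropped_days)
    return traces, report


def write_dam_monitor(traces: Sequence[ActivityTrace], path) -> None:
    """Write traces (<= 32, equal length/start, 1-min bins) in monitor format.

    Channels are assigned in order; unmapped channels are zero columns.
    ``read_dam_monitor`` on the result reproduces the traces (round-trip).
    """
    if not traces:
        raise ValueError("no traces to write")
    if len(traces) > N_CHANNELS:
        raise ValueError("a monitor file holds at most 32 channels")
    first = traces[0]
    if any(
        t.bin_minutes != 1 or t.counts.size != first.counts.size or t.start != first.start
        for t in traces
    ):
        raise ValueError("traces must share start, length and 1-min bins")
    n = first.counts.size
    mat = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, t in enumerate(traces):
        mat[:, ch] = t.counts
    stamps = [first.start + timedelta(minutes=i) for i in range(n)]
    with open(path, "w") as fh:
        for i, ts in enumerate(stamps):
            meta = [
                str(i + 1),
                ts.strftime(_DATE_FMT).lstrip("0"),
                ts.strftime("%H:%M:%S"),
                "1",
            ] + ["0"] * 6
            fh.write("\t".join(meta + [str(int(c)) for c in mat[i]]) + "\n")


def trace_to_tidy(trace: ActivityTrace) -> pd.DataFrame:
    """Long-format view: one row per bin with (fly_id, line_id, day, ZT_min, count)."""
    idx = np.arange(trace.counts.size)
    absolute = trace.zt_offset_min + idx * trace.bin_minutes
    return pd.DataFrame(
        {
            "fly_id": trace.fly_id,
            "line_id": trace.line_id,
            "day": absolute // MINUTES_PER_DAY,
            "ZT_min": absolute % MINUTES_PER_DAY,
            "count": trace.counts,
        }
    )
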