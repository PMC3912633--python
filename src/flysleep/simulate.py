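"""Synthetic data with known ground truth for every pipeline input.

Four generators emulate the statistical structure of a forward-genetic sleep
screen:

* activity traces with wild-type or short-sleep architecture (shorter bouts,
  more night episodes, partially dominant heterozygotes), optional
  free-running period and deprivation/rebound perturbations;
* a screen of many mutagenized lines with approximately normal line means
  and planted outlier mutants;
* recombinant progeny over an ordered marker map under a Haldane
  (no-interference) crossover model;
* a mutagenized genome: isogenic background variants shared by mutant and
  parental strains, EMS-induced mutations private to the mutant, a planted
  causal missense change, and coverage-dependent per-strain detection.

All generators are seed-deterministic and return machine-readable truth
alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dam import MINUTES_PER_DAY, ActivityTrace, LightSchedule, write_dam_monitor
from .mapping import (
    MARKER_ALLELE,
    MUTANT_ALLELE,
    PHENO_MUTANT,
    PHENO_NON_MUTANT,
    CrossRecord,
    GenomicInterval,
    Marker,
    MarkerMap,
)
from .variants import GeneModelSet, Transcript, Variant, annotate_coding_effect

__all__ = [
    "ActivitySimConfig",
    "simulate_activity",
    "simulate_cohort",
    "simulate_deprivation_pair",
    "simulate_screen_line_means",
    "simulate_screen_dataset",
    "CrossSimConfig",
    "simulate_recombinants",
    "GenomeSimConfig",
    "SimulatedGenome",
    "simulate_mutagenized_genome",
    "write_genome_files",
]

_EPOCH = datetime(2014, 1, 6, 8, 0)  # arbitrary fixed start at lights-on


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivitySimConfig:
    """Sleep-architecture generator settings.

    Defaults produce a wild-type female profile: ~4 siesta bouts of ~50 min
    in a mid-day window and ~5 night bouts of ~90 min, scoring around
    600 min of daily sleep, with Poisson beam crossings (mean ``wake_rate``
    per waking minute).  A short-sleep mutant is modelled by
    ``mutant_scaling`` < 1 multiplying bout durations plus
    ``night_bout_shift`` extra night episodes (fragmented night sleep);
    :data:`SHORT_SLEEP_MUTANT` holds the default severe-mutant settings.
    Heterozygotes scale the effect by ``dominance`` (partial dominance).
    """

    n_ld_days: int = 5
    n_dd_days: int = 0
    lights_on: str = "08:00"
    wake_rate: float = 1.5
    day_bout_n_mean: float = 4.0
    night_bout_n_mean: float = 5.0
    day_bout_mean_min: float = 50.0
    night_bout_mean_min: float = 90.0
    min_bout_min: int = 5
    mutant_scaling: float = 1.0
    night_bout_shift: float = 0.0
    dominance: float = 0.5
    period_h: float = 24.0
    zero_truncated_wake: bool = False
    day_window_zt_min: tuple[int, int] = (300, 720)
    night_window_zt_min: tuple[int, int] = (720, 1440)

    def __post_init__(self) -> None:
        if self.wake_rate < 0:
            raise ValueError("wake_rate must be non-negative")
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must lie in [0, 1]")
        if self.mutant_scaling <= 0:
            raise ValueError("mutant_scaling must be positive")
        if self.n_ld_days + self.n_dd_days < 1:
            raise ValueError("need at least one day")

    @property
    def n_days(self) -> int:
        return self.n_ld_days + self.n_dd_days

    def schedule(self) -> LightSchedule:
        return LightSchedule(
            lights_on=self.lights_on,
            regime=("LD",) * self.n_ld_days + ("DD",) * self.n_dd_days,
        )

    def for_genotype(self, genotype: str) -> "ActivitySimConfig":
        """'wt', 'het' or 'mut': apply the (partially dominant) mutant effect."""
        if genotype == "wt":
            return replace(self, mutant_scaling=1.0, night_bout_shift=0.0)
        if genotype == "mut":
            return self
        if genotype == "het":
            scale = 1.0 - self.dominance * (1.0 - self.mutant_scaling)
            shift = self.dominance * self.night_bout_shift
            return replace(self, mutant_scaling=scale, night_bout_shift=shift)
        raise ValueError(f"unknown genotype {genotype!r}")


#: Severe short-sleeper: bout durations cut to a quarter, three extra night
#: episodes — >50% total-sleep loss with *more* night episodes, the
#: fragmented-maintenance architecture of a sleep-maintenance mutant.
SHORT_SLEEP_MUTANT = {"mutant_scaling": 0.25, "night_bout_shift": 3.0}


def _shifted_geometric(rng, mean: float, minimum: int, size: int) -> np.ndarray:
    """Bout durations: minimum + geometric tail (memoryless wake-up)."""
    mean = max(mean, minimum + 1e-6)
    p = 1.0 / (mean - minimum + 1.0)
    return minimum + rng.geometric(p, size=size) - 1


def _place_bouts(
    rng,
    occupied: np.ndarray,
    day_start: int,
    window: tuple[int, int],
    durations: np.ndarray,
    center_weighted: bool,
    min_bout: int = 5,
) -> list[tuple[int, int]]:
    """Place bouts in a day window without overlap.

    Starts are sampled among the feasible positions (a 1-min waking margin
    keeps adjacent bouts distinct); day bouts are centre-weighted to build a
    siesta.  A bout with no feasible start (window saturated) is skipped
    with a warning.
    """
    placed = []
    lo, hi = window
    for dur in durations:
        dur = int(dur)
        lo_c = max(day_start + lo, 0)
        hi_c = min(day_start + hi, occupied.size)
        if hi_c - lo_c <= dur:
            continue
        # feasible starts s in [lo_c, hi_c - dur]: occupied[s-1 : s+dur+1] empty
        occ = occupied[max(lo_c - 1, 0) : min(hi_c + 1, occupied.size)].astype(np.int32)
        c = np.concatenate(([0], np.cumsum(occ)))
        offset = lo_c - max(lo_c - 1, 0)
        starts = np.arange(lo_c, hi_c - dur + 1)
        rel = starts - max(lo_c - 1, 0)
        span_lo = np.maximum(rel - 1, 0)
        span_hi = np.minimum(rel + dur + 1, occ.size)
        feasible = starts[(c[span_hi] - c[span_lo]) == 0]
        if feasible.size == 0:
            # Window too full for the drawn duration: truncate the bout to
            # the largest free gap (sleep saturates, it does not vanish).
            free = ~occupied[lo_c:hi_c]
            edges = np.diff(np.concatenate(([0], free.astype(np.int8), [0])))
            run_starts = np.nonzero(edges == 1)[0]
            run_ends = np.nonzero(edges == -1)[0]
            usable = []
            for a, b in zip(run_starts, run_ends):
                ga, gb = lo_c + a, lo_c + b
                if ga > 0 and occupied[ga - 1]:
                    ga += 1
                if gb < occupied.size and occupied[gb]:
                    gb -= 1
                if gb - ga > 0:
                    usable.append((ga, gb))
            if not usable:
                warnings.warn(
                    "no room left for a sleep bout in its window; skipped",
                    stacklevel=3,
                )
                continue
            ga, gb = max(usable, key=lambda r: r[1] - r[0])
            dur_t = min(dur, gb - ga)
            if dur_t < min_bout:
                continue
            s = int(rng.integers(ga, gb - dur_t + 1))
            occupied[s : s + dur_t] = True
            placed.append((s, int(dur_t)))
            continue
        if center_weighted:
            center = day_start + (lo + hi) / 2 - dur / 2
            w = np.exp(-0.5 * ((feasible - center) / ((hi - lo) / 5)) ** 2)
            w /= w.sum()
            s = int(rng.choice(feasible, p=w))
        else:
            s = int(feasible[rng.integers(feasible.size)])
        occupied[s : s + dur] = True
        placed.append((s, int(dur)))
    return placed


def simulate_activity(
    cfg: ActivitySimConfig,
    seed: int | np.random.Generator,
    fly_id: str = "fly",
    line_id: str = "line",
) -> tuple[ActivityTrace, list[tuple[int, int]]]:
    """Simulate one fly's trace; returns (trace, truth bout list).

    Truth bouts are the placed (start_min, duration_min) pairs.  Waking
    minutes draw Poisson(``wake_rate``) counts; with
    ``zero_truncated_wake`` every waking minute has at least one crossing,
    so the sleep scorer recovers the truth bouts exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_min = cfg.n_days * MINUTES_PER_DAY
    occupied = np.zeros(n_min, dtype=bool)
    truth: list[tuple[int, int]] = []

    # Subjective days: calendar days while entrained (LD), then days of
    # length period_h in free run (DD); sleep windows scale with day length.
    day_starts: list[tuple[int, float]] = [
        (d * MINUTES_PER_DAY, 1.0) for d in range(cfg.n_ld_days)
    ]
    t = cfg.n_ld_days * MINUTES_PER_DAY
    plen = cfg.period_h * 60.0
    while t < n_min:
        day_starts.append((int(round(t)), plen / MINUTES_PER_DAY))
        t += plen

    for day_start, scale in day_starts:
        n_day = rng.poisson(cfg.day_bout_n_mean)
        n_night = rng.poisson(max(cfg.night_bout_n_mean + cfg.night_bout_shift, 0.0))
        day_durs = _shifted_geometric(
            rng, cfg.day_bout_mean_min * cfg.mutant_scaling, cfg.min_bout_min, n_day
        )
        night_durs = _shifted_geometric(
            rng, cfg.night_bout_mean_min * cfg.mutant_scaling, cfg.min_bout_min, n_night
        )
        dlo, dhi = (int(round(v * scale)) for v in cfg.day_window_zt_min)
        nlo, nhi = (int(round(v * scale)) for v in cfg.night_window_zt_min)
        truth += _place_bouts(
            rng, occupied, day_start, (dlo, dhi), day_durs, True, cfg.min_bout_min
        )
        truth += _place_bouts(
            rng, occupied, day_start, (nlo, nhi), night_durs, False, cfg.min_bout_min
        )

    counts = rng.poisson(cfg.wake_rate, size=n_min)
    if cfg.zero_truncated_wake:
        counts = np.maximum(counts, 1)
    counts[occupied] = 0
    trace = ActivityTrace(
        fly_id=fly_id,
        line_id=line_id,
        start=_EPOCH.replace(
            hour=int(cfg.lights_on[:2]), minute=int(cfg.lights_on[3:5])
        ),
        bin_minutes=1,
        counts=counts,
        schedule=cfg.schedule(),
    )
    truth.sort()
    return trace, truth


def simulate_cohort(
    cfg: ActivitySimConfig,
    n_flies: int,
    seed: int,
    genotype: str | None = None,
    line_id: str | None = None,
) -> list[ActivityTrace]:
    """Simulate ``n_flies`` traces (seed-deterministic).

    ``genotype`` ('wt', 'het', 'mut') optionally reinterprets ``cfg``'s
    mutant effect through :meth:`ActivitySimConfig.for_genotype`; by default
    the config is used as given.
    """
    rng = np.random.default_rng(seed)
    gcfg = cfg if genotype is None else cfg.for_genotype(genotype)
    line = line_id or genotype or "cohort"
    return [
        simulate_activity(gcfg, rng, fly_id=f"{line}_{i}", line_id=line)[0]
        for i in range(n_flies)
    ]


def simulate_deprivation_pair(
    cfg: ActivitySimConfig,
    rebound_boost_min: int,
    seed: int | np.random.Generator,
    *,
    sd_day: int | None = None,
    sd_window_zt_h: tuple[float, float] = (18.0, 24.0),
    rebound_start_zt_min: int = 60,
) -> tuple[ActivityTrace, ActivityTrace, int]:
    """Baseline and deprived traces for one fly plus the SD day index.

    The deprived trace is an independent draw from the same architecture in
    which (i) the stimulation window (default ZT18–24) of the SD day is kept
    awake — mechanical shaking yields at least one crossing per minute — and
    (ii) the following morning carries ``rebound_boost_min`` extra minutes
    of sleep as one contiguous bout starting at ZT1, inside the rebound
    window.  The default day window starts at ZT5, so the ZT0–5 rebound
    window is otherwise sleep-free up to rare accidental quiescence and the
    expected rebound gain equals the boost.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sd_day is None:
        sd_day = cfg.n_days - 2
    if not 0 <= sd_day < cfg.n_days - 1:
        raise ValueError("sd_day must leave a following rebound day")
    baseline, _ = simulate_activity(cfg, rng, fly_id="baseline")
    deprived, _ = simulate_activity(cfg, rng, fly_id="deprived")
    counts = deprived.counts.copy()
    lo = sd_day * MINUTES_PER_DAY + int(sd_window_zt_h[0] * 60)
    hi = sd_day * MINUTES_PER_DAY + int(sd_window_zt_h[1] * 60)
    counts[lo:hi] = np.maximum(rng.poisson(cfg.wake_rate, size=hi - lo), 1)
    rb_lo = (sd_day + 1) * MINUTES_PER_DAY + rebound_start_zt_min
    rb_hi = min(rb_lo + rebound_boost_min, counts.size)
    counts[rb_lo:rb_hi] = 0
    if rb_lo > 0:
        counts[rb_lo - 1] = max(counts[rb_lo - 1], 1)
    if rb_hi < counts.size:
        counts[rb_hi] = max(counts[rb_hi], 1)
    deprived = replace(deprived, counts=counts)
    return baseline, deprived, sd_day


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------


def simulate_screen_line_means(
    n_lines: int = 2000,
    flies_per_line: int = 6,
    seed: int | np.random.Generator = 0,
    *,
    mean_sleep_min: float = 850.0,
    line_sd_min: float = 55.0,
    fly_sd_min: float = 40.0,
    planted: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Line-mean fidelity screen: per-fly sleep means drawn normally.

    Line effects are N(0, ``line_sd_min``); fly means add N(0,
    ``fly_sd_min``) noise, so line means are normal with SD
    sqrt(line_sd² + fly_sd²/flies).  ``planted`` maps line ids (``"L0042"``)
    to effects in units of that line-mean SD (e.g. −5.0 for a severe
    short-sleeper).  Returns the per-line table consumed by
    :func:`flysleep.screen.call_screen_outliers` plus a truth dict.
    """
    if n_lines < 10:
        raise ValueError("a screen needs at least 10 lines")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    planted = dict(planted or {})
    line_ids = [f"L{i:04d}" for i in range(n_lines)]
    unknown = set(planted) - set(line_ids)
    if unknown:
        raise ValueError(f"planted lines not in screen: {sorted(unknown)}")
    sd_line_means = float(np.sqrt(line_sd_min**2 + fly_sd_min**2 / flies_per_line))
    line_effects = rng.normal(0.0, line_sd_min, size=n_lines)
    fly_means = (
        mean_sleep_min
        + line_effects[:, None]
        + rng.normal(0.0, fly_sd_min, size=(n_lines, flies_per_line))
    )
    means = fly_means.mean(axis=1)
    for lid, eff in planted.items():
        means[line_ids.index(lid)] = mean_sleep_min + eff * sd_line_means
    means = np.clip(means, 0.0, MINUTES_PER_DAY)
    table = pd.DataFrame(
        {"line_id": line_ids, "n_flies": flies_per_line, "mean_sleep_min": means}
    )
    truth = {
        "planted": planted,
        "sd_line_means": sd_line_means,
        "mean_sleep_min": mean_sleep_min,
    }
    return table, truth


def simulate_screen_dataset(
    n_lines: int,
    flies_per_line: int = 6,
    seed: int = 0,
    *,
    base: ActivitySimConfig | None = None,
    planted_scaling: Mapping[str, float] | None = None,
    line_jitter_sd: float = 0.08,
    dropout_p: float = 0.0,
    write_dir: str | Path | None = None,
) -> tuple[list[ActivityTrace], dict]:
    """Trace-level screen: full DAM traces per fly, with planted mutants.

    Each line's bout durations are scaled by a N(1, ``line_jitter_sd``)
    factor (truncated at 0.2), producing approximately normal line means;
    ``planted_scaling`` maps line ids to explicit duration scalings (e.g.
    0.35 for a severe short-sleeper).  Each fly dies mid-recording with
    probability ``dropout_p`` (counts zeroed from a random day onward; the
    dead-fly policy truncates such flies downstream).  With ``write_dir``
    the traces are also written as Trikinetics monitor files, 32 channels
    per file, in the dialect :func:`flysleep.dam.read_dam_monitor` reads.
    """
    if n_lines < 10:
        raise ValueError("a screen needs at least 10 lines")
    rng = np.random.default_rng(seed)
    base = base or ActivitySimConfig(n_ld_days=2)
    planted_scaling = dict(planted_scaling or {})
    traces: list[ActivityTrace] = []
    truth_scaling: dict[str, float] = {}
    for i in range(n_lines):
        lid = f"L{i:04d}"
        scale = planted_scaling.get(
            lid, float(max(rng.normal(1.0, line_jitter_sd), 0.2))
        )
        truth_scaling[lid] = scale
        cfg = replace(base, mutant_scaling=scale)
        for j in range(flies_per_line):
            trace, _ = simulate_activity(cfg, rng, fly_id=f"{lid}_f{j}", line_id=lid)
            if dropout_p and rng.random() < dropout_p and cfg.n_days > 1:
                death_day = int(rng.integers(1, cfg.n_days))
                counts = trace.counts.copy()
                counts[death_day * MINUTES_PER_DAY :] = 0
                trace = replace(trace, counts=counts).flag_dead_days()
            traces.append(trace)
    truth = {"scaling": truth_scaling, "planted": dict(planted_scaling)}
    if write_dir is not None:
        write_dir = Path(write_dir)
        write_dir.mkdir(parents=True, exist_ok=True)
        channel_maps = {}
        for k in range(0, len(traces), 32):
            chunk = traces[k : k + 32]
            name = f"Monitor{k // 32 + 1}.txt"
            write_dam_monitor(chunk, write_dir / name)
            channel_maps[name] = {
                ch + 1: (t.fly_id, t.line_id) for ch, t in enumerate(chunk)
            }
        truth["channel_maps"] = channel_maps
    return traces, truth


# ---------------------------------------------------------------------------
# Recombination cross
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossSimConfig:
    """Backcross simulator: Haldane crossovers over an ordered marker map."""

    marker_map: MarkerMap
    causal_pos_bp: int
    n_recombinants: int = 100
    phenotyping_error_rate: float = 0.0
    #: When True, chromatids are resampled until they carry exactly one
    #: crossover — the composition of a mapping panel built, as in a
    #: backcross design, from selected single recombinants.  Marker-interval
    #: exclusion logic is exact on such a panel.  The default (False) keeps
    #: raw Haldane gametes, whose rare double crossovers between adjacent
    #: markers can contradict marker-resolution inference.
    single_crossover_panel: bool = False

    def __post_init__(self) -> None:
        mm = self.marker_map
        if not mm.markers[0].pos_bp <= self.causal_pos_bp <= mm.markers[-1].pos_bp:
            raise ValueError("causal position must lie within the marker span")
        if not 0 <= self.phenotyping_error_rate < 0.5:
            raise ValueError("phenotyping_error_rate must lie in [0, 0.5)")

    @property
    def causal_cm(self) -> float:
        """Genetic position of the causal locus (linear bp→cM interpolation)."""
        mm = self.marker_map.markers
        for a, b in zip(mm, mm[1:]):
            if a.pos_bp <= self.causal_pos_bp <= b.pos_bp:
                f = (self.causal_pos_bp - a.pos_bp) / (b.pos_bp - a.pos_bp)
                return a.cm + f * (b.cm - a.cm)
        raise AssertionError("unreachable: causal position inside span")


def simulate_recombinants(
    cfg: CrossSimConfig, seed: int | np.random.Generator
) -> tuple[list[CrossRecord], GenomicInterval]:
    """Simulate recombinant chromatids; returns (records, truth interval).

    Crossover counts per chromatid are Poisson with mean equal to the map
    length in Morgans; positions are uniform in genetic distance (Haldane,
    no interference).  Marker genotypes read off the strand of origin; the
    phenotype follows the causal-locus genotype, flipped with the
    phenotyping error rate.  The truth interval is bounded by the markers
    flanking the causal position.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mm = cfg.marker_map
    cm0, cm1 = mm.markers[0].cm, mm.markers[-1].cm
    length_m = (cm1 - cm0) / 100.0
    marker_cm = np.array([m.cm for m in mm.markers])
    causal_cm = cfg.causal_cm

    records = []
    for i in range(cfg.n_recombinants):
        n_xo = rng.poisson(length_m)
        if cfg.single_crossover_panel:
            while n_xo != 1:
                n_xo = rng.poisson(length_m)
        xo = np.sort(rng.uniform(cm0, cm1, size=n_xo))
        start_mut = bool(rng.integers(2))

        def origin(g: float) -> str:
            flips = int(np.searchsorted(xo, g, side="right"))
            mut = start_mut ^ (flips % 2 == 1)
            return MUTANT_ALLELE if mut else MARKER_ALLELE

        genotypes = tuple(origin(g) for g in marker_cm)
        pheno = PHENO_MUTANT if origin(causal_cm) == MUTANT_ALLELE else PHENO_NON_MUTANT
        if cfg.phenotyping_error_rate and rng.random() < cfg.phenotyping_error_rate:
            pheno = PHENO_NON_MUTANT if pheno == PHENO_MUTANT else PHENO_MUTANT
        records.append(CrossRecord(f"R{i:04d}", genotypes, pheno))

    left = max(
        (m for m in mm.markers if m.pos_bp <= cfg.causal_pos_bp),
        key=lambda m: m.pos_bp,
    )
    right = min(
        (m for m in mm.markers if m.pos_bp >= cfg.causal_pos_bp),
        key=lambda m: m.pos_bp,
    )
    truth = GenomicInterval(mm.chrom, left.pos_bp, right.pos_bp, left.name, right.name)
    return records, truth


# ---------------------------------------------------------------------------
# Mutagenized genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimConfig:
    """Desk-scale mutagenized genome: 5 Mb, 50 genes, shared background
    variants, private EMS mutations and coverage-dependent detection.

    ``detect_p_mutant``/``detect_p_parental`` model the per-variant call
    probability implied by each strain's sequencing coverage.  The planted
    causal mutation (an EMS transition producing a missense change in the
    causal gene) is always present in the mutant call set: it is the premise
    of the mapping experiment, while detection dropout applies to incidental
    variants.
    """

    chrom: str = "3R"
    chrom_length: int = 5_000_000
    n_genes: int = 50
    cds_exon_length: int = 450  # two exons per gene; divisible by 3
    intron_length: int = 500
    n_background_variants: int = 300
    n_ems_mutations: int = 40
    ems_transition_fraction: float = 0.9
    detect_p_mutant: float = 0.95
    detect_p_parental: float = 0.88
    causal_gene_index: int = 25
    interval_halfwidth: int = 500_000

    def __post_init__(self) -> None:
        for p in (self.ems_transition_fraction, self.detect_p_mutant, self.detect_p_parental):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cds_exon_length % 3:
            raise ValueError("cds_exon_length must be divisible by 3")
        if not 0 <= self.causal_gene_index < self.n_genes:
            raise ValueError("causal_gene_index out of range")


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    models: GeneModelSet
    mutant_variants: list[Variant]
    parental_variants: list[Variant]
    ems_variants: list[Variant]  # truth: all induced mutations incl. causal
    background_variants: list[Variant]  # truth: shared isogenic variants
    causal: Variant  # annotated
    interval: GenomicInterval  # default mapping interval around the causal gene

    def sanger_confirm(self, variant: Variant) -> bool:
        """In-silico re-sequencing of a candidate site in both strains.

        Returns False for candidates that are really shared background
        polymorphisms (missed in the parental calls through incomplete
        coverage): targeted re-sequencing of the site in the parental strain
        reveals the allele there.  Genuine induced mutations are confirmed.
        """
        return variant.key not in {b.key for b in self.background_variants}

    def truth_json(self) -> str:
        def vkey(v: Variant):
            return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}

        return json.dumps(
            {
                "causal": {**vkey(self.causal), "effect": self.causal.effect,
                           "aa_change": self.causal.aa_change,
                           "gene": self.causal.gene_id},
                "ems": [vkey(v) for v in self.ems_variants],
                "background": [vkey(v) for v in self.background_variants],
                "interval": {
                    "chrom": self.interval.chrom,
                    "start_bp": self.interval.start_bp,
                    "end_bp": self.interval.end_bp,
                },
            },
            indent=2,
        )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _sample_positions(rng, length: int, n: int, taken: set[int]) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        for p in rng.integers(1, length + 1, size=n - len(out)):
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
    return out


def _non_ems_alt(rng, ref: str) -> str:
    ems_alt = {"C": "T", "G": "A"}.get(ref)
    choices = [b for b in "ACGT" if b != ref and b != ems_alt]
    return choices[int(rng.integers(len(choices)))]


def simulate_mutagenized_genome(
    cfg: GenomeSimConfig, seed: int | np.random.Generator
) -> SimulatedGenome:
    """Generate genome, gene models, per-strain variant calls and truth."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = list(_random_sequence(rng, cfg.chrom_length))

    # Evenly spaced two-exon genes, random strand.
    spacing = cfg.chrom_length // (cfg.n_genes + 1)
    transcripts = []
    for i in range(cfg.n_genes):
        start = (i + 1) * spacing
        e1 = (start, start + cfg.cds_exon_length - 1)
        s2 = e1[1] + cfg.intron_length + 1
        e2 = (s2, s2 + cfg.cds_exon_length - 1)
        strand = "+" if rng.integers(2) else "-"
        transcripts.append(
            Transcript(
                transcript_id=f"g{i:03d}.t1",
                gene_id=f"g{i:03d}",
                chrom=cfg.chrom,
                strand=strand,
                cds=(e1, e2),
            )
        )
    genome = {cfg.chrom: "".join(seq)}
    models = GeneModelSet(transcripts, genome)

    taken: set[int] = set()

    # Planted causal mutation: EMS transition, missense, in the causal gene.
    causal_tx = transcripts[cfg.causal_gene_index]
    cds_positions = [
        p for s, e in causal_tx.cds for p in range(s, e + 1)
    ]
    rng.shuffle(cds_positions)
    causal = None
    for p in cds_positions:
        ref = genome[cfg.chrom][p - 1]
        if ref not in "CG":
            continue
        cand = Variant(cfg.chrom, p, ref, "T" if ref == "C" else "A")
        cand = annotate_coding_effect(cand, models)
        if cand.effect == "missense":
            causal = cand
            break
    if causal is None:  # pragma: no cover - CG sites are abundant
        raise RuntimeError("could not plant a causal missense; enlarge the CDS")
    taken.add(causal.pos)

    background = []
    for p in _sample_positions(rng, cfg.chrom_length, cfg.n_background_variants, taken):
        ref = genome[cfg.chrom][p - 1]
        alts = [b for b in "ACGT" if b != ref]
        background.append(Variant(cfg.chrom, p, ref, alts[int(rng.integers(3))]))

    ems = [causal]
    n_remaining = cfg.n_ems_mutations - 1
    for _ in range(n_remaining):
        if rng.random() < cfg.ems_transition_fraction:
            while True:
                p = _sample_positions(rng, cfg.chrom_length, 1, taken)[0]
                ref = genome[cfg.chrom][p - 1]
                if ref in "CG":
                    ems.append(Variant(cfg.chrom, p, ref, "T" if ref == "C" else "A"))
                    break
                taken.discard(p)
        else:
            p = _sample_positions(rng, cfg.chrom_length, 1, taken)[0]
            ref = genome[cfg.chrom][p - 1]
            ems.append(Variant(cfg.chrom, p, ref, _non_ems_alt(rng, ref)))

    mutant_calls = [
        v for v in background if rng.random() < cfg.detect_p_mutant
    ] + [causal] + [
        v for v in ems[1:] if rng.random() < cfg.detect_p_mutant
    ]
    parental_calls = [v for v in background if rng.random() < cfg.detect_p_parental]

    center = (causal_tx.cds[0][0] + causal_tx.cds[-1][1]) // 2
    interval = GenomicInterval(
        cfg.chrom,
        max(1, center - cfg.interval_halfwidth),
        min(cfg.chrom_length, center + cfg.interval_halfwidth),
    )
    return SimulatedGenome(
        genome=genome,
        models=models,
        mutant_variants=sorted(mutant_calls, key=lambda v: v.pos),
        parental_variants=sorted(parental_calls, key=lambda v: v.pos),
        ems_variants=sorted(ems, key=lambda v: v.pos),
        background_variants=sorted(background, key=lambda v: v.pos),
        causal=causal,
        interval=interval,
    )


def write_genome_files(sim: SimulatedGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, per-strain VCFs, interval BED and truth JSON."""
    from Bio import SeqIO
    from Bio.Seq import Seq as BioSeq
    from Bio.SeqRecord import SeqRecord

    from .mapping import interval_to_bed
    from .variants import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "mutant_vcf": out / "mutant.vcf",
        "parental_vcf": out / "parental.vcf",
        "bed": out / "interval.bed",
        "truth": out / "truth.json",
    }
    records = [
        SeqRecord(BioSeq(s), id=c, description="synthetic chromosome")
        for c, s in sim.genome.items()
    ]
    SeqIO.write(records, paths["fasta"], "fasta")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sim.models.transcripts:
            g_start, g_end = tx.cds[0][0], tx.cds[-1][1]
            fh.write(
                f"{tx.chrom}\tflysleep\tgene\t{g_start}\t{g_end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.gene_id}\n"
            )
            fh.write(
                f"{tx.chrom}\tflysleep\tmRNA\t{g_start}\t{g_end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            segs = tx.cds if tx.strand == "+" else tuple(reversed(tx.cds))
            phase = 0
            for s, e in segs:
                fh.write(
                    f"{tx.chrom}\tflysleep\tCDS\t{s}\t{e}\t.\t{tx.strand}\t{phase}\t"
                    f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3
        fh.flush()

    contigs = {c: len(s) for c, s in sim.genome.items()}
    write_vcf(sim.mutant_variants, paths["mutant_vcf"], contigs)
    write_vcf(sim.parental_variants, paths["parental_vcf"], contigs)
    paths["bed"].write_text(interval_to_bed(sim.interval) + "\n")
    paths["truth"].write_text(sim.truth_json())
    return paths
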