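# Methods

This note documents the models and procedures implemented in `flysleep`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Sleep scoring from DAM counts

A Drosophila Activity Monitor reports beam crossings per minute per fly.
Sleep is scored as every maximal run of zero-count minutes of length ≥ 5
(the field's standard inactivity criterion; configurable via
`min_inactive_min`). Scoring therefore requires minute-resolution bins —
coarser recordings are accepted for rhythm analysis but rejected for bout
detection.

Time is Zeitgeber-anchored: ZT0 = lights-on, day phase = ZT0 to the
photoperiod end (ZT12 at 12:12 LD), and the day boundary for per-day
summaries is lights-on, not midnight. In constant darkness the entrained
schedule is projected forward, so ZT doubles as circadian time. A bout
crossing ZT12 or ZT0 contributes its minutes to each phase separately but
is counted as one episode, in the phase where it started; this keeps both
minute conservation (day + night = total) and episode-count semantics
exact, and both are enforced by tests.

Dead flies: a trace whose final ≥ 24 h contain no counts is truncated at
its last active day; flagged days are excluded from all means. Monitor-file
gaps are a hard error unless a policy is chosen (`zeros` fills,
`drop-day` excludes the affected Zeitgeber day). The activity index is
total counts divided by waking minutes; since counts inside bouts are zero
by construction, it isolates waking intensity.

## Screen statistics

Per-fly means are computed over surviving days, line means over flies
(unweighted), and the screen read-out is the distribution of line means:
histogram in 25-min bins anchored at 0, outliers beyond the grand mean
± 3 sample SD (n−1), computed *including* candidate outliers — matching the
raw screen read-out rather than a robust variant (a MAD-based option exists
but is off by default). Exact boundary values are not called. At screen
scale (~2000 lines) the two-sided 3-SD false-call expectation is ~0.27% of
lines, which the simulated screen reproduces.

## Rhythmicity and period

DD days `(3, 11)` (1-based within DD; nine days, skipping two days of
transients after release) are binned to 30 min and linearly detrended —
without detrending, DC leakage dominates the circadian band. The power
spectrum is computed with zero-padding to the next power of two at or
above 4× the sample count: for a 9-day record the raw padded-to-512 grid
would space periods ~2.3 h apart near 24 h, coarser than the Rayleigh
resolution (24²/216 ≈ 2.7 h) warrants, so the 4× oversampled grid (~0.56 h
spacing) is used for the period read-out. The rhythmicity statistic
("FFT value") is the power at the circadian-band (18–30 h) peak divided by
total non-DC power; it is exactly invariant to count scaling, and the 0.01
rhythmicity threshold is retained as the conventional cut-off. The
normalisation itself is this package's fixed definition — commercial
implementations do not publish theirs, so only count-derived quantities
(percent rhythmic, recovered periods), not absolute statistic values, are
meaningful across implementations. A 10–14 h band peak exceeding the
circadian peak flags flies whose LD bimodality persists in DD as an
apparent ~12 h rhythm.

## Interval mapping

Phenotyping is a binary call supplied upstream (the mapping module never
re-thresholds sleep). For a recessive mutation scored against the mutant
chromosome, a mutant-phenotype recombinant carries the mutant-strain allele
at the locus, so any marker showing the marker-strain allele excludes its
side of the crossover (and symmetrically for non-mutant recombinants).
Allowed regions are open at excluded markers, intersected across
recombinants as interval sets; the result is reported between the closest
excluding markers (positions at those markers). Contradictory data raise an
error naming a minimal conflicting record pair; with no informative
recombinant the full chromosome is returned with a warning. Adding records
can only shrink the interval, and error-free data always bracket the locus
— both properties are tested. Double crossovers between adjacent markers
are assumed absent by the interval logic; simulated raw gametes can violate
this (see below), and the contradiction path surfaces it.

## Variant filter cascade

Inputs are variant calls (VCF) for the mutant and its isogenic parental
strain — alignment and SNP calling are upstream. Stages: (1) variants
private to the mutant by (chrom, pos, alt), each flagged for parental call
coverage when available, since a parental variant missed through low
coverage masquerades as mutant-unique; (2) restriction to the mapped
interval (1-based inclusive bounds); (3) strand-aware codon annotation
against CDS models backed by genome sequence, taking the maximal-severity
effect across transcripts (nonsense > missense > splice_flag > synonymous >
noncoding; `splice_flag` = intronic within 2 bp of a junction; indels and
codons extending past a declared CDS are `unannotated`); (4) ranking of
amino-acid-changing candidates by EMS signature (C→T/G→A on the reference
strand) then severity then position (a deterministic tie-break, nothing
more), with candidates at sites independently polymorphic in the parental
strain demoted below all others — such sites are background variation, not
induced lesions. An optional confirmation hook re-checks candidates
(modelling targeted re-sequencing) and removes failures. Stage counts are
recorded and are non-increasing by construction.

## Expression quantification

ΔΔCt: fold = 2^−(ΔCt − ΔCt_calibrator) with ΔCt = Ct_target − Ct_reference;
the calibrator's fold is exactly 1 and samples lacking a reference Ct are
dropped with a warning. Densitometry: band/loading ratios anchored so the
ZT0 value is 1; when genotypes share a blot, the control's ZT0 lane is
passed as the common calibrator so between-genotype level differences
survive normalisation. Peak detection uses circular strict local maxima
(the day wraps; constant profiles and plateaus yield none) with bimodality
defined as exactly two peaks ≥ 2 timepoints apart. Genotype comparisons use
a two-sample t-test on replicate-level daily means — replicates, not
timepoints, are independent — and at the study-typical n = 3 a +40% level
difference is detected in most but not all runs, a power limitation the
tests document rather than hide.

## Synthetic data: what is emulated, what is not

**Activity.** Sleep bouts are placed within a siesta window (ZT5–12,
centre-weighted) and a night window (ZT12–24): bout counts are Poisson
(defaults: 4 day, 5 night), durations are shifted-geometric with a 5-min
floor (memoryless wake-up; means 50/90 min), waking minutes draw
Poisson(1.5) crossings. These defaults were chosen once to score ~600 min
daily sleep with ~5 night episodes, typical of wild-type females, and are
not adjusted per experiment. When a drawn bout no longer fits its window,
it is truncated to the largest free gap (sleep saturates rather than
vanishes). The severe short-sleep mutant (`SHORT_SLEEP_MUTANT`) scales
durations ×0.25 and adds 3 night episodes: > 50% sleep loss with *more*
night episodes — a maintenance defect; heterozygotes scale the effect by a
dominance coefficient (default 0.5, partial dominance). In free run,
subjective days of length `period_h` follow DD onset with windows scaled by
period/24 (per-calendar-day phase shifting aliases once cumulative drift
passes a day). With `zero_truncated_wake` every waking minute has ≥ 1
crossing and scoring recovers the placed bouts exactly; with the default
Poisson wake, rare accidental quiescence adds realistic scoring noise. Not
emulated: ultradian structure in waking activity, startle responses,
age/sex effects, arousal thresholds.

**Deprivation.** The stimulation window is kept awake (≥ 1 crossing per
minute, as under mechanical shaking); the following morning carries a
planted contiguous rebound bout (default start ZT1). Because natural day
bouts start at ZT5, the ZT0–5 rebound window is otherwise sleep-free up to
rare accidental runs that cancel in expectation between baseline and
deprived traces, so the expected measured rebound equals the planted boost.

**Screen.** Two fidelities: `simulate_screen_line_means` draws per-fly
sleep means normally (line SD 55 min, fly SD 40 min around 850 min) —
sufficient and fast for outlier statistics, which consume only line means —
and `simulate_screen_dataset` generates full traces with per-line duration
jitter and writes Trikinetics-format monitor files for end-to-end ingestion
tests. Planted effects are specified in line-mean SD units (means fidelity)
or duration scalings (trace fidelity).

**Crosses.** Chromatids carry Poisson(map length in Morgans) crossovers
placed uniformly in genetic distance (Haldane, no interference); marker
genotypes read off the strand of origin and the phenotype follows the
causal locus, flipped with a configurable error rate. The 10-cM
recombination fraction matches Haldane's (1−e^−2d)/2 closed form by
construction. `single_crossover_panel` resamples to exactly one crossover
per chromatid, the composition of a backcross mapping panel built from
selected single recombinants, on which marker-interval logic is exact;
containment properties use this mode, the closed-form check uses raw
gametes.

**Genome.** Desk scale: one 5-Mb contig, 50 evenly spaced two-exon genes
(900-bp CDS, 500-bp intron, random strand), 300 background variants shared
by both strains, 40 EMS mutations private to the mutant (90% C→T/G→A), and
a causal EMS missense planted in the CDS of a designated gene. Sequencing
is modelled at the call level: each incidental variant is detected per
strain with probability 0.95 (mutant) / 0.88 (parental), reflecting their
genome coverages; the causal variant is always present in the mutant call
set, since a mapping experiment presupposes the lesion was sequenced —
dropout applies to incidental variants. The default mapping interval is the
causal gene ± 500 kb. Not emulated: read-level errors, indels, structural
variants, repeat content, linked selection on the background.

Passing tests on these generators show the *methods* are correct under the
stated statistical structure; they do not certify performance on real data
with non-Poisson activity, genotyping error or alignment artefacts.

## Problem sizes and determinism

Acceptance-scale runs use 1,000 random traces for the bout oracle, 100
seeds each for period recovery and the variant cascade, 50 two-thousand-
line screens, 50 error-free crosses of 200 recombinants plus one 5,000-
gamete Haldane check, 100 random annotation variants, and 200 deprivation
replicates. All generators take explicit seeds and are deterministic given
one; the acceptance script derives every stream from its `--seed`
argument.

## Known limitations

- The rhythmicity statistic's absolute scale is implementation-specific;
  compare thresholds only within this package.
- Interval logic is marker-resolution: real double crossovers between
  adjacent markers surface as contradictions rather than being resolved.
- Coding annotation handles single-nucleotide substitutions only; indels
  pass through unannotated.
- The screen's normal model ignores line-level mortality and retesting
  (a dropout knob exists but defaults to 0).
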