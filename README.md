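# flysleep

Analysis pipeline for forward-genetic sleep screens in *Drosophila
melanogaster*: from beam-break activity recordings to sleep architecture,
screen statistics and circadian rhythmicity, and from recombinant genotypes
and strain variant calls to a ranked short-list of candidate causal
mutations.

## Who this is for

Fly sleep and circadian labs running EMS mutagenesis screens with
Trikinetics Drosophila Activity Monitors (DAM), and anyone mapping a
chemically induced mutation by combining recombination mapping with
whole-genome sequencing of the mutant and its isogenic parental strain.
Every input the pipeline consumes can also be simulated with known ground
truth, so methods can be validated end to end before touching real data.

## The methods at the core

**Sleep scoring.** Fly sleep is operationally a run of ≥ 5 consecutive
minutes without a beam crossing. For each fly-day the package reports total,
daytime (ZT0–12) and night-time (ZT12–24) sleep, episode counts and mean
durations per phase, and the activity index (mean crossings per *waking*
minute, separating short sleep from hyperactivity).

**Screen statistics.** With ~4–8 flies per mutagenized line, line mean sleep
is approximately normal across a screen. Candidate mutants are lines beyond
the grand mean ± 3·SD of the line means (sample SD, 25-min histogram bins
anchored at zero, strict exceedance).

**Rhythmicity.** In constant darkness, counts are binned to 30 min,
linearly detrended, and the discrete Fourier power spectrum computed on a
zero-padded grid. The rhythmicity statistic is the share of non-DC power at
the peak within the 18–30 h circadian band; flies above 0.01 are rhythmic,
with a 10–14 h band flagging persistent bimodal (~12 h) behavior.

**Interval mapping.** Each phenotyped recombinant whose marker
strain-of-origin disagrees with its phenotype excludes the chromosome on
that side of its crossover; the mapping interval is the intersection of all
surviving regions, reported between its closest excluding markers.

**Mutation-by-sequencing.** Variants private to the mutant strain are
filtered to the mapped interval, annotated for coding effect against gene
models and genome sequence (strand-aware codon substitution), and ranked:
EMS-signature transitions (C→T/G→A) first, then severity
(nonsense > missense > splice), with sites that are independently
polymorphic in the parental background demoted. Counts shrink monotonically
along the cascade.

**Expression.** ΔΔCt fold changes against a reference gene, loading-
normalised densitometry anchored at ZT0 ≡ 1, circular peak detection for
bimodal daily profiles, and genotype comparisons on replicate-level daily
means.

## Worked example

```bash
python examples/variant_cascade.py
```

```
unique to mutant:            76
inside mapped interval:      13
amino-acid-changing:         1
after confirmation/demotion: 1

top candidate: 3R:2549039 G>A missense P292L in g025 (EMS transition: True)
planted causal: 3R:2549039 G>A P292L
```

A 5-Mb mutagenized genome is simulated (shared isogenic background
variants, private EMS mutations, per-strain detection at 95%/88% coverage),
written to VCF/GFF3/FASTA, re-read, and pushed through the cascade: 76
variants appear unique to the mutant (some only because the parental strain
was sequenced at lower coverage), 13 fall inside the mapped interval, one
changes an amino acid, and it is exactly the planted causal G→A missense
transition.

The other scripts in `examples/` each demonstrate one capability (sleep
scoring, screen outliers, DD rhythmicity, interval mapping, deprivation and
rebound, expression profiles) and print what the numbers mean.

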