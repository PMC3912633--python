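"""Recombination-interval mapping from recombinant genotypes and phenotypes.

A recessive mutation is localised by crossing the mutant chromosome against a
multiply-marked chromosome, recovering single recombinants, and scoring each
recombinant both for the marker alleles it carries (visible markers or SNPs)
and for the mutant phenotype.  A recombinant's chromosome is a mosaic of
mutant-strain and marker-strain segments; the phenotype reveals which segment
carries the causal locus, so every marker whose strain-of-origin is
discordant with the phenotype excludes the chromosome on its side of the
crossover.  Intersecting the surviving regions across recombinants yields
the mapping interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Marker",
    "MarkerMap",
    "CrossRecord",
    "GenomicInterval",
    "MappingContradictionError",
    "infer_mapping_interval",
    "interval_to_bed",
]

MUTANT_ALLELE = "M"  # mutant-strain origin
MARKER_ALLELE = "P"  # marker-strain (phenotypic marker) origin
UNKNOWN_ALLELE = "U"

PHENO_MUTANT = "mutant"
PHENO_NON_MUTANT = "non_mutant"
PHENO_UNTESTED = "untested"


@dataclass(frozen=True)
class Marker:
    name: str
    kind: str  # "visible" or "SNP"
    chrom: str
    pos_bp: int  # 1-based physical position
    cm: float  # genetic position

    def __post_init__(self) -> None:
        if self.kind not in ("visible", "SNP"):
            raise ValueError(f"marker kind must be 'visible' or 'SNP', got {self.kind!r}")
        if self.pos_bp < 1:
            raise ValueError("physical positions are 1-based (>= 1)")


class MarkerMap:
    """An ordered marker map on one chromosome arm.

    Physical and genetic positions must both be strictly increasing along
    the marker order.
    """

    def __init__(self, markers: Sequence[Marker], chrom_length_bp: int | None = None):
        markers = list(markers)
        if len(markers) < 2:
            raise ValueError("a marker map needs at least 2 markers")
        chroms = {m.chrom for m in markers}
        if len(chroms) != 1:
            raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
        for a, b in zip(markers, markers[1:]):
            if not (a.pos_bp < b.pos_bp and a.cm < b.cm):
                raise ValueError(
                    f"marker order violated between {a.name} and {b.name}: "
                    "physical and genetic positions must both increase"
                )
        self.markers = markers
        self.chrom = markers[0].chrom
        self.chrom_length_bp = chrom_length_bp or markers[-1].pos_bp

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def length_cm(self) -> float:
        return self.markers[-1].cm - self.markers[0].cm

    def marker_at_bp(self, pos: int) -> Marker | None:
        for m in self.markers:
            if m.pos_bp == pos:
                return m
        return None


@dataclass(frozen=True)
class CrossRecord:
    """One recombinant: per-marker strain-of-origin calls plus phenotype."""

    recombinant_id: str
    genotypes: tuple[str, ...]  # per marker: M / P / U
    phenotype: str  # mutant / non_mutant / untested

    def __post_init__(self) -> None:
        bad = set(self.genotypes) - {MUTANT_ALLELE, MARKER_ALLELE, UNKNOWN_ALLELE}
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        if self.phenotype not in (PHENO_MUTANT, PHENO_NON_MUTANT, PHENO_UNTESTED):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    def is_informative(self) -> bool:
        """True if the strain-of-origin switches between adjacent typed markers."""
        typed = [g for g in self.genotypes if g != UNKNOWN_ALLELE]
        return any(a != b for a, b in zip(typed, typed[1:]))


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # 1-based inclusive
    left_flank: str | None = None
    right_flank: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


class MappingContradictionError(ValueError):
    """Recombinant data admit no common interval."""

    def __init__(self, rec_a: str, rec_b: str):
        self.conflicting = (rec_a, rec_b)
        super().__init__(
            f"contradictory recombinants: {rec_a} and {rec_b} exclude "
            "complementary regions (phenotyping error or double crossover?)"
        )


def _allowed_regions(
    record: CrossRecord, mmap: MarkerMap
) -> list[tuple[int, int]] | None:
    """Regions of the chromosome consistent with one scored recombinant.

    The causal locus must sit on a chromosome segment whose strain of origin
    matches the phenotype (mutant phenotype ⇒ mutant-strain segment, since
    phenotyping is against the mutant chromosome and the lesion is
    recessive).  Each maximal run of concordant markers yields one allowed
    region, bounded by the nearest discordant markers on either side (or the
    chromosome ends).  Returns None for uninformative (untested) records.
    """
    if record.phenotype == PHENO_UNTESTED:
        return None
    want = MUTANT_ALLELE if record.phenotype == PHENO_MUTANT else MARKER_ALLELE
    markers = mmap.markers
    typed = [
        (i, m) for i, m in enumerate(markers) if record.genotypes[i] != UNKNOWN_ALLELE
    ]
    if not typed:
        return None
    concordant = {i for i, m in typed if record.genotypes[i] == want}
    discordant = [i for i, m in typed if record.genotypes[i] != want]
    if not discordant:
        return [(1, mmap.chrom_length_bp)]
    if not concordant:
        # Phenotype discordant with every typed marker: locus lies outside
        # the typed span, beyond the outermost discordant markers.
        left_end = markers[min(discordant)].pos_bp - 1
        right_start = markers[max(discordant)].pos_bp + 1
        regions = []
        if left_end >= 1:
            regions.append((1, left_end))
        if right_start <= mmap.chrom_length_bp:
            regions.append((right_start, mmap.chrom_length_bp))
        return regions or [(1, mmap.chrom_length_bp)]

    # Maximal runs of consecutive typed markers that are concordant.
    regions = []
    runs: list[list[int]] = []
    cur: list[int] = []
    for i, _ in typed:
        if i in concordant:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    for run in runs:
        left_disc = [j for j in discordant if j < run[0]]
        right_disc = [j for j in discordant if j > run[-1]]
        # open at excluded markers: the locus cannot sit on a discordant marker
        lo = markers[max(left_disc)].pos_bp + 1 if left_disc else 1
        hi = markers[min(right_disc)].pos_bp - 1 if right_disc else mmap.chrom_length_bp
        if lo <= hi:
            regions.append((lo, hi))
    return regions


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((lo, hi))
    out.sort()
    return out


def infer_mapping_interval(
    records: Iterable[CrossRecord], mmap: MarkerMap
) -> GenomicInterval:
    """Intersect the allowed regions of all scored recombinants.

    Returns the interval bounded by the closest excluding markers on each
    side (or the chromosome ends); with error-free data the causal locus
    lies strictly inside.  Raises :class:`MappingContradictionError`, naming
    a minimal conflicting record pair, when the intersection is empty; with
    no informative recombinants the full chromosome is returned with a
    warning.
    """
    records = list(records)
    scored = [r for r in records if r.phenotype != PHENO_UNTESTED]
    current: list[tuple[int, int]] = [(1, mmap.chrom_length_bp)]
    contributors: list[CrossRecord] = []
    any_informative = False
    for rec in scored:
        regions = _allowed_regions(rec, mmap)
        if regions is None:
            continue
        if rec.is_informative():
            any_informative = True
        new = _intersect(current, regions)
        if not new:
            # Find a minimal conflicting pair for the error message.
            for prev in contributors:
                if not _intersect(_allowed_regions(prev, mmap), regions):
                    raise MappingContradictionError(prev.recombinant_id, rec.recombinant_id)
            raise MappingContradictionError(
                contributors[-1].recombinant_id if contributors else "<prior>",
                rec.recombinant_id,
            )
        current = new
        contributors.append(rec)

    if not any_informative:
        warnings.warn(
            "no informative recombinants: returning the full chromosome",
            stacklevel=2,
        )
        return GenomicInterval(mmap.chrom, 1, mmap.chrom_length_bp)

    if len(current) > 1:
        warnings.warn(
            f"{len(current)} disjoint regions survive (double crossovers?); "
            "reporting their bounding interval",
            stacklevel=2,
        )
    start = current[0][0]
    end = current[-1][1]
    # Report bounds at the closest excluding markers where they exist.
    left = mmap.marker_at_bp(start - 1)
    right = mmap.marker_at_bp(end + 1)
    return GenomicInterval(
        mmap.chrom,
        left.pos_bp if left else start,
        right.pos_bp if right else end,
        left_flank=left.name if left else None,
        right_flank=right.name if right else None,
    )


def interval_to_bed(interval: GenomicInterval) -> str:
    """One BED line (0-based half-open) for the interval."""
    name = f"{interval.left_flank or 'start'}--{interval.right_flank or 'end'}"
    return f"{interval.chrom}\t{interval.start_bp - 1}\t{interval.end_bp}\t{name}"
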