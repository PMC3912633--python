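"""Mutation-by-sequencing filter cascade for EMS mutagenesis screens.

Starting from variant calls for a mutagenized strain and its isogenic
parental strain, the cascade (i) pools variants unique to the mutant as
potential EMS-induced mutations, (ii) restricts them to the genetically
mapped interval, (iii) annotates coding effects against gene models and the
genome sequence, and (iv) ranks the surviving amino-acid-changing candidates,
favouring the C→T/G→A transitions characteristic of EMS and demoting sites
where the parental strain itself carries a different non-reference allele
(such sites are strain polymorphisms, not induced lesions).

Incomplete sequencing coverage of the parental strain produces false
"unique" variants — parental polymorphisms missed in the parental calls —
which is why candidates can optionally be re-checked against a confirmation
hook (the in-silico analogue of Sanger re-sequencing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .mapping import GenomicInterval

__all__ = [
    "Variant",
    "Transcript",
    "GeneModelSet",
    "CandidateReport",
    "read_vcf",
    "write_vcf",
    "unique_mutant_variants",
    "filter_to_interval",
    "annotate_coding_effect",
    "ems_signature",
    "rank_candidates",
    "run_filter_cascade",
]

EFFECTS = ("noncoding", "synonymous", "splice_flag", "missense", "nonsense", "unannotated")
_SEVERITY = {"noncoding": 0, "unannotated": 0, "synonymous": 1, "splice_flag": 2,
             "missense": 3, "nonsense": 4}
SPLICE_WINDOW_BP = 2
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class Variant:
    """A strain-tagged substitution anchored to 1-based genome coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str = "unannotated"
    aa_change: str = ""
    gene_id: str | None = None
    parental_covered: bool | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "missense" and not self.aa_change:
            raise ValueError("missense variants need an aa_change")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def ems_type(self) -> bool:
        """True for the C→T / G→A transitions typical of EMS mutagenesis."""
        return (self.ref.upper(), self.alt.upper()) in {("C", "T"), ("G", "A")}

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt.upper())


def ems_signature(variant: Variant) -> bool:
    """C→T or G→A in reference-strand terms (the EMS mutational signature)."""
    return variant.ems_type


# ---------------------------------------------------------------------------
# Gene models and coding-effect annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """CDS structure of one transcript; coordinates 1-based inclusive."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds: tuple[tuple[int, int], ...]  # ascending genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError(f"CDS segments of {self.transcript_id} not ascending")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


class GeneModelSet:
    """Transcript CDS models plus the backing genome sequence.

    Build directly from in-memory objects or from GFF3 + FASTA files via
    :meth:`from_files`.
    """

    def __init__(self, transcripts: Sequence[Transcript], genome: Mapping[str, str]):
        self.transcripts = list(transcripts)
        self.genome = dict(genome)
        for tx in self.transcripts:
            if tx.chrom not in self.genome:
                raise ValueError(f"transcript {tx.transcript_id} on unknown contig {tx.chrom}")
            chrom_len = len(self.genome[tx.chrom])
            if tx.cds and tx.cds[-1][1] > chrom_len:
                raise ValueError(
                    f"transcript {tx.transcript_id} extends past contig end"
                )

    @classmethod
    def from_files(cls, gff3_path, fasta_path) -> "GeneModelSet":
        import gffutils
        from Bio import SeqIO

        genome = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        transcripts = []
        for mrna in db.features_of_type("mRNA"):
            cds = sorted(
                (c.start, c.end) for c in db.children(mrna, featuretype="CDS")
            )
            if not cds:
                continue
            parents = list(db.parents(mrna, featuretype="gene"))
            gene_id = parents[0].id if parents else mrna.id
            transcripts.append(
                Transcript(
                    transcript_id=mrna.id,
                    gene_id=gene_id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    cds=tuple(cds),
                )
            )
        return cls(transcripts, genome)

    def cds_sequence(self, tx: Transcript) -> str:
        """Spliced CDS in coding (5'→3') orientation."""
        seq = "".join(self.genome[tx.chrom][s - 1 : e] for s, e in tx.cds)
        if tx.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq.upper()

    def translate_cds(self, tx: Transcript) -> str:
        return str(Seq(self.cds_sequence(tx)).translate())


def _cds_index(tx: Transcript, pos: int) -> int | None:
    """0-based index of ``pos`` within the spliced CDS in coding orientation."""
    offset = 0
    plus_index = None
    for s, e in tx.cds:
        if s <= pos <= e:
            plus_index = offset + (pos - s)
            break
        offset += e - s + 1
    if plus_index is None:
        return None
    return plus_index if tx.strand == "+" else tx.cds_length - 1 - plus_index


def _near_splice(tx: Transcript, pos: int) -> bool:
    """True when ``pos`` is intronic within 2 bp of an exon–intron junction."""
    for (s1, e1), (s2, e2) in zip(tx.cds, tx.cds[1:]):
        intron_lo, intron_hi = e1 + 1, s2 - 1
        if intron_lo <= pos <= intron_hi and (
            pos - intron_lo < SPLICE_WINDOW_BP or intron_hi - pos < SPLICE_WINDOW_BP
        ):
            return True
    return False


def annotate_coding_effect(variant: Variant, models: GeneModelSet) -> Variant:
    """Attach the maximal-severity coding effect across overlapping transcripts.

    For each transcript whose CDS covers the variant, the codon containing
    the site is translated before and after the substitution (strand-aware:
    minus-strand CDS complements both alleles).  Severity order:
    nonsense > missense > splice_flag > synonymous > noncoding.  Indels and
    variants whose codon extends past the declared CDS are returned
    ``unannotated`` (the latter with a warning).
    """
    if not variant.is_snv:
        return replace(variant, effect="unannotated", aa_change="")
    if variant.chrom not in models.genome:
        raise ValueError(f"no genome sequence for contig {variant.chrom}")

    best_effect, best_aa, best_gene = "noncoding", "", None
    for tx in models.transcripts:
        if tx.chrom != variant.chrom:
            continue
        idx = _cds_index(tx, variant.pos)
        if idx is None:
            if _near_splice(tx, variant.pos) and _SEVERITY["splice_flag"] > _SEVERITY[best_effect]:
                best_effect, best_aa, best_gene = "splice_flag", "", tx.gene_id
            continue
        if tx.cds_length % 3:
            warnings.warn(
                f"CDS length of {tx.transcript_id} not divisible by 3; "
                f"variant at {variant.chrom}:{variant.pos} left unannotated",
                stacklevel=2,
            )
            return replace(variant, effect="unannotated", aa_change="", gene_id=tx.gene_id)
        cds_seq = models.cds_sequence(tx)
        codon_i, within = divmod(idx, 3)
        codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            warnings.warn(
                f"codon of variant {variant.chrom}:{variant.pos} extends past the "
                f"declared CDS of {tx.transcript_id}; left unannotated",
                stacklevel=2,
            )
            return replace(variant, effect="unannotated", aa_change="", gene_id=tx.gene_id)
        ref_c = variant.ref.upper()
        alt_c = variant.alt.upper()
        if tx.strand == "-":
            ref_c = ref_c.translate(_COMPLEMENT)
            alt_c = alt_c.translate(_COMPLEMENT)
        if codon[within] != ref_c:
            warnings.warn(
                f"reference allele mismatch at {variant.chrom}:{variant.pos} "
                f"(genome has {codon[within]}, variant says {ref_c})",
                stacklevel=2,
            )
        new_codon = codon[:within] + alt_c + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(new_codon).translate())
        if aa_alt == aa_ref:
            effect, aa = "synonymous", ""
        elif aa_alt == "*":
            effect, aa = "nonsense", f"{aa_ref}{codon_i + 1}*"
        else:
            effect, aa = "missense", f"{aa_ref}{codon_i + 1}{aa_alt}"
        if _SEVERITY[effect] > _SEVERITY[best_effect]:
            best_effect, best_aa, best_gene = effect, aa, tx.gene_id
    return replace(variant, effect=best_effect, aa_change=best_aa, gene_id=best_gene)


# ---------------------------------------------------------------------------
# Cascade filters
# ---------------------------------------------------------------------------


def unique_mutant_variants(
    mutant: Iterable[Variant],
    parental: Iterable[Variant],
    parental_called_sites: set[tuple[str, int]] | None = None,
) -> list[Variant]:
    """Variants called in the mutant and absent from the parental strain.

    Matching is by (chrom, pos, alt).  When ``parental_called_sites`` (the
    set of positions with any parental call) is given, each unique variant
    is flagged ``parental_covered`` — uncovered sites are where incomplete
    parental sequencing manufactures false uniques.
    """
    mutant = list(mutant)
    parental = list(parental)
    if mutant and parental:
        m_contigs = {v.chrom for v in mutant}
        p_contigs = {v.chrom for v in parental}
        if m_contigs.isdisjoint(p_contigs):
            raise ValueError(
                "mutant and parental variant sets share no contigs — "
                "reference build mismatch?"
            )
    parental_keys = {v.key for v in parental}
    out = []
    for v in mutant:
        if v.key in parental_keys:
            continue
        if parental_called_sites is not None:
            v = replace(
                v, parental_covered=(v.chrom, v.pos) in parental_called_sites
            )
        out.append(v)
    return out


def filter_to_interval(
    variants: Iterable[Variant], interval: GenomicInterval
) -> list[Variant]:
    """Variants with interval.start <= pos <= interval.end on interval.chrom."""
    return [v for v in variants if interval.contains(v.chrom, v.pos)]


CODING_CHANGE_EFFECTS = {"missense", "nonsense", "splice_flag"}


@dataclass
class CandidateReport:
    """Ranked causal candidates plus the cascade's stage counts."""

    candidates: list[Variant]
    demoted: list[Variant]
    n_unique_mutant: int
    n_in_interval: int
    n_coding_change: int
    n_after_parental_exclusion: int
    rationale: dict[tuple[str, int, str], str] = field(default_factory=dict)

    @property
    def ranked(self) -> list[Variant]:
        """Full ranking: non-demoted candidates first, demoted last."""
        return self.candidates + self.demoted

    @property
    def stage_counts(self) -> tuple[int, int, int, int]:
        return (
            self.n_unique_mutant,
            self.n_in_interval,
            self.n_coding_change,
            self.n_after_parental_exclusion,
        )


def _rank_key(v: Variant):
    return (not v.ems_type, -_SEVERITY[v.effect], v.chrom, v.pos)


def rank_candidates(
    variants: Iterable[Variant],
    parental_site_alleles: Mapping[tuple[str, int], str] | None = None,
    *,
    n_unique_mutant: int | None = None,
    n_in_interval: int | None = None,
    confirm: Callable[[Variant], bool] | None = None,
) -> CandidateReport:
    """Rank annotated, interval-filtered variants as causal candidates.

    Keeps amino-acid-changing effects (missense, nonsense, splice_flag);
    variants at sites where the parental strain carries a *different*
    non-reference allele are demoted below all other candidates (the site is
    polymorphic in the background, so an induced origin is unlikely).
    Remaining candidates are ordered by EMS signature first, then severity,
    then position for determinism.  The optional ``confirm`` hook re-checks
    each coding candidate (in-silico Sanger) and removes failures.
    """
    variants = list(variants)
    n_in = len(variants) if n_in_interval is None else n_in_interval
    n_uni = n_in if n_unique_mutant is None else n_unique_mutant
    coding = [v for v in variants if v.effect in CODING_CHANGE_EFFECTS]
    n_coding = len(coding)
    rationale: dict[tuple[str, int, str], str] = {}

    if confirm is not None:
        kept = []
        for v in coding:
            if confirm(v):
                kept.append(v)
            else:
                rationale[v.key] = "removed: failed confirmation re-check"
        coding = kept

    demoted, primary = [], []
    for v in coding:
        other = (
            parental_site_alleles.get((v.chrom, v.pos))
            if parental_site_alleles is not None
            else None
        )
        if other is not None and other.upper() != v.alt.upper() and other.upper() != v.ref.upper():
            demoted.append(v)
            rationale[v.key] = (
                f"demoted: site also polymorphic in parental strain ({v.ref}->{other})"
            )
        else:
            primary.append(v)
    primary.sort(key=_rank_key)
    demoted.sort(key=_rank_key)
    for rank, v in enumerate(primary, 1):
        rationale.setdefault(
            v.key,
            f"rank {rank}: {v.effect}"
            + (f" {v.aa_change}" if v.aa_change else "")
            + (", EMS-type transition" if v.ems_type else ", non-EMS substitution"),
        )
    return CandidateReport(
        candidates=primary,
        demoted=demoted,
        n_unique_mutant=n_uni,
        n_in_interval=n_in,
        n_coding_change=n_coding,
        n_after_parental_exclusion=len(primary),
        rationale=rationale,
    )


def run_filter_cascade(
    mutant: Iterable[Variant],
    parental: Iterable[Variant],
    interval: GenomicInterval,
    models: GeneModelSet,
    *,
    parental_site_alleles: Mapping[tuple[str, int], str] | None = None,
    confirm: Callable[[Variant], bool] | None = None,
) -> CandidateReport:
    """Full cascade: unique → interval → coding annotation → ranking.

    ``parental_site_alleles`` defaults to the alt alleles of the parental
    call set, which drives the demotion rule for sites polymorphic in the
    background strain.
    """
    parental = list(parental)
    if parental_site_alleles is None:
        parental_site_alleles = {(v.chrom, v.pos): v.alt for v in parental}
    parental_sites = {(v.chrom, v.pos) for v in parental}
    unique = unique_mutant_variants(list(mutant), parental, parental_sites)
    in_interval = filter_to_interval(unique, interval)
    annotated = [annotate_coding_effect(v, models) for v in in_interval]
    return rank_candidates(
        annotated,
        parental_site_alleles,
        n_unique_mutant=len(unique),
        n_in_interval=len(in_interval),
        confirm=confirm,
    )


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)
# ---------------------------------------------------------------------------


def read_vcf(path) -> list[Variant]:
    """Read a (plain or bgzipped) VCF into Variant records.

    Multi-allelic records are split into one Variant per alt allele.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return out


def write_vcf(
    variants: Sequence[Variant], path, contig_lengths: Mapping[str, int]
) -> None:
    """Write variants as an uncompressed VCF with the given contig headers."""
    import pysam

    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            vcf.write(rec)
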