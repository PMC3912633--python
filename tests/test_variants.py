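"""Variant filter cascade: set logic, coding-effect annotation, ranking, VCF I/O."""

import numpy as np
import pytest
from Bio.Seq import Seq

from flysleep.mapping import GenomicInterval
from flysleep.variants import (
    GeneModelSet,
    Transcript,
    Variant,
    annotate_coding_effect,
    ems_signature,
    filter_to_interval,
    rank_candidates,
    read_vcf,
    run_filter_cascade,
    unique_mutant_variants,
    write_vcf,
)


def v(pos, ref="C", alt="T", chrom="3R", **kw):
    return Variant(chrom, pos, ref, alt, **kw)


class TestEmsSignature:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("C", "T", True), ("G", "A", True), ("A", "C", False), ("T", "C", False)],
    )
    def test_signature(self, ref, alt, expected):
        assert ems_signature(v(100, ref, alt)) is expected


class TestUniqueVariants:
    def test_set_difference(self):
        uniq = unique_mutant_variants([v(1), v(2)], [v(2)])
        assert [u.pos for u in uniq] == [1]

    def test_identical_sets_empty(self):
        assert unique_mutant_variants([v(1), v(2)], [v(1), v(2)]) == []

    def test_same_site_different_alt_stays_unique(self):
        # parental polymorphic at the same site with another allele
        uniq = unique_mutant_variants([v(5, "C", "T")], [v(5, "C", "A")])
        assert len(uniq) == 1

    def test_contig_mismatch_rejected(self):
        with pytest.raises(ValueError, match="reference build"):
            unique_mutant_variants([v(1, chrom="3R")], [v(1, chrom="chr3R")])

    def test_parental_coverage_flag(self):
        uniq = unique_mutant_variants(
            [v(1), v(2)], [v(9)], parental_called_sites={("3R", 1)}
        )
        flags = {u.pos: u.parental_covered for u in uniq}
        assert flags == {1: True, 2: False}


class TestIntervalFilter:
    def test_boundaries_inclusive(self):
        iv = GenomicInterval("3R", 100, 200)
        vs = [v(99), v(100), v(200), v(201)]
        assert [x.pos for x in filter_to_interval(vs, iv)] == [100, 200]

    def test_whole_chromosome_identity(self):
        iv = GenomicInterval("3R", 1, 10**9)
        vs = [v(i) for i in (5, 500, 50_000)]
        assert filter_to_interval(vs, iv) == vs

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vs = [v(int(p)) for p in rng.integers(1, 10_000, 200)]
        iv = GenomicInterval("3R", 2_000, 7_000)
        got = filter_to_interval(vs, iv)
        expected = [x for x in vs if 2_000 <= x.pos <= 7_000]
        assert got == expected


def single_gene_models(cds_seq, strand="+", upstream=30, intron_at=None, chrom="3R"):
    """One gene on a synthetic contig; optionally split by a 100-bp intron."""
    if strand == "-":
        genomic_cds = str(Seq(cds_seq).reverse_complement())
    else:
        genomic_cds = cds_seq
    if intron_at is None:
        genome = "A" * upstream + genomic_cds + "A" * 30
        cds = ((upstream + 1, upstream + len(cds_seq)),)
    else:
        left = genomic_cds[:intron_at]
        right = genomic_cds[intron_at:]
        intron = "G" * 100
        genome = "A" * upstream + left + intron + right + "A" * 30
        cds = (
            (upstream + 1, upstream + len(left)),
            (upstream + len(left) + 101, upstream + len(left) + 100 + len(right)),
        )
    tx = Transcript("t1", "g1", chrom, strand, cds)
    return GeneModelSet([tx], {chrom: genome})


class TestCodingEffect:
    def test_acg_to_atg_is_thr_to_met(self):
        # codon 2 of the CDS is ACG; C→T makes ATG: Thr→Met missense
        models = single_gene_models("ATGACGTAA")
        var = v(35, "C", "T")  # position of the C in ACG (codon 2)
        out = annotate_coding_effect(var, models)
        assert out.effect == "missense"
        assert out.aa_change == "T2M"

    def test_wobble_synonymous(self):
        # ACC→ACT: both threonine
        models = single_gene_models("ATGACCTAA")
        out = annotate_coding_effect(v(36, "C", "T"), models)
        assert out.effect == "synonymous"

    def test_nonsense(self):
        # TGG (Trp) → TGA (stop) by G→A at codon position 3
        models = single_gene_models("ATGTGGTAA")
        out = annotate_coding_effect(v(36, "G", "A"), models)
        assert out.effect == "nonsense"
        assert out.aa_change.endswith("*")

    def test_minus_strand_mirror(self):
        """A minus-strand gene gives the same aa_change as its mirror."""
        plus = single_gene_models("ATGACGTAA", strand="+")
        minus = single_gene_models("ATGACGTAA", strand="-")
        out_plus = annotate_coding_effect(v(35, "C", "T"), plus)
        # same CDS base on the minus strand: genomic coordinates mirror, and
        # the genomic allele is the complement (G→A)
        pos_in_cds = 4  # 0-based index of the C within the CDS
        start = minus.transcripts[0].cds[0][0]
        length = minus.transcripts[0].cds_length
        mirror_pos = start + (length - 1 - pos_in_cds)
        out_minus = annotate_coding_effect(v(mirror_pos, "G", "A"), minus)
        assert out_minus.effect == out_plus.effect == "missense"
        assert out_minus.aa_change == out_plus.aa_change == "T2M"

    def test_splice_flag_near_junction(self):
        models = single_gene_models("ATGACGACCACGTAA", intron_at=6)
        tx = models.transcripts[0]
        intron_start = tx.cds[0][1] + 1
        out = annotate_coding_effect(v(intron_start, "G", "A"), models)
        assert out.effect == "splice_flag"
        deep = annotate_coding_effect(v(intron_start + 50, "G", "A"), models)
        assert deep.effect == "noncoding"

    def test_intergenic_noncoding(self):
        models = single_gene_models("ATGACGTAA")
        out = annotate_coding_effect(v(5, "A", "G"), models)
        assert out.effect == "noncoding"

    def test_indel_unannotated(self):
        models = single_gene_models("ATGACGTAA")
        out = annotate_coding_effect(Variant("3R", 35, "CA", "C"), models)
        assert out.effect == "unannotated"

    def test_matches_whole_protein_retranslation_oracle(self):
        """Random CDS substitutions agree with re-translating the protein."""
        rng = np.random.default_rng(99)
        bases = "ACGT"
        for trial in range(100):
            n_codons = int(rng.integers(5, 30))
            cds = "ATG" + "".join(
                bases[i] for i in rng.integers(0, 4, 3 * (n_codons - 2))
            ) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            models = single_gene_models(cds, strand=strand)
            tx = models.transcripts[0]
            # pick a random CDS position, avoiding the stop codon
            idx = int(rng.integers(0, tx.cds_length - 3))
            start = tx.cds[0][0]
            pos = start + idx if strand == "+" else start + (tx.cds_length - 1 - idx)
            genome_ref = models.genome["3R"][pos - 1]
            alt = bases[int(rng.integers(0, 4))]
            if alt == genome_ref:
                continue
            out = annotate_coding_effect(v(pos, genome_ref, alt), models)

            # oracle: substitute in the genome, retranslate the whole protein
            g2 = dict(models.genome)
            s = g2["3R"]
            g2["3R"] = s[: pos - 1] + alt + s[pos:]
            before = models.translate_cds(tx)
            after = GeneModelSet([tx], g2).translate_cds(tx)
            diffs = [i for i, (x, y) in enumerate(zip(before, after)) if x != y]
            if not diffs:
                assert out.effect == "synonymous"
            elif after[diffs[0]] == "*":
                assert out.effect == "nonsense"
            else:
                assert out.effect == "missense"
                assert out.aa_change == (
                    f"{before[diffs[0]]}{diffs[0] + 1}{after[diffs[0]]}"
                )


class TestRanking:
    def _missense(self, pos, ref="C", alt="T"):
        return Variant("3R", pos, ref, alt, effect="missense", aa_change="T2M")

    def test_parental_polymorphic_site_demoted(self):
        a = self._missense(100)
        b = self._missense(200)
        rep = rank_candidates([a, b], {("3R", 100): "G"})
        assert rep.candidates == [b]
        assert rep.demoted == [a]
        assert rep.ranked[0] is b
        assert "polymorphic" in rep.rationale[a.key]

    def test_single_candidate_rank_one(self):
        a = self._missense(100)
        rep = rank_candidates([a], {("3R", 100): "G"})
        assert rep.ranked[0] is a

    def test_ems_before_non_ems(self):
        ems = self._missense(500, "C", "T")
        non = Variant("3R", 100, "A", "G", effect="missense", aa_change="K3E")
        rep = rank_candidates([non, ems])
        assert rep.candidates[0] is ems

    def test_severity_then_position(self):
        mis = self._missense(100)
        non = Variant("3R", 50, "C", "T", effect="nonsense", aa_change="")
        rep = rank_candidates([mis, non])
        assert rep.candidates[0].effect == "nonsense"

    def test_noncoding_dropped(self):
        silent = Variant("3R", 10, "C", "T", effect="synonymous")
        rep = rank_candidates([silent, self._missense(20)])
        assert rep.n_coding_change == 1

    def test_confirm_hook_removes_false_candidates(self):
        a = self._missense(100)
        b = self._missense(200)
        rep = rank_candidates([a, b], confirm=lambda x: x.pos != 100)
        assert rep.candidates == [b]


class TestCascadeCounts:
    def test_counts_non_increasing(self):
        from flysleep.simulate import GenomeSimConfig, simulate_mutagenized_genome

        cfg = GenomeSimConfig(
            chrom_length=500_000, n_genes=10, n_background_variants=60,
            n_ems_mutations=10, causal_gene_index=5, interval_halfwidth=100_000,
        )
        for seed in range(5):
            sim = simulate_mutagenized_genome(cfg, seed)
            rep = run_filter_cascade(
                sim.mutant_variants, sim.parental_variants, sim.interval, sim.models
            )
            c = rep.stage_counts
            assert c[0] >= c[1] >= c[2] >= c[3]


class TestVcfIO:
    def test_round_trip(self, tmp_path):
        vs = [v(10), v(20, "G", "A"), v(30, "A", "C")]
        path = tmp_path / "test.vcf"
        write_vcf(vs, path, {"3R": 1_000})
        back = read_vcf(path)
        assert [(x.chrom, x.pos, x.ref, x.alt) for x in back] == [
            ("3R", 10, "C", "T"),
            ("3R", 20, "G", "A"),
            ("3R", 30, "A", "C"),
        ]
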