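"""Interval index, sequence masks and genic categorisation."""

import numpy as np
import pytest

from iidmr.annotation import (
    GeneModel,
    GenicCategory,
    GenomicInterval,
    IntervalIndex,
    classify_variant,
    find_dinucleotide_runs,
    find_homopolymer_runs,
    merge_intervals,
    overlap_fraction,
    read_bed,
    write_bed,
)


class TestIntervalIndex:
    def test_query_inside_single_interval(self):
        iv = GenomicInterval("chr1", 100, 200, "x")
        idx = IntervalIndex([iv])
        assert idx.overlap("chr1", 150, 160) == [iv]

    def test_empty_index(self):
        assert IntervalIndex().overlap("chr1", 0, 10) == []

    def test_adjacency_is_not_overlap(self):
        idx = IntervalIndex([GenomicInterval("chr1", 100, 200)])
        assert not idx.overlaps("chr1", 200, 300)
        assert not idx.overlaps("chr1", 0, 100)
        assert idx.overlaps("chr1", 199, 200)

    def test_matches_brute_force_on_random_set(self):
        rng = np.random.default_rng(0)
        ivs = []
        for i in range(1000):
            s = int(rng.integers(0, 10_000))
            ivs.append(
                GenomicInterval(f"chr{rng.integers(1, 4)}", s, s + int(rng.integers(1, 300)), str(i))
            )
        idx = IntervalIndex(ivs)
        for _ in range(200):
            chrom = f"chr{rng.integers(1, 4)}"
            qs = int(rng.integers(0, 10_000))
            qe = qs + int(rng.integers(1, 500))
            expected = sorted(
                (iv for iv in ivs if iv.chrom == chrom and iv.start < qe and qs < iv.end),
                key=lambda iv: (iv.start, iv.end, iv.label),
            )
            assert idx.overlap(chrom, qs, qe) == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestBedRoundTrip:
    def test_write_read(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 100, "IAP", 4.0),
            GenomicInterval("chr2", 50, 70, "RLTR4"),
        ]
        path = tmp_path / "a.bed"
        write_bed(ivs, path)
        back = read_bed(path)
        assert [(i.chrom, i.start, i.end, i.label) for i in back] == [
            (i.chrom, i.start, i.end, i.label) for i in ivs
        ]
        assert back[0].score == 4.0 and back[1].score is None


class TestHomopolymerMask:
    def test_nine_base_run_masked_with_flanks(self):
        seq = "C" + "A" * 9 + "C" * 5
        runs = find_homopolymer_runs(seq, min_len=8, flank=1)
        assert [(r.start, r.end) for r in runs] == [(0, 11)]

    def test_eight_base_run_not_masked(self):
        seq = "C" + "A" * 8 + "CGCGC"
        assert find_homopolymer_runs(seq, min_len=8, flank=1) == []

    def test_alternating_sequence_unmasked(self):
        assert find_homopolymer_runs("ACGT" * 100, min_len=8, flank=1) == []

    def test_clipping_at_sequence_bounds(self):
        runs = find_homopolymer_runs("A" * 9, min_len=8, flank=1)
        assert [(r.start, r.end) for r in runs] == [(0, 9)]

    def test_n_never_forms_runs(self):
        assert find_homopolymer_runs("N" * 50, min_len=8, flank=1) == []

    def test_every_masked_base_in_run_before_flanking(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500)) + "G" * 12 + "".join(
            rng.choice(list("ACGT"), 100)
        )
        for r in find_homopolymer_runs(seq, min_len=8, flank=0):
            assert len(set(seq[r.start : r.end])) == 1
            assert r.end - r.start > 8


class TestDinucleotideMask:
    def test_sixteen_bp_run_masked(self):
        seq = "GC" + "AT" * 8 + "GGC"
        runs = find_dinucleotide_runs(seq, min_len=14, flank=1)
        assert [(r.start, r.end) for r in runs] == [(1, 19)]

    def test_fourteen_bp_run_not_masked(self):
        seq = "GC" + "AT" * 7 + "GGC"
        assert find_dinucleotide_runs(seq, min_len=14, flank=1) == []

    def test_period_four_repeat_unmasked(self):
        assert find_dinucleotide_runs("ACGT" * 10, min_len=14, flank=1) == []

    def test_odd_length_run_counted(self):
        # 15 bp of alternating CA, starting mid-unit
        seq = "GG" + "AC" * 7 + "A" + "GG"
        runs = find_dinucleotide_runs(seq, min_len=14, flank=0)
        assert [(r.start, r.end) for r in runs] == [(2, 17)]

    def test_homodimer_excluded(self):
        # AAAA... is the homopolymer rule's business
        assert find_dinucleotide_runs("A" * 30, min_len=14, flank=1) == []


def plus_gene(g=10_000):
    """Gene on +: exon1 [g, g+300) (UTR to g+150), intron, exon2 [g+800, g+1100)."""
    return GeneModel(
        "gA", "chr1", "+", [(g, g + 300), (g + 800, g + 1100)], g + 150, g + 950
    )


def make_ref(gene, length=20_000):
    seq = list("ACGT" * (length // 4))
    cds_pos = list(range(gene.cds_start, gene.exons[0][1])) + list(
        range(gene.exons[1][0], gene.cds_end)
    )
    for i, p in enumerate(cds_pos):
        seq[p] = "GCT"[i % 3]
    return {"chr1": "".join(seq)}


class TestClassifyVariant:
    def setup_method(self):
        self.gene = plus_gene()
        self.ref = make_ref(self.gene)
        self.genes = [self.gene]

    def call(self, pos, alt="C", ref_base=None):
        ref_base = ref_base or self.ref["chr1"][pos]
        return classify_variant("chr1", pos, ref_base, alt, self.genes, self.ref)

    def test_synonymous_third_position(self):
        # GCT -> GCC, both Ala
        pos = self.gene.cds_start + 2
        assert self.call(pos, alt="C") == GenicCategory.exonic_synonymous

    def test_nonsynonymous_second_position(self):
        # GCT -> GTT, Ala -> Val
        pos = self.gene.cds_start + 1
        assert self.call(pos, alt="T") == GenicCategory.exonic_nonsynonymous

    def test_upstream_within_2kb(self):
        assert self.call(10_000 - 1500, alt="A", ref_base="C") == GenicCategory.upstream_2kb

    def test_downstream_within_2kb(self):
        assert self.call(11_100 + 500, alt="A", ref_base="C") == GenicCategory.downstream_2kb

    def test_intergenic_beyond_2kb(self):
        assert self.call(10_000 - 2500, alt="A", ref_base="C") == GenicCategory.intergenic

    def test_utr_and_intron_and_splice(self):
        assert self.call(10_050, alt="A", ref_base="C") == GenicCategory.utr
        assert self.call(10_500, alt="A", ref_base="C") == GenicCategory.intronic
        assert self.call(10_300, alt="A", ref_base="C") == GenicCategory.splice_junction
        assert self.call(10_799, alt="C", ref_base="A") == GenicCategory.splice_junction
        # third bp into the intron is plain intronic
        assert self.call(10_302, alt="A", ref_base="C") == GenicCategory.intronic

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("chr1", 100, "AT", "A", self.genes, self.ref)

    def test_reverse_complement_symmetry(self):
        """A minus-strand gene classifies the complement like its plus mirror."""
        from Bio.Seq import Seq

        g = 10_000
        plus = self.gene
        ref_plus = self.ref["chr1"]
        length = len(ref_plus)
        # mirror construction: reverse-complement genome, flip coordinates
        ref_minus = {"chr1": str(Seq(ref_plus).reverse_complement())}
        minus = GeneModel(
            "gA_rc",
            "chr1",
            "-",
            [(length - e, length - s) for s, e in plus.exons],
            length - plus.cds_end,
            length - plus.cds_start,
        )
        for pos, alt in [
            (plus.cds_start + 2, "C"),
            (plus.cds_start + 1, "T"),
            (10_050, "A"),
            (10_500, "A"),
        ]:
            fwd = classify_variant(
                "chr1", pos, ref_plus[pos], alt, [plus], {"chr1": ref_plus}
            )
            mpos = length - 1 - pos
            mref = str(Seq(ref_plus[pos]).complement())
            malt = str(Seq(alt).complement())
            rev = classify_variant("chr1", mpos, mref, malt, [minus], ref_minus)
            assert fwd == rev

    def test_partition_is_exhaustive_and_unique(self):
        rng = np.random.default_rng(3)
        cats = []
        for _ in range(300):
            pos = int(rng.integers(5_000, 15_000))
            ref_base = self.ref["chr1"][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            cats.append(self.call(pos, alt=str(alt), ref_base=ref_base))
        assert len(cats) == 300  # every SNV got exactly one category
        assert all(isinstance(c, GenicCategory) for c in cats)


class TestOverlapFraction:
    def test_half_overlap(self):
        a = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 100, 110)]
        b = [GenomicInterval("chr1", 5, 8)]
        assert overlap_fraction(a, b) == (1, 0.5)

    def test_identical_sets(self):
        a = [GenomicInterval("chr1", 0, 10)]
        assert overlap_fraction(a, a) == (1, 1.0)

    def test_empty_a_undefined(self):
        assert overlap_fraction([], [GenomicInterval("chr1", 0, 10)]) == (0, None)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)

        def random_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                out.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 100))))
            return out

        a, b = random_set(80), random_set(60)
        count, frac = overlap_fraction(a, b)
        brute = sum(
            1 for x in a if any(x.start < y.end and y.start < x.end for y in b)
        )
        assert count == brute and frac == brute / len(a)


class TestMergeIntervals:
    def test_output_disjoint_and_covering(self):
        rng = np.random.default_rng(5)
        ivs = []
        for _ in range(200):
            s = int(rng.integers(0, 2000))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 50))))
        merged = merge_intervals(ivs)
        for m1, m2 in zip(merged, merged[1:]):
            assert m1.end < m2.start
        covered = set()
        for iv in ivs:
            covered.update(range(iv.start, iv.end))
        merged_cov = set()
        for m in merged:
            merged_cov.update(range(m.start, m.end))
        assert covered == merged_cov
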