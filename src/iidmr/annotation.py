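"""Genomic interval collections, sequence-derived masks and genic categories.

Coordinates are 0-based half-open throughout; 1-based formats (BED is
already 0-based; GFF3 is converted) are handled at the boundary.  Overlap
everywhere means an intersection of at least 1 bp on half-open intervals —
adjacency is not overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "IntervalIndex",
    "GeneModel",
    "GenicCategory",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "find_homopolymer_runs",
    "find_dinucleotide_runs",
    "read_gene_models",
    "classify_variant",
    "overlap_fraction",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval with a free-text label and optional score."""

    chrom: str
    start: int
    end: int
    label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalIndex:
    """Overlap-queryable collection of :class:`GenomicInterval`.

    Queries return the original (unmerged) intervals intersecting the probe
    by at least 1 bp.
    """

    def __init__(self, intervals: list[GenomicInterval] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals or []:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlap(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.label))
        return hits

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))


def read_bed(path, label_col: int = 3, score_col: int | None = 4) -> list[GenomicInterval]:
    """Read a BED(3-6+) file into intervals.

    ``label_col``/``score_col`` pick which 0-based columns supply the label
    and score (repeat periodicity, mapping quality, ...); columns beyond
    what the file has are ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = []
    for row in df.itertuples(index=False):
        label = str(row[label_col]) if label_col < len(row) else ""
        score = None
        if score_col is not None and score_col < len(row):
            try:
                score = float(row[score_col])
            except (TypeError, ValueError):
                score = None
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), label, score))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\n")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or touching runs merged per chromosome."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def _flank_clip_merge(
    runs: list[tuple[int, int]], flank: int, seq_len: int, chrom: str, label: str
) -> list[GenomicInterval]:
    ivs = [
        GenomicInterval(chrom, max(0, s - flank), min(seq_len, e + flank), label)
        for s, e in runs
    ]
    merged = merge_intervals(ivs)
    return [GenomicInterval(m.chrom, m.start, m.end, label) for m in merged]


def find_homopolymer_runs(
    sequence: str, min_len: int = 8, flank: int = 1, chrom: str = ""
) -> list[GenomicInterval]:
    """Mask maximal single-base runs strictly longer than ``min_len``.

    Each qualifying run is extended by ``flank`` bp on both sides and
    clipped to the sequence; overlapping masks are merged.  ``N`` never
    forms a run.  Defaults mask homopolymers >8 bp plus 1 bp either end.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = sequence.upper()
    runs = [
        (m.start(), m.end())
        for m in re.finditer(r"([ACGT])\1*", seq)
        if m.end() - m.start() > min_len
    ]
    return _flank_clip_merge(runs, flank, len(seq), chrom or "seq", "homopolymer")


_DIMERS = [
    a + b for a in "ACGT" for b in "ACGT" if a != b
]  # homodimers covered by the homopolymer rule


def find_dinucleotide_runs(
    sequence: str, min_len: int = 14, flank: int = 1, chrom: str = ""
) -> list[GenomicInterval]:
    """Mask maximal perfect dinucleotide tandem runs strictly longer than ``min_len`` bp.

    A run is a stretch of alternating distinct bases (e.g. ATATAT...,
    partial trailing unit included in the length).  Qualifying runs are
    flanked, clipped and merged as in :func:`find_homopolymer_runs`.
    Defaults mask dinucleotide runs >14 bp plus 1 bp either end.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = sequence.upper()
    runs: list[tuple[int, int]] = []
    for d in _DIMERS:
        # at least two full units, optional trailing half unit
        pat = re.compile(f"(?:{d}){{2,}}(?:{d[0]})?")
        for m in pat.finditer(seq):
            if m.end() - m.start() > min_len:
                runs.append((m.start(), m.end()))
    return _flank_clip_merge(runs, flank, len(seq), chrom or "seq", "dinucleotide")


@dataclass
class GeneModel:
    """Single-transcript gene model with exon structure and CDS bounds.

    ``exons`` are non-overlapping half-open intervals in genomic order;
    ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates (None for non-coding genes).  ``strand`` is '+' or '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: half-specified CDS bounds")
        if self.cds_start is not None:
            if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
                raise ValueError(f"{self.gene_id}: CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def cds_segments(self) -> list[tuple[int, int]]:
        """Exon pieces inside the CDS bounds, genomic order."""
        if not self.is_coding:
            return []
        segs = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                segs.append((cs, ce))
        return segs


class GenicCategory(str, Enum):
    """Mutually exclusive genic categories for an SNV (precedence order)."""

    exonic_nonsynonymous = "exonic_nonsynonymous"
    exonic_synonymous = "exonic_synonymous"
    splice_junction = "splice_junction"
    utr = "UTR"
    intronic = "intronic"
    upstream_2kb = "upstream_2kb"
    downstream_2kb = "downstream_2kb"
    intergenic = "intergenic"


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Read single-transcript gene models from GFF3 (gene/mRNA/exon/CDS)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def _coding_effect(gene: GeneModel, pos: int, ref: str, alt: str, chrom_seq: str) -> GenicCategory:
    """Synonymous/non-synonymous call for a position inside the CDS."""
    segs = gene.cds_segments()
    offset = 0
    cds_off = None
    for s, e in segs:
        if s <= pos < e:
            cds_off = offset + (pos - s)
            break
        offset += e - s
    if cds_off is None:  # pragma: no cover - guarded by caller
        raise ValueError("position not in CDS")
    cds_seq = "".join(chrom_seq[s:e] for s, e in segs).upper()
    alt_seq = cds_seq[:cds_off] + alt.upper() + cds_seq[cds_off + 1 :]
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_seq = str(Seq(alt_seq).reverse_complement())
        cds_off = len(cds_seq) - 1 - cds_off
    codon_i = cds_off // 3
    ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = alt_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(ref_codon) < 3:  # trailing partial codon: treat conservatively
        return GenicCategory.exonic_nonsynonymous
    if str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate()):
        return GenicCategory.exonic_synonymous
    return GenicCategory.exonic_nonsynonymous


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: list[GeneModel],
    reference: dict[str, str],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    splice_bp: int = 2,
) -> GenicCategory:
    """Assign an SNV to exactly one genic category.

    Precedence when a variant relates to several genes or several features
    of one gene: coding exon (synonymous/non-synonymous by codon
    substitution under the standard genetic code) > splice junction (within
    ``splice_bp`` of an exon-intron boundary, intronic side) > UTR (exonic
    non-coding) > intronic > upstream (within ``upstream_bp`` 5' of the
    transcript, strand-aware) > downstream > intergenic.
    """
    if len(ref) != 1 or len(alt) != 1 or ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
        raise ValueError(f"{chrom}:{pos} {ref}>{alt}: only single-base SNVs supported")
    found: set[GenicCategory] = set()
    coding_call: GenicCategory | None = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if gene.start <= pos < gene.end:
            in_exon = any(s <= pos < e for s, e in gene.exons)
            if in_exon:
                if gene.is_coding and gene.cds_start <= pos < gene.cds_end:
                    call = _coding_effect(gene, pos, ref, alt, reference[chrom])
                    if coding_call is None or call == GenicCategory.exonic_nonsynonymous:
                        coding_call = call
                else:
                    # exonic but non-coding: UTR of a coding gene, or any
                    # exon of a non-coding gene
                    found.add(GenicCategory.utr)
            else:
                near_junction = any(
                    (e <= pos < e + splice_bp) or (s - splice_bp <= pos < s)
                    for s, e in gene.exons
                )
                found.add(
                    GenicCategory.splice_junction if near_junction else GenicCategory.intronic
                )
        else:
            if gene.strand == "+":
                up = gene.start - upstream_bp <= pos < gene.start
                down = gene.end <= pos < gene.end + downstream_bp
            else:
                up = gene.end <= pos < gene.end + upstream_bp
                down = gene.start - downstream_bp <= pos < gene.start
            if up:
                found.add(GenicCategory.upstream_2kb)
            elif down:
                found.add(GenicCategory.downstream_2kb)
    if coding_call is not None:
        return coding_call
    for cat in (
        GenicCategory.splice_junction,
        GenicCategory.utr,
        GenicCategory.intronic,
        GenicCategory.upstream_2kb,
        GenicCategory.downstream_2kb,
    ):
        if cat in found:
            return cat
    return GenicCategory.intergenic


def overlap_fraction(
    regions_a: list[GenomicInterval], regions_b: list[GenomicInterval]
) -> tuple[int, float | None]:
    """Count and fraction of a-regions intersecting (>=1 bp) any b-region.

    Returns ``(count, fraction)``; fraction is None (undefined) for an
    empty a-set.
    """
    if not regions_a:
        return 0, None
    index = IntervalIndex(list(regions_b))
    count = sum(1 for a in regions_a if index.overlaps(a.chrom, a.start, a.end))
    return count, count / len(regions_a)
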