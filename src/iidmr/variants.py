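"""Variant-level QC: zygosity, post-call exclusion filters, table
partitioning between two individuals, and germline mutation-rate
extrapolation.

Zygosity is classified purely from the variant-supporting read fraction:
above 0.90 homozygous-variant, at least 0.30 heterozygous, anything
positive below 0.30 discarded as unreliable, exactly 0 reference.  The
post-call filters remove variants in repetitive or low-confidence sequence
(simple repeats of short periodicity, homopolymer and dinucleotide runs,
low mapping quality) and clustered heterozygous calls inside annotated
repeats or segmental duplications — the signature of mismapped paralogous
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .annotation import GenicCategory, GenomicInterval, IntervalIndex

__all__ = [
    "ZygosityClass",
    "VariantCall",
    "MutationRateParams",
    "classify_zygosity",
    "read_vcf_calls",
    "apply_exclusion_filters",
    "partition_variant_tables",
    "estimate_mutation_rate",
]


class ZygosityClass(str, Enum):
    homozygous_variant = "homozygous_variant"
    heterozygous = "heterozygous"
    reference = "reference"
    discarded = "discarded"


def classify_zygosity(
    variant_fraction: float,
    min_het_fraction: float = 0.30,
    min_hom_fraction: float = 0.90,
) -> ZygosityClass:
    """Zygosity from the variant-supporting read fraction.

    Strictly more than ``min_hom_fraction`` -> homozygous-variant (a
    fraction of exactly 0.90 is heterozygous); at least ``min_het_fraction``
    -> heterozygous; positive but below that -> discarded; zero ->
    reference.
    """
    if not 0 <= variant_fraction <= 1:
        raise ValueError("variant fraction must be in [0, 1]")
    if variant_fraction > min_hom_fraction:
        return ZygosityClass.homozygous_variant
    if variant_fraction >= min_het_fraction:
        return ZygosityClass.heterozygous
    if variant_fraction > 0:
        return ZygosityClass.discarded
    return ZygosityClass.reference


@dataclass
class VariantCall:
    """An SNV with per-individual allele support and mask membership flags."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    fractions: dict[str, float]  # individual -> variant-supporting fraction
    depths: dict[str, int]
    flags: set[str] = field(default_factory=set)
    category: GenicCategory | None = None

    def zygosity(self, individual: str, **thresholds) -> ZygosityClass:
        return classify_zygosity(self.fractions[individual], **thresholds)


def read_vcf_calls(path, individuals: list[str] | None = None) -> list[VariantCall]:
    """Read SNV calls from a VCF, deriving variant-support fractions.

    The fraction per sample comes from the AD (allelic depth) field when
    present, else from DP4; absence of both is an error.  Multi-allelic and
    non-SNV records are skipped.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = individuals or list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            fractions: dict[str, float] = {}
            depths: dict[str, int] = {}
            for s in samples:
                sample = rec.samples[s]
                if "AD" in sample and sample["AD"] is not None and sample["AD"][0] is not None:
                    ad = sample["AD"]
                    ref_d, alt_d = int(ad[0]), int(ad[1])
                elif "DP4" in sample and sample["DP4"] is not None:
                    dp4 = sample["DP4"]
                    ref_d = int(dp4[0]) + int(dp4[1])
                    alt_d = int(dp4[2]) + int(dp4[3])
                else:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: sample {s} has neither AD nor DP4"
                    )
                depth = ref_d + alt_d
                fractions[s] = alt_d / depth if depth else 0.0
                depths[s] = depth
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=ref,
                    alt=alt,
                    fractions=fractions,
                    depths=depths,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def apply_exclusion_filters(
    variants: list[VariantCall],
    masks: dict[str, list[GenomicInterval]] | None = None,
    segdup_or_repeat: list[GenomicInterval] | None = None,
    cluster_window_bp: int = 10_000,
    cluster_min: int = 3,
    cluster_mode: str = "variant",
) -> tuple[list[VariantCall], list[tuple[VariantCall, list[str]]]]:
    """Apply the post-call exclusion filters.

    ``masks`` maps a reason name (e.g. ``simple_repeat``, ``homopolymer``,
    ``dinucleotide``, ``low_mq``) to intervals; a variant overlapping any
    mask is excluded with that reason.  Independently, heterozygous calls
    lying in a maximal group of at least ``cluster_min`` heterozygous calls
    with consecutive spacing <= ``cluster_window_bp`` *and* overlapping a
    segmental-duplication/repeat annotation are excluded with reason
    ``clustered_het``.  With ``cluster_mode="region"`` every call in the
    span of a qualifying cluster is excluded instead of only the members
    overlapping the annotation.

    Returns ``(passed, excluded)`` where each excluded entry carries its
    reasons; input order (genome order) is preserved.
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    mask_indices = {
        name: IntervalIndex(ivs) for name, ivs in (masks or {}).items()
    }
    segdup_index = IntervalIndex(segdup_or_repeat or [])

    reasons: dict[int, list[str]] = {i: [] for i in range(len(variants))}
    for i, v in enumerate(variants):
        for name, index in mask_indices.items():
            if index.overlaps(v.chrom, v.pos, v.pos + 1):
                reasons[i].append(name)

    # clustered heterozygotes: any individual heterozygous at the site
    het_idx = [
        i
        for i, v in enumerate(variants)
        if any(
            classify_zygosity(f) is ZygosityClass.heterozygous
            for f in v.fractions.values()
        )
    ]
    group: list[int] = []

    def flush(group: list[int]) -> None:
        if len(group) < cluster_min:
            return
        members = [variants[i] for i in group]
        in_segdup = [
            segdup_index.overlaps(m.chrom, m.pos, m.pos + 1) for m in members
        ]
        if cluster_mode == "variant":
            for i, hit in zip(group, in_segdup):
                if hit:
                    reasons[i].append("clustered_het")
        elif cluster_mode == "region":
            if any(in_segdup):
                span = (members[0].chrom, members[0].pos, members[-1].pos + 1)
                for i, v in enumerate(variants):
                    if v.chrom == span[0] and span[1] <= v.pos < span[2]:
                        if "clustered_het" not in reasons[i]:
                            reasons[i].append("clustered_het")
        else:
            raise ValueError(f"unknown cluster_mode {cluster_mode!r}")

    for i in het_idx:
        if group and (
            variants[i].chrom != variants[group[-1]].chrom
            or variants[i].pos - variants[group[-1]].pos > cluster_window_bp
        ):
            flush(group)
            group = []
        group.append(i)
    flush(group)

    passed, excluded = [], []
    for i, v in enumerate(variants):
        if reasons[i]:
            v.flags.update(reasons[i])
            excluded.append((v, reasons[i]))
        else:
            passed.append(v)
    return passed, excluded


_CATEGORY_ORDER = [
    GenicCategory.intergenic,
    GenicCategory.intronic,
    GenicCategory.exonic_nonsynonymous,
    GenicCategory.exonic_synonymous,
    GenicCategory.splice_junction,
    GenicCategory.upstream_2kb,
    GenicCategory.downstream_2kb,
    GenicCategory.utr,
]


def partition_variant_tables(
    variants: list[VariantCall],
    individual_a: str,
    individual_b: str,
) -> dict[str, pd.DataFrame | dict]:
    """Partition two individuals' calls into the published table layout.

    ``differs_between_mice``: unequal zygosity classes (e.g. heterozygous
    in one, reference in the other); ``shared_het``: both heterozygous;
    ``shared_hom``: both homozygous-variant; a discarded class in either
    individual routes the site to ``indeterminate``; both-reference sites
    are counted separately.  Per-partition counts are broken down by
    :class:`~iidmr.annotation.GenicCategory` when variants carry one.
    """
    bins: dict[str, list[VariantCall]] = {
        "differs_between_mice": [],
        "shared_het": [],
        "shared_hom": [],
        "both_reference": [],
        "indeterminate": [],
    }
    for v in variants:
        za = v.zygosity(individual_a)
        zb = v.zygosity(individual_b)
        if ZygosityClass.discarded in (za, zb):
            bins["indeterminate"].append(v)
        elif za == zb == ZygosityClass.reference:
            bins["both_reference"].append(v)
        elif za == zb == ZygosityClass.heterozygous:
            bins["shared_het"].append(v)
        elif za == zb == ZygosityClass.homozygous_variant:
            bins["shared_hom"].append(v)
        else:
            bins["differs_between_mice"].append(v)

    def category_counts(calls: list[VariantCall]) -> pd.Series:
        counts = {c.value: 0 for c in _CATEGORY_ORDER}
        for v in calls:
            if v.category is not None:
                counts[v.category.value] += 1
        s = pd.Series(counts)
        s["total"] = len(calls)
        return s

    table = pd.DataFrame(
        {name: category_counts(calls) for name, calls in bins.items()}
    )
    return {"bins": bins, "counts": table}


@dataclass(frozen=True)
class MutationRateParams:
    """Inputs of the germline mutation-rate extrapolation.

    n_validated_de_novo
        Candidates confirmed absent from both parents (true de novo).
    n_tested
        Candidates for which parental data could be obtained.
    n_candidates
        Genome-wide pool of candidate variants of the tested class.
    false_discovery_rate
        Experimentally derived fraction of false-positive calls (0.20).
    false_negative_rate
        Fraction of true variants missed by calling (0.23).
    callable_bp
        Genome length in which variants of this class could be called
        (2.136e9 bp after removing sex chromosomes, unplaced contigs and
        repetitive/low-coverage sequence).
    n_transmitted_genomes
        Haploid genome transmissions observed (two diploid probands = 4).
    """

    n_validated_de_novo: int
    n_tested: int
    n_candidates: int
    false_discovery_rate: float = 0.20
    false_negative_rate: float = 0.23
    callable_bp: int = 2_136_000_000
    n_transmitted_genomes: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.false_discovery_rate < 1:
            raise ValueError("false_discovery_rate must be in [0, 1)")
        if not 0 <= self.false_negative_rate < 1:
            raise ValueError("false_negative_rate must be in [0, 1)")
        if not 0 <= self.n_validated_de_novo <= self.n_tested <= self.n_candidates:
            raise ValueError("need n_validated <= n_tested <= n_candidates")


def estimate_mutation_rate(params: MutationRateParams) -> float:
    """Extrapolated germline mutation rate per base pair per generation.

    The validated de-novo fraction among tested candidates is scaled to the
    genome-wide candidate pool, corrected down for the false-discovery rate
    and up for the false-negative rate, and divided by the callable genome
    times the number of transmitted haploid genomes::

        rate = (v / t) * C * (1 - FDR) / (1 - FNR) / (callable_bp * G)
    """
    if params.n_tested == 0:
        raise ValueError("n_tested must be positive")
    denom = params.callable_bp * params.n_transmitted_genomes
    if denom == 0:
        raise ValueError("callable_bp and n_transmitted_genomes must be positive")
    expected_true = (
        (params.n_validated_de_novo / params.n_tested)
        * params.n_candidates
        * (1 - params.false_discovery_rate)
        / (1 - params.false_negative_rate)
    )
    return expected_true / denom
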