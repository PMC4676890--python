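"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: multi-individual
WGBS count data with planted DMRs, repeat/ERV annotations, a variant
fixture (VCF + GFF3 + FASTA + BED masks) realising requested genic-category
and zygosity structure, and clonal bisulphite call sets.

The methylome generator emulates the study design: five inbred littermates,
beta-distributed per-CpG methylation with a global mean near 0.8,
negative-binomial read coverage placing most CpGs at or above six reads,
and two classes of planted DMRs — large-range "ERV-like" regions and
modest-range "regulatory-like" regions.  Outside planted regions every
individual shares the same per-CpG methylation probability, so the
heterogeneity test sees a true null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenicCategory, GenomicInterval
from .clonal import CloneSet
from .methylome import MethylomeSet

__all__ = [
    "PlantedDMR",
    "SimulationConfig",
    "generate_planted_dmrs",
    "simulate_methylomes",
    "split_strand_counts",
    "VariantFixtureConfig",
    "VariantFixture",
    "simulate_variant_fixture",
    "simulate_clones",
    "write_vcf",
    "write_gff3",
    "write_fasta",
]


# Published per-category variant counts from the two-littermate whole-genome
# comparison that this fixture emulates: variants differing between the two
# mice (heterozygous in one, wild type in the other), and variants shared by
# both against the reference strain (both heterozygous / both homozygous).
# The shared-het exonic subdivision is 12 non-synonymous + 7 synonymous as
# printed; the fixture realises the subdivision, so its exonic total is 19.
LITTERMATE_DIFF_COUNTS: dict[str, int] = {
    "intergenic": 607,
    "intronic": 324,
    "exonic_nonsynonymous": 7,
    "exonic_synonymous": 4,
    "splice_junction": 1,
    "upstream_2kb": 18,
    "downstream_2kb": 16,
    "UTR": 8,
}  # total 985

COLONY_SHARED_HET_COUNTS: dict[str, int] = {
    "intergenic": 734,
    "intronic": 345,
    "exonic_nonsynonymous": 12,
    "exonic_synonymous": 7,
    "splice_junction": 0,
    "upstream_2kb": 7,
    "downstream_2kb": 11,
    "UTR": 12,
}  # printed total 1130 with exonic 21; subdivision sums to 19

COLONY_SHARED_HOM_COUNTS: dict[str, int] = {
    "intergenic": 2926,
    "intronic": 1891,
    "exonic_nonsynonymous": 19,
    "exonic_synonymous": 30,
    "splice_junction": 9,
    "upstream_2kb": 79,
    "downstream_2kb": 65,
    "UTR": 36,
}  # total 5055


@dataclass(frozen=True)
class PlantedDMR:
    """A planted differentially methylated region.

    ``targets`` gives each individual's true methylation probability inside
    the region; ``n_cpgs`` CpGs are placed evenly across the interval.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    targets: tuple[float, ...]
    class_tag: str = "regulatory-like"  # or "ERV-like"

    def __post_init__(self) -> None:
        if self.n_cpgs < 6:
            raise ValueError("planted DMRs carry >= 6 CpGs")
        if any(not 0 <= t <= 1 for t in self.targets):
            raise ValueError("targets must be in [0, 1]")
        if self.end - self.start < 2 * self.n_cpgs:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} too small "
                f"for {self.n_cpgs} CpGs"
            )


@dataclass
class SimulationConfig:
    """Study conditions for the methylome generator.

    Defaults echo the printed properties of the real data: five
    individuals, global methylation centred on 0.8 (Beta(8, 2)), and
    negative-binomial coverage (mean 15, dispersion 10) under which the
    large majority of CpGs reach six reads.
    """

    seed: int = 0
    n_individuals: int = 5
    individual_names: list[str] | None = None
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    cpg_spacing_bp: float = 100.0  # mean background inter-CpG gap
    island_every_bp: float = 50_000.0  # mean spacing of CpG-island clusters
    island_n_cpgs: int = 30
    island_spacing_bp: float = 15.0
    coverage_mean: float = 15.0
    coverage_dispersion: float = 10.0
    beta_a: float = 8.0
    beta_b: float = 2.0
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)

    def names(self) -> list[str]:
        if self.individual_names is not None:
            return list(self.individual_names)
        return [f"mouse{i + 1}" for i in range(self.n_individuals)]


def generate_planted_dmrs(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n_individuals: int,
    n_erv_like: int = 0,
    n_regulatory_like: int = 0,
    erv_range: float = 0.6,
    erv_range_sd: float = 0.1,
    regulatory_range: float = 0.25,
    regulatory_range_sd: float = 0.05,
    n_cpgs: int = 8,
    width_bp: int = 600,
    margin_bp: int = 2000,
) -> list[PlantedDMR]:
    """Draw non-overlapping planted DMRs of the two classes.

    Each region gets per-individual targets spanning a methylation range
    drawn from N(range, sd) (clipped to [0.1, 0.9]); the remaining
    individuals sit uniformly between the extremes.  ERV-like regions get
    the large default range, regulatory-like the modest one.
    """
    specs = [("ERV-like", erv_range, erv_range_sd)] * n_erv_like + [
        ("regulatory-like", regulatory_range, regulatory_range_sd)
    ] * n_regulatory_like
    chroms = sorted(chrom_lengths)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[PlantedDMR] = []
    for tag, mean_range, sd in specs:
        r = float(np.clip(rng.normal(mean_range, sd), 0.1, 0.9))
        hi_cap = 0.95 - r
        lo = float(rng.uniform(0.05, hi_cap)) if hi_cap > 0.05 else 0.05
        mids = rng.uniform(lo, lo + r, size=max(0, n_individuals - 2))
        targets = np.concatenate([[lo, lo + r], mids])
        rng.shuffle(targets)
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(margin_bp, chrom_lengths[chrom] - width_bp - margin_bp))
            end = start + width_bp
            if all(
                end + margin_bp <= s or start >= e + margin_bp
                for s, e in taken[chrom]
            ):
                taken[chrom].append((start, end))
                out.append(
                    PlantedDMR(chrom, start, end, n_cpgs, tuple(targets), tag)
                )
                break
        else:
            raise RuntimeError("could not place planted DMR without overlap")
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def _cpg_positions(rng: np.random.Generator, config: SimulationConfig, chrom: str) -> np.ndarray:
    """Clustered CpG point process: background + islands + planted CpGs."""
    length = config.chrom_lengths[chrom]
    n_bg = int(length / config.cpg_spacing_bp * 1.5) + 10
    gaps = rng.geometric(1.0 / config.cpg_spacing_bp, size=n_bg)
    bg = np.cumsum(gaps)
    bg = bg[bg < length - 1]
    islands = []
    n_islands = rng.poisson(length / config.island_every_bp)
    for _ in range(n_islands):
        centre = rng.integers(0, length - 1)
        gaps = rng.geometric(1.0 / config.island_spacing_bp, size=config.island_n_cpgs)
        ipos = centre + np.cumsum(gaps)
        islands.append(ipos[ipos < length - 1])
    planted = []
    for dmr in config.planted_dmrs:
        if dmr.chrom != chrom:
            continue
        step = (dmr.end - dmr.start) / dmr.n_cpgs
        ppos = dmr.start + (np.arange(dmr.n_cpgs) * step).astype(np.int64)
        planted.append(ppos)
    pos = np.unique(np.concatenate([bg] + islands + planted)) if (len(islands) + len(planted)) else np.unique(bg)
    # CpG dinucleotides cannot overlap: enforce spacing >= 2
    keep = np.ones(len(pos), dtype=bool)
    keep[1:] = np.diff(pos) >= 2
    pos = pos[keep]
    for dmr in config.planted_dmrs:
        if dmr.chrom != chrom:
            continue
        inside = np.sum((pos >= dmr.start) & (pos < dmr.end))
        if inside < dmr.n_cpgs:
            raise ValueError(
                f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} hosts only "
                f"{inside} CpGs (requested {dmr.n_cpgs})"
            )
    return pos.astype(np.int64)


def _nb_coverage(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_methylomes(
    config: SimulationConfig,
) -> tuple[MethylomeSet, pd.DataFrame]:
    """Generate a methylome set and its planted-DMR truth table.

    Per CpG and individual: coverage ~ NegativeBinomial(mean, dispersion)
    and methylated reads ~ Binomial(coverage, p), with p drawn once per CpG
    from Beta(a, b) outside planted regions (shared by all individuals) and
    equal to the per-individual target inside them.  Bit-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    names = config.names()
    k = len(names)
    by_chrom: dict[str, list[PlantedDMR]] = {}
    for dmr in config.planted_dmrs:
        by_chrom.setdefault(dmr.chrom, []).append(dmr)
        if len(dmr.targets) != k:
            raise ValueError(
                f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} has "
                f"{len(dmr.targets)} targets for {k} individuals"
            )
    for dmrs in by_chrom.values():
        dmrs.sort(key=lambda d: d.start)
        for a, b in zip(dmrs, dmrs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"planted DMRs overlap: {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
    chroms_out, pos_out, meth_out, tot_out = [], [], [], []
    for chrom in sorted(config.chrom_lengths):
        pos = _cpg_positions(rng, config, chrom)
        n = len(pos)
        p = np.repeat(rng.beta(config.beta_a, config.beta_b, size=n)[:, None], k, axis=1)
        for dmr in config.planted_dmrs:
            if dmr.chrom != chrom:
                continue
            inside = (pos >= dmr.start) & (pos < dmr.end)
            p[inside] = np.asarray(dmr.targets)[None, :]
        cov = _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, (n, k))
        meth = rng.binomial(cov, p)
        chroms_out.append(np.full(n, chrom, dtype=object))
        pos_out.append(pos)
        meth_out.append(meth)
        tot_out.append(cov)
    mset = MethylomeSet(
        individuals=names,
        chrom=np.concatenate(chroms_out),
        pos=np.concatenate(pos_out),
        meth=np.vstack(meth_out),
        total=np.vstack(tot_out),
    )
    truth_rows = []
    for i, dmr in enumerate(config.planted_dmrs):
        row = {
            "dmr_id": f"dmr{i + 1}",
            "chrom": dmr.chrom,
            "start": dmr.start,
            "end": dmr.end,
            "n_cpgs": dmr.n_cpgs,
            "class": dmr.class_tag,
            "range": max(dmr.targets) - min(dmr.targets),
        }
        for name, t in zip(names, dmr.targets):
            row[f"target.{name}"] = t
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return mset, truth


def planted_annotations(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    erv_labels: tuple[str, ...] = ("IAP", "RLTR4"),
) -> dict[str, list[GenomicInterval]]:
    """Annotation intervals aligned with the planted DMRs.

    ERV-like planted regions get an overlapping ERV element (IAP or RLTR4
    label, alternating); regulatory-like ones get a tsDMR interval.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    ervs, tsdmrs = [], []
    n_erv = 0
    for dmr in config.planted_dmrs:
        jitter = int(rng.integers(-100, 100))
        iv = GenomicInterval(
            dmr.chrom,
            max(0, dmr.start + jitter),
            dmr.end + jitter + 200,
        )
        if dmr.class_tag == "ERV-like":
            label = erv_labels[n_erv % len(erv_labels)]
            n_erv += 1
            ervs.append(GenomicInterval(iv.chrom, iv.start, iv.end, label))
        else:
            tsdmrs.append(GenomicInterval(iv.chrom, iv.start, iv.end, "tsDMR"))
    return {"erv": ervs, "tsdmr": tsdmrs}


def split_strand_counts(
    rng: np.random.Generator, meth: np.ndarray, total: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split merged CpG counts into forward/reverse strand read counts.

    Reads fall on either strand with equal probability; methylated reads
    are apportioned hypergeometrically so strand sums reproduce the input
    exactly.  Returns (meth_fwd, total_fwd, meth_rev, total_rev).
    """
    total_fwd = rng.binomial(total, 0.5)
    meth_fwd = rng.hypergeometric(
        np.maximum(meth, 0), np.maximum(total - meth, 0), total_fwd
    )
    return meth_fwd, total_fwd, meth - meth_fwd, total - total_fwd


def write_methylome_fixture(
    config: SimulationConfig, outdir
) -> dict[str, object]:
    """Simulate and write the full WGBS fixture to ``outdir``.

    Emits one cytosine-report TSV per individual (strand-split), planted
    annotation BEDs (ERV, tsDMR) and the truth table; returns paths plus
    the in-memory objects.
    """
    import pathlib

    from .annotation import write_bed
    from .methylome import write_cytosine_report

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mset, truth = simulate_methylomes(config)
    rng = np.random.default_rng(config.seed + 7)
    report_paths = {}
    for j, ind in enumerate(mset.individuals):
        mf, tf, mr, tr = split_strand_counts(rng, mset.meth[:, j], mset.total[:, j])
        fwd = pd.DataFrame(
            {"chrom": mset.chrom, "pos": mset.pos, "strand": "+", "meth": mf, "total": tf}
        )
        rev = pd.DataFrame(
            {"chrom": mset.chrom, "pos": mset.pos + 1, "strand": "-", "meth": mr, "total": tr}
        )
        table = pd.concat([fwd, rev]).sort_values(["chrom", "pos"]).reset_index(drop=True)
        path = outdir / f"{ind}.CpG_report.txt"
        write_cytosine_report(table, path)
        report_paths[ind] = path
    annots = planted_annotations(config)
    write_bed(annots["erv"], outdir / "erv.bed")
    write_bed(annots["tsdmr"], outdir / "tsdmr.bed")
    truth.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    return {
        "methylome": mset,
        "truth": truth,
        "reports": report_paths,
        "annotations": annots,
        "erv_bed": outdir / "erv.bed",
        "tsdmr_bed": outdir / "tsdmr.bed",
        "truth_tsv": outdir / "truth_dmrs.tsv",
    }


# ---------------------------------------------------------------------------
# Variant fixture
# ---------------------------------------------------------------------------

_PATTERNS = {
    "het_ref": (0.5, 0.0),
    "ref_het": (0.0, 0.5),
    "hom_ref": (0.95, 0.0),
    "het_het": (0.5, 0.5),
    "hom_hom": (0.95, 0.95),
}


@dataclass
class VariantFixtureConfig:
    """Requested structure of the two-individual variant fixture.

    ``counts`` maps a zygosity pattern name (het_ref, ref_het, hom_ref,
    het_het, hom_hom) to per-category variant counts.  ``masked_counts``
    adds het_ref variants placed inside the named mask regions
    (simple_repeat, homopolymer, dinucleotide, low_mq, clustered_het) for
    exercising the exclusion filters.
    """

    seed: int = 0
    counts: dict[str, dict[GenicCategory, int]] = field(default_factory=dict)
    masked_counts: dict[str, int] = field(default_factory=dict)
    sample_names: tuple[str, str] = ("yellow", "pseudoagouti")
    variant_spacing_bp: int = 25
    depth: int = 20
    max_cassettes: int = 50  # caps genome size; exceeding it is "infeasible"


@dataclass
class VariantFixture:
    """The realised fixture: file contents plus ground truth."""

    reference: dict[str, str]
    genes: list
    truth: pd.DataFrame
    masks: dict[str, list[GenomicInterval]]
    segdups: list[GenomicInterval]
    sample_names: tuple[str, str]


_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


class _Cassette:
    """One plus-strand gene cassette and its plantable site pools.

    Layout from gene start g: exon1 [g, g+300) with 5'UTR [g, g+150) and
    CDS from g+150; intron [g+300, g+800); exon2 [g+800, g+1100) with CDS
    to g+950 and 3'UTR after.  The CDS is tiled with GCT (Ala) codons, so
    third positions are synonymous sites (GCT->GCC) and first positions
    non-synonymous (GCT->CCT, Ala->Pro).
    """

    GENE_LEN = 1100
    UP = 2000
    DOWN = 2000

    def __init__(self, gene_start: int):
        g = gene_start
        self.gene_start = g
        self.exons = [(g, g + 300), (g + 800, g + 1100)]
        self.cds = (g + 150, g + 950)
        cds_positions = list(range(g + 150, g + 300)) + list(range(g + 800, g + 950))
        self.syn_sites = [p for i, p in enumerate(cds_positions) if i % 3 == 2]
        self.nonsyn_sites = [p for i, p in enumerate(cds_positions) if i % 3 == 0]
        self.splice_sites = [g + 300, g + 301, g + 798, g + 799]
        self.utr_sites = list(range(g + 5, g + 150, 5)) + list(range(g + 955, g + 1095, 5))
        self.intron_sites = list(range(g + 310, g + 790, 5))
        self.upstream_sites = list(range(g - self.UP + 5, g - 5, 10))
        self.downstream_sites = list(range(g + self.GENE_LEN + 5, g + self.GENE_LEN + self.DOWN - 5, 10))


def _category_alt(seq: list[str], pos: int, category: GenicCategory) -> tuple[str, str]:
    ref = seq[pos]
    if category == GenicCategory.exonic_synonymous:
        # GCT third position: T -> C keeps Ala
        assert ref == "T", "synonymous sites sit at GCT third positions"
        return ref, "C"
    if category == GenicCategory.exonic_nonsynonymous:
        # GCT first position: G -> C gives Pro
        assert ref == "G", "non-synonymous sites sit at GCT first positions"
        return ref, "C"
    return ref, _ALT[ref]


def simulate_variant_fixture(config: VariantFixtureConfig) -> VariantFixture:
    """Construct a genome, gene models and variants matching the request.

    Every requested (pattern, category) count is realised exactly: coding
    placements use codons engineered so the synonymous/non-synonymous
    split holds under the standard genetic code.  Raises when a request
    exceeds the constructed capacity.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chrV"

    needed: dict[GenicCategory, int] = {c: 0 for c in GenicCategory}
    for per_cat in config.counts.values():
        for cat, n in per_cat.items():
            needed[GenicCategory(cat)] += n

    per_cassette = {
        GenicCategory.exonic_synonymous: 100,
        GenicCategory.exonic_nonsynonymous: 100,
        GenicCategory.splice_junction: 4,
        GenicCategory.utr: 57,
        GenicCategory.intronic: 96,
        GenicCategory.upstream_2kb: 199,
        GenicCategory.downstream_2kb: 199,
    }
    n_cassettes = 1
    for cat, cap in per_cassette.items():
        n_cassettes = max(n_cassettes, -(-needed[cat] // cap))
    if n_cassettes > config.max_cassettes:
        worst = max(per_cassette, key=lambda c: -(-needed[c] // per_cassette[c]))
        raise ValueError(
            f"requested {needed[worst]} {worst.value} variants exceeds fixture "
            f"capacity ({config.max_cassettes * per_cassette[worst]} at "
            f"max_cassettes={config.max_cassettes})"
        )

    cassette_pitch = _Cassette.UP + _Cassette.GENE_LEN + _Cassette.DOWN + 3000
    cassettes = [
        _Cassette(3000 + _Cassette.UP + i * cassette_pitch) for i in range(n_cassettes)
    ]
    intergenic_start = 3000 + n_cassettes * cassette_pitch + 2000
    intergenic_len = needed[GenicCategory.intergenic] * config.variant_spacing_bp + 4000
    mask_region_start = intergenic_start + intergenic_len + 1000
    mask_pitch = 2000
    mask_names = ["simple_repeat", "homopolymer", "dinucleotide", "low_mq", "clustered_het"]
    genome_len = mask_region_start + mask_pitch * (len(mask_names) + 1) + 12_000

    seq = list(rng.choice(list("ACGT"), size=genome_len))
    # avoid accidental long runs in the random backbone
    for i in range(2, genome_len):
        if seq[i] == seq[i - 1] == seq[i - 2]:
            seq[i] = _ALT[seq[i]]

    from .annotation import GeneModel

    genes = []
    for ci, cas in enumerate(cassettes):
        cds_positions = list(range(cas.cds[0], cas.exons[0][1])) + list(
            range(cas.exons[1][0], cas.cds[1])
        )
        for i, p in enumerate(cds_positions):
            seq[p] = "GCT"[i % 3]
        intron_s, intron_e = cas.exons[0][1], cas.exons[1][0]
        seq[intron_s], seq[intron_s + 1] = "G", "T"
        seq[intron_e - 2], seq[intron_e - 1] = "A", "G"
        genes.append(
            GeneModel(
                gene_id=f"gene{ci + 1}",
                chrom=chrom,
                strand="+",
                exons=list(cas.exons),
                cds_start=cas.cds[0],
                cds_end=cas.cds[1],
            )
        )

    pools: dict[GenicCategory, list[int]] = {
        GenicCategory.exonic_synonymous: [],
        GenicCategory.exonic_nonsynonymous: [],
        GenicCategory.splice_junction: [],
        GenicCategory.utr: [],
        GenicCategory.intronic: [],
        GenicCategory.upstream_2kb: [],
        GenicCategory.downstream_2kb: [],
    }
    for cas in cassettes:
        pools[GenicCategory.exonic_synonymous].extend(cas.syn_sites)
        pools[GenicCategory.exonic_nonsynonymous].extend(cas.nonsyn_sites)
        pools[GenicCategory.splice_junction].extend(cas.splice_sites)
        pools[GenicCategory.utr].extend(cas.utr_sites)
        pools[GenicCategory.intronic].extend(cas.intron_sites)
        pools[GenicCategory.upstream_2kb].extend(cas.upstream_sites)
        pools[GenicCategory.downstream_2kb].extend(cas.downstream_sites)
    pools[GenicCategory.intergenic] = list(
        range(intergenic_start, intergenic_start + intergenic_len - 2000, config.variant_spacing_bp)
    )

    for cat, n in needed.items():
        if n > len(pools.get(cat, [])):
            raise ValueError(
                f"requested {n} {cat.value} variants but fixture capacity is "
                f"{len(pools.get(cat, []))}"
            )

    rows = []
    cursors = {cat: 0 for cat in pools}
    for pattern, per_cat in config.counts.items():
        if pattern not in _PATTERNS:
            raise ValueError(f"unknown zygosity pattern {pattern!r}")
        for cat, n in per_cat.items():
            cat = GenicCategory(cat)
            for _ in range(n):
                pos = pools[cat][cursors[cat]]
                cursors[cat] += 1
                ref, alt = _category_alt(seq, pos, cat)
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "category": cat.value,
                        "pattern": pattern,
                        "mask": "",
                    }
                )

    # mask regions with planted masked variants (always emitted so filter
    # behaviour is testable; variants only when requested)
    masks: dict[str, list[GenomicInterval]] = {n: [] for n in mask_names[:4]}
    segdups: list[GenomicInterval] = []
    region_of = {}
    for mi, name in enumerate(mask_names):
        s = mask_region_start + mi * mask_pitch
        region_of[name] = s
    hs = region_of["homopolymer"]
    for i in range(12):  # 12 x A: run > 8
        seq[hs + i] = "A"
    seq[hs - 1] = seq[hs + 12] = "C"  # pin boundaries so the run is exact
    masks["homopolymer"].append(GenomicInterval(chrom, hs - 1, hs + 13, "homopolymer"))
    ds = region_of["dinucleotide"]
    for i in range(20):  # (AT)x10: run > 14
        seq[ds + i] = "AT"[i % 2]
    seq[ds - 1] = seq[ds + 20] = "G"  # break alternation at both ends
    seq[ds - 2] = "C"
    seq[ds + 21] = "C"
    masks["dinucleotide"].append(GenomicInterval(chrom, ds - 1, ds + 21, "dinucleotide"))
    ss = region_of["simple_repeat"]
    masks["simple_repeat"].append(GenomicInterval(chrom, ss, ss + 60, "4", 4.0))
    ls = region_of["low_mq"]
    masks["low_mq"].append(GenomicInterval(chrom, ls, ls + 200, "low_mq", 25.0))
    cs = region_of["clustered_het"]
    segdups.append(GenomicInterval(chrom, cs - 100, cs + 9100, "segdup"))

    mask_pos = {
        "simple_repeat": [ss + 10, ss + 30],
        "homopolymer": [hs + 4],
        "dinucleotide": [ds + 8],
        "low_mq": [ls + 50, ls + 120],
        "clustered_het": [cs, cs + 4000, cs + 8000],
    }
    for name, n in config.masked_counts.items():
        positions = mask_pos[name]
        if n > len(positions):
            raise ValueError(f"at most {len(positions)} planted {name} variants supported")
        for pos in positions[:n]:
            ref = seq[pos]
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": _ALT[ref],
                    "category": "",
                    "pattern": "het_ref",
                    "mask": name,
                }
            )

    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "category", "pattern", "mask"]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    if truth["pos"].duplicated().any():
        raise RuntimeError("fixture placed two variants at one position")
    return VariantFixture(
        reference={chrom: "".join(seq)},
        genes=genes,
        truth=truth,
        masks=masks,
        segdups=segdups,
        sample_names=config.sample_names,
    )


def write_vcf(
    fixture: VariantFixture, path, depth: int = 20
) -> None:
    """Write the fixture's variants as VCF v4.2 with GT:AD:DP per sample."""
    a, b = fixture.sample_names
    lines = [
        "##fileformat=VCFv4.2",
    ]
    for chrom, s in fixture.reference.items():
        lines.append(f"##contig=<ID={chrom},length={len(s)}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{a}\t{b}",
    ]
    for row in fixture.truth.itertuples(index=False):
        fa, fb = _PATTERNS[row.pattern]
        fields = [row.chrom, str(row.pos + 1), ".", row.ref, row.alt, "60", "PASS", "."]
        fields.append("GT:AD:DP")
        for f in (fa, fb):
            alt_d = round(f * depth)
            ref_d = depth - alt_d
            gt = "1/1" if f > 0.9 else ("0/1" if f >= 0.3 else "0/0")
            fields.append(f"{gt}:{ref_d},{alt_d}:{depth}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gff3(fixture: VariantFixture, path) -> None:
    """Write the fixture's gene models as GFF3 (gene/mRNA/exon/CDS)."""
    lines = ["##gff-version 3"]
    for g in fixture.genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons):
            lines.append(
                f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{i + 1};Parent={mrna}"
            )
        if g.is_coding:
            for s, e in g.cds_segments():
                lines.append(
                    f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, s in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def simulate_clones(
    n_clones: int, n_cpgs: int, methylation_prob: float, seed: int,
    individual: str = "ind", locus: str = "locus",
) -> CloneSet:
    """I.i.d. Bernoulli clonal bisulphite calls at one locus."""
    if not 0 <= methylation_prob <= 1:
        raise ValueError("methylation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = rng.binomial(1, methylation_prob, size=(n_clones, n_cpgs))
    return CloneSet(individual=individual, locus=locus, clones=calls.tolist())
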