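"""Reproduce the two-littermate variant-table structure on a synthetic genome.

Builds a fixture realising the published per-category counts (variants that
differ between two littermates, and colony variants shared by both), runs
the genic classifier over the constructed gene models, partitions the calls
by zygosity pattern, and extrapolates a germline mutation rate.
"""

from iidmr.annotation import classify_variant
from iidmr.simulate import (
    COLONY_SHARED_HET_COUNTS,
    COLONY_SHARED_HOM_COUNTS,
    LITTERMATE_DIFF_COUNTS,
    VariantFixtureConfig,
    simulate_variant_fixture,
)
from iidmr.variants import (
    MutationRateParams,
    VariantCall,
    estimate_mutation_rate,
    partition_variant_tables,
)

fx = simulate_variant_fixture(
    VariantFixtureConfig(
        seed=20,
        counts={
            "het_ref": LITTERMATE_DIFF_COUNTS,
            "het_het": COLONY_SHARED_HET_COUNTS,
            "hom_hom": COLONY_SHARED_HOM_COUNTS,
        },
    )
)
frac = {"het_ref": (0.5, 0.0), "het_het": (0.5, 0.5), "hom_hom": (0.95, 0.95)}
calls = []
for row in fx.truth.itertuples(index=False):
    fa, fb = frac[row.pattern]
    v = VariantCall(
        row.chrom, row.pos, row.ref, row.alt,
        {"yellow": fa, "pseudoagouti": fb}, {"yellow": 20, "pseudoagouti": 20},
    )
    v.category = classify_variant(v.chrom, v.pos, v.ref, v.alt, fx.genes, fx.reference)
    calls.append(v)

part = partition_variant_tables(calls, "yellow", "pseudoagouti")
counts = part["counts"][["differs_between_mice", "shared_het", "shared_hom"]]
print(counts.to_string())
# Columns: variants polymorphic between the two mice, variants heterozygous
# in both, variants homozygous in both — each broken down by genic category.

rate = estimate_mutation_rate(
    MutationRateParams(n_validated_de_novo=4, n_tested=32, n_candidates=985)
)
print(f"\nextrapolated germline mutation rate: {rate:.3g} per bp per generation")
# 4 of 32 parent-tested candidates were true de novo events; scaled to the
# genome-wide candidate pool, FDR/FNR-corrected and divided by the callable
# genome times four transmitted haploid genomes.
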