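"""Simulation benchmarks: planted-region recovery and null error control.

These are the package's standing experiments: plant regions of known
methylation difference in an otherwise homogeneous five-individual genome,
run the caller end to end, and score recovery against the planted truth —
or run with nothing planted and count how often the caller invents a
region.  Problem sizes default to a 10 Mb genome (roughly 10^5 CpGs) at
coverage 20, repeated over 10 seeds.
"""

from __future__ import annotations

import numpy as np

from .caller import CallerConfig, call_iidmrs
from .methylome import coverage_filter
from .simulate import SimulationConfig, generate_planted_dmrs, simulate_methylomes

__all__ = ["recovery_benchmark", "null_benchmark"]


def _overlaps_any(region, truth_rows) -> bool:
    return any(
        region.chrom == t.chrom and region.start < t.end and t.start < region.end
        for t in truth_rows
    )


def recovery_benchmark(
    seed: int = 0,
    n_seeds: int = 10,
    genome_bp: int = 10_000_000,
    n_dmrs: int = 50,
    planted_range: float = 0.5,
    n_cpgs: int = 8,
    coverage_mean: float = 20.0,
    n_individuals: int = 5,
    config: CallerConfig | None = None,
) -> dict:
    """Sensitivity and false-region count for planted-DMR recovery.

    Per replicate: ``n_dmrs`` regions of methylation range
    ``planted_range`` with ``n_cpgs`` CpGs each are planted on a
    ``genome_bp`` genome; sensitivity is the fraction of planted regions
    intersected by a called region, false regions are calls intersecting
    none.  Returns per-seed values and their medians.
    """
    sens, false_counts = [], []
    for rep in range(n_seeds):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        lengths = {"chr1": genome_bp}
        dmrs = generate_planted_dmrs(
            rng, lengths, n_individuals,
            n_erv_like=n_dmrs, erv_range=planted_range, erv_range_sd=0.0,
            n_cpgs=n_cpgs,
        )
        sim = SimulationConfig(
            seed=rep_seed, n_individuals=n_individuals, chrom_lengths=lengths,
            coverage_mean=coverage_mean, planted_dmrs=dmrs,
        )
        mset, truth = simulate_methylomes(sim)
        regions = call_iidmrs(mset, config)
        truth_rows = list(truth.itertuples(index=False))
        hit = sum(
            1
            for t in truth_rows
            if any(
                r.chrom == t.chrom and r.start < t.end and t.start < r.end
                for r in regions
            )
        )
        sens.append(hit / len(truth_rows))
        false_counts.append(sum(1 for r in regions if not _overlaps_any(r, truth_rows)))
    return {
        "sensitivity_per_seed": sens,
        "false_regions_per_seed": false_counts,
        "median_sensitivity": float(np.median(sens)),
        "median_false_regions": float(np.median(false_counts)),
        "n_seeds": n_seeds,
        "n_planted": n_dmrs,
    }


def null_benchmark(
    seed: int = 0,
    n_seeds: int = 10,
    genome_bp: int = 10_000_000,
    coverage_mean: float = 20.0,
    n_individuals: int = 5,
    config: CallerConfig | None = None,
) -> dict:
    """Region calls per 10^5 informative CpGs when nothing is planted."""
    config = config or CallerConfig()
    rates, n_regions, n_informative = [], [], []
    for rep in range(n_seeds):
        sim = SimulationConfig(
            seed=seed + rep, n_individuals=n_individuals,
            chrom_lengths={"chr1": genome_bp}, coverage_mean=coverage_mean,
        )
        mset, _ = simulate_methylomes(sim)
        informative = coverage_filter(mset, config.min_coverage).n_sites
        regions = call_iidmrs(mset, config)
        n_regions.append(len(regions))
        n_informative.append(informative)
        rates.append(len(regions) / informative * 1e5 if informative else 0.0)
    return {
        "regions_per_seed": n_regions,
        "informative_cpgs_per_seed": n_informative,
        "rate_per_1e5_per_seed": rates,
        "median_rate_per_1e5": float(np.median(rates)),
        "n_seeds": n_seeds,
    }
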