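"""Discover inter-individual DMRs in a simulated five-littermate genome.

Plants ten differentially methylated regions (five large-range ERV-like,
five modest-range regulatory-like) on a 2 Mb genome, runs the full caller
(per-CpG chi-squared heterogeneity test, segmentation, range filter) and
classifies the calls against the planted ERV annotation.
"""

import numpy as np

from iidmr.caller import call_iidmrs, classify_erv_overlap, compare_ranges, iidmrs_to_frame
from iidmr.simulate import (
    SimulationConfig,
    generate_planted_dmrs,
    planted_annotations,
    simulate_methylomes,
)

rng = np.random.default_rng(42)
lengths = {"chr1": 2_000_000}
dmrs = generate_planted_dmrs(rng, lengths, 5, n_erv_like=5, n_regulatory_like=5)
config = SimulationConfig(
    seed=42, chrom_lengths=lengths, planted_dmrs=dmrs, coverage_mean=20
)
mset, truth = simulate_methylomes(config)
print(f"simulated {mset.n_sites} CpGs for {mset.n_individuals} individuals")

regions = call_iidmrs(mset)
regions = classify_erv_overlap(regions, planted_annotations(config)["erv"])
frame = iidmrs_to_frame(regions, mset.individuals)
print(frame[["chrom", "start", "end", "n_cpgs", "calling_range", "class"]].to_string())

erv = frame.loc[frame["class"] == "ERV", "range_all"]
other = frame.loc[frame["class"] != "ERV", "range_all"]
if len(erv) >= 2 and len(other) >= 2:
    res = compare_ranges(erv, other)
    print(
        f"\nERV regions span a wider methylation range than the rest: "
        f"t = {res['t']:.2f}, one-sided p = {res['p_greater']:.3g}"
    )
# Each row is a called region: its member-CpG count, the spread between the
# most and least methylated individual (calling_range), and whether it
# overlaps an annotated endogenous retrovirus.  Large-range calls coincide
# with the planted ERV-like truth; modest-range regulatory-like regions are
# recovered less reliably, as expected at a 0.20 range threshold.
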