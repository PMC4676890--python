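import numpy as np
import pytest

from iidmr.methylome import MethylomeSet
from iidmr.simulate import (
    SimulationConfig,
    generate_planted_dmrs,
    simulate_methylomes,
)


def make_methylome(meth, total, individuals=None, chrom="chr1", pos=None):
    """Small MethylomeSet from explicit count matrices."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n, k = meth.shape
    if individuals is None:
        individuals = [f"m{i + 1}" for i in range(k)]
    if pos is None:
        pos = np.arange(n) * 100
    return MethylomeSet(
        individuals=individuals,
        chrom=np.full(n, chrom, dtype=object),
        pos=np.asarray(pos),
        meth=meth,
        total=total,
    )


@pytest.fixture
def small_simulation():
    """A 2 Mb five-individual simulation with 10 planted DMRs."""
    rng = np.random.default_rng(42)
    lengths = {"chr1": 2_000_000}
    dmrs = generate_planted_dmrs(
        rng, lengths, 5, n_erv_like=5, n_regulatory_like=5, n_cpgs=8
    )
    config = SimulationConfig(
        seed=42, chrom_lengths=lengths, planted_dmrs=dmrs, coverage_mean=20
    )
    mset, truth = simulate_methylomes(config)
    return config, mset, truth
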