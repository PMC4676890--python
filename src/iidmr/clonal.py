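"""Statistics for clonal bisulphite sequencing validation.

Each sequenced clone is one PCR-cloned molecule (one cell's allele) read
over the CpGs of a locus; its methylation fraction is the proportion of
methylated CpGs.  Two individuals are compared at a locus by a Student's
t-test on their per-clone fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CloneSet", "clone_fractions", "compare_clone_sets", "read_clone_tsv"]


@dataclass
class CloneSet:
    """Per-clone binary methylation calls at one locus for one individual.

    ``clones`` is a list of equal-length sequences of 0/1 calls, one per
    sequenced clone.
    """

    individual: str
    locus: str
    clones: list[list[int]]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("need at least one clone")
        n = len(self.clones[0])
        if n == 0:
            raise ValueError("zero-length clone")
        for c in self.clones:
            if len(c) != n:
                raise ValueError("clones must have equal CpG counts")
            if any(x not in (0, 1) for x in c):
                raise ValueError("calls must be binary")

    @property
    def n_clones(self) -> int:
        return len(self.clones)


def clone_fractions(clone_set: CloneSet) -> list[float]:
    """Per-clone methylation fraction (methylated CpGs / total CpGs)."""
    return [sum(c) / len(c) for c in clone_set.clones]


def compare_clone_sets(
    set_a: CloneSet,
    set_b: CloneSet,
    alternative: str = "two-sided",
) -> dict[str, float]:
    """Student's t-test (pooled variance) on per-clone methylation fractions.

    Returns the t statistic and p-value.  When both groups have zero
    variance and equal means the result is t = 0, p = 1.
    """
    fa = np.asarray(clone_fractions(set_a))
    fb = np.asarray(clone_fractions(set_b))
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need >= 2 clones per set")
    res = stats.ttest_ind(fa, fb, equal_var=True, alternative=alternative)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        if np.isclose(fa.mean(), fb.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, different means: unbounded evidence
            t = float("inf") if fa.mean() > fb.mean() else float("-inf")
            p = 0.0
    return {"t": t, "p_value": p, "n_a": len(fa), "n_b": len(fb)}


def read_clone_tsv(path) -> list[CloneSet]:
    """Read clone data from TSV (individual, locus, clone, cpg_index, call)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["individual", "locus", "clone", "cpg_index", "call"],
        header=0,
    )
    out = []
    for (ind, locus), grp in df.groupby(["individual", "locus"], sort=True):
        clones = []
        for _, cg in grp.groupby("clone", sort=True):
            clones.append(cg.sort_values("cpg_index")["call"].astype(int).tolist())
        out.append(CloneSet(individual=str(ind), locus=str(locus), clones=clones))
    return out
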