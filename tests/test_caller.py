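"""Per-CpG heterogeneity test, segmentation, and region calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_methylome
from iidmr.annotation import GenomicInterval
from iidmr.caller import (
    CallerConfig,
    call_iidmrs,
    chisq_heterogeneity,
    classify_erv_overlap,
    compare_ranges,
    cpg_chisq_test,
    segment_regions,
    weighted_region_methylation,
)


def chisq_oracle(meth, unmeth):
    """Direct sum((O - E)^2 / E) on the 2xk table."""
    obs = np.array([meth, unmeth], dtype=float)
    col = obs.sum(axis=0)
    row = obs.sum(axis=1)
    n = obs.sum()
    stat = 0.0
    for r in range(2):
        for c in range(len(meth)):
            e = row[r] * col[c] / n
            if e > 0:
                stat += (obs[r, c] - e) ** 2 / e
    p = stats.chi2.sf(stat, len(meth) - 1)
    return stat, p


class TestChiSquared:
    def test_two_by_two_closed_form(self):
        # counts (8,2) vs (2,8): all expected counts 5, chi2 = 4 * 9/5 = 7.2
        res = cpg_chisq_test([(8, 2), (2, 8)])
        assert res.chi2_statistic == pytest.approx(7.2, abs=1e-12)
        assert res.p_value < 0.05 and res.significant
        assert res.df == 1

    def test_identical_proportions_null(self):
        res = cpg_chisq_test([(5, 5), (5, 5)])
        assert res.chi2_statistic == 0 and res.p_value == 1

    def test_homogeneous_four_individuals(self):
        res = cpg_chisq_test([(10, 10)] * 4)
        assert res.chi2_statistic == 0 and not res.significant
        assert res.df == 3

    def test_degenerate_all_methylated(self):
        res = cpg_chisq_test([(5, 0), (7, 0), (3, 0)])
        assert res.degenerate
        assert res.chi2_statistic == 0 and res.p_value == 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cpg_chisq_test([(0, 0), (5, 5)])

    def test_matches_direct_computation_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            k = rng.integers(2, 6)
            total = rng.integers(1, 40, size=k)
            meth = rng.binomial(total, rng.uniform(0.05, 0.95))
            stat, p, degen = chisq_heterogeneity(meth[None, :], total[None, :])
            o_stat, o_p = chisq_oracle(meth, total - meth)
            if degen[0]:
                assert stat[0] == 0 and p[0] == 1
            else:
                assert stat[0] == pytest.approx(o_stat, abs=1e-9)
                assert p[0] == pytest.approx(o_p, abs=1e-9)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            total = rng.integers(5, 30, size=4)
            meth = np.clip(rng.binomial(total, 0.5), 1, total - 1)
            stat, p, _ = chisq_heterogeneity(meth[None, :], total[None, :])
            ref = stats.chi2_contingency(
                np.array([meth, total - meth]), correction=False
            )
            assert stat[0] == pytest.approx(ref.statistic, abs=1e-9)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-9)


class TestWeightedRegionMethylation:
    def test_weighted_mean(self):
        assert weighted_region_methylation([5, 10], [10, 10]) == pytest.approx(0.75)

    def test_single_cpg(self):
        assert weighted_region_methylation([3], [6]) == pytest.approx(0.5)

    def test_equal_coverage_equals_unweighted_mean(self):
        meth, total = np.array([3, 6, 9]), np.array([10, 10, 10])
        assert weighted_region_methylation(meth, total) == pytest.approx(
            np.mean(meth / total)
        )

    def test_zero_coverage_missing(self):
        assert np.isnan(weighted_region_methylation([0], [0]))


def segmentation_oracle(pos, sig, config):
    """Brute-force enumeration of qualifying windows, greedily reduced.

    A window [i, j] qualifies when consecutive members are within the gap,
    its boundaries are significant, it has at least min_cpgs members, and
    at no prefix does the non-significant count exceed the budget for the
    prefix length.  Reduction: repeatedly take the qualifying window with
    the smallest start (largest end on ties) and discard windows starting
    at or before its end.
    """
    n = len(pos)
    wins = []
    for i in range(n):
        if not sig[i]:
            continue
        nonsig = 0
        ok = True
        for j in range(i, n):
            if j > i:
                if pos[j] - pos[j - 1] > config.max_gap_bp:
                    break
                if not sig[j]:
                    nonsig += 1
                if nonsig > config.allowed_nonsignificant(j - i + 1):
                    ok = False
                    break
            if sig[j] and j - i + 1 >= config.min_cpgs:
                wins.append((i, j))
        del ok
    out = []
    wins.sort(key=lambda w: (w[0], -w[1]))
    cutoff = -1
    for i, j in wins:
        if i > cutoff:
            out.append((i, j))
            cutoff = j
    return out


class TestSegmentation:
    config = CallerConfig()

    def test_six_significant_cpgs_form_one_region(self):
        pos = np.arange(6) * 100
        sig = np.ones(6, bool)
        assert segment_regions(pos, sig, self.config) == [(0, 5)]

    def test_large_gap_splits_runs_below_minimum(self):
        pos = np.concatenate([np.arange(5) * 100, 1000 + np.arange(5) * 100])
        pos[5:] += 600  # gap of > 500 between the two runs of five
        sig = np.ones(10, bool)
        assert segment_regions(pos, sig, self.config) == []

    def test_single_interior_nonsignificant_tolerated(self):
        pos = np.arange(7) * 100
        sig = np.array([1, 1, 1, 0, 1, 1, 1], bool)
        assert segment_regions(pos, sig, self.config) == [(0, 6)]

    def test_boundaries_must_be_significant(self):
        pos = np.arange(8) * 100
        sig = np.array([0, 1, 1, 1, 1, 1, 1, 0], bool)
        assert segment_regions(pos, sig, self.config) == [(1, 6)]

    def test_budget_excess_closes_then_reopens(self):
        pos = np.arange(14) * 100
        sig = np.array([1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1], bool)
        assert segment_regions(pos, sig, self.config) == [(0, 5), (8, 13)]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 700), st.booleans()), min_size=1, max_size=15
        ),
        st.integers(2, 7),
    )
    def test_segmentation_property_against_enumeration(self, steps, min_cpgs):
        gaps = np.array([g for g, _ in steps])
        pos = np.cumsum(gaps)
        sig = np.array([s for _, s in steps], dtype=bool)
        cfg = CallerConfig(min_cpgs=min_cpgs)
        assert segment_regions(pos, sig, cfg) == segmentation_oracle(pos, sig, cfg)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 16))
        gaps = rng.choice([50, 100, 400, 600, 900], size=n)
        pos = np.cumsum(gaps)
        sig = rng.random(n) < 0.6
        cfg = CallerConfig(min_cpgs=int(rng.integers(2, 7)))
        assert segment_regions(pos, sig, cfg) == segmentation_oracle(pos, sig, cfg)


class TestCompareRanges:
    def test_identical_lists(self):
        res = compare_ranges([0.5, 0.5, 0.6], [0.5, 0.5, 0.6])
        assert res["t"] == 0 and res["p_two_sided"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = 0.8 + rng.normal(0, 1e-6, 4)
        b = 0.2 + rng.normal(0, 1e-6, 4)
        res = compare_ranges(a, b)
        assert res["p_two_sided"] < 0.05 and res["t"] > 0
        assert res["p_greater"] < 0.05

    def test_simulated_class_difference(self):
        rng = np.random.default_rng(1)
        erv = rng.normal(0.6, 0.1, 50)
        reg = rng.normal(0.25, 0.05, 50)
        assert compare_ranges(erv, reg)["p_greater"] < 0.05

    def test_group_size_validated(self):
        with pytest.raises(ValueError):
            compare_ranges([0.5], [0.2, 0.3])

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0.5, 0.1, 20), rng.normal(0.4, 0.2, 15)
        res = compare_ranges(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p_two_sided"] == pytest.approx(ref.pvalue)


class TestErvClassification:
    def regions(self):
        from iidmr.caller import IIDMR

        return [
            IIDMR("chr1", 1000, 1500, [1000], 6, 0, {}, 0.5),
        ]

    def test_one_bp_overlap_is_erv(self):
        r = classify_erv_overlap(
            self.regions(), [GenomicInterval("chr1", 1400, 2400, "IAP")]
        )[0]
        assert r.annotation_class == "ERV" and r.subfamilies == ["IAP"]

    def test_half_open_adjacency_is_not_overlap(self):
        r = classify_erv_overlap(
            self.regions(), [GenomicInterval("chr1", 1500, 2400, "IAP")]
        )[0]
        assert r.annotation_class == "non-ERV"

    def test_multiple_subfamilies_attached(self):
        r = classify_erv_overlap(
            self.regions(),
            [
                GenomicInterval("chr1", 1400, 2400, "IAP"),
                GenomicInterval("chr1", 900, 1100, "RLTR4"),
            ],
        )[0]
        assert r.annotation_class == "ERV"
        assert set(r.subfamilies) == {"IAP", "RLTR4"}


def planted_recovery(regions, truth):
    hits = 0
    for row in truth.itertuples(index=False):
        if any(
            r.chrom == row.chrom and r.start < row.end and row.start < r.end
            for r in regions
        ):
            hits += 1
    return hits


class TestCallIidmrs:
    def test_recovers_planted_dmrs(self, small_simulation):
        config, mset, truth = small_simulation
        regions = call_iidmrs(mset)
        erv_truth = truth[truth["class"] == "ERV-like"]
        assert planted_recovery(regions, erv_truth) == len(erv_truth)

    def test_mask_removes_exactly_covered_regions(self, small_simulation):
        config, mset, truth = small_simulation
        unmasked = call_iidmrs(mset)
        masked_truth = truth.iloc[:3]
        mask = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in masked_truth.itertuples(index=False)
        ]
        masked = call_iidmrs(mset, simple_repeat_mask=mask)
        removed = {
            (r.chrom, r.start, r.end)
            for r in unmasked
            if any(
                m.chrom == r.chrom and m.start < r.end and r.start < m.end
                for m in mask
            )
        }
        kept = {(r.chrom, r.start, r.end) for r in masked}
        assert kept == {(r.chrom, r.start, r.end) for r in unmasked} - removed

    def test_raising_min_range_never_adds_regions(self, small_simulation):
        _, mset, _ = small_simulation
        loose = {(r.chrom, r.start) for r in call_iidmrs(mset, CallerConfig(min_range=0.2))}
        strict = {(r.chrom, r.start) for r in call_iidmrs(mset, CallerConfig(min_range=0.4))}
        assert strict <= loose

    def test_lowering_alpha_never_adds_regions(self, small_simulation):
        _, mset, _ = small_simulation
        loose = call_iidmrs(mset, CallerConfig(alpha=0.05))
        strict = call_iidmrs(mset, CallerConfig(alpha=0.005))
        loose_cpgs = {(r.chrom, p) for r in loose for p in r.member_cpg_positions}
        strict_cpgs = {(r.chrom, p) for r in strict for p in r.member_cpg_positions}
        assert strict_cpgs <= loose_cpgs

    def test_excluded_individual_does_not_affect_calls(self, small_simulation):
        _, mset, _ = small_simulation
        included = mset.individuals[1:]
        before = call_iidmrs(mset, included_individuals=included)
        # permute the excluded individual's counts
        rng = np.random.default_rng(9)
        perm = rng.permutation(mset.n_sites)
        mset.meth[:, 0] = mset.meth[perm, 0]
        mset.total[:, 0] = mset.total[perm, 0]
        after = call_iidmrs(mset, included_individuals=included)
        assert [(r.chrom, r.start, r.end) for r in before] == [
            (r.chrom, r.start, r.end) for r in after
        ]
        # ... but its reported methylation is still present in the output
        assert all(mset.individuals[0] in r.methylation for r in after)

    def test_reported_methylation_covers_all_individuals(self, small_simulation):
        _, mset, _ = small_simulation
        regions = call_iidmrs(mset, included_individuals=mset.individuals[1:])
        for r in regions:
            assert set(r.methylation) == set(mset.individuals)
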