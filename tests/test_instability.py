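"""KS testing on discrete length multisets, BH correction, unstable-locus
calling, and the Wilcoxon group comparison — each checked against an
independent oracle (brute-force ECDF supremum, hand step-up, exhaustive
rank enumeration)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miracle.catalog import MicrosatelliteLocus, make_locus_id
from miracle.instability import (
    DetectionConfig,
    InstabilityError,
    bh_fdr,
    call_unstable,
    compare_groups,
    ks_permutation_pvalue,
    ks_two_sample,
)
from miracle.refnormal import ReferenceNormal

from conftest import profile_from_counts


def ecdf_sup_diff(x: dict, y: dict) -> float:
    """Brute-force KS statistic: sup over merged support of |ECDF_x - ECDF_y|."""
    n_x, n_y = sum(x.values()), sum(y.values())
    best = 0.0
    for v in sorted(set(x) | set(y)):
        fx = sum(c for k, c in x.items() if k <= v) / n_x
        fy = sum(c for k, c in y.items() if k <= v) / n_y
        best = max(best, abs(fx - fy))
    return best


def _random_multiset(rng, max_support=6, max_count=8):
    support = rng.choice(np.arange(5, 40), size=rng.integers(1, max_support + 1),
                         replace=False)
    return {int(v): int(rng.integers(1, max_count + 1)) for v in support}


class TestKS:
    def test_identical_distributions(self):
        d, p = ks_two_sample({10: 5}, {10: 5})
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample({10: 5}, {12: 5})
        assert d == 1.0

    def test_worked_example(self):
        # ECDFs at 10 differ by |0.6 - 0.2| = 0.4, the supremum
        d, _ = ks_two_sample({10: 3, 11: 2}, {10: 1, 11: 3, 12: 1})
        assert d == pytest.approx(0.4, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(InstabilityError):
            ks_two_sample({}, {10: 5})

    def test_matches_bruteforce_on_random_multisets(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            x, y = _random_multiset(rng), _random_multiset(rng)
            d, _ = ks_two_sample(x, y)
            assert abs(d - ecdf_sup_diff(x, y)) < 1e-12

    @given(st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_relabeling_invariance(self, data):
        lengths = data.draw(st.lists(st.integers(5, 30), min_size=1, max_size=5,
                                     unique=True))
        x = {v: data.draw(st.integers(1, 5)) for v in lengths}
        y = {v + data.draw(st.integers(0, 3)): c for v, c in x.items()}
        d1, _ = ks_two_sample(x, y)
        relabel = lambda m: {3 * k * k: c for k, c in m.items()}  # strictly increasing on k>0
        d2, _ = ks_two_sample(relabel(x), relabel(y))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_exact_small_n_mode(self):
        d_a, p_a = ks_two_sample({10: 4}, {12: 4}, method="asymp")
        d_e, p_e = ks_two_sample({10: 4}, {12: 4}, method="auto_exact")
        assert d_a == d_e == 1.0
        assert p_e <= 1 and p_e != p_a

    def test_permutation_pvalue_null_behaviour(self):
        # identical multisets: every permutation reaches the observed D
        p = ks_permutation_pvalue({10: 5, 11: 5}, {10: 5, 11: 5}, n_perm=200, seed=1)
        assert p == 1.0


def hand_step_up(pvals):
    """Independent BH oracle: sorted p * n / rank with cumulative minimum."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.05], [0.05]),
    ])
    def test_worked_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_invalid_pvalues_error(self):
        with pytest.raises(InstabilityError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(InstabilityError):
            bh_fdr([1.5])

    def test_q_dominates_p_and_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 20)).tolist()
            q = bh_fdr(p)
            assert np.all(q >= np.asarray(p) - 1e-15)
            assert q == pytest.approx(hand_step_up(p), abs=1e-12)

    def test_step_up_rejection_rule_exhaustive_small_n(self):
        # rejections at q < alpha must match the classical step-up rule
        rng = np.random.default_rng(11)
        alpha = 0.05
        for n in range(1, 7):
            for _ in range(40):
                p = rng.uniform(1e-4, 1, size=n)
                q = bh_fdr(p)
                srt = np.sort(p)
                ks = [k for k in range(1, n + 1) if srt[k - 1] <= alpha * k / n]
                if ks:
                    cut = srt[max(ks) - 1]
                    expected = p <= cut
                else:
                    expected = np.zeros(n, dtype=bool)
                assert np.array_equal(q < alpha, expected)

    def test_bh_superset_of_bonferroni(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, size=30)
        q = bh_fdr(p)
        bonf = p < 0.05 / len(p)
        assert np.all((q < 0.05) | ~bonf)


def _locus(lid, region="UTR3", motif="A"):
    chrom, rest = "chr1", lid
    return MicrosatelliteLocus(
        chrom=chrom, start=100, end=110, motif=motif, region=region,
        gene="G", locus_id=lid,
    )


class TestCallUnstable:
    def test_identical_to_reference_is_stable(self):
        tumor = profile_from_counts("T", {"L1": {12: 10}})
        ref = ReferenceNormal({"L1": (12, 10)})
        calls, summary = call_unstable(tumor, ref, [_locus("L1")])
        (c,) = calls
        assert c.D == 0.0 and c.q == 1.0 and not c.unstable
        assert summary.n_tested() == 1 and summary.n_unstable() == 0

    def test_shifted_distribution_unstable(self):
        tumor = profile_from_counts("T", {"L1": {9: 10}})
        ref = ReferenceNormal({"L1": (12, 10)})
        calls, _ = call_unstable(tumor, ref, [_locus("L1")])
        (c,) = calls
        assert c.D == 1.0 and c.unstable and c.q < 0.05

    def test_min_reads_applies_to_both_sides(self):
        tumor = profile_from_counts("T", {"L1": {9: 4}, "L2": {9: 10}})
        ref = ReferenceNormal({"L1": (12, 10), "L2": (12, 4)})
        # L1 thin on the tumor side, L2 thin on the reference side
        tumor.counts["L3"] = {9: 10}
        ref.entries["L3"] = (12, 10)
        calls, _ = call_unstable(tumor, ref, [_locus(l) for l in ("L1", "L2", "L3")])
        assert [c.locus_id for c in calls] == ["L3"]

    def test_bh_spans_all_tested_loci(self):
        counts = {f"L{i}": {12: 10} for i in range(20)}
        counts["L0"] = {11: 5, 12: 5}
        tumor = profile_from_counts("T", counts)
        ref = ReferenceNormal({f"L{i}": (12, 10) for i in range(20)})
        calls, _ = call_unstable(tumor, ref, [_locus(f"L{i}") for i in range(20)])
        by_id = {c.locus_id: c for c in calls}
        assert by_id["L0"].q == pytest.approx(min(by_id["L0"].p * 20, 1.0))

    def test_zero_tested_loci_errors_with_diagnostic(self):
        tumor = profile_from_counts("T", {"L1": {12: 2}})
        ref = ReferenceNormal({"L1": (12, 10)})
        with pytest.raises(InstabilityError, match="min_reads"):
            call_unstable(tumor, ref, [_locus("L1")])

    def test_summary_strata_sum_to_totals(self):
        tumor = profile_from_counts("T", {
            "L1": {12: 10}, "L2": {9: 10}, "L3": {12: 10}})
        ref = ReferenceNormal({l: (12, 10) for l in ("L1", "L2", "L3")})
        loci = [_locus("L1", "UTR3"), _locus("L2", "CDS", "AG"), _locus("L3", "CDS")]
        _, summary = call_unstable(tumor, ref, loci)
        total = sum(t for t, _ in summary.strata.values())
        assert total == summary.n_tested() == 3
        assert summary.n_tested(region="CDS") == 2
        assert summary.n_unstable(region="CDS", repeat_class="di") == 1

    def test_matched_normal_profile_as_comparator(self):
        tumor = profile_from_counts("T", {"L1": {9: 6, 12: 6}})
        normal = profile_from_counts("N", {"L1": {12: 12}})
        calls, _ = call_unstable(tumor, normal, [_locus("L1")])
        assert calls[0].D == pytest.approx(0.5)


def _exact_ranksum_pvalue(a, b):
    """Exhaustive enumeration over all rank assignments (no ties)."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for x in xs for y in ys if x > y))
    n = len(us)
    more_extreme = sum(1 for u in us if min(u, n_a * len(b) - u) <= min(u_obs, n_a * len(b) - u_obs))
    return more_extreme / n


class TestCompareGroups:
    def test_exact_small_sample(self):
        _, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(_exact_ranksum_pvalue([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_p_one(self):
        _, p = compare_groups([3, 3, 4, 5], [3, 3, 4, 5])
        assert p == pytest.approx(1.0)

    def test_unbalanced_exact_enumeration(self):
        _, p = compare_groups([10, 11, 12, 13], [1, 2, 3])
        assert p == pytest.approx(2 / math.comb(7, 3), abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(InstabilityError):
            compare_groups([], [1, 2])
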