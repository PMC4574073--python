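"""Tests for pair enumeration, rank-sum testing and cohort comparisons."""

from itertools import combinations

import numpy as np
import pytest

from repstab.cohort_stats import (
    bonferroni,
    compare_cohorts,
    compare_msi,
    enumerate_normal_pairs,
    pathway_enrichment,
    profile_pair,
    rank_sum_test,
)
from repstab.instability import gene_flags, match_repeats
from repstab.repeat_finder import TandemRepeat


def exact_wrs_p(a, b):
    """Independent oracle: exhaustive enumeration of all group assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:n_a].sum()
    null = [sum(ranks[list(idx)])
            for idx in combinations(range(len(pooled)), n_a)]
    null = np.asarray(null)
    mean = null.mean()
    return float(np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-9))


class TestEnumerateNormalPairs:
    def test_35_genomes_give_595_pairs(self):
        pairs = enumerate_normal_pairs([f"g{i}" for i in range(35)])
        assert len(pairs) == 595
        assert len({frozenset(p) for p in pairs}) == 595

    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 6), (10, 45)])
    def test_small_counts(self, n, expected):
        assert len(enumerate_normal_pairs(list(range(n)))) == expected

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_normal_pairs(["only"])


class TestRankSumTest:
    def test_worked_example(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_raw == pytest.approx(0.1)

    def test_identical_groups(self):
        res = rank_sum_test([2, 2, 2], [2, 2])
        assert res.p_raw == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            n_a = int(rng.integers(1, 8))
            n_b = int(rng.integers(1, 13 - n_a))
            pooled = rng.choice(1000, size=n_a + n_b, replace=False) / 7.0
            a, b = pooled[:n_a], pooled[n_a:]
            res = rank_sum_test(a, b)
            assert res.p_raw == pytest.approx(exact_wrs_p(a, b), abs=1e-9)

    def test_exact_and_asymptotic_agree_at_n8(self):
        # the continuity-corrected normal approximation deviates most in the
        # mid-range of p (up to ~0.011 at n=m=8), hence the 0.02 bound
        rng = np.random.default_rng(9)
        from scipy import stats
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            exact = rank_sum_test(a, b).p_raw  # tie-free -> exact branch
            approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic",
                                        use_continuity=True).pvalue
            assert abs(exact - approx) < 0.02
            if exact < 0.3:  # decision-relevant region is tighter
                assert abs(exact - approx) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 5) == [0.05]
        assert bonferroni([0.5], 5) == [1.0]
        assert bonferroni([0.0], 1000) == [0.0]

    def test_never_decreases_and_caps(self):
        rng = np.random.default_rng(4)
        ps = rng.uniform(size=20)
        adj = bonferroni(ps, 30)
        assert all(q >= p for p, q in zip(ps, adj))
        assert all(q <= 1.0 for q in adj)

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


def _rep(unit="AC", start=0, copies=25.0):
    period = len(unit)
    length = int(copies * period)
    return TandemRepeat(start=start, length=length, unit=unit, period=period,
                        copy_number=copies, score=2 * length, identity=1.0,
                        indel_fraction=0.0)


def _flags(status, unit="AC"):
    if status == "gain":
        return gene_flags(match_repeats([_rep(unit)], []))
    if status == "copy_change":
        return gene_flags(match_repeats([_rep(unit, copies=25)],
                                        [_rep(unit, copies=23)]))
    return gene_flags(match_repeats([_rep(unit)], [_rep(unit)]))


class TestProfilePair:
    def test_identical_genomes_zero_counts(self):
        prof = profile_pair({("g1", "promoter"): _flags("stable")}, "p", "tumor_normal")
        assert all(v == 0 for v in prof.counts.values())

    def test_gene_counts_from_events(self):
        flags = {(f"g{i}", "promoter"): _flags("gain") for i in range(3)}
        flags.update({(f"h{i}", "promoter"): _flags("copy_change")
                      for i in range(2)})
        prof = profile_pair(flags, "p", "tumor_normal")
        assert prof.counts["promoter_orphan"] == 3
        assert prof.counts["promoter_unstable"] == 2
        assert prof.counts["promoter_instability"] == 5

    def test_gene_with_both_event_types_counted_once_per_category(self):
        both = gene_flags(match_repeats(
            [_rep("AC", 0, 25), _rep("AG", 100, 25)],
            [_rep("AC", 0, 23)]))
        prof = profile_pair({("g1", "promoter"): both}, "p", "tumor_normal")
        assert prof.counts["promoter_orphan"] == 1
        assert prof.counts["promoter_unstable"] == 1
        assert prof.counts["promoter_instability"] == 1

    def test_pathway_proportions_denominator(self):
        flags = {("g1", "promoter"): _flags("gain")}
        prof = profile_pair(flags, "p", "tumor_normal",
                            analyzed_genes=["g1", "g2", "g3", "g4"],
                            pathways={"pw": {"g1", "g2", "g3", "g4"},
                                      "empty": {"g9"}})
        assert prof.pathway_props[("pw", "promoter", "orphan")] == 0.25
        assert prof.pathway_props[("empty", "promoter", "orphan")] == 0.0


def _profiles(counts, pair_class, msi=None, props=None):
    from repstab.cohort_stats import PairProfile

    return [PairProfile(f"{pair_class}{i}", pair_class,
                        msi[i] if msi else None,
                        {"promoter_instability": c},
                        props or {})
            for i, c in enumerate(counts)]


class TestComparisons:
    def test_compare_cohorts_detects_shift(self):
        t = _profiles([30, 28, 35, 31], "tumor_normal")
        n = _profiles([3, 5, 2, 4, 6, 1], "normal_normal")
        res = compare_cohorts(t, n, "promoter_instability")
        assert res.p_raw < 0.05

    def test_compare_cohorts_identical_constants(self):
        t = _profiles([4, 4, 4], "tumor_normal")
        n = _profiles([4, 4, 4], "normal_normal")
        assert compare_cohorts(t, n, "promoter_instability").p_raw == 1.0

    def test_compare_msi_requires_both_groups(self):
        t = _profiles([1, 2, 3], "tumor_normal", msi=[True, True, True])
        with pytest.raises(ValueError):
            compare_msi(t, "promoter_instability")

    def test_compare_msi_bonferroni_family(self):
        t = _profiles([9, 8, 1, 2, 1, 2], "tumor_normal",
                      msi=[True, True, False, False, False, False])
        res = compare_msi(t, "promoter_instability", family_size=4)
        assert res.correction == "bonferroni"
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 4))

    def test_pathway_identical_proportions_p1(self):
        props = {("pw", "promoter", "unstable"): 0.2,
                 ("pw", "promoter", "orphan"): 0.2}
        t = _profiles([0, 0, 0], "tumor_normal", props=props)
        n = _profiles([0, 0, 0], "normal_normal", props=props)
        results = pathway_enrichment(t, n, ["pw"])
        assert all(r.p_raw == 1.0 and r.p_adjusted == 1.0 for r in results)
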