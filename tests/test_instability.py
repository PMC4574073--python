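"""Tests for repeat matching, classification and matrix construction."""

import numpy as np
import pytest

from repstab.instability import (
    build_matrix,
    call_pair,
    classify_match,
    gene_flags,
    match_repeats,
)
from repstab.repeat_finder import TandemRepeat


def rep(unit="AC", start=0, copies=20.0, score=None):
    period = len(unit)
    length = int(round(copies * period))
    return TandemRepeat(start=start, length=length, unit=unit, period=period,
                        copy_number=copies,
                        score=score if score is not None else 2 * length,
                        identity=1.0, indel_fraction=0.0)


class TestMatchRepeats:
    def test_within_window_matched(self):
        m = match_repeats([rep(start=100)], [rep(start=140)])
        assert len(m) == 1 and m[0].status == "stable"

    def test_outside_window_two_orphans(self):
        m = match_repeats([rep(start=100)], [rep(start=160)])
        assert sorted(x.status for x in m) == ["orphan_a", "orphan_b"]

    def test_greedy_nearest_assignment(self):
        # A has repeats at 100 and 130; B at 120: B pairs with 130 (d=10)
        a = [rep(start=100), rep(start=130)]
        b = [rep(start=120)]
        m = match_repeats(a, b)
        by_status = {x.status: x for x in m}
        assert by_status["stable"].repeat_a.start == 130
        assert by_status["orphan_a"].repeat_a.start == 100

    def test_different_units_never_match(self):
        m = match_repeats([rep("AC", 100)], [rep("AG", 100)])
        assert sorted(x.status for x in m) == ["orphan_a", "orphan_b"]

    def test_revcomp_units_matched_only_when_enabled(self):
        # canonical("AC") = "AC"; its reverse complement "GT" canonical "GT"
        a, b = [rep("AC", 100)], [rep("GT", 110)]
        plain = match_repeats(a, b)
        assert all(x.status.startswith("orphan") for x in plain)
        rc = match_repeats(a, b, identify_revcomp=True)
        assert len(rc) == 1 and rc[0].status == "stable"

    def test_conservation_and_symmetry(self):
        rng = np.random.default_rng(0)
        units = ["A", "AC", "ACG", "AG"]
        for _ in range(50):
            a = [rep(units[rng.integers(4)], int(rng.integers(0, 300)))
                 for _ in range(rng.integers(0, 5))]
            b = [rep(units[rng.integers(4)], int(rng.integers(0, 300)))
                 for _ in range(rng.integers(0, 5))]
            ab = match_repeats(a, b)
            ba = match_repeats(b, a)
            # every repeat appears exactly once
            n_both = sum(1 for m in ab if m.status in ("stable", "unstable"))
            n_orph = sum(1 for m in ab if m.status.startswith("orphan"))
            assert len(a) + len(b) == 2 * n_both + n_orph
            # symmetry up to orphan label swap
            swap = {"orphan_a": "orphan_b", "orphan_b": "orphan_a"}
            assert sorted(swap.get(m.status, m.status) for m in ab) == \
                sorted(m.status for m in ba)

    def test_greedy_close_to_optimal_assignment(self):
        """Greedy nearest-distance matching is compared with the brute-force
        optimal (max-cardinality, then min total distance) assignment on
        small instances: it always finds at least half as many pairs (a
        maximal matching guarantee) and almost always the same pairing."""
        from itertools import permutations

        def optimal_pairs(a, b, max_shift=50):
            best = (-1, float("inf"))
            na, nb = len(a), len(b)
            if na > nb:
                a, b, na, nb = b, a, nb, na
            for perm in permutations(range(nb), na):
                pairs = [(i, j) for i, j in enumerate(perm)
                         if abs(a[i].start - b[j].start) <= max_shift]
                cost = sum(abs(a[i].start - b[j].start) for i, j in pairs)
                key = (len(pairs), -cost)
                if key > (best[0], -best[1]):
                    best = (len(pairs), cost)
            return best[0]

        rng = np.random.default_rng(2)
        same = total = 0
        for _ in range(150):
            a = [rep("AC", int(rng.integers(0, 160)))
                 for _ in range(rng.integers(0, 4))]
            b = [rep("AC", int(rng.integers(0, 160)))
                 for _ in range(rng.integers(0, 4))]
            m = match_repeats(a, b)
            greedy_pairs = sum(1 for x in m
                               if x.status in ("stable", "unstable"))
            opt = optimal_pairs(a, b)
            assert greedy_pairs * 2 >= opt  # maximal-matching guarantee
            same += greedy_pairs == opt
            total += 1
        assert same / total > 0.9  # divergence is rare on small instances

    def test_max_shift_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = [rep("AC", int(rng.integers(0, 200))) for _ in range(3)]
            b = [rep("AC", int(rng.integers(0, 200))) for _ in range(3)]
            orphans = []
            for shift in (0, 10, 25, 50, 100, 250):
                m = match_repeats(a, b, max_shift=shift)
                orphans.append(sum(1 for x in m
                                   if x.status.startswith("orphan")))
            assert orphans == sorted(orphans, reverse=True)


class TestClassify:
    @pytest.mark.parametrize("ca,cb,status", [
        (10.0, 12.0, "unstable"),
        (10.0, 10.0, "stable"),
        (10.0, 10.4, "stable"),   # below the one-unit threshold
        (10.0, 11.0, "unstable"),  # exactly one unit
    ])
    def test_copy_delta_threshold(self, ca, cb, status):
        assert classify_match(rep(copies=ca), rep(copies=cb)) == status

    def test_one_sided_is_orphan(self):
        assert classify_match(rep(), None) == "orphan_a"
        assert classify_match(None, rep()) == "orphan_b"
        with pytest.raises(ValueError):
            classify_match(None, None)

    def test_float_safe_at_exact_one_unit(self):
        # 46/3 vs 49/3 is one unit but not exactly 1.0 in floats
        assert classify_match(rep("ACT", copies=46 / 3),
                              rep("ACT", copies=49 / 3)) == "unstable"


class TestGeneFlags:
    def test_orphan_plus_stable(self):
        m = match_repeats([rep("AC", 0), rep("AG", 100)], [rep("AC", 0)])
        f = gene_flags(m)
        assert f.has_orphan and not f.has_unstable and f.has_instability

    def test_all_stable(self):
        f = gene_flags(match_repeats([rep("AC", 0)], [rep("AC", 0)]))
        assert not f.has_instability

    def test_mono_subset_implies_general(self):
        m = match_repeats([rep("A", 0, copies=45)], [rep("A", 0, copies=43)])
        f = gene_flags(m)
        assert f.mono_has_unstable and f.has_unstable
        assert f.mono_has_instability and f.has_instability


class TestBuildMatrix:
    def test_zero_rate_empty_matrix(self):
        flags = {"P0": {}, "P1": {}}
        m = build_matrix(flags)
        assert m.empty

    def test_single_event_single_entry(self):
        stable = gene_flags(match_repeats([rep("AC", 0)], [rep("AC", 0)]))
        gain = gene_flags(match_repeats([rep("AC", 0)], []))
        flags = {
            "P0": {("g1", "promoter"): gain, ("g2", "promoter"): stable},
            "P1": {("g1", "promoter"): stable, ("g2", "promoter"): stable},
        }
        m = build_matrix(flags)
        assert list(m.index) == ["g1"]
        assert bool(m.loc["g1", "P0"]) and not bool(m.loc["g1", "P1"])


def test_call_pair_roundtrip(small_cohort, detect20):
    """Instability calls on a rendered pair agree with the generator truth."""
    from repstab.pipeline import detect_cohort_repeats, _repeats_by_genome

    patient = small_cohort.reference.events.patients[0]
    genomes = {g: small_cohort.genomes[g]
               for g in (f"{patient}_T", f"{patient}_N")}
    by_genome = _repeats_by_genome(detect_cohort_repeats(genomes, detect20))
    matches, flags = call_pair(by_genome.get(f"{patient}_T", {}),
                               by_genome.get(f"{patient}_N", {}))
    truth = small_cohort.truth
    sub = truth[truth.patient_id == patient]
    event_of = {"unstable": "copy_change", "orphan_a": "gain",
                "orphan_b": "loss"}
    called = {(m.gene_id, m.region_kind): event_of[m.status]
              for m in matches if m.status in event_of}
    expected = {(r.gene_id, r.region_kind): r.event
                for r in sub.itertuples(index=False) if r.event != "none"}
    assert called == expected
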