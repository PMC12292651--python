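"""Grammar rules, tier classification and candidate enumeration."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sfze import (
    GrammarError,
    SiteSet,
    SyntaxFlags,
    SyntaxGrammar,
    TFClass,
    Tier,
    arrangement_string,
    best_instance,
    classify,
    enumerate_candidates,
    evaluate_rules,
    make_instance,
    parse_arrangement,
)
from sfze.syntax_grammar import FLAG_NAMES, TIER_RANK

from conftest import make_site


def full_direct_members():
    """The canonical compliant layout: S> F> F> Z> <E within one nucleosome."""
    return [
        make_site("S", 5, 13, "+"),
        make_site("F", 40, 48, "+"),
        make_site("F", 60, 68, "+"),
        make_site("Z", 80, 90, "+"),
        make_site("E", 120, 124, "-"),
    ]


class TestEvaluateRules:
    def test_canonical_layout_passes_every_rule(self, grammar):
        flags = evaluate_rules(full_direct_members(), grammar)
        assert flags.complete_core and flags.s_present
        assert flags.order_ok and not flags.mirror_used
        assert flags.ze_face_to_face and flags.fz_same_dir
        assert flags.span_ok
        # core span over F/Z/E only: 124 - 40
        inst = make_instance(full_direct_members(), grammar)
        assert inst.core_span == 84

    def test_zic_and_ets_same_orientation_fails_face_to_face(self, grammar):
        members = full_direct_members()
        members[4] = make_site("E", 120, 124, "+")
        flags = evaluate_rules(members, grammar)
        assert not flags.ze_face_to_face
        assert flags.order_ok and flags.span_ok and flags.fz_same_dir

    def test_core_spread_beyond_nucleosome_fails_span(self, grammar):
        members = [
            make_site("S", 5, 13, "+"),
            make_site("F", 40, 48, "+"),
            make_site("F", 60, 68, "+"),
            make_site("Z", 150, 160, "+"),
            make_site("E", 236, 241, "-"),
        ]
        flags = evaluate_rules(members, grammar)
        assert not flags.span_ok
        assert flags.order_ok and flags.ze_face_to_face

    def test_zic_adjacent_foxh1_on_opposite_strand_fails(self, grammar):
        members = full_direct_members()
        members[2] = make_site("F", 60, 68, "-")  # the F nearest to Z
        flags = evaluate_rules(members, grammar)
        assert not flags.fz_same_dir

    def test_distant_foxh1_strand_is_irrelevant(self, grammar):
        members = full_direct_members()
        members[1] = make_site("F", 40, 48, "-")  # far from Z
        assert evaluate_rules(members, grammar).fz_same_dir

    def test_mixed_sequence_ids_raise(self, grammar):
        members = full_direct_members()
        members[0] = make_site("S", 5, 13, "+", seq_id="other")
        with pytest.raises(GrammarError):
            evaluate_rules(members, grammar)

    def test_suh_like_counts_as_s(self, grammar):
        members = full_direct_members()
        members[0] = make_site("S_LIKE", 5, 12, "+")
        flags = evaluate_rules(members, grammar)
        assert flags.s_present and flags.order_ok

    def test_s_distance_constraint(self):
        g = SyntaxGrammar(s_max_distance=20)
        members = full_direct_members()  # S ends at 13, core starts at 40
        flags = evaluate_rules(members, g)
        assert not flags.s_present
        near = [make_site("S", 25, 33, "+")] + members[1:]
        assert evaluate_rules(near, SyntaxGrammar(s_max_distance=20)).s_present


class TestClassify:
    def test_all_rules_passing_is_full(self, grammar):
        assert make_instance(full_direct_members(), grammar).tier is Tier.SFZE_FULL

    def test_sezf_order_is_partially_inverted(self, grammar):
        """S-E-Z-F with intact orientations: order deviates, tier inverted."""
        members = [
            make_site("S", 5, 13, "+"),
            make_site("E", 30, 35, "+"),
            make_site("Z", 60, 70, "-"),
            make_site("F", 90, 98, "-"),
        ]
        inst = make_instance(members, grammar)
        assert inst.flags.ze_face_to_face and inst.flags.fz_same_dir
        assert not inst.flags.order_ok
        assert inst.tier is Tier.SFZE_LIKE_INVERTED

    def test_mirrored_arrangement_is_full_with_mirror_flag(self, grammar):
        members = [
            make_site("E", 10, 15, "+"),
            make_site("Z", 40, 50, "-"),
            make_site("F", 70, 78, "-"),
            make_site("F", 95, 103, "-"),
            make_site("S", 130, 138, "-"),
        ]
        inst = make_instance(members, grammar)
        assert inst.tier is Tier.SFZE_FULL
        assert inst.flags.mirror_used

    def test_mirror_rejected_when_disallowed(self):
        g = SyntaxGrammar(allow_mirror=False)
        members = [
            make_site("E", 10, 15, "+"),
            make_site("Z", 40, 50, "-"),
            make_site("F", 70, 78, "-"),
            make_site("S", 100, 108, "-"),
        ]
        inst = make_instance(members, g)
        assert not inst.flags.order_ok
        assert inst.tier is Tier.SFZE_LIKE_INVERTED

    def test_missing_core_class_is_incomplete(self, grammar):
        members = [m for m in full_direct_members() if m.tf_class is not TFClass.Z]
        assert make_instance(members, grammar).tier is Tier.INCOMPLETE

    def test_order_intact_without_s_is_inverted_tier(self, grammar):
        members = full_direct_members()[1:]
        inst = make_instance(members, grammar)
        assert inst.flags.order_ok and not inst.flags.s_present
        assert inst.tier is Tier.SFZE_LIKE_INVERTED

    def test_orientation_violation_outranks_span_violation(self, grammar):
        members = [
            make_site("F", 0, 8, "+"),
            make_site("Z", 100, 110, "+"),
            make_site("E", 300, 305, "+"),  # same strand as Z, span 305
        ]
        assert make_instance(members, grammar).tier is Tier.SFZE_LIKE_ORIENT

    def test_every_flag_combination_maps_to_exactly_one_tier(self):
        """classify is total and deterministic over the full flag lattice."""
        seen = {}
        for bits in itertools.product([False, True], repeat=len(FLAG_NAMES)):
            flags = SyntaxFlags(**dict(zip(FLAG_NAMES, bits)))
            tier = classify(flags)
            assert isinstance(tier, Tier)
            assert classify(flags) is tier
            seen[bits] = tier
        assert len(seen) == 2 ** len(FLAG_NAMES)
        assert set(seen.values()) == set(Tier)


class TestEnumeration:
    def test_candidate_count_matches_exhaustive_generator(self, grammar):
        sites = [
            make_site("S", 5, 13, "+"),
            make_site("F", 40, 48, "+"),
            make_site("F", 60, 68, "+"),
            make_site("Z", 80, 90, "+"),
            make_site("E", 120, 124, "-"),
        ]
        instances = enumerate_candidates(SiteSet("region", tuple(sites)), grammar)
        # independent count: 1 Z x 1 E x (C(2,1)+C(2,2)) F subsets x (S or no S)
        f_subsets = [c for k in (1, 2) for c in itertools.combinations(range(2), k)]
        assert len(instances) == 1 * 1 * len(f_subsets) * 2

    def test_missing_zic_yields_incomplete_candidates(self, grammar):
        sites = [m for m in full_direct_members() if m.tf_class is not TFClass.Z]
        instances = enumerate_candidates(SiteSet("region", tuple(sites)), grammar)
        assert instances
        assert all(i.tier is Tier.INCOMPLETE for i in instances)
        assert all(not i.flags.complete_core for i in instances)

    def test_empty_site_set_yields_no_candidates(self, grammar):
        assert enumerate_candidates(SiteSet("region"), grammar) == []

    def test_budget_exceeded_raises_instead_of_truncating(self):
        g = SyntaxGrammar(enumeration_budget=3)
        sites = tuple(full_direct_members())
        with pytest.raises(GrammarError, match="budget"):
            enumerate_candidates(SiteSet("region", sites), g)

    def test_agrees_with_brute_force_subset_oracle(self, grammar):
        """Every oracle-generated member combination appears exactly once."""
        sites = [
            make_site("S", 0, 8, "+"),
            make_site("S_LIKE", 20, 27, "-"),
            make_site("F", 40, 48, "+"),
            make_site("F", 60, 68, "-"),
            make_site("F", 75, 83, "+"),
            make_site("Z", 90, 100, "+"),
            make_site("Z", 110, 120, "-"),
            make_site("E", 130, 135, "-"),
        ]
        got = enumerate_candidates(SiteSet("region", tuple(sites)), grammar)
        keys = {tuple(sorted((m.start, m.tf_class.value) for m in i.member_sites))
                for i in got}
        assert len(keys) == len(got)
        # oracle: iterate all subsets of <= 15 sites, keep the legal shapes
        expected = set()
        for r in range(1, len(sites) + 1):
            for combo in itertools.combinations(sites, r):
                n = {cls: sum(s.tf_class is cls for s in combo) for cls in TFClass}
                ns = n[TFClass.S] + n[TFClass.S_LIKE]
                if n[TFClass.Z] != 1 or n[TFClass.E] != 1 or ns > 1:
                    continue
                if not 1 <= n[TFClass.F] <= grammar.max_f:
                    continue
                expected.add(tuple(sorted((s.start, s.tf_class.value) for s in combo)))
        assert keys == expected
        # and tiers agree with direct evaluation of the same members
        for inst in got:
            assert inst.tier is classify(evaluate_rules(inst.member_sites, grammar))


class TestArrangementString:
    def test_full_direct_rendering(self, grammar):
        inst = make_instance(full_direct_members(), grammar)
        assert arrangement_string(inst) == "S> F> F> Z> <E"

    def test_mirrored_rendering(self, grammar):
        members = [
            make_site("E", 10, 15, "+"),
            make_site("Z", 40, 50, "-"),
            make_site("F", 70, 78, "-"),
            make_site("F", 95, 103, "-"),
            make_site("S", 130, 138, "-"),
        ]
        inst = make_instance(members, grammar)
        assert arrangement_string(inst) == "E> <Z <F <F <S"

    def test_single_site_rendering(self, grammar):
        inst = make_instance([make_site("Z", 10, 20, "-")], grammar)
        assert arrangement_string(inst) == "<Z"

    def test_round_trip(self, grammar):
        inst = make_instance(full_direct_members(), grammar)
        text = arrangement_string(inst)
        parsed = parse_arrangement(text)
        assert parsed == [
            (s.tf_class, s.strand)
            for s in sorted(inst.member_sites, key=lambda s: s.start)
        ]


class TestBestInstance:
    def test_full_beats_any_like_tier(self, grammar):
        full = make_instance(full_direct_members(), grammar)
        members = full_direct_members()
        members[4] = make_site("E", 120, 124, "+")
        orient = make_instance(members, grammar)
        assert best_instance([orient, full]) is full

    def test_smaller_core_span_wins_between_equal_tiers(self, grammar):
        tight = make_instance(full_direct_members(), grammar)
        loose_members = [
            make_site("S", 5, 13, "+"),
            make_site("F", 20, 28, "+"),
            make_site("F", 60, 68, "+"),
            make_site("Z", 80, 90, "+"),
            make_site("E", 135, 140, "-"),
        ]
        loose = make_instance(loose_members, grammar)
        assert tight.tier is loose.tier is Tier.SFZE_FULL
        assert best_instance([loose, tight]) is tight

    def test_empty_collection_gives_none(self):
        assert best_instance([]) is None

    def test_tier_ranking_is_strict(self):
        assert len(set(TIER_RANK.values())) == len(Tier)


class TestStrandFlipInvariance:
    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_mirrored_site_geometry_preserves_tier(self, seed):
        """Reverse-complementing a region keeps the tier; mirror toggles."""
        import numpy as np

        from sfze import mirror_site

        grammar = SyntaxGrammar()
        rng = np.random.default_rng(seed)
        # random geometry built from the canonical one by jitter
        members = full_direct_members()
        if rng.random() < 0.5:
            members[4] = make_site("E", 120, 124, "+")
        if rng.random() < 0.5:
            members = members[1:]
        length = 200
        inst = make_instance(members, grammar)
        mirrored = make_instance([mirror_site(s, length) for s in members], grammar)
        assert mirrored.tier is inst.tier
        if inst.flags.order_ok:
            assert mirrored.flags.mirror_used != inst.flags.mirror_used
        assert mirrored.core_span == inst.core_span
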