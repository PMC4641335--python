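"""Scoring engine: recoding, missing policies, categorisation (with an
exhaustive enumeration oracle), composites and profile building."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from semas.instrument import BarrierCategory, default_instrument
from semas.scoring import (
    ResponseRecord,
    ScoringError,
    build_profile,
    categorize,
    recode_item,
    resolve_coping,
    resolve_locus,
    score_construct,
)

from conftest import complete_record

NONE, MINOR, MAJOR, NS = (
    BarrierCategory.NONE,
    BarrierCategory.MINOR,
    BarrierCategory.MAJOR,
    BarrierCategory.NOT_SCORABLE,
)


# ---------------------------------------------------------------------------
# recoding


def test_coping_often_and_very_often_score_identically(instrument):
    item = instrument.items["cop_p_1"]
    assert recode_item(item, 4) == recode_item(item, 5) == 3


def test_social_support_recode_0_0_0_1_2(instrument):
    item = instrument.items["ss_1"]
    # no / completely false / somewhat false -> 0; somewhat true -> 1;
    # completely true -> 2
    assert [recode_item(item, c) for c in (1, 2, 3, 4, 5)] == [0, 0, 0, 1, 2]


def test_missing_propagates(instrument):
    assert recode_item(instrument.items["se_1"], None) is None


def test_reverse_item_mirrors_score(instrument):
    import dataclasses

    item = dataclasses.replace(instrument.items["se_1"], reverse=True)
    assert recode_item(item, 1) == 3 and recode_item(item, 4) == 0


def test_illegal_code_lenient_logs_and_strict_raises(instrument):
    item = instrument.items["se_1"]
    issues = []
    assert recode_item(item, 9, issues=issues) is None
    assert issues and "se_1" in issues[0]
    with pytest.raises(ScoringError):
        recode_item(item, 9, strict=True)


def test_vas_out_of_range(instrument):
    item = instrument.items["burden"]
    assert recode_item(item, 12.0) is None
    with pytest.raises(ScoringError):
        recode_item(item, -1.0, strict=True)


# ---------------------------------------------------------------------------
# missing policies


def test_exclude_case_any_missing_voids_construct(instrument):
    rec = ResponseRecord("r", {"se_1": 4})  # se_2 missing
    sc = score_construct(instrument.constructs["self_efficacy"], rec)
    assert sc.sum_score is None and sc.category is NS and sc.n_missing == 1


def test_social_support_missing_scored_zero(instrument):
    rec = ResponseRecord("r", {"ss_1": 5, "ss_2": 5})  # 4 of 6 missing
    sc = score_construct(instrument.constructs["social_support"], rec)
    assert sc.sum_score == 4 and sc.category is NONE and sc.n_missing == 4


def test_social_support_all_missing_not_scorable(instrument):
    sc = score_construct(instrument.constructs["social_support"], ResponseRecord("r", {}))
    assert sc.sum_score is None and sc.category is NS


# ---------------------------------------------------------------------------
# categorisation: spot values + exhaustive oracle


@pytest.mark.parametrize(
    "construct, total, expected",
    [
        ("self_efficacy", 5, NONE),
        ("self_efficacy", 2, MINOR),
        ("self_efficacy", 0, MAJOR),
        ("burden", 0, MINOR),
        ("burden", 5, NONE),
        ("burden", 9, MINOR),
        ("social_support", 2, MINOR),
        ("social_support", 1, MAJOR),
        ("social_support", 3, NONE),
    ],
)
def test_published_band_examples(instrument, construct, total, expected):
    assert categorize(instrument.constructs[construct], total) is expected


def _oracle_self_efficacy(total):
    # scores 4 to 6 -> high self-efficacy, no barrier; 2-3 minor; 0-1 major
    if 4 <= total <= 6:
        return NONE
    if 2 <= total <= 3:
        return MINOR
    return MAJOR


def _oracle_social_support(total):
    # 3-12 no barrier; 2 minor; 1-0 major
    if total >= 3:
        return NONE
    if total == 2:
        return MINOR
    return MAJOR


def _oracle_burden(vas):
    # low burden (0-2) minor; high (8-10) minor; 3-7 none; half-up rounding
    import math

    v = math.floor(vas + 0.5)
    return MINOR if v <= 2 or v >= 8 else NONE


def test_self_efficacy_exhaustive_oracle(instrument):
    """All 16 response combinations agree with the published banding text."""
    con = instrument.constructs["self_efficacy"]
    for c1, c2 in itertools.product(range(1, 5), repeat=2):
        sc = score_construct(con, ResponseRecord("r", {"se_1": c1, "se_2": c2}))
        assert sc.sum_score == (c1 - 1) + (c2 - 1)
        assert sc.category is _oracle_self_efficacy(sc.sum_score)


def test_social_support_exhaustive_oracle(instrument):
    """All 5^6 response combinations agree with the published banding."""
    con = instrument.constructs["social_support"]
    smap = {1: 0, 2: 0, 3: 0, 4: 1, 5: 2}
    ids = [it.item_id for it in con.items]
    for combo in itertools.product(range(1, 6), repeat=6):
        sc = score_construct(con, ResponseRecord("r", dict(zip(ids, combo))))
        total = sum(smap[c] for c in combo)
        assert sc.sum_score == total
        assert sc.category is _oracle_social_support(total)


def test_burden_vas_grid_oracle(instrument):
    """Every 0.1 step on the VAS agrees with the u-shaped banding."""
    con = instrument.constructs["burden"]
    for tenth in range(0, 101):
        vas = tenth / 10
        sc = score_construct(con, ResponseRecord("r", {"burden": vas}))
        assert sc.category is _oracle_burden(vas), vas


# ---------------------------------------------------------------------------
# composites


def _coping_rule(instrument):
    return instrument.composites["coping"]


def _locus_rule(instrument):
    return instrument.composites["locus"]


def test_single_dominant_problem_solving_is_no_barrier(instrument):
    styles, cat = resolve_coping({"P": 6, "E": 2, "D": 2}, _coping_rule(instrument))
    assert styles == {"P"} and cat is NONE


def test_tied_styles_are_a_minor_barrier(instrument):
    styles, cat = resolve_coping({"P": 4, "E": 4, "D": 1}, _coping_rule(instrument))
    assert styles == {"P", "E"} and cat is MINOR


def test_full_tie_all_three_styles(instrument):
    styles, cat = resolve_coping({"P": 3, "E": 3, "D": 3}, _coping_rule(instrument))
    assert styles == {"P", "E", "D"} and cat is MINOR


def test_dominant_emotion_or_distraction_is_minor(instrument):
    for style in ("E", "D"):
        sums = {"P": 1, "E": 1, "D": 1}
        sums[style] = 5
        styles, cat = resolve_coping(sums, _coping_rule(instrument))
        assert styles == {style} and cat is MINOR


def test_unscorable_style_voids_coping(instrument):
    styles, cat = resolve_coping({"P": 6, "E": None, "D": 2}, _coping_rule(instrument))
    assert styles is None and cat is NS


def test_locus_dichotomy(instrument):
    rule = _locus_rule(instrument)
    assert resolve_locus(3, 1, rule) == ("internal", NONE)
    assert resolve_locus(0, 3, rule) == ("external", MINOR)
    assert resolve_locus(2, 2, rule) == ("internal", NONE)  # tie -> internal
    assert resolve_locus(None, 2, rule) == (None, NS)


def test_coping_dominance_exhaustive_oracle(instrument):
    """Dominance over all 7^3 sum triples matches a literal argmax rule."""
    rule = _coping_rule(instrument)
    for p, e, d in itertools.product(range(7), repeat=3):
        styles, cat = resolve_coping({"P": p, "E": e, "D": d}, rule)
        best = max(p, e, d)
        expected = {s for s, v in zip("PED", (p, e, d)) if v == best}
        assert styles == expected
        if len(expected) > 1:
            assert cat is MINOR
        else:
            assert cat is (NONE if expected == {"P"} else MINOR)


# ---------------------------------------------------------------------------
# profiles


def test_all_none_profile_has_zero_barriers(instrument):
    rec = complete_record(instrument, code_index=-1)  # top of every scale
    # top coping codes tie all three styles -> minor; use P-dominant instead
    rec.responses["cop_e_1"] = rec.responses["cop_e_2"] = 1
    rec.responses["cop_d_1"] = rec.responses["cop_d_2"] = 1
    rec.responses["loc_ext"] = 1
    rec.responses["ss_1"] = rec.responses["ss_2"] = 5
    rec.responses["dep_1"] = rec.responses["dep_2"] = rec.responses["dep_3"] = 1
    rec.responses["anx_1"] = rec.responses["anx_2"] = 1
    rec.responses["anx_3"] = rec.responses["anx_4"] = 1
    p = build_profile(rec, instrument)
    assert p.barrier_count == 0
    assert all(
        p.scores[u].category is NONE for u in instrument.barrier_units()
    )


def test_minor_plus_major_counts_two_barriers(instrument):
    rec = complete_record(instrument, code_index=-1)
    rec.responses.update(
        {
            "cop_e_1": 1, "cop_e_2": 1, "cop_d_1": 1, "cop_d_2": 1,
            "loc_ext": 1, "dep_1": 1, "dep_2": 1, "dep_3": 1,
            "anx_1": 1, "anx_2": 1, "anx_3": 1, "anx_4": 1,
        }
    )
    rec.responses.update({"se_1": 2, "se_2": 2})  # sum 2 -> minor
    rec.responses.update({"anx_1": 5, "anx_2": 5})  # sum 8 -> major (placeholder bands)
    p = build_profile(rec, instrument)
    assert p.scores["self_efficacy"].category is MINOR
    assert p.scores["anxiety"].category is MAJOR
    assert p.barrier_count == 2


def test_not_scorable_units_flagged_and_excluded_from_count(instrument):
    rec = complete_record(instrument, code_index=-1)
    del rec.responses["dep_1"]
    p = build_profile(rec, instrument)
    assert "depression" in p.not_scorable
    assert p.scores["depression"].category is NS


def test_guidance_items_recorded_never_counted(instrument):
    rec = complete_record(instrument, code_index=0)  # bottom of every scale
    p = build_profile(rec, instrument)
    assert set(p.guidance_flags) == {
        "computer_skills", "group_functioning", "self_monitoring_willingness"
    }
    assert p.barrier_count <= len(instrument.barrier_units())


def test_cohort_barrier_count_distribution_sums_to_cohort_size(
    instrument, scored_cohort
):
    from collections import Counter

    tally = Counter(p.barrier_count for p in scored_cohort)
    assert sum(tally.values()) == 204
    assert all(0 <= k <= 7 for k in tally)


# ---------------------------------------------------------------------------
# properties


@given(codes=st.lists(st.integers(1, 4), min_size=2, max_size=2))
def test_determinism(codes):
    inst = default_instrument()
    rec = ResponseRecord("r", {"se_1": codes[0], "se_2": codes[1]})
    a = score_construct(inst.constructs["self_efficacy"], rec)
    b = score_construct(inst.constructs["self_efficacy"], rec)
    assert a == b


@given(
    combo=st.lists(st.integers(1, 5), min_size=6, max_size=6),
    which=st.integers(0, 5),
)
def test_monotonicity_social_support(combo, which):
    """Raising any single social-support response never worsens the category."""
    inst = default_instrument()
    con = inst.constructs["social_support"]
    ids = [it.item_id for it in con.items]
    rank = {NONE: 0, MINOR: 1, MAJOR: 2}
    base = score_construct(con, ResponseRecord("r", dict(zip(ids, combo))))
    if combo[which] < 5:
        bumped = list(combo)
        bumped[which] += 1
        after = score_construct(con, ResponseRecord("r", dict(zip(ids, bumped))))
        assert rank[after.category] <= rank[base.category]


@given(perm=st.permutations(list(range(6))))
def test_sum_is_permutation_invariant(perm):
    inst = default_instrument()
    con = inst.constructs["social_support"]
    ids = [it.item_id for it in con.items]
    codes = [1, 2, 3, 4, 5, 4]
    direct = score_construct(con, ResponseRecord("r", dict(zip(ids, codes))))
    permuted = score_construct(
        con, ResponseRecord("r", {ids[i]: codes[perm[i]] for i in range(6)})
    )
    assert direct.sum_score == sum(
        {1: 0, 2: 0, 3: 0, 4: 1, 5: 2}[c] for c in codes
    )
    assert permuted.sum_score == direct.sum_score
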