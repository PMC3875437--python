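"""Behavior classification: change criterion, fold changes, position codes,
enhancement counts, allosteric response flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rheoscan as rs
from rheoscan.classify import (
    allosteric_change_flags,
    clamp_activities,
    enhancement_percent,
    profile_fold_changes,
)

from conftest import make_profile

measurement = st.tuples(
    st.floats(min_value=1e-3, max_value=1e4),
    st.floats(min_value=0.0, max_value=1e3),
)


class TestIsChanged:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            # ratio exactly 2 (not >2) and overlapping sd intervals
            (((0.12, 0.06)), ((0.06, 0.06)), False),
            # ratio ~21 and disjoint intervals
            (((15.0, 4.0)), ((0.7, 0.2)), True),
            # identical inputs
            (((5.0, 1.0)), ((5.0, 1.0)), False),
            # >2-fold but overlapping sds: no change
            (((10.0, 8.0)), ((4.0, 1.0)), False),
            # disjoint sds but ratio below 2: no change
            (((10.0, 0.5)), ((6.0, 0.5)), False),
        ],
    )
    def test_dual_criterion_cases(self, a, b, expected):
        assert rs.is_changed(a, b) is expected

    @given(a=measurement, b=measurement)
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_and_irreflexive(self, a, b):
        assert rs.is_changed(a, b) == rs.is_changed(b, a)
        assert rs.is_changed(a, a) is False


class TestFoldChange:
    def test_parent_vs_itself_is_one(self):
        fc = rs.fold_change((0.12, 0.06), (0.12, 0.06))
        assert fc.value == pytest.approx(1.0)
        assert not fc.changed

    @pytest.mark.parametrize(
        "parent, variant, expected",
        [((15.0, 4.0), (0.7, 0.2), 15.0 / 0.7),     # strong enhancement
         ((120.0, 16.0), (0.5, 0.1), 240.0)],       # ~240-fold enhancement
    )
    def test_enhancement_ratios(self, parent, variant, expected):
        fc = rs.fold_change(parent, variant)
        assert fc.value == pytest.approx(expected, rel=1e-6)
        assert fc.changed

    def test_at_min_against_del_control(self):
        fc = rs.fold_change((1.0, 0.1), (150.0, 20.0), del_control=200.0)
        assert fc.at_min  # within 2-fold of DEL
        fc2 = rs.fold_change((1.0, 0.1), (30.0, 3.0), del_control=200.0)
        assert not fc2.at_min

    def test_zero_activity_clamped_to_half_smallest_positive(self):
        vals = clamp_activities([0.0, 0.4, 2.0])
        assert vals == [0.2, 0.4, 2.0]


class TestClassifyPosition:
    def test_all_within_twofold_is_neutral(self):
        p = make_profile(1.0, 0.05, 200.0, [0.6, 0.8, 0.9, 1.1, 1.3, 1.8, 0.55, 1.9])
        assert rs.classify_position(p).code == "N"

    def test_progressive_span_over_two_decades_is_rheostat(self):
        p = make_profile(1.0, 0.0, 200.0, [0.1, 0.4, 1.5, 6.0, 25.0, 120.0])
        call = rs.classify_position(p)
        assert call.code == "R"
        assert call.span_log10 == pytest.approx(math.log10(1200), abs=1e-3)

    def test_biphasic_parent_and_min_is_toggle(self):
        p = make_profile(1.0, 0.05, 200.0,
                         [0.8, 0.9, 1.0, 1.2, 1.5, 150.0, 180.0, 200.0, 220.0, 190.0])
        assert rs.classify_position(p).code == "T"

    def test_three_tight_levels_is_three_state(self):
        p = make_profile(1.0, 0.0, 400.0,
                         [1.0, 1.1, 0.9, 20.0, 22.0, 18.0, 400.0, 390.0, 410.0])
        assert rs.classify_position(p).code == "3"

    def test_all_at_min_is_x(self):
        p = make_profile(1.0, 0.05, 200.0, [150.0, 190.0, 200.0, 240.0, 175.0])
        assert rs.classify_position(p).code == "x"

    def test_too_few_substitutions_is_hash_not_exception(self):
        p = make_profile(1.0, 0.05, 200.0, [0.5, 3.0, 9.0])
        assert rs.classify_position(p).code == "#"

    def test_within_fivefold_but_not_twofold_is_lowercase_n(self):
        p = make_profile(1.0, 0.0, 200.0, [0.25, 0.5, 0.9, 1.2, 3.0, 4.5])
        assert rs.classify_position(p).code == "n"

    def test_min_subset_plus_rheostat_is_hybrid(self):
        # five substitutions abolish repression, five span ~3 decades
        acts = [0.05, 0.3, 2.0, 10.0, 45.0, 3900.0, 4000.0, 4100.0, 3950.0, 4050.0]
        p = make_profile(1.0, 0.0, 4000.0, acts)
        assert rs.classify_position(p).code in ("R+T", "r+T")

    def test_reordering_measurements_never_changes_the_call(self, clean_dataset):
        _, variants, _, contexts = clean_dataset
        rng = np.random.default_rng(0)
        shuffled = variants.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = rs.classify_dataset(variants, contexts).sort_values(
            ["homolog", "position"]).reset_index(drop=True)
        b = rs.classify_dataset(shuffled, contexts).sort_values(
            ["homolog", "position"]).reset_index(drop=True)
        assert (a["code"] == b["code"]).all()

    @pytest.mark.parametrize("factor", [0.01, 0.5, 3.0, 250.0])
    def test_common_rescaling_leaves_call_unchanged(self, factor):
        base = [0.1, 0.4, 1.5, 6.0, 25.0, 120.0]
        p1 = make_profile(1.0, 0.02, 200.0, base)
        p2 = make_profile(1.0 * factor, 0.02 * factor, 200.0 * factor,
                          [a * factor for a in base])
        assert rs.classify_position(p1).code == rs.classify_position(p2).code

    def test_excluded_variants_do_not_count(self):
        p = make_profile(1.0, 0.05, 200.0, [0.9, 1.0, 1.1, 0.8])
        # four scored variants: below the minimum of five
        assert rs.classify_position(p).code == "#"


class TestEnhancement:
    @pytest.mark.parametrize(
        "enhanced, total, parents, expected",
        [(21, 126, 13, 19), (0, 96, 14, 0), (10, 100, 13, 11), (2, 92, 14, 3)],
    )
    def test_percent_formula_with_half_up_rounding(self, enhanced, total,
                                                   parents, expected):
        assert enhancement_percent(enhanced, total, parents) == expected

    def test_degenerate_denominator_reported_missing(self):
        assert enhancement_percent(0, 5, 5) is None

    def test_table_matches_brute_force_count(self, noisy_dataset):
        _, variants, _, contexts = noisy_dataset
        table = rs.enhancement_table(variants, contexts)
        # independent recount with plain loops
        for _, row in table.iterrows():
            pos = row["position"]
            enhanced = 0
            n_subs = 0
            parents = set()
            for hom, ctx in contexts.items():
                sub = variants[
                    (variants["homolog"] == hom)
                    & (variants["position"] == pos)
                    & (variants["condition"] == ctx.active_condition)
                    & (~variants["excluded"])
                ]
                if len(sub) == 0:
                    continue
                parents.add(hom)
                for _, v in sub.iterrows():
                    n_subs += 1
                    if ctx.parent_activity / max(v["mean_miller"], 1e-12) > 10:
                        enhanced += 1
            assert row["total_variants"] == n_subs + len(parents)
            assert row["enhanced"] == enhanced
            assert row["parents_mutated"] == len(parents)
            expected_pct = math.floor(100 * enhanced / (n_subs) + 0.5)
            assert row["pct_enhanced"] == expected_pct


class TestAllostery:
    def test_variant_scaled_like_parent_not_flagged(self, clean_dataset):
        _, variants, truth, contexts = clean_dataset
        flags = allosteric_change_flags(variants, contexts)
        merged = flags.merge(truth, on=["homolog", "position", "sub_aa"])
        normal = merged[~merged["altered_allostery_y"]]
        assert not normal["altered_allostery_x"].astype(bool).any()

    def test_planted_variants_recovered_exactly_at_zero_noise(self, clean_dataset):
        _, variants, truth, contexts = clean_dataset
        flags = allosteric_change_flags(variants, contexts)
        merged = flags.merge(truth, on=["homolog", "position", "sub_aa"])
        assert (
            merged["altered_allostery_x"].astype(bool)
            == merged["altered_allostery_y"]
        ).all()
        assert merged["altered_allostery_y"].sum() == 30

    def test_missing_condition_gives_undetermined(self, clean_dataset):
        _, variants, _, contexts = clean_dataset
        one_condition = variants[variants["condition"] == rs.MINUS]
        flags = allosteric_change_flags(one_condition, contexts)
        # homologs read out in the minus condition lack their plus data
        minus_homs = [h for h, c in contexts.items() if c.active_condition == rs.MINUS]
        sub = flags[flags["homolog"].isin(minus_homs)]
        assert sub["altered_allostery"].isna().all()
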