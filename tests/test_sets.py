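import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonself.model import ExpressionRecord, ResponseSet, ValidationError
from nonself.sets import (
    build_response_set,
    fc_concordance,
    fisher_exact_2x2,
    magnitude_bias,
    overlap_test,
    pool_conditions,
    specific_fraction,
    threshold_profile_overlap,
    venn,
)
from oracles import fisher_two_tail, venn_regions


def _rec(gid, lfc, p, cond="VsSf2h"):
    return ExpressionRecord(gid, cond, lfc, p)


def _rs(members, direction="up", label="s"):
    return ResponseSet(label, direction, 2.0, 0.01, frozenset(members))


class TestBuildResponseSet:
    def test_strict_inequalities_exclude_boundary(self):
        recs = [_rec("g1", 2.0, 0.001), _rec("g2", 2.0001, 0.001),
                _rec("g3", 2.5, 0.01)]
        up = build_response_set(recs, "up", 2.0, 0.01)
        assert up.members == {"g2"}

    def test_hand_evaluated_toy_table(self):
        recs = [_rec("a", 3, 0.001), _rec("b", -3, 0.001),
                _rec("c", 1, 0.001), _rec("d", 4, 0.001),
                _rec("e", 5, 0.5), _rec("f", -5, 0.5)]
        up = build_response_set(recs, "up", 2.0, 0.01)
        down = build_response_set(recs, "down", 2.0, 0.01)
        assert up.members == {"a", "d"} and down.members == {"b"}

    def test_zero_max_p_gives_empty_sets(self):
        recs = [_rec("a", 9, 0.0001)]
        assert len(build_response_set(recs, "up", 2.0, 0.0)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            build_response_set([], "up", -1.0, 0.01)

    def test_up_and_down_disjoint(self, small_expression):
        tables, _ = small_expression
        up = build_response_set(tables["VI"], "up", 2.0, 0.01)
        down = build_response_set(tables["VI"], "down", 2.0, 0.01)
        assert not up.members & down.members


class TestPooling:
    def test_disjoint_union_size(self):
        pooled = pool_conditions(_rs("abc"), _rs("defg"))
        assert len(pooled) == 7

    def test_idempotent_on_identical_sets(self):
        s = _rs("abc")
        assert pool_conditions(s, s).members == s.members

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValidationError):
            pool_conditions(_rs("a"), _rs("b", direction="down"))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_inclusion_exclusion(self, a, b):
        sa, sb = _rs(map(str, a)), _rs(map(str, b))
        pooled = pool_conditions(sa, sb)
        assert len(pooled) == len(sa) + len(sb) - len(sa.members & sb.members)


class TestVenn:
    def test_disjoint_sets_have_empty_intersections(self):
        v = venn([_rs("ab"), _rs("cd"), _rs("ef")])
        assert v.count(True, True, False) == 0
        assert v.count(True, True, True) == 0
        assert v.union_size() == 6

    def test_nested_sets_populate_nested_regions_only(self):
        v = venn([_rs("a"), _rs("ab"), _rs("abc")])
        assert v.count(True, True, True) == 1
        assert v.count(False, True, True) == 1
        assert v.count(False, False, True) == 1
        assert v.count(True, False, False) == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle_and_reconstructs_sizes(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(100)]
        raw = [set(rng.choice(universe, rng.integers(0, 60), replace=False))
               for _ in range(3)]
        v = venn([_rs(s) for s in raw])
        assert v.region_counts == {
            k: n for k, n in {**{k: 0 for k in v.region_counts},
                              **venn_regions(raw)}.items()
        }
        for i in range(3):
            assert v.set_size(i) == len(raw[i])

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ValidationError):
            venn([_rs("a")] * 4)


class TestSpecificFraction:
    def test_printed_style_percentages(self):
        b = _rs({f"s{i}" for i in range(1462)})
        a = _rs({f"s{i}" for i in range(1462)} | {f"x{i}" for i in range(153)})
        assert round(specific_fraction(a, b), 1) == 9.5

    def test_identical_sets_give_zero(self):
        s = _rs("abc")
        assert specific_fraction(s, s) == 0.0

    def test_empty_reference_flagged_nan(self):
        assert math.isnan(specific_fraction(_rs(""), _rs("a")))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.sets(st.integers(0, 40), min_size=1), st.sets(st.integers(0, 40)))
    def test_complement_identity(self, a, b):
        sa, sb = _rs(map(str, a)), _rs(map(str, b))
        shared_pct = 100 * len(sa.members & sb.members) / len(sa)
        assert specific_fraction(sa, sb) + shared_pct == pytest.approx(100.0)


class TestOverlapTest:
    def test_identical_sets_reach_extreme_fold(self):
        s = _rs({f"g{i}" for i in range(10)})
        r = overlap_test(s, s, universe_size=100)
        assert r.fold == pytest.approx(10.0)
        assert r.p_two_tail < 1e-10

    def test_exact_p_matches_enumeration_oracle(self):
        r = overlap_test(
            _rs({f"a{i}" for i in range(30)} | {f"c{i}" for i in range(20)}),
            _rs({f"b{i}" for i in range(10)} | {f"c{i}" for i in range(20)}),
            universe_size=1000,
        )
        assert (r.a, r.b, r.c, r.d) == (20, 30, 10, 940)
        assert r.p_two_tail == pytest.approx(fisher_two_tail(20, 30, 10, 940),
                                             rel=1e-8)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValidationError):
            overlap_test(_rs("abc"), _rs("def"), universe_size=4)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fold_invariant_under_swapping_sets(self, seed):
        rng = np.random.default_rng(seed)
        uni = [f"g{i}" for i in range(200)]
        a = _rs(rng.choice(uni, 50, replace=False))
        b = _rs(rng.choice(uni, 80, replace=False))
        r1, r2 = overlap_test(a, b, 200), overlap_test(b, a, 200)
        assert r1.fold == pytest.approx(r2.fold)
        assert r1.p_two_tail == pytest.approx(r2.p_two_tail)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_fisher_p_invariant_under_table_symmetries(self, table):
        a, b, c, d = table
        base = fisher_exact_2x2(a, b, c, d)
        for t in [(c, d, a, b), (b, a, d, c), (a, c, b, d), (d, c, b, a)]:
            assert fisher_exact_2x2(*t) == pytest.approx(base, rel=1e-9)

    def test_chi_square_variant_agrees_in_direction(self):
        s = _rs({f"g{i}" for i in range(40)})
        t = _rs({f"g{i}" for i in range(20, 60)})
        pf = overlap_test(s, t, 500, method="fisher_exact").p_two_tail
        pc = overlap_test(s, t, 500, method="chi_square").p_two_tail
        assert pf < 0.01 and pc < 0.01


class TestMagnitudeBias:
    def test_identical_tables_all_tied(self):
        recs = [_rec("a", 3, 0.001), _rec("b", -4, 0.001)]
        mb = magnitude_bias(recs, list(recs), {"a", "b"})
        assert mb.n_tied == 2 and mb.test.p_two_tail == 1.0

    def test_three_genes_all_greater_in_a(self):
        ra = [_rec("a", 5, 0.001), _rec("b", 6, 0.001), _rec("c", -7, 0.001)]
        rb = [_rec("a", 4, 0.001), _rec("b", 5, 0.001), _rec("c", -6, 0.001)]
        mb = magnitude_bias(ra, rb, {"a", "b", "c"})
        assert mb.n_greater_in_a == 3
        assert mb.test.p_two_tail == pytest.approx(0.25)  # 2 * (1/2)^3

    def test_generated_ratio_detected_at_500_genes(self):
        rng = np.random.default_rng(5)
        base = 2.0 + rng.exponential(1.5, 500)
        ra = [_rec(f"g{i}", float(b * 1.5), 0.001) for i, b in enumerate(base)]
        rb = [_rec(f"g{i}", float(b + rng.normal(0, 0.2)), 0.001)
              for i, b in enumerate(base)]
        mb = magnitude_bias(ra, rb, {f"g{i}" for i in range(500)})
        assert mb.n_greater_in_a > mb.n_greater_in_b
        assert mb.test.p_two_tail < 0.01

    def test_empty_shared_rejected(self):
        with pytest.raises(ValidationError):
            magnitude_bias([], [], set())


class TestConcordance:
    def test_self_correlation_is_one(self):
        recs = [_rec(f"g{i}", float(i), 0.5) for i in range(5)]
        assert fc_concordance(recs, list(recs), {r.gene_id for r in recs}) \
            == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self):
        ra = [_rec(f"g{i}", float(i + 1), 0.5) for i in range(5)]
        rb = [_rec(f"g{i}", float(-(i + 1)), 0.5) for i in range(5)]
        assert fc_concordance(ra, rb, {f"g{i}" for i in range(5)}) \
            == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [2.0, 1.0, 5.0, 4.0, 8.0]
        ra = [_rec(f"g{i}", v, 0.5) for i, v in enumerate(x)]
        rb = [_rec(f"g{i}", v, 0.5) for i, v in enumerate(y)]
        mx, my = sum(x) / 5, sum(y) / 5
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x)
                        * sum((b - my) ** 2 for b in y))
        assert fc_concordance(ra, rb, {f"g{i}" for i in range(5)},
                              method="pearson") == pytest.approx(num / den)

    def test_zero_variance_flagged(self):
        ra = [_rec(f"g{i}", 2.0, 0.5) for i in range(3)]
        rb = [_rec(f"g{i}", float(i), 0.5) for i in range(3)]
        assert math.isnan(fc_concordance(ra, rb, {"g0", "g1", "g2"}))


class TestThresholdProfile:
    def test_reference_equal_to_universe_gives_100_percent(self):
        recs = [_rec(f"g{i}", 3.0 + i, 0.001) for i in range(10)]
        ref = {"up": _rs({f"g{i}" for i in range(10)}),
               "down": _rs(set(), direction="down")}
        df = threshold_profile_overlap({"c": recs}, [2.0], ref, 1000, 0.01)
        up = df[(df.direction == "up")]
        assert (up.overlap_pct == 100.0).all()

    def test_threshold_above_max_flags_empty(self):
        recs = [_rec("g1", 3.0, 0.001)]
        ref = {"up": _rs({"g1"}), "down": _rs(set(), direction="down")}
        df = threshold_profile_overlap({"c": recs}, [50.0], ref, 100, 0.01)
        assert df.is_empty.all()
        assert df.overlap_pct.isna().all()

    def test_overlap_decays_with_threshold_on_generated_data(
        self, full_expression
    ):
        tables, truth = full_expression
        ref = {
            "up": _rs(truth.pools["VI_up"]),
            "down": _rs(truth.pools["VI_down"], direction="down"),
        }
        # strongest record per gene across the two time points
        best = {}
        for r in tables["VsSf2h"] + tables["VsSf6h"]:
            if r.gene_id not in best or abs(r.log2fc) > abs(best[r.gene_id].log2fc):
                best[r.gene_id] = r
        df = threshold_profile_overlap({"VsSf": list(best.values())},
                                       [2.0, 3.0, 4.0, 5.0], ref,
                                       10635, 0.01)
        up = df[df.direction == "up"].sort_values("threshold")
        assert up.overlap_pct.is_monotonic_decreasing
        assert up.overlap_pct.iloc[0] - up.overlap_pct.iloc[-1] > 10
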