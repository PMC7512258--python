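import numpy as np
import pytest
from hypothesis import given, strategies as st

from sampen import TimeSeries
from sampen.bruteforce import count_matches_bruteforce
from sampen.bucket import build_buckets, count_matches_bucket, integrate_series

from helpers import ar1_series, oracle_counts, oracle_pairs


class TestIntegrateSeries:
    @pytest.mark.parametrize(
        "m, expected",
        [(2, [3.0, 3.0, 3.0, 3.0]), (1, [1.0, 2.0, 1.0, 2.0, 1.0])],
    )
    def test_window_sums(self, toy_series, m, expected):
        assert integrate_series(toy_series, m).tolist() == expected

    def test_constant_series(self):
        X = integrate_series(TimeSeries([4.0] * 7), 3)
        assert (X == 12.0).all()


class TestBuildBuckets:
    def test_toy_m1_assignment(self, toy_series):
        grid = build_buckets(
            integrate_series(toy_series, 1), toy_series, r_abs=0.5, rsplit=1
        )
        # normalized X' = [1,2,1,2,1]; width 0.5 -> bucket ids ceil(X'/0.5)
        assert grid.n_buckets == 4
        assert set(grid.members_of(2)) == {0, 2, 4}
        assert set(grid.members_of(4)) == {1, 3}
        assert grid.members_of(1).size == 0

    def test_toy_m2_sorted_by_first_element(self, toy_series):
        # only the N - m counted template starts are integrated and bucketed
        X = integrate_series(toy_series, 2)
        assert X.shape == (4,)
        grid = build_buckets(X, toy_series, r_abs=0.5, rsplit=1)
        # bucket 2 holds templates 0..3; first elements 1,2,1,2 -> order 0,2,1,3
        assert grid.members_of(2).tolist() == [0, 2, 1, 3]

    def test_split_factor_shrinks_width(self, toy_series):
        X = integrate_series(toy_series, 1)
        g1 = build_buckets(X, toy_series, 0.5, 1)
        g5 = build_buckets(X, toy_series, 0.5, 5)
        assert g5.width == pytest.approx(g1.width / 5)
        assert g5.n_buckets > g1.n_buckets
        assert g5.span == 1 * 5 + 1

    def test_every_template_in_exactly_one_bucket(self, rng):
        s = TimeSeries(rng.standard_normal(200))
        grid = build_buckets(integrate_series(s, 2), s, 0.3, 5)
        all_members = np.concatenate(list(grid.buckets().values()))
        assert sorted(all_members.tolist()) == list(range(198))

    def test_within_bucket_first_elements_nondecreasing(self, rng):
        s = TimeSeries(rng.integers(0, 4, 150).astype(float))
        grid = build_buckets(integrate_series(s, 2), s, 0.5, 2)
        for members in grid.buckets().values():
            firsts = s.values[np.asarray(members)]
            assert (np.diff(firsts) >= 0).all()


class TestCounting:
    @pytest.mark.parametrize("m, r, expected", [(1, 0.5, (4, 2)), (2, 0.5, (2, 1))])
    def test_worked_example(self, toy_series, m, r, expected):
        mc = count_matches_bucket(toy_series, m, r, rsplit=1)
        assert (mc.b_pairs, mc.a_pairs) == expected

    @pytest.mark.parametrize("rsplit", [1, 2, 5, 15])
    def test_counts_invariant_in_rsplit(self, rng, rsplit):
        x = ar1_series(rng, 2000, phi=0.9)
        s = TimeSeries(x)
        r = 0.2 * s.sample_sd()
        expected = count_matches_bruteforce(s, 2, r)
        mc = count_matches_bucket(s, 2, r, rsplit)
        assert (mc.b_pairs, mc.a_pairs) == (expected.b_pairs, expected.a_pairs)

    def test_similar_pairs_stay_within_neighbour_span(self, rng):
        """Any m-similar pair lands within m*rsplit (+1 guard) buckets."""
        for m, rsplit in [(1, 1), (2, 5), (3, 2)]:
            x = rng.standard_normal(150)
            s = TimeSeries(x)
            r = 0.3
            grid = build_buckets(integrate_series(s, m), s, r, rsplit)
            for i, j in oracle_pairs(x, m, r):
                assert abs(grid.bucket_ids[i] - grid.bucket_ids[j]) <= m * rsplit + 1

    def test_prunes_comparisons_on_long_gaussian_series(self, rng):
        s = TimeSeries(rng.standard_normal(1000))
        r = 0.2 * s.sample_sd()
        brute = count_matches_bruteforce(s, 2, r)
        pruned = count_matches_bucket(s, 2, r, 5)
        assert pruned.element_comparisons < brute.element_comparisons
        assert (pruned.b_pairs, pruned.a_pairs) == (brute.b_pairs, brute.a_pairs)


@given(
    values=st.lists(
        st.floats(min_value=-20, max_value=20, allow_nan=False), min_size=6, max_size=40
    ),
    m=st.integers(1, 3),
    r=st.floats(min_value=0.05, max_value=3.0),
    rsplit=st.sampled_from([1, 2, 5, 15]),
)
def test_matches_pure_python_enumeration(values, m, r, rsplit):
    if len(values) < m + 2:
        values = values + [0.0] * (m + 2 - len(values))
    mc = count_matches_bucket(TimeSeries(np.array(values)), m, r, rsplit)
    assert (mc.b_pairs, mc.a_pairs) == oracle_counts(values, m, r)
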