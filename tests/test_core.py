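import math

import numpy as np
import pytest

from sampen import (
    MatchCounts,
    SampEnParams,
    TimeSeries,
    compute_sampen,
    resolve_tolerance,
    sampen_from_counts,
    sample_entropy,
    templates_similar,
)


class TestTimeSeries:
    def test_coercion_and_length(self):
        s = TimeSeries([1, 2, 3])
        assert s.n == 3
        assert s.values.dtype == np.float64

    @pytest.mark.parametrize("bad", [[], [1.0, float("nan")], [[1.0, 2.0]]])
    def test_rejects_invalid_values(self, bad):
        with pytest.raises(ValueError):
            TimeSeries(np.array(bad))

    def test_sample_sd_uses_n_minus_one_denominator(self):
        assert TimeSeries([-10.0, 0.0, 10.0]).sample_sd() == pytest.approx(10.0)


class TestResolveTolerance:
    def test_absolute_mode_is_identity(self):
        s = TimeSeries([1.0, 5.0, 9.0])
        assert resolve_tolerance(s, 3.5, "absolute") == 3.5

    def test_sd_fraction_scales_by_sample_sd(self):
        s = TimeSeries([-10.0, 0.0, 10.0])  # sample SD exactly 10
        assert resolve_tolerance(s, 0.2, "sd_fraction") == pytest.approx(2.0)

    def test_constant_series_in_sd_mode_raises(self):
        with pytest.raises(ValueError, match="constant"):
            resolve_tolerance(TimeSeries([5.0] * 6), 0.2, "sd_fraction")

    @pytest.mark.parametrize("r", [0.0, -1.0])
    def test_nonpositive_tolerance_raises(self, r):
        with pytest.raises(ValueError):
            resolve_tolerance(TimeSeries([1.0, 2.0]), r, "absolute")


class TestTemplatesSimilar:
    def test_matching_windows(self, toy_series):
        assert templates_similar(toy_series, 0, 2, m=2, r_abs=0.5)

    def test_failing_first_coordinate(self, toy_series):
        assert not templates_similar(toy_series, 0, 1, m=2, r_abs=0.5)

    def test_identical_windows_always_similar(self, toy_series):
        assert templates_similar(toy_series, 0, 4, m=1, r_abs=1e-12)

    def test_out_of_range_raises(self, toy_series):
        with pytest.raises(IndexError):
            templates_similar(toy_series, 0, 5, m=2, r_abs=0.5)

    def test_self_comparison_rejected(self, toy_series):
        with pytest.raises(ValueError):
            templates_similar(toy_series, 1, 1, m=2, r_abs=0.5)


class TestSampenFromCounts:
    def test_worked_example_value_and_norms(self):
        res = sampen_from_counts(MatchCounts(b_pairs=4, a_pairs=2), n=6, m=1)
        assert res.value == pytest.approx(math.log(2), abs=1e-12)
        assert res.b_norm == pytest.approx(4 / 25)
        assert res.a_norm == pytest.approx(2 / 25)
        assert res.degenerate_flag == "none"

    def test_all_pairs_match_gives_zero(self):
        res = sampen_from_counts(MatchCounts(b_pairs=6, a_pairs=6), n=6, m=2)
        assert res.value == 0.0

    def test_zero_counts_give_infinity_with_flags(self):
        res = sampen_from_counts(MatchCounts(b_pairs=0, a_pairs=0), n=6, m=1)
        assert math.isinf(res.value)
        assert "a_zero" in res.degenerate_flag
        assert "b_zero" in res.degenerate_flag

    def test_a_zero_only(self):
        res = sampen_from_counts(MatchCounts(b_pairs=3, a_pairs=0), n=8, m=1)
        assert math.isinf(res.value)
        assert res.degenerate_flag == "a_zero"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchCounts(b_pairs=1, a_pairs=2)


class TestComputeSampen:
    def test_unknown_backend_raises(self, toy_series):
        params = SampEnParams.create(toy_series, 1, 0.5, "absolute")
        with pytest.raises(ValueError, match="unknown backend"):
            compute_sampen(toy_series, params, algorithm="quadtree")

    def test_series_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy([1.0, 2.0, 3.0], m=2, r=1.0, r_mode="absolute")

    def test_auto_resolves_to_a_named_backend(self, toy_series):
        res = sample_entropy(toy_series, m=1, r=0.5, r_mode="absolute")
        assert res.algorithm == "lightweight"  # m=1 policy
        assert res.value == pytest.approx(math.log(2))

    @pytest.mark.parametrize(
        "kwargs", [{"m": 0}, {"r": -0.1}, {"rsplit": 0}]
    )
    def test_invalid_parameters_raise(self, toy_series, kwargs):
        full = dict(m=2, r=0.5, r_mode="absolute", rsplit=5)
        full.update(kwargs)
        with pytest.raises(ValueError):
            sample_entropy(toy_series, **full)

    def test_value_is_log_ratio_of_counts(self, rng):
        res = sample_entropy(rng.standard_normal(200), m=2, r=0.2, algorithm="bruteforce")
        assert res.value == pytest.approx(
            math.log(res.counts.b_pairs / res.counts.a_pairs), abs=0
        )
        assert res.value >= 0.0
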