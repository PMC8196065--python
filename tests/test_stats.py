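"""Unit and property tests for the condensation moment statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from droptubes import stats as cs


def g1_direct(x):
    """Literal bias-corrected skewness formula, independent of the package."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = x.std(ddof=1)
    m3 = ((x - x.mean()) ** 3).mean()
    return n**2 / ((n - 1) * (n - 2)) * m3 / s**3


def g2_direct(x):
    """Literal bias-corrected excess kurtosis formula."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m2 = ((x - x.mean()) ** 2).mean()
    m4 = ((x - x.mean()) ** 4).mean()
    g2 = m4 / m2**2 - 3.0
    return ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))


class TestMomentEstimators:
    def test_symmetric_sample_has_zero_skewness(self):
        assert cs.sample_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_matches_direct_formula(self):
        assert cs.sample_skewness([0, 0, 0, 1]) == pytest.approx(
            g1_direct([0, 0, 0, 1]), abs=1e-14
        )
        assert cs.sample_excess_kurtosis([0, 0, 1, 1, 5]) == pytest.approx(
            g2_direct([0, 0, 1, 1, 5]), abs=1e-14
        )

    def test_oracle_equivalence_on_seeded_random_samples(self):
        """G1/G2 agree with the direct formula and scipy on 1000 random lists."""
        rng = np.random.default_rng(123)
        worst_s = worst_k = 0.0
        for _ in range(1000):
            n = int(rng.integers(5, 200))
            x = rng.gamma(rng.uniform(0.5, 5), 10, size=n)
            s = cs.sample_skewness(x)
            k = cs.sample_excess_kurtosis(x)
            worst_s = max(worst_s, abs(s - g1_direct(x)), abs(s - sps.skew(x, bias=False)))
            worst_k = max(
                worst_k, abs(k - g2_direct(x)), abs(k - sps.kurtosis(x, bias=False))
            )
        assert worst_s <= 1e-12
        assert worst_k <= 1e-12

    @pytest.mark.parametrize(
        "case, draw, statistic, expected, two_se",
        [
            (1, "exponential", cs.sample_skewness, 2.0, 0.016),
            (2, "uniform", cs.sample_excess_kurtosis, -1.2, 0.0021),
            (3, "normal", cs.sample_skewness, 0.0, 0.0046),
            (4, "normal", cs.sample_excess_kurtosis, 0.0, 0.0097),
        ],
    )
    def test_analytic_limits_at_large_n(self, case, draw, statistic, expected, two_se):
        """Estimators hit the analytic distribution values within 2 SE at n=1e6.

        Tolerances are 2 Monte-Carlo standard errors of each estimator at
        this sample size; each case draws from an independent substream.
        """
        rng = np.random.default_rng([42, case])
        x = getattr(rng, draw)(size=1_000_000)
        assert statistic(x) == pytest.approx(expected, abs=two_se)

    @given(
        data=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=8, max_size=100),
        a=st.floats(1e-3, 1e3),
        b=st.floats(-1e4, 1e4),
    )
    @settings(derandomize=True, max_examples=200)
    def test_affine_invariance(self, data, a, b):
        """Skewness/kurtosis are exposure-agnostic: invariant under v -> a v + b."""
        x = np.asarray(data)
        if x.std(ddof=1) < 1e-6:
            return
        s0, k0 = cs.sample_skewness(x), cs.sample_excess_kurtosis(x)
        s1, k1 = cs.sample_skewness(a * x + b), cs.sample_excess_kurtosis(a * x + b)
        assert s1 == pytest.approx(s0, rel=1e-9, abs=1e-9)
        assert k1 == pytest.approx(k0, rel=1e-9, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            cs.sample_skewness([1.0, 2.0])
        with pytest.raises(ValueError):
            cs.sample_skewness([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            cs.sample_excess_kurtosis([1.0, 2.0, 3.0])


class TestUniqueValueReduction:
    def test_forced_example(self):
        assert cs.unique_value_reduction([5, 5, 5, 7], 1.0).tolist() == [5.0, 7.0]

    def test_identical_values_collapse_to_one(self):
        assert cs.unique_value_reduction([9, 9, 9], 1.0).tolist() == [9.0]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cs.unique_value_reduction([], 1.0)

    @given(
        data=st.lists(st.integers(0, 5000), min_size=1, max_size=300),
        w=st.sampled_from([1.0, 2.0, 5.0, 0.5]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_binning(self, data, w):
        """Equals the set of left edges of occupied histogram bins."""
        x = np.asarray(data, dtype=float)
        lo = x.min()
        expected = sorted({lo + np.floor((v - lo) / w) * w for v in x})
        got = cs.unique_value_reduction(x, w).tolist()
        assert got == pytest.approx(expected)


class _Droplet:
    def __init__(self, values, frame=0):
        self.pixel_values = np.asarray(values)
        self.frame_index = frame


class TestSummariesAndAggregation:
    def test_constant_droplet_excluded_with_reason(self):
        s = cs.summarize_droplet(_Droplet([7] * 60), mode="pixels")
        assert not s.valid
        assert s.excluded_reason == "zero variance"

    def test_mode_is_recorded_and_modes_differ(self):
        values = [0] * 96 + [10, 20, 30, 40]
        sp = cs.summarize_droplet(_Droplet(values), mode="pixels")
        su = cs.summarize_droplet(_Droplet(values), mode="unique")
        assert sp.mode == "pixels" and su.mode == "unique"
        # the unique reduction discards occupancy, so the two diverge
        assert abs(sp.skewness - su.skewness) > 0.5

    def test_aggregate_two_droplet_arithmetic(self):
        sums = [
            cs.MomentSummary(0, 0, 100, 1, 1, 0.5, 0.1, "pixels"),
            cs.MomentSummary(1, 0, 100, 1, 1, 1.5, 0.3, "pixels"),
        ]
        p = cs.aggregate_population(sums, time_min=10.0)
        assert p.mean_skewness == pytest.approx(1.0)
        assert p.sd_skewness == pytest.approx(0.70710678, abs=1e-6)
        assert p.n_droplets == 2

    def test_single_droplet_sd_reported_as_zero_and_flagged(self):
        p = cs.aggregate_population(
            [cs.MomentSummary(0, 0, 100, 1, 1, 0.7, 0.2, "pixels")], 0.0
        )
        assert p.mean_skewness == pytest.approx(0.7)
        assert p.sd_skewness == 0.0
        assert p.single_droplet

    def test_aggregate_matches_brute_force_on_seeded_summaries(self):
        rng = np.random.default_rng(5)
        sk = rng.normal(1, 0.5, 100)
        ku = rng.normal(2, 1.0, 100)
        sums = [
            cs.MomentSummary(i, 0, 100, 1, 1, s, k, "pixels")
            for i, (s, k) in enumerate(zip(sk, ku))
        ]
        p = cs.aggregate_population(sums, 0.0)
        assert p.mean_skewness == pytest.approx(sk.mean(), abs=1e-12)
        assert p.sd_kurtosis == pytest.approx(ku.std(ddof=1), abs=1e-12)

    def test_zero_valid_droplets_raise_naming_frame(self):
        s = cs.summarize_droplet(_Droplet([7] * 60, frame=3), mode="pixels")
        with pytest.raises(ValueError, match="frame 3"):
            cs.aggregate_population([s], 42.0)

    def test_timecourse_sorted_and_duplicates_rejected(self):
        mk = lambda t: (t, [cs.MomentSummary(0, 0, 100, 1, 1, t / 10, 0.0, "pixels")])
        tc = cs.build_timecourse([mk(30.0), mk(10.0), mk(20.0)])
        assert [p.time_min for p in tc.points] == [10.0, 20.0, 30.0]
        with pytest.raises(ValueError, match="duplicate"):
            cs.build_timecourse([mk(10.0), mk(10.0)])
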