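import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acoustolev.device import ValidationError
from acoustolev.stats import (DegenerateFitError, PopulationStats,
                              central_interval_width, circularity,
                              empirical_fraction_within_slab, fit_gaussian,
                              fraction_within_slab, group_report,
                              ks_two_sample, misalignment)
from acoustolev.synth import generate_preset


def brute_force_ks(x, y):
    """sup |ECDF_x - ECDF_y| by direct enumeration at every data point."""
    pts = np.concatenate([x, y])
    return max(
        abs(np.mean(np.asarray(x) <= t) - np.mean(np.asarray(y) <= t))
        for t in pts
    )


class TestFitGaussian:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(100)
        data = rng.normal(510, 50, 285)
        fit = fit_gaussian(data)
        assert abs(fit.mean - 510) < 3 * 50 / np.sqrt(285)
        assert abs(fit.sd - 50) < 3 * 50 / np.sqrt(2 * 285)
        assert fit.goodness < 0.1

    def test_shift_equivariance(self):
        rng = np.random.default_rng(101)
        data = rng.normal(0, 20, 64)
        f0 = fit_gaussian(data)
        f1 = fit_gaussian(data + 100)
        assert f1.mean == pytest.approx(f0.mean + 100)
        assert f1.sd == pytest.approx(f0.sd)

    def test_two_point_sample_hand_computed(self):
        fit = fit_gaussian([0.0, 2.0], min_n=2)
        assert fit.mean == pytest.approx(1.0)
        assert fit.sd == pytest.approx(np.sqrt(2))   # n-1 convention

    def test_constant_data_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gaussian([5.0] * 20)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            fit_gaussian([1.0, 2.0, 3.0])

    def test_parameter_recovery_bias_below_5_percent(self):
        """Mean absolute bias over replicates < 5% of sigma at n = 200."""
        rng = np.random.default_rng(102)
        sds = [fit_gaussian(rng.normal(500, 60, 200)).sd for _ in range(100)]
        assert abs(np.mean(sds) - 60) < 0.05 * 60


class TestSlabMetrics:
    def test_sedimented_slab_thickness_220(self):
        """sigma = 105 um -> central-70% slab 217.6 um, i.e. 220 reported."""
        w = central_interval_width(105, 0.70)
        assert w == pytest.approx(2 * 1.0364 * 105, abs=0.1)
        assert round(w, -1) == 220

    def test_levitated_slab_thickness(self):
        assert central_interval_width(50, 0.70) == pytest.approx(103.64,
                                                                 abs=0.05)

    def test_zero_coverage_limit(self):
        assert central_interval_width(50, 1e-12) == pytest.approx(0.0,
                                                                  abs=1e-6)

    def test_coverage_validation(self):
        with pytest.raises(ValidationError):
            central_interval_width(50, 1.2)

    @pytest.mark.parametrize("mu,sd,t,frac", [
        (510, 50, 150, 0.8664),    # 2*Phi(1.5) - 1
        (500, 80, 150, 0.6514),    # 2*Phi(0.9375) - 1
    ])
    def test_fraction_within_slab_values(self, mu, sd, t, frac):
        assert fraction_within_slab(mu, sd, t) == pytest.approx(frac,
                                                                abs=2e-4)

    def test_fraction_limits(self):
        assert fraction_within_slab(0, 50, 1e9) == pytest.approx(1.0)
        assert fraction_within_slab(0, 0, 10) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(sd=st.floats(1.0, 500.0), coverage=st.floats(0.01, 0.99))
    def test_width_and_fraction_are_inverses(self, sd, coverage):
        w = central_interval_width(sd, coverage)
        assert fraction_within_slab(0.0, sd, w) == pytest.approx(coverage,
                                                                 abs=1e-9)

    def test_empirical_sliding_window(self):
        h = [0, 10, 20, 30, 100]
        assert empirical_fraction_within_slab(h, 30) == pytest.approx(0.8)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3, 1.5, 2.5], [4, 5, 6, 4.5, 5.5])
        assert d == 1.0

    @pytest.mark.parametrize("x,y", [
        ([1.0, 2.0], [1.5, 2.5]),
        ([1, 2, 3, 4, 5], [1.2, 2.4, 3.1, 8.0, 9.0]),
        ([0.1, 0.2, 0.9], [0.15, 0.5, 0.6, 0.8]),
    ])
    def test_statistic_matches_brute_force_enumeration(self, x, y):
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    def test_null_rejection_rate_calibrated(self):
        """Same-distribution pairs rejected at ~alpha = 0.05."""
        rng = np.random.default_rng(2024)
        n_rep, n = 1000, 100
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(500, 50, n)
            y = rng.normal(500, 50, n)
            _, p = ks_two_sample(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        se3 = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < se3


class TestMisalignmentAndCircularity:
    def make_stats(self, group, mean, sd=10.0):
        return PopulationStats(group=group, n=100, mean=mean, sd=sd,
                               thickness_70=2 * 1.0364 * sd, goodness=0.05)

    def test_printed_sedimented_gap(self):
        """Fitted centers 150 and 235 um: populations misaligned by 85 um."""
        a = self.make_stats("HepG2-140-sed", 150, 105)
        b = self.make_stats("HepG2-340-sed", 235, 95)
        assert misalignment(a, b) == pytest.approx(85.0)
        assert misalignment(b, a) == pytest.approx(85.0)
        assert misalignment(a, a) == 0.0

    def test_circularity_of_circle_and_square(self):
        assert circularity(np.pi, 2 * np.pi) == pytest.approx(1.0)
        assert circularity(1.0, 4.0) == pytest.approx(np.pi / 4)

    @pytest.mark.parametrize("n_sides", [3, 4, 6, 12, 64])
    def test_regular_polygons_below_one(self, n_sides):
        theta = np.pi / n_sides
        area = 0.5 * n_sides * np.sin(2 * theta)   # circumradius 1
        perimeter = 2 * n_sides * np.sin(theta)
        c = circularity(area, perimeter)
        assert c <= 1.0 + 1e-12
        if n_sides == 64:
            assert c == pytest.approx(1.0, abs=1e-2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            circularity(0.0, 1.0)


class TestGroupReport:
    def test_levitated_populations_align(self):
        """HepG2-140 and HepG2-340 levitated presets: KS p > 0.05."""
        samples = (generate_preset("HepG2-140-levitated", seed=0)
                   + generate_preset("HepG2-340-levitated", seed=0))
        stats_df, ks_df = group_report(samples)
        assert set(stats_df["group"]) == {"HepG2-140-levitated",
                                          "HepG2-340-levitated"}
        cross = ks_df[ks_df.group_a != ks_df.group_b]
        assert len(cross) == 1
        assert cross["ks_pvalue"].iloc[0] > 0.05

    def test_single_group_trivial_matrix(self):
        samples = generate_preset("HCT-140-levitated", seed=1)
        stats_df, ks_df = group_report(samples)
        assert len(stats_df) == 1
        assert ks_df.iloc[0]["ks_statistic"] == 0.0
        assert ks_df.iloc[0]["ks_pvalue"] == 1.0

    def test_identical_groups_have_zero_distance(self):
        a = generate_preset("HepG2-140-levitated", seed=5)
        b = [type(s)(height_um=s.height_um, diameter_um=s.diameter_um,
                     group="copy", block=s.block) for s in a]
        _, ks_df = group_report(a + b)
        cross = ks_df[ks_df.group_a != ks_df.group_b]
        assert cross["ks_statistic"].iloc[0] == 0.0

    def test_small_group_flagged_not_fitted(self):
        from acoustolev.synth import HeightSample
        small = [HeightSample(height_um=100 + i, diameter_um=140,
                              group="tiny") for i in range(5)]
        big = generate_preset("HepG2-140-levitated", seed=2)
        stats_df, ks_df = group_report(small + big)
        row = stats_df[stats_df.group == "tiny"].iloc[0]
        assert not row["fitted"]
        assert np.isnan(row["mean"])
        assert "tiny" not in set(ks_df.group_a) | set(ks_df.group_b)
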