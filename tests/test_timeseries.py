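import math

import numpy as np
import pytest

from phagehost.core import ValidationError
from phagehost.timeseries import (
    Well,
    absolute_quantification,
    acf_pacf,
    ccf,
    coefficient_of_variation,
    false_alarm_level,
    geometric_summary,
    lomb_scargle,
    qc_wells,
    spline_trend,
)


class TestWellQc:
    def test_inclusive_boundary(self):
        wells = [Well("a", 10_000, 5), Well("b", 9_999, 5)]
        accepted = qc_wells(wells)
        assert [w.sample_id for w in accepted] == ["a"]

    def test_empty_list(self):
        assert qc_wells([]) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            Well("x", 1000, -1)
        with pytest.raises(ValidationError):
            Well("x", -1, 0)

    def test_positive_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            Well("x", 100, 101)


class TestAbsoluteQuantification:
    def test_all_negative_well_is_zero_and_below_loq(self):
        q = absolute_quantification(Well("x", 15_000, 0))
        assert q.copies_per_reaction == 0.0
        assert q.below_loq and not q.saturated

    def test_closed_form_lambda_of_one(self):
        # positive/total = 1 - e^-1 gives exactly one copy per droplet
        total = 100_000
        positive = round(total * (1 - math.exp(-1)))
        q = absolute_quantification(Well("x", total, positive))
        expected = 1.0 / 0.85 * 1000.0 * 20.0  # lambda/droplet_nl -> per 20 uL
        assert q.copies_per_reaction == pytest.approx(expected, rel=1e-3)

    def test_saturated_well_flagged(self):
        q = absolute_quantification(Well("x", 1000, 1000))
        assert q.saturated
        assert np.isfinite(q.copies_per_reaction)

    def test_monte_carlo_inversion_recovers_concentration(self):
        """Binomial droplet partitioning at a known concentration inverts to
        within 2% on average across 200 wells."""
        rng = np.random.default_rng(0)
        lam = 0.5  # copies per droplet
        total = 15_000
        estimates = []
        for _ in range(200):
            positive = rng.binomial(total, 1 - math.exp(-lam))
            q = absolute_quantification(Well("w", total, int(positive)))
            estimates.append(q.copies_per_reaction)
        truth = lam / 0.85 * 1000.0 * 20.0
        assert np.mean(estimates) == pytest.approx(truth, rel=0.02)


class TestGeometricSummary:
    def test_equal_replicates_zero_width_ci(self):
        s = geometric_summary([5.0] * 10, loq=1.0)
        assert s.geometric_mean == pytest.approx(5.0)
        assert s.ci_low == pytest.approx(5.0) and s.ci_high == pytest.approx(5.0)
        assert not s.below_loq

    def test_closed_form_geometric_mean(self):
        s = geometric_summary([1.0, 10.0, 100.0], loq=0.1)
        assert s.geometric_mean == pytest.approx(10.0)

    def test_zeros_excluded_and_counted(self):
        s = geometric_summary([0.0, 10.0, 10.0], loq=1.0)
        assert s.n_used == 2 and s.n_excluded == 1

    def test_substitute_at_loq_mode(self):
        s = geometric_summary([0.0, 10.0], loq=1.0, substitute_at_loq=True)
        assert s.n_used == 2 and s.n_excluded == 0
        assert s.geometric_mean == pytest.approx(math.sqrt(10.0))

    def test_single_usable_value_flagged_without_ci(self):
        s = geometric_summary([0.0, 10.0], loq=1.0)
        assert s.ci_low is None and s.ci_high is None

    def test_below_loq_flag_suppresses_error_bars_downstream(self):
        s = geometric_summary([0.5, 0.6, 0.4], loq=1.0)
        assert s.below_loq

    def test_coverage_of_geometric_t_interval(self):
        """95% back-transformed t-intervals cover the true geometric mean in
        95% +/- 1.5% of log-normal samples (n=10 per trial)."""
        rng = np.random.default_rng(1)
        mu, sigma, n, trials = 2.0, 0.5, 10, 2000
        covered = 0
        true_gm = 10.0 ** mu
        for _ in range(trials):
            values = 10.0 ** rng.normal(mu, sigma, size=n)
            s = geometric_summary(values, loq=1e-12)
            covered += s.ci_low <= true_gm <= s.ci_high
        assert abs(covered / trials - 0.95) <= 0.015


class TestAcfPacf:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(2)
        a, p = acf_pacf(rng.normal(size=50), max_lag=10)
        assert a[0] == pytest.approx(1.0)
        assert len(a) == 11 and len(p) == 11

    def test_alternating_series_lag1_near_minus_one(self):
        x = np.tile([1.0, -1.0], 100)
        a, _ = acf_pacf(x, max_lag=2)
        assert a[1] == pytest.approx(-1.0, abs=0.02)
        assert a[2] == pytest.approx(1.0, abs=0.02)

    def test_white_noise_within_sampling_bounds(self):
        rng = np.random.default_rng(3)
        n, bound = 200, 2.5 / math.sqrt(200)
        ok = 0
        seeds = 300
        for _ in range(seeds):
            a, _ = acf_pacf(rng.normal(size=n), max_lag=10)
            ok += bool(np.all(np.abs(a[1:]) < bound))
        # per-lag exceedance prob ~1.2%, ten near-independent lags => ~88%
        assert ok / seeds > 0.80

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError):
            acf_pacf(np.ones(30), max_lag=5)

    def test_series_shorter_than_max_lag_rejected(self):
        with pytest.raises(ValidationError):
            acf_pacf(np.arange(5.0), max_lag=10)


class TestCcf:
    def test_identical_series_argmax_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        lags, r, best = ccf(x, x, max_lag=10)
        assert best == 0
        assert r[list(lags).index(0)] == pytest.approx(1.0)

    def test_noise_free_shift_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        b = np.roll(x, 2)  # b follows a by 2 sampling steps
        _, _, best = ccf(x, b, max_lag=10)
        assert best == 2

    def test_antisymmetry_between_orders(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=35)
        b = rng.normal(size=35)
        lags, r_ab, _ = ccf(a, b, max_lag=10)
        _, r_ba, _ = ccf(b, a, max_lag=10)
        np.testing.assert_allclose(r_ab, r_ba[::-1], atol=1e-12)
        assert np.all(np.abs(r_ab) <= 1.0 + 1e-12)

    def test_null_argmax_value_stays_moderate(self):
        rng = np.random.default_rng(7)
        ok = 0
        seeds = 300
        for _ in range(seeds):
            a = rng.normal(size=35)
            b = rng.normal(size=35)
            _, r, _ = ccf(a, b, max_lag=10)
            ok += r.max() < 0.5
        assert ok / seeds >= 0.95

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValidationError):
            ccf(np.arange(10.0), np.arange(12.0))


class TestLombScargle:
    def test_planted_period_recovered_on_uneven_dates(self):
        rng = np.random.default_rng(8)
        dates = np.sort(rng.choice(80, size=35, replace=False)).astype(float)
        y = np.sin(2 * np.pi * dates / 20.0)
        pg = lomb_scargle(dates, y)
        grid_step = pg.frequency[1] - pg.frequency[0]
        assert abs(pg.peak_frequency - 0.05) <= grid_step

    def test_recovery_across_random_sampling_patterns(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            dates = np.sort(rng.choice(90, size=30, replace=False)).astype(float)
            y = np.sin(2 * np.pi * dates / 20.0) + rng.normal(0, 0.1, 30)
            pg = lomb_scargle(dates, y)
            grid_step = pg.frequency[1] - pg.frequency[0]
            assert abs(pg.peak_frequency - 0.05) <= 2 * grid_step

    def test_even_sampling_agrees_with_dft_oracle(self):
        n = 64
        dates = np.arange(n, dtype=float)
        y = np.sin(2 * np.pi * dates / 8.0)
        pg = lomb_scargle(dates, y)
        spectrum = np.abs(np.fft.rfft(y - y.mean())) ** 2
        dft_freqs = np.fft.rfftfreq(n, d=1.0)
        dft_peak = dft_freqs[int(np.argmax(spectrum))]
        grid_step = pg.frequency[1] - pg.frequency[0]
        assert abs(pg.peak_frequency - dft_peak) <= grid_step

    def test_white_noise_rarely_beats_false_alarm_level(self):
        rng = np.random.default_rng(10)
        dates = np.sort(rng.choice(80, size=35, replace=False)).astype(float)
        exceed = 0
        seeds = 200
        for _ in range(seeds):
            pg = lomb_scargle(dates, rng.normal(size=35))
            level = false_alarm_level(0.01, 35, pg.frequency.size)
            exceed += pg.peak_power > level
        assert exceed / seeds <= 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            lomb_scargle([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0])


class TestSplineTrend:
    def test_linear_data_reproduced_exactly(self):
        x = np.arange(35.0)
        y = 2.0 + 0.1 * x
        trend = spline_trend(x, y)
        np.testing.assert_allclose(trend.fitted, y, atol=1e-8)

    def test_denoises_a_sinusoid(self):
        rng = np.random.default_rng(11)
        x = np.sort(rng.choice(120, size=40, replace=False)).astype(float)
        truth = np.sin(2 * np.pi * x / 60.0)
        sigma = 0.3
        y = truth + rng.normal(0, sigma, size=x.size)
        trend = spline_trend(x, y)
        rmse = float(np.sqrt(np.mean((trend.fitted - truth) ** 2)))
        assert rmse < sigma

    def test_duplicate_dates_rejected(self):
        with pytest.raises(ValidationError):
            spline_trend([0, 1, 1, 2, 3], [1.0, 2.0, 2.0, 3.0, 4.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            spline_trend([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])


class TestCoefficientOfVariation:
    def test_constant_series_is_zero(self):
        assert coefficient_of_variation([3.0] * 10 ) == 0.0

    def test_hand_computed_value(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        assert coefficient_of_variation(x) == \
            pytest.approx(float(x.std(ddof=1) / x.mean()))

    def test_doubled_deviations_double_the_cv(self):
        base = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        doubled = base.mean() + 2 * (base - base.mean())
        assert coefficient_of_variation(doubled) == \
            pytest.approx(2 * coefficient_of_variation(base))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([-1.0, 1.0])
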