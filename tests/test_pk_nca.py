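"""Linear-log trapezoidal AUC, terminal slope, and NCA parameter summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqtpipe import (
    accumulation_ratio,
    auc_extrapolate,
    auc_linlog,
    cmax_tmax,
    fit_lambda_z,
    metabolite_ratio,
    nca_profile,
    steady_state_fraction,
    summarize_parameter,
    unbound_concentration,
)
from cqtpipe.errors import ValidationError
from cqtpipe.pk_nca import predicted_accumulation_ratio

LN2 = math.log(2.0)


class TestAucLinLog:
    @pytest.mark.parametrize(
        "times, concs, expected",
        [
            ([0, 2], [10, 10], 20.0),              # flat segment, linear rule
            ([0, 1], [10, 5], 5.0 / LN2),          # descending, log rule
            ([0, 1], [0, 10], 5.0),                # rising from zero, linear rule
            ([0, 1], [10, 0], 5.0),                # falling to zero, linear rule
        ],
    )
    def test_segment_rules(self, times, concs, expected):
        assert auc_linlog(times, concs) == pytest.approx(expected, rel=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            auc_linlog([0, 2, 1], [1, 2, 3])

    @given(
        times=st.lists(st.floats(0, 48), min_size=3, max_size=8, unique=True),
        concs=st.lists(st.floats(0, 100), min_size=8, max_size=8),
        cut=st.integers(1, 6),
    )
    @settings(max_examples=100, deadline=None)
    def test_additive_over_partition(self, times, concs, cut):
        t = sorted(times)
        c = concs[: len(t)]
        cut = min(cut, len(t) - 2)
        whole = auc_linlog(t, c)
        left = auc_linlog(t[: cut + 1], c[: cut + 1])
        right = auc_linlog(t[cut:], c[cut:])
        assert whole == pytest.approx(left + right, rel=1e-9, abs=1e-9)

    @given(
        c1=st.floats(1e-3, 1e3), ratio=st.floats(1e-3, 0.999), dt=st.floats(0.1, 24)
    )
    @settings(max_examples=200, deadline=None)
    def test_log_trapezoid_below_linear_on_declines(self, c1, ratio, dt):
        """The exponential chord lies below the straight chord."""
        c2 = c1 * ratio
        log_auc = auc_linlog([0, dt], [c1, c2])
        lin_auc = 0.5 * (c1 + c2) * dt
        assert log_auc <= lin_auc + 1e-12


class TestCmaxTmax:
    def test_tie_takes_first_time(self):
        cmax, tmax = cmax_tmax([0, 1, 3, 4, 8], [0, 8, 10, 10, 4])
        assert (cmax, tmax) == (10.0, 3.0)

    def test_monotone_rising_profile(self):
        cmax, tmax = cmax_tmax([0, 1, 2], [1.0, 2.0, 3.0])
        assert (cmax, tmax) == (3.0, 2.0)


class TestLambdaZ:
    def test_exact_exponential_recovered(self):
        t = np.array([24.0, 48.0, 72.0])
        c = 100.0 * np.exp(-(LN2 / 16.4) * t)
        t_full = np.concatenate([[0.0, 2.0], t])
        c_full = np.concatenate([[0.0, 120.0], c])
        fit = fit_lambda_z(t_full, c_full)
        assert fit.estimable
        assert fit.t_half == pytest.approx(16.4, rel=1e-12)

    def test_flat_profile_not_estimable(self):
        fit = fit_lambda_z([0, 2, 8, 12, 24], [0, 5, 5, 5, 5])
        assert not fit.estimable
        assert math.isnan(fit.lambda_z)

    def test_noisy_exponential_median_within_5pct(self):
        """Log-normal 10% noise: the median half-life over 200 seeds stays
        within 5% of truth."""
        t = np.array([0.0, 1.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0])
        base = 100.0 * np.exp(-(LN2 / 16.4) * t)
        base[0] = 0.0
        est = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = base * np.exp(rng.normal(0, 0.1, len(t)))
            noisy[0] = 0.0
            fit = fit_lambda_z(t, noisy)
            if fit.estimable:
                est.append(fit.t_half)
        assert len(est) >= 190
        assert np.median(est) == pytest.approx(16.4, rel=0.05)


class TestExtrapolationAndRatios:
    def test_zero_last_concentration_adds_nothing(self):
        auc_inf, frac = auc_extrapolate(100.0, 0.0, 0.05)
        assert auc_inf == 100.0 and frac == 0.0

    def test_extrapolation_arithmetic(self):
        auc_inf, frac = auc_extrapolate(100.0, 10.0, 0.1)
        assert auc_inf == pytest.approx(200.0)
        assert frac == pytest.approx(0.5)

    def test_dense_one_compartment_profile_matches_closed_forms(self):
        """Full NCA on a densely sampled one-compartment curve reproduces the
        analytic AUC (Dose/CL) and half-life within 1%."""
        ka, ke, dose_over_v = 0.75, LN2 / 16.4, 1.0
        t = np.concatenate([np.linspace(0, 24, 200), np.linspace(24.5, 240, 500)])
        c = dose_over_v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        res = nca_profile(t, c)
        auc_analytic = dose_over_v / ke  # F*Dose/CL on the conc scale used
        assert res["auc_inf"] == pytest.approx(auc_analytic, rel=0.01)
        assert res["t_half"] == pytest.approx(16.4, rel=0.01)

    @pytest.mark.parametrize("d10, d1, expected", [(50.0, 50.0, 1.0), (80.0, 40.0, 2.0)])
    def test_accumulation_ratio(self, d10, d1, expected):
        assert accumulation_ratio(d10, d1) == expected

    def test_predicted_linear_accumulation_for_bid_dosing(self):
        """tau = 12 h at a 16.4 h half-life: closed form gives ~2.51."""
        assert predicted_accumulation_ratio(12.0, 16.4) == pytest.approx(2.51, abs=0.01)

    @pytest.mark.parametrize(
        "t_half, duration, expected",
        [(10.0, 10.0, 0.5), (16.4, 96.0, 0.9827), (1.0, 1e6, 1.0)],
    )
    def test_steady_state_fraction(self, t_half, duration, expected):
        assert steady_state_fraction(t_half, duration) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "total, fu, expected", [(2.76, 0.025, 0.069), (5.0, 1.0, 5.0), (5.0, 0.0, 0.0)]
    )
    def test_unbound_concentration(self, total, fu, expected):
        assert unbound_concentration(total, fu) == pytest.approx(expected)

    def test_free_fraction_domain(self):
        with pytest.raises(ValidationError):
            unbound_concentration(1.0, 1.5)


class TestSummaries:
    def test_identical_values(self):
        s = summarize_parameter([7.0, 7.0, 7.0])
        assert s.geo_mean == pytest.approx(7.0)
        assert s.geo_cv_pct == pytest.approx(0.0)

    def test_geometric_mean_of_1_and_100(self):
        assert summarize_parameter([1.0, 100.0]).geo_mean == pytest.approx(10.0)

    def test_non_positive_values_rejected_for_geometric(self):
        with pytest.raises(ValidationError):
            summarize_parameter([1.0, 0.0])

    def test_metabolite_ratio_is_mean_of_per_subject_ratios(self):
        import pandas as pd

        parent = pd.Series([10.0, 10.0], index=["a", "b"])
        met = pd.Series([4.0, 5.0], index=["a", "b"])
        assert metabolite_ratio(parent, met) == pytest.approx(0.45)
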