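"""ACF estimation and the two correlogram features."""

import numpy as np
import pytest

from hrrhythm.acf_features import (
    AcfResult,
    autocorrelation,
    count_peaks,
    count_significant_lags,
)
from reference_implementations import reference_acf


def _acf_from_values(r, n=100):
    r = np.asarray(r, dtype=float)
    return AcfResult(
        lags=np.arange(r.size),
        acf_values=r,
        conf_bound=np.full(r.size, 1.96 / np.sqrt(n)),
        n_effective=n,
    )


class TestAutocorrelation:
    def test_matches_brute_force_double_loop(self, rng):
        for n in (50, 120, 200):
            x = rng.normal(size=n)
            got = autocorrelation(x, max_lag=20).acf_values
            assert got == pytest.approx(reference_acf(x, 20), abs=1e-10)

    def test_lag_zero_is_one_and_bounded(self, rng):
        res = autocorrelation(rng.normal(size=500), max_lag=100)
        assert res.acf_values[0] == pytest.approx(1.0)
        assert np.all(np.abs(res.acf_values) <= 1.0 + 1e-12)

    def test_ar1_matches_closed_form(self):
        # AR(1) with phi=0.5 has acf[k] = 0.5^k
        rng = np.random.default_rng(11)
        phi, n = 0.5, 200_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        r = autocorrelation(x, max_lag=5).acf_values
        assert r[1:] == pytest.approx(phi ** np.arange(1, 6), abs=0.02)

    def test_iid_noise_false_positive_rate_near_five_percent(self):
        # the 1.96/sqrt(n) band is calibrated for lags << n; at lags of
        # order n the biased estimator's variance (n-k)/n^2 shrinks the
        # exceedance rate below nominal, so test in the calibrated regime
        rates = []
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(1200)
            res = autocorrelation(x, max_lag=100)
            rates.append(count_significant_lags(res) / 100)
        assert 0.03 < np.mean(rates) < 0.07

    def test_location_invariance(self, rng):
        x = rng.normal(size=300)
        a = autocorrelation(x, max_lag=50).acf_values
        b = autocorrelation(x + 123.4, max_lag=50).acf_values
        assert a == pytest.approx(b, abs=1e-10)

    def test_bartlett_band_wider_than_constant_beyond_lag_one(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=500))  # strongly autocorrelated
        const = autocorrelation(x, max_lag=50, band="constant")
        bart = autocorrelation(x, max_lag=50, band="bartlett")
        assert np.all(bart.conf_bound[2:] >= const.conf_bound[2:])

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            autocorrelation(np.full(100, 72.0), max_lag=10)

    def test_too_short_for_max_lag_rejected(self, rng):
        with pytest.raises(ValueError):
            autocorrelation(rng.normal(size=20), max_lag=19)


class TestCountSignificantLags:
    def test_all_zero_acf_beyond_lag_zero(self):
        assert count_significant_lags(_acf_from_values([1.0, 0, 0, 0, 0])) == 0

    def test_counts_exceedances_of_band(self):
        res = _acf_from_values([1.0, 0.5, -0.5, 0.01], n=100)  # band ~0.196
        assert count_significant_lags(res) == 2

    def test_persistence_monotonicity(self):
        # stronger AR(1) persistence -> more significant lags, on average
        def mean_sig(phi):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                n = 1200
                x = np.empty(n)
                x[0] = rng.normal()
                eps = rng.normal(size=n)
                for t in range(1, n):
                    x[t] = phi * x[t - 1] + eps[t]
                vals.append(
                    count_significant_lags(autocorrelation(x, max_lag=600))
                )
            return np.mean(vals)

        assert mean_sig(0.9) > mean_sig(0.2)


class TestCountPeaks:
    def test_hand_worked_example(self):
        # local maxima at the 0.5 and 0.4 entries
        res = _acf_from_values([1.0, 0.2, 0.5, 0.1, 0.4, 0.0])
        assert count_peaks(res) == 2

    def test_monotone_decay_has_no_peaks(self):
        res = _acf_from_values(0.8 ** np.arange(20))
        assert count_peaks(res) == 0

    def test_ties_break_toward_non_peak(self):
        res = _acf_from_values([1.0, 0.5, 0.5, 0.2])
        assert count_peaks(res) == 0

    def test_significant_only_mode_restricts_count(self):
        res = _acf_from_values([1.0, 0.02, 0.05, 0.01, 0.5, 0.0], n=100)
        assert count_peaks(res) == 2
        assert count_peaks(res, significant_only=True) == 1

    def test_white_noise_rougher_than_persistent_signal(self):
        white, persistent = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1200
            w = rng.standard_normal(n)
            p = np.cumsum(rng.standard_normal(n))
            white.append(count_peaks(autocorrelation(w, max_lag=300)))
            persistent.append(count_peaks(autocorrelation(p, max_lag=300)))
        assert np.mean(white) > np.mean(persistent)
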