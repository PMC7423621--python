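"""Synthetic generators of known correlation structure and the analytic DFA oracle."""

import numpy as np
import pytest

from dynhrv.dfa import fit_alpha, fluctuation_function
from dynhrv import synthetic as syn


class TestFGN:
    def test_h_half_is_white(self):
        x = syn.generate_fgn(0.5, 10000, seed=3)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3.0 / np.sqrt(10000)

    def test_autocovariance_matches_closed_form(self):
        # average raw-product estimates over realizations; the target law
        # γ(k) = (1/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) must hold in 3 SE
        H, n, reps = 0.8, 256, 2000
        xs = np.array([syn.generate_fgn(H, n, seed=s) for s in range(reps)])
        for k in range(1, 6):
            est = (xs[:, : n - k] * xs[:, k:]).mean(axis=1)
            se = est.std(ddof=1) / np.sqrt(reps)
            assert abs(est.mean() - syn.fgn_autocovariance(k, H)) < 3 * se

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(syn.generate_fgn(0.7, 512, seed=9),
                                      syn.generate_fgn(0.7, 512, seed=9))

    def test_h_half_passes_whiteness_test_on_most_seeds(self):
        from scipy.stats import chi2

        passed = 0
        n, nlags, seeds = 2000, 10, 40
        for s in range(seeds):
            x = syn.generate_fgn(0.5, n, seed=s)
            x = x - x.mean()
            acf = np.array([x[: n - k] @ x[k:] for k in range(1, nlags + 1)]) / (x @ x)
            # Ljung-Box statistic against chi2(nlags) at 1%
            q = n * (n + 2) * np.sum(acf**2 / (n - np.arange(1, nlags + 1)))
            if q < chi2.ppf(0.99, nlags):
                passed += 1
        assert passed >= 0.95 * seeds

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_fgn(1.2, 100)


class TestAR:
    def test_empty_coeffs_is_white_noise(self):
        x = syn.generate_ar([], 5000, seed=0)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 3 / np.sqrt(5000)

    @pytest.mark.parametrize("phi", [0.6, -0.5])
    def test_lag1_autocorrelation(self, phi):
        x = syn.generate_ar([phi], 50000, seed=4)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(phi, abs=0.01)

    def test_nonstationary_coeffs_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_ar([1.01], 100)


class TestPink:
    def test_periodogram_slope_near_minus_one(self):
        from scipy.signal import periodogram

        slopes = []
        for s in range(5):
            x = syn.generate_pink(2**14, seed=s)
            f, p = periodogram(x)
            keep = (f > 1e-3) & (f < 0.4) & (p > 0)
            slopes.append(np.polyfit(np.log(f[keep]), np.log(p[keep]), 1)[0])
        assert np.mean(slopes) == pytest.approx(-1.0, abs=0.1)

    def test_dfa_exponent_near_one(self):
        alphas = []
        scales = np.unique(np.geomspace(8, 128, 12).astype(int))
        for s in range(5):
            sp = fluctuation_function(syn.generate_pink(2**14, seed=s), scales, 1)
            alphas.append(fit_alpha(sp, 8, 128))
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.1)

    def test_reproducible(self):
        np.testing.assert_array_equal(syn.generate_pink(256, seed=1),
                                      syn.generate_pink(256, seed=1))


class TestTheoreticalSpectrum:
    WHITE = staticmethod(lambda k: 1.0 if k == 0 else 0.0)

    def test_white_noise_alpha_approaches_half(self):
        _, alpha = syn.theoretical_dfa_spectrum(self.WHITE, np.array([64]), order=1)
        assert alpha[0] == pytest.approx(0.5, abs=0.02)

    def test_fgn_alpha_approaches_hurst(self):
        acov = syn.fgn_autocovariance(np.arange(70), 0.8)
        _, alpha = syn.theoretical_dfa_spectrum(acov, np.array([64]), order=1)
        assert alpha[0] == pytest.approx(0.8, abs=0.02)

    @pytest.mark.parametrize(
        "acov,label",
        [
            (lambda k: 1.0 if k == 0 else 0.0, "white"),
            (lambda k: 0.5**k / 0.75, "ar+"),
            (lambda k: (-0.5) ** k / 0.75, "ar-"),
            (lambda k: syn.fgn_autocovariance(k, 0.2).item(), "fgn0.2"),
            (lambda k: syn.fgn_autocovariance(k, 0.8).item(), "fgn0.8"),
        ],
    )
    def test_matches_monte_carlo_fluctuations(self, acov, label):
        """E[F²(s)] agrees with empirical maximally-overlapping F within 3 SE."""
        scales = np.array([4, 8, 16, 32, 64])
        F_theory, _ = syn.theoretical_dfa_spectrum(acov, scales, order=1)
        if label == "white":
            gen = lambda seed: np.random.default_rng(seed).standard_normal(1500)
        elif label == "ar+":
            gen = lambda seed: syn.generate_ar([0.5], 1500, seed=seed)
        elif label == "ar-":
            gen = lambda seed: syn.generate_ar([-0.5], 1500, seed=seed)
        elif label == "fgn0.2":
            gen = lambda seed: syn.generate_fgn(0.2, 1500, seed=seed)
        else:
            gen = lambda seed: syn.generate_fgn(0.8, 1500, seed=seed)
        reps = 60
        f2 = np.array([fluctuation_function(gen(s), scales, 1).F ** 2 for s in range(reps)])
        mean, se = f2.mean(axis=0), f2.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - F_theory**2) < 3.5 * se + 1e-12)

    def test_amplitude_linearity(self):
        scales = np.array([8, 16])
        F1, _ = syn.theoretical_dfa_spectrum(self.WHITE, scales, 1)
        F2, _ = syn.theoretical_dfa_spectrum(lambda k: 4.0 * self.WHITE(k), scales, 1)
        np.testing.assert_allclose(F2, 2.0 * F1, rtol=1e-12)

    def test_indefinite_acov_rejected(self):
        with pytest.raises(ValueError):
            syn.theoretical_dfa_spectrum(lambda k: [1.0, -0.9, 0.9][min(k, 2)],
                                         np.array([8]), 1)


class TestIntervalExercise:
    def test_beat_accounting(self):
        schedule = [("rest", 300.0), ("intense", 160.0)]
        series = syn.generate_interval_exercise(schedule, seed=0)
        expected = 300.0 * 1000 / 700.0 + 160.0 * 1000 / 350.0
        assert len(series) == pytest.approx(expected, rel=0.02)

    def test_default_schedule_has_six_intense_intervals(self):
        labels = [r for r, _ in syn.DEFAULT_INTERVAL_SCHEDULE]
        assert labels.count("intense") == 6
        assert all(d == pytest.approx(160.0) for r, d in syn.DEFAULT_INTERVAL_SCHEDULE
                   if r == "intense")

    def test_regimes_separate_in_ddfa(self):
        """Intense running shows anticorrelated RRIs, recovery shows persistence."""
        from dynhrv.ddfa import compute_ddfa

        series, labels = syn.generate_interval_exercise(seed=1, return_labels=True)
        field = compute_ddfa(series, scales=[8], a=5.0)
        t = field.table
        frac_intense = np.array(
            [np.mean(labels[int(s): int(s) + int(l)] == "intense")
             for s, l in zip(t["start"], t["length"])]
        )
        assert t["alpha"][frac_intense > 0.9].mean() < 0.5
        assert t["alpha"][frac_intense < 0.1].mean() > 0.5

    def test_intense_regime_has_higher_hr(self):
        series, labels = syn.generate_interval_exercise(seed=5, return_labels=True)
        assert series.hr[labels == "intense"].mean() > series.hr[labels == "rest"].mean() + 40

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_interval_exercise([("rest", -1.0)])
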