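"""Tests of profile extraction, registration, fitting and statistics."""

import numpy as np
import pytest

from hhwave import PathwayParameters, SimulationConfig, SourceDescriptor, run_simulation
from hhwave.profiles import (
    ProfileError,
    RegistrationError,
    SpatialProfile,
    UndefinedPeakError,
    extract_profile,
    fit_exponential_decay,
    fit_polynomial,
    peak_separation,
    profiles_from_csv,
    profiles_to_csv,
    ptc_bound_fraction,
    register_profile,
    summarize_profiles,
    welch_one_tailed_t,
)


def make_profile(x, **levels):
    return SpatialProfile(np.asarray(x, float),
                          {k: np.asarray(v, float) for k, v in levels.items()})


class TestExtract:
    def test_uniform_states_give_flat_profile(self):
        # no source, no rates: every cell keeps its (cv = 0) basal state
        zero = {k: 1e-300 for k in ("k1", "k2", "k3", "k4", "beta2", "beta3",
                                    "alpha2", "alpha3")}
        p = PathwayParameters().replace(cv=0.0, alpha1=0.0, **zero)
        cfg = SimulationConfig(params=p, source=SourceDescriptor(alpha1=0.0),
                               total_time=20.0, snapshot_interval=10.0, seed=0)
        prof = extract_profile(run_simulation(cfg), 20.0)
        for sp in ("ptc", "cia"):
            assert np.ptp(prof.levels[sp]) <= 1e-9 * prof.levels[sp].max()

    def test_moving_source_profiles_are_comoving(self):
        p = PathwayParameters()
        cfg = SimulationConfig(params=p,
                               source=SourceDescriptor(speed=1.0, alpha1=p.alpha1),
                               total_time=240.0, snapshot_interval=60.0, seed=0)
        trace = run_simulation(cfg)
        d0 = extract_profile(trace, 0.0).distances
        d240 = extract_profile(trace, 240.0).distances
        # the same outermost cells are 20 um nearer the front after 4 h
        assert d240.max() == pytest.approx(d0.max() - 20.0, abs=1.0)

    def test_empty_tissue_rejected(self, static_trace):
        with pytest.raises(ProfileError):
            extract_profile(static_trace, 620.0, bin_width=-1.0)


class TestRegister:
    def test_peak_at_first_bin_means_zero_shift(self):
        prof = make_profile(np.arange(10) * 5.0 + 2.5,
                            hh=50 * np.exp(-np.arange(10) / 2.0))
        reg = register_profile(prof, smoothing_window=1)
        assert reg.distances[0] == 0.0
        assert reg.registered

    def test_plateau_then_decay_origin_at_last_plateau_bin(self):
        # brute-force scan of raw forward differences: first negative
        # difference sits at the last plateau bin
        y = np.array([5.0, 5.0, 5.0, 3.0, 1.5, 0.7, 0.3, 0.1])
        x = np.arange(8) * 5.0
        reg = register_profile(make_profile(x, hh=y), smoothing_window=1)
        assert reg.distances[2] == 0.0

    def test_monotone_rise_fails(self):
        prof = make_profile(np.arange(8) * 5.0, hh=np.arange(8) * 1.0 + 1)
        with pytest.raises(RegistrationError):
            register_profile(prof)

    def test_noise_around_constant_fails(self, rng):
        y = 10.0 + rng.normal(0, 0.3, 30)
        prof = make_profile(np.arange(30) * 2.0, hh=np.clip(y, 0, None))
        with pytest.raises(RegistrationError):
            register_profile(prof)


class TestPolynomialFit:
    def test_nested_model_exactness(self):
        # degree-3 data fitted with order 7 is reproduced exactly
        x = np.linspace(0, 40, 15)
        y = 5 + 0.3 * x - 0.004 * x**2 + 5e-5 * x**3   # positive on [0, 40]
        fit = fit_polynomial(make_profile(x, ptc=y), order=7)
        np.testing.assert_allclose(fit.curve("ptc", x), y, rtol=1e-8)

    def test_too_few_bins_rejected(self):
        x = np.arange(8) * 5.0
        with pytest.raises(ProfileError):
            fit_polynomial(make_profile(x, ptc=np.ones(8)), order=7)

    def test_noisy_exponential_within_noise_envelope(self, rng):
        x = np.linspace(0, 45, 20)
        truth = 30 * np.exp(-x / 12.0)
        sd = 0.5
        y = np.clip(truth + rng.normal(0, sd, x.shape), 0, None)
        fit = fit_polynomial(make_profile(x, hh=y), order=7)
        rmse = np.sqrt(np.mean((fit.curve("hh", x) - truth) ** 2))
        assert rmse <= 1.5 * sd


class TestAverageProfiles:
    def grid(self):
        return np.linspace(0, 45, 16)

    def truth(self, x):
        return 20 * np.exp(-x / 15.0) + 2

    def test_identical_replicates_zero_band(self):
        x = self.grid()
        profs = [make_profile(x, ptc=self.truth(x), hh=self.truth(x),
                              cia=self.truth(x)) for _ in range(4)]
        s = summarize_profiles(profs)
        np.testing.assert_allclose(s.ci50_upper["ptc"], s.ci50_lower["ptc"],
                                   atol=1e-9)
        np.testing.assert_allclose(s.mean_curve["ptc"],
                                   np.interp(s.grid, x, self.truth(x)), rtol=0.02)

    def test_truth_inside_band_for_symmetric_noise(self, rng):
        x = self.grid()
        profs = []
        for _ in range(12):
            noise = rng.normal(0, 0.4, x.shape)
            profs.append(make_profile(x, ptc=np.clip(self.truth(x) + noise, 0, None)))
        s = summarize_profiles(profs)
        truth = self.truth(s.grid)
        inside = (truth >= s.ci50_lower["ptc"] - 0.4) & (truth <= s.ci50_upper["ptc"] + 0.4)
        assert inside.mean() >= 0.95

    def test_coefficient_mean_tracks_pointwise_mean(self, rng):
        x = self.grid()
        profs = [make_profile(x, ptc=np.clip(
            self.truth(x) * np.exp(rng.normal(0, 0.1)), 0, None))
            for _ in range(6)]
        s = summarize_profiles(profs)
        dynamic_range = np.ptp(s.pointwise_mean["ptc"])
        gap = np.max(np.abs(s.mean_curve["ptc"] - s.pointwise_mean["ptc"]))
        assert gap <= 0.05 * dynamic_range

    def test_incompatible_domains_rejected(self):
        from hhwave.profiles import average_profiles
        x = self.grid()
        f1 = fit_polynomial(make_profile(x, ptc=self.truth(x)), order=7)
        f2 = fit_polynomial(make_profile(x + 30, ptc=self.truth(x)), order=7)
        with pytest.raises(ProfileError):
            average_profiles([f1, f2])


class TestExponentialDecay:
    def test_noiseless_recovery_is_exact(self):
        x = np.linspace(0, 60, 25)
        prof = make_profile(x, ptc=8.0 * np.exp(-x / 12.0))
        A, expo, lam = fit_exponential_decay(prof, "ptc")
        assert lam == pytest.approx(12.0, rel=1e-6)
        assert A == pytest.approx(8.0, rel=1e-6)
        assert expo == pytest.approx(1 / 12.0, rel=1e-6)

    def test_flat_profile_rejected(self):
        prof = make_profile(np.arange(10) * 5.0, ptc=np.full(10, 3.0))
        with pytest.raises(ProfileError):
            fit_exponential_decay(prof, "ptc")

    def test_noisy_recovery_rate(self):
        # Monte-Carlo: 5% multiplicative noise, 20 bins, lambda = 13 um
        x = np.linspace(0, 50, 20)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 10 * np.exp(-x / 13.0) * np.exp(rng.normal(0, 0.05, x.shape))
            _, _, lam = fit_exponential_decay(make_profile(x, ptc=y), "ptc")
            hits += abs(lam - 13.0) <= 1.3
        assert hits >= 90

    def test_scale_equivariance(self):
        x = np.linspace(0, 50, 18)
        y = 6.0 * np.exp(-x / 9.0) + 0.01 * np.sin(x)
        A1, _, lam1 = fit_exponential_decay(make_profile(x, ptc=np.clip(y, 0, None)), "ptc")
        A2, _, lam2 = fit_exponential_decay(make_profile(x, ptc=np.clip(7 * y, 0, None)), "ptc")
        assert lam2 == pytest.approx(lam1, rel=1e-6)
        assert A2 == pytest.approx(7 * A1, rel=1e-6)


class TestPeakSeparation:
    def gaussian(self, x, mu):
        return np.exp(-((x - mu) ** 2) / 18.0)

    def test_two_gaussians(self):
        x = np.arange(0, 40, 2.5)
        pa = make_profile(x, ptc=self.gaussian(x, 5.0))
        pb = make_profile(x, cia=self.gaussian(x, 15.0))
        res = peak_separation(pa, pb)
        assert res.separation == pytest.approx(10.0, abs=2.5)
        assert res.separated

    def test_identical_profiles_not_separated(self):
        x = np.arange(0, 40, 2.5)
        prof = make_profile(x, ptc=self.gaussian(x, 10.0),
                            cia=self.gaussian(x, 10.0))
        res = peak_separation(prof, prof)
        assert res.separation == 0.0
        assert not res.separated

    def test_boundary_peak_flagged(self):
        x = np.arange(0, 40, 5.0)
        prof = make_profile(x, ptc=np.exp(-x / 20.0), cia=np.exp(x / 20.0) - 1 + 0.01)
        res = peak_separation(prof, prof)
        assert res.boundary_peak

    def test_flat_profile_is_undefined(self):
        x = np.arange(0, 40, 5.0)
        prof = make_profile(x, ptc=np.ones_like(x), cia=np.ones_like(x))
        with pytest.raises(UndefinedPeakError):
            peak_separation(prof, prof)

    def test_mismatched_domains_rejected(self):
        x = np.arange(0, 40, 5.0)
        pa = make_profile(x, ptc=self.gaussian(x, 5.0), cia=self.gaussian(x, 5.0))
        pb = make_profile(x + 1, ptc=self.gaussian(x, 5.0), cia=self.gaussian(x, 5.0))
        with pytest.raises(ProfileError):
            peak_separation(pa, pb)


class TestBoundFraction:
    def test_ninety_percent_everywhere(self):
        d = np.linspace(0, 45, 60)
        xs, fr = ptc_bound_fraction(np.ones(60), np.full(60, 9.0), d)
        np.testing.assert_allclose(fr, 0.9, rtol=1e-12)

    def test_no_complex_means_zero(self):
        d = np.linspace(0, 45, 30)
        _, fr = ptc_bound_fraction(np.ones(30), np.zeros(30), d)
        np.testing.assert_allclose(fr, 0.0)

    def test_empty_pool_bin_dropped_with_warning(self):
        d = np.array([1.0, 2.0, 11.0, 12.0])
        ptc = np.array([1.0, 1.0, 0.0, 0.0])
        hh_ptc = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            xs, fr = ptc_bound_fraction(ptc, hh_ptc, d)
        assert len(xs) == 1


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_one_tailed_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_zero_variance_equal_means_convention(self):
        with pytest.warns(UserWarning):
            t, df, p = welch_one_tailed_t([2.0, 2.0], [2.0, 2.0])
        assert p == 0.5

    def test_small_sample_vs_permutation_oracle(self):
        from itertools import combinations
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, df, p = welch_one_tailed_t(a, b, direction="b_greater")
        assert p < 0.05
        # exhaustive permutation oracle on the 20 assignments
        pooled = a + b
        observed = np.mean(b) - np.mean(a)
        count = 0
        for idx in combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            count += (np.mean(gb) - np.mean(ga)) >= observed - 1e-12
        assert count / 20 <= 0.05

    def test_direction_flip(self):
        a, b = [4.0, 5, 6], [1.0, 2, 3]
        _, _, p_wrong = welch_one_tailed_t(a, b, direction="b_greater")
        _, _, p_right = welch_one_tailed_t(a, b, direction="a_greater")
        assert p_right < 0.05 < p_wrong

    def test_matches_scipy(self, rng):
        from scipy import stats
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 2, 13)
        t, df, p = welch_one_tailed_t(a, b, direction="b_greater")
        ref = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestPipelineOnSimulation:
    def test_pipeline_identity_on_simulated_profiles(self, battery_traces):
        """extract -> register -> fit -> average reproduces the raw binned
        profiles within 2% RMSE of the dynamic range."""
        profs = [register_profile(extract_profile(tr, 300.0))
                 for tr in battery_traces.values()]
        summary = summarize_profiles(profs)
        for sp in ("hh", "ptc"):
            raw = np.stack([np.interp(summary.grid, p.distances, p.levels[sp])
                            for p in profs]).mean(axis=0)
            rmse = np.sqrt(np.mean((summary.mean_curve[sp] - raw) ** 2))
            assert rmse <= 0.02 * np.ptp(raw)

    def test_csv_roundtrip(self, static_trace, tmp_path):
        profs = [extract_profile(static_trace, t) for t in (100.0, 300.0)]
        path = tmp_path / "profiles.csv"
        profiles_to_csv(profs, path)
        back = profiles_from_csv(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].distances, profs[0].distances)
        np.testing.assert_allclose(back[1].levels["cia"], profs[1].levels["cia"])
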