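"""Monotone fitting, Monte Carlo envelopes and the dating estimators."""

import numpy as np
import pytest

from icpd.agemodel import (Ensemble, MonotoneAgeModel, OutOfRangeError,
                           Series, assign_sigma, combine_cores,
                           envelope_overlap, estimate_age_ensemble,
                           estimate_age_window, fit_monotone,
                           monte_carlo_envelope)
from icpd.synth import KineticParams, SynthConfig, generate_dataset, \
    trajectory_dl


def _series(ages, dl, sigma=None, groups=None):
    return Series("X", "Asx", "THAA", np.asarray(ages, float),
                  np.asarray(dl, float),
                  None if sigma is None else np.asarray(sigma, float),
                  None if groups is None else np.asarray(groups,
                                                         dtype=object))


def _noisy_series(rng, n_ages=12, step=25, sigma=0.005, a=0.0183, b=0.45,
                  d0=0.05):
    ages = np.repeat(np.arange(1, n_ages + 1) * step, 2).astype(float)
    truth = d0 + a * ages ** b
    dl = truth + rng.normal(0, sigma, ages.size)
    return _series(ages, dl, np.full(ages.size, sigma))


class TestAssignSigma:
    def test_two_point_sd_assigned_everywhere(self):
        s = _series([10, 10, 50], [0.50, 0.52, 0.6],
                    groups=["a", "a", "b"])
        out = assign_sigma(s)
        assert out.sigma == pytest.approx([0.0141421356] * 3)

    def test_identical_replicates_rejected(self):
        s = _series([10, 10, 50], [0.5, 0.5, 0.6], groups=["a", "a", "b"])
        with pytest.raises(ValueError, match="identical"):
            assign_sigma(s)

    def test_no_replicates_rejected(self):
        s = _series([10, 20, 50], [0.5, 0.55, 0.6])
        with pytest.raises(ValueError, match="replicated"):
            assign_sigma(s)

    def test_pooling_equal_within_group_sd_returns_it(self):
        # two groups, each with within-group sd s -> pooled sd = s
        s_val = 0.01 / np.sqrt(2)  # sd of (x-h, x+h) is h*sqrt(2)
        h = 0.005
        s = _series([10, 10, 50, 50], [0.5 - h, 0.5 + h, 0.6 - h, 0.6 + h],
                    groups=["a", "a", "b", "b"])
        out = assign_sigma(s)
        expected = np.std([0.5 - h, 0.5 + h], ddof=1)
        assert out.sigma[0] == pytest.approx(expected)
        del s_val


class TestFitMonotone:
    def test_noiseless_increasing_data_interpolated_at_zero_smoothing(self):
        ages = [0, 10, 20, 30, 40]
        dl = [0.1, 0.15, 0.22, 0.3, 0.31]
        m = fit_monotone(_series(ages, dl, [0.01] * 5), smoothing=0.0)
        assert m.knot_dl == pytest.approx(dl, abs=1e-7)

    def test_fit_is_nondecreasing_despite_downward_blip(self):
        ages = [0, 10, 20, 30, 40, 50]
        dl = [0.10, 0.15, 0.14, 0.22, 0.30, 0.31]  # blip within 1 sigma
        m = fit_monotone(_series(ages, dl, [0.02] * 6), smoothing=0.0)
        assert np.all(np.diff(m.knot_dl) >= -1e-12)

    def test_misfit_bounded_by_isotonic_regression_oracle(self, rng):
        """At zero smoothing the fit equals weighted isotonic regression;
        sklearn's independent implementation bounds the chi-square."""
        from sklearn.isotonic import IsotonicRegression
        s = _noisy_series(rng)
        m = fit_monotone(s, smoothing=0.0)
        chi2 = float(np.sum(((m.predict(s.ages) - s.dl) / s.sigma) ** 2))
        iso = IsotonicRegression().fit(s.ages, s.dl,
                                       sample_weight=1 / s.sigma ** 2)
        chi2_oracle = float(np.sum(((iso.predict(s.ages) - s.dl)
                                    / s.sigma) ** 2))
        assert chi2 <= chi2_oracle + 1e-6

    def test_large_smoothing_approaches_common_slope(self, rng):
        ages = np.repeat(np.arange(0, 200, 20), 2).astype(float)
        dl = 0.1 + 0.001 * ages + rng.normal(0, 0.005, ages.size)
        s = _series(ages, dl, np.full(ages.size, 0.005))
        m = fit_monotone(s, smoothing=1e6)
        slopes = m.slopes
        assert slopes.max() - slopes.min() < 1e-6
        wls_slope = np.polyfit(ages, dl, 1)[0]
        assert slopes.mean() == pytest.approx(wls_slope, rel=1e-3)

    def test_negative_smoothing_rejected(self):
        with pytest.raises(ValueError):
            fit_monotone(_series([0, 1, 2], [0.1, 0.2, 0.3], [0.01] * 3),
                         smoothing=-1.0)

    def test_monotone_on_random_noise(self, rng):
        for _ in range(10):
            ages = np.sort(rng.choice(np.arange(1, 200), 8, replace=False))
            dl = np.abs(rng.normal(0.2, 0.1, 8))
            m = fit_monotone(_series(ages, dl, np.full(8, 0.02)))
            assert np.all(np.diff(m.knot_dl) >= -1e-12)


class TestMonteCarloEnvelope:
    def test_zero_noise_limit_collapses_to_deterministic_fit(self):
        ages = [0, 10, 20, 30, 40]
        dl = [0.1, 0.15, 0.22, 0.3, 0.31]
        s = _series(ages, dl, [1e-7] * 5)
        env, ens = monte_carlo_envelope(s, n_iter=50, smoothing=0.0,
                                        rate_jitter=0.0, seed=1)
        base = fit_monotone(s, smoothing=0.0)
        assert np.allclose(env.hi95 - env.lo95, 0.0, atol=1e-5)
        assert env.median_dl == pytest.approx(
            base.predict(env.grid_ages), abs=1e-5)

    def test_quantile_ordering_and_member_monotonicity(self, rng):
        s = _noisy_series(rng)
        env, ens = monte_carlo_envelope(s, n_iter=200, seed=5)
        assert np.all(env.lo95 <= env.lo68 + 1e-12)
        assert np.all(env.lo68 <= env.median_dl + 1e-12)
        assert np.all(env.median_dl <= env.hi68 + 1e-12)
        assert np.all(env.hi68 <= env.hi95 + 1e-12)
        assert np.all(np.diff(ens.curves, axis=1) >= -1e-10)
        assert np.all(np.diff(env.median_dl) >= -1e-10)

    def test_doubling_sigma_widens_envelope(self, rng):
        s1 = _noisy_series(rng)
        s2 = _series(s1.ages, s1.dl, s1.sigma * 2)
        env1, _ = monte_carlo_envelope(s1, n_iter=300, seed=9)
        env2, _ = monte_carlo_envelope(s2, n_iter=300, seed=9)
        w1 = env1.hi95 - env1.lo95
        w2 = env2.hi95 - env2.lo95
        assert np.all(w2 >= w1 - 1e-9)
        assert w2.mean() > w1.mean()

    def test_fixed_seed_bit_identical(self, rng):
        s = _noisy_series(rng)
        env1, ens1 = monte_carlo_envelope(s, n_iter=100, seed=77)
        env2, ens2 = monte_carlo_envelope(s, n_iter=100, seed=77)
        assert np.array_equal(ens1.curves, ens2.curves)
        assert np.array_equal(env1.median_dl, env2.median_dl)
        assert np.array_equal(env1.hi95, env2.hi95)

    def test_seed_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            monte_carlo_envelope(_noisy_series(rng), n_iter=10)


class TestEstimateAgeEnsemble:
    def _single_curve(self):
        grid = np.arange(0.0, 101.0)
        curve = 0.1 + 0.002 * grid
        return Ensemble(grid, curve[None, :], seed=1,
                        series=_series([0, 100], [0.1, 0.3]))

    def test_exact_inversion_on_single_curve(self):
        ens = self._single_curve()
        est = estimate_age_ensemble(ens, 0.1 + 0.002 * 40, dl_sigma=0.0)
        assert est.median_age == pytest.approx(40.0, abs=1e-9)
        assert est.ci95 == pytest.approx((40.0, 40.0))

    def test_flat_segment_inverts_to_midpoint(self):
        grid = np.arange(0.0, 11.0)
        curve = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.2, 0.3, 0.4, 0.5,
                          0.6, 0.7])
        ens = Ensemble(grid, curve[None, :], seed=1,
                       series=_series([0, 10], [0.1, 0.7]))
        est = estimate_age_ensemble(ens, 0.2, dl_sigma=0.0)
        assert est.median_age == pytest.approx(3.0)  # mid of ages 1..5

    def test_out_of_span_refused(self):
        ens = self._single_curve()
        with pytest.raises(OutOfRangeError, match="span"):
            estimate_age_ensemble(ens, 0.9, 0.0)

    def test_increasing_measurement_sigma_never_narrows_ci95(self, rng):
        s = _noisy_series(rng)
        _, ens = monte_carlo_envelope(s, n_iter=400, seed=3)
        widths = []
        for ds in (0.001, 0.005, 0.01, 0.02):
            est = estimate_age_ensemble(ens, 0.22, ds, seed=17)
            widths.append(est.ci95[1] - est.ci95[0])
        assert np.all(np.diff(widths) >= -1e-9)


class TestEstimateAgeWindow:
    def test_equal_in_window_ages_zero_width(self):
        est = estimate_age_window([50] * 6, [0.2] * 6, 0.2)
        assert est.median_age == 50
        assert est.ci95 == (50, 50)

    def test_hand_arithmetic_interval(self):
        est = estimate_age_window([1900, 1910, 1920], [0.2, 0.2, 0.2], 0.2,
                                  min_support=3)
        assert est.median_age == pytest.approx(1910)
        assert est.ci68 == pytest.approx((1900, 1920))
        assert est.ci95 == pytest.approx((1890, 1930))

    def test_widening_window_never_loses_support(self, rng):
        ages = rng.uniform(0, 300, 200)
        dls = 0.001 * ages + rng.normal(0, 0.01, 200)
        n_prev = 0
        for w in (0.005, 0.01, 0.02, 0.05):
            est = estimate_age_window(ages, dls, 0.15, window=w)
            assert est.n_support >= n_prev
            n_prev = est.n_support

    def test_sparse_window_is_error(self):
        with pytest.raises(ValueError, match="widen"):
            estimate_age_window([1, 2, 3], [0.1, 0.5, 0.9], 0.5,
                                window=0.01)


class TestEnvelopeOverlap:
    def test_identical_envelopes_overlap_everywhere(self, rng):
        s = _noisy_series(rng)
        env, _ = monte_carlo_envelope(s, n_iter=150, seed=8)
        _, overlap, summary = envelope_overlap(env, env, level=95)
        assert summary == 0.0 and overlap.all()

    def test_distinct_rate_multipliers_separate(self, rng):
        """Colonies racemizing 1.0x vs 1.5x must show disjoint 95% bands."""
        p = KineticParams(d0=0.05, a=0.0183, b=0.45)
        envs = []
        for mult, seed in ((1.0, 21), (1.5, 22)):
            ages = np.repeat(np.arange(1, 13) * 25.0, 2)
            truth = trajectory_dl(ages, KineticParams(
                d0=p.d0, a=p.a * mult, b=p.b))
            dl = truth + rng.normal(0, 0.003, ages.size)
            s = _series(ages, dl, np.full(ages.size, 0.003))
            env, _ = monte_carlo_envelope(s, n_iter=300, seed=seed)
            envs.append(env)
        _, _, summary95 = envelope_overlap(envs[0], envs[1], level=95)
        assert summary95 > 0.0

    def test_two_sigma_overlap_contains_one_sigma_overlap(self, rng):
        p = KineticParams(d0=0.05, a=0.0183, b=0.45)
        envs = []
        for mult, seed in ((1.0, 31), (1.15, 32)):
            ages = np.repeat(np.arange(1, 13) * 25.0, 2)
            truth = trajectory_dl(ages, KineticParams(
                d0=p.d0, a=p.a * mult, b=p.b))
            dl = truth + rng.normal(0, 0.004, ages.size)
            s = _series(ages, dl, np.full(ages.size, 0.004))
            env, _ = monte_carlo_envelope(s, n_iter=300, seed=seed)
            envs.append(env)
        _, ov95, _ = envelope_overlap(envs[0], envs[1], level=95)
        _, ov68, _ = envelope_overlap(envs[0], envs[1], level=68)
        assert np.all(ov95 >= ov68)  # wherever 68% bands meet, 95% do too


class TestCombineCores:
    def test_self_combination_doubles_multiplicity(self, rng):
        s = assign_sigma(_series([10, 10, 50, 50], [0.2, 0.21, 0.3, 0.32],
                                 groups=["a", "a", "b", "b"]))
        out = combine_cores([s, s])
        assert len(out) == 2 * len(s)
        assert sorted(out.ages) == sorted(np.repeat(s.ages, 2))

    def test_mixed_amino_acids_rejected(self):
        s1 = _series([1, 2, 3], [0.1, 0.2, 0.3], [0.01] * 3)
        s2 = Series("Y", "Glx", "THAA", np.array([1.0, 2, 3]),
                    np.array([0.1, 0.2, 0.3]), np.array([0.01] * 3))
        with pytest.raises(ValueError, match="mixed"):
            combine_cores([s1, s2])

    def test_pooled_window_interval_wider_with_colony_spread(self):
        """Pooling colonies with distinct rate multipliers inflates the
        window-method dating uncertainty relative to a single colony."""
        cfg = SynthConfig(n_colonies=8, ages=tuple(range(10, 310, 10)),
                          seed=42)
        ds, truth = generate_dataset(cfg)
        mult = truth.drop_duplicates("core_code").set_index(
            "core_code")["colony_multiplier"]
        target_code = mult.index[0]
        target_dl = 0.05 + 0.0183 * float(mult[target_code]) * 150 ** 0.45

        def window_ci(codes):
            ages, dls = [], []
            for a in ds.analyses:
                if a.core_code in codes and a.fraction == "THAA" \
                        and "Asx" in a.dl:
                    ages.append(1990 - a.assigned_year)
                    dls.append(a.dl["Asx"])
            est = estimate_age_window(ages, dls, target_dl, window=0.01)
            return est.ci95[1] - est.ci95[0]

        assert window_ci(set(mult.index)) > window_ci({target_code})


class TestModelResultsApi:
    def test_from_dataset_fit_and_summary(self, small_dataset):
        ds, _ = small_dataset
        model = MonotoneAgeModel.from_dataset(ds, "SIM01", "Asx", "THAA")
        res = model.fit()
        assert np.all(np.diff(res.knot_dl) >= -1e-12)
        assert "SIM01" in res.summary()
        mc = model.fit_monte_carlo(n_iter=60, seed=2)
        assert "iterations:    60" in mc.summary()
        est = mc.estimate_age(float(mc.envelope.median_dl[50]), 0.005)
        assert mc.envelope.grid_ages[0] <= est.median_age \
            <= mc.envelope.grid_ages[-1]


def test_ensemble_exponent_recovery():
    """On power-law truth the ensemble's post-hoc exponent distribution
    must cover the true exponent in >= 90% of replicate experiments."""
    a_true, b_true = 0.0183, 0.45
    hits, runs = 0, 100
    for i in range(runs):
        rng = np.random.default_rng(1000 + i)
        ages = np.repeat(np.array([5.0, 30, 60, 100, 150, 210, 280, 360]),
                         2)
        dl = a_true * ages ** b_true + rng.normal(0, 0.005, ages.size)
        s = _series(ages, dl, np.full(ages.size, 0.005))
        _, ens = monte_carlo_envelope(s, n_iter=250, seed=2000 + i)
        bs = []
        for c in ens.curves[::5]:
            mask = (ens.grid_ages > 0) & (c > 1e-6)
            bs.append(np.polyfit(np.log(ens.grid_ages[mask]),
                                 np.log(c[mask]), 1)[0])
        lo, hi = np.quantile(bs, [0.025, 0.975])
        hits += lo <= b_true <= hi
    assert hits >= 90
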