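"""Rate inference: OLS significance filter, kinetic classes, corrections."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpnmethane.rates import (
    CarbonFixationInput, InsufficientDataError, InvalidLabellingError,
    carbon_fixation_rate, classify_and_finalize, fit_linear_rate,
)
from mpnmethane.tracer import ExcessSeries


def series(times, excess, labelling=1.0):
    return ExcessSeries(times_h=np.asarray(times, float),
                        excess_nmol_per_l=np.asarray(excess, float),
                        correction_factors=np.ones(len(times)),
                        labelling_fraction=labelling)


def ols_normal_equations(t, y):
    """Independent brute-force OLS oracle via the normal equations."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(t)
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return beta[1], np.sqrt(cov[1, 1]), r2


class TestFitLinearRate:
    def test_collinear_points_exact_slope(self):
        s = series([0, 6, 12, 24], [0, 1, 2, 4])
        res = fit_linear_rate(s)
        assert res.slope == pytest.approx(4.0, rel=1e-12)  # 1/6 per h
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_one_sided < 1e-9
        assert res.df == 2

    def test_null_input_not_significant(self):
        res = fit_linear_rate(series([0, 6, 12, 24], [0, 0, 0, 0]))
        assert res.slope == 0.0
        assert res.p_one_sided == 1.0

    def test_four_points_give_df_2(self):
        res = fit_linear_rate(series([0, 6, 12, 24, 48], [0, .1, .3, .2, 9]))
        assert res.df == 2  # 48 h point excluded from the fit

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_linear_rate(series([0, 6, 12], [0, 1, 2]))

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_normal_equations_oracle(self, y, seed):
        t = np.array([0.0, 6.0, 12.0, 24.0])
        y = np.asarray(y) + np.random.default_rng(seed).normal(0, 1e-3, 4)
        res = fit_linear_rate(series(t, y))
        slope, se, r2 = ols_normal_equations(t, y)
        assert res.slope == pytest.approx(slope * 24, rel=1e-10, abs=1e-10)
        assert res.slope_se == pytest.approx(se * 24, rel=1e-8, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-8, abs=1e-10)


class TestClassification:
    def test_late_onset_formation_set_to_zero(self):
        s = series([0, 6, 12, 24], [0, 0, 0, 2])
        res = classify_and_finalize(fit_linear_rate(s), s)
        assert res.kinetic_class == "exponential"
        assert res.net_rate == 0.0

    def test_dic_labelling_correction(self):
        # significant linear rise, 10% labelled DIC pool -> x10 correction
        s = series([0, 6, 12, 24], [0, 0.125, 0.25, 0.5], labelling=0.10)
        res = classify_and_finalize(fit_linear_rate(s), s)
        assert res.kinetic_class == "linear_significant"
        assert res.net_rate == pytest.approx(5.0, rel=1e-9)

    def test_mpn_full_labelling_no_correction(self):
        s = series([0, 6, 12, 24], [0, 0.1, 0.2, 0.4], labelling=1.0)
        res = classify_and_finalize(fit_linear_rate(s), s)
        assert res.net_rate == pytest.approx(0.4, rel=1e-9)

    def test_weak_fit_insignificant(self):
        s = series([0, 6, 12, 24], [0, 0.3, 0.1, 0.35])
        res = classify_and_finalize(fit_linear_rate(s), s)
        assert res.kinetic_class == "insignificant"
        assert res.net_rate == 0.0

    def test_negative_slope_never_significant(self):
        s = series([0, 6, 12, 24], [0, -1, -2, -4])
        res = classify_and_finalize(fit_linear_rate(s), s)
        assert res.kinetic_class == "insignificant"
        assert res.net_rate == 0.0

    def test_detection_floor_blocks_late_onset_label(self):
        s = series([0, 6, 12, 24], [0, 0, 0, 0.1])
        res = classify_and_finalize(fit_linear_rate(s), s, detection_sd=0.05)
        assert res.kinetic_class == "insignificant"

    def test_unit_coherence_under_rescaling(self):
        """net_rate scales linearly with the excess values."""
        y = [0, 0.11, 0.19, 0.42]
        s1 = series([0, 6, 12, 24], y)
        s2 = series([0, 6, 12, 24], [v * 7.5 for v in y])
        r1 = classify_and_finalize(fit_linear_rate(s1), s1)
        r2 = classify_and_finalize(fit_linear_rate(s2), s2)
        assert r2.net_rate == pytest.approx(7.5 * r1.net_rate, rel=1e-9)
        assert r2.p_one_sided == pytest.approx(r1.p_one_sided, rel=1e-9)


class TestCarbonFixation:
    def test_hand_computed_uptake(self):
        inp = CarbonFixationInput(poc_concentration=20.0, atom_pct_poc_t0=1.08,
                                  atom_pct_poc_tf=1.58, atom_pct_dic=5.08,
                                  duration_d=1.0)
        assert carbon_fixation_rate(inp) == pytest.approx(2.5, rel=1e-12)

    def test_no_uptake_is_zero(self):
        inp = CarbonFixationInput(20.0, 1.08, 1.08, 5.08, 1.0)
        assert carbon_fixation_rate(inp) == 0.0

    def test_doubling_duration_halves_rate(self):
        a = CarbonFixationInput(20.0, 1.08, 1.58, 5.08, 1.0)
        b = CarbonFixationInput(20.0, 1.08, 1.58, 5.08, 2.0)
        assert carbon_fixation_rate(a) == pytest.approx(
            2 * carbon_fixation_rate(b))

    def test_negative_uptake_warns(self):
        inp = CarbonFixationInput(20.0, 1.08, 1.00, 5.08, 1.0)
        with pytest.warns(UserWarning):
            assert carbon_fixation_rate(inp) < 0

    def test_invalid_labelling_rejected(self):
        with pytest.raises(InvalidLabellingError):
            CarbonFixationInput(20.0, 1.08, 1.58, 1.00, 1.0)


class TestFilterCalibration:
    def test_type_i_error_of_joint_filter(self):
        """Null incubations (no production, Gaussian noise) pass the joint
        p<=0.05 & R^2>0.81 filter at most 5% of the time."""
        rng = np.random.default_rng(20260929)
        t = [0.0, 6.0, 12.0, 24.0]
        n_sims, hits = 2000, 0
        for _ in range(n_sims):
            y = np.concatenate([[0.0], rng.normal(0, 0.05, 3)])
            s = series(t, y)
            res = classify_and_finalize(fit_linear_rate(s), s)
            hits += res.kinetic_class == "linear_significant"
        assert hits / n_sims <= 0.05

    @pytest.mark.parametrize("true_rate", [0.06, 0.4, 1.3])
    def test_median_recovery_within_10_percent(self, true_rate):
        """At moderate noise, recovered net rates are centred on truth."""
        from mpnmethane.synth import SimulationConfig, simulate_incubation
        from mpnmethane.tracer import excess_13c_series
        rng = np.random.default_rng(11)
        recovered = []
        for _ in range(200):
            cfg = SimulationConfig(seed=0, true_rate=true_rate,
                                   noise_sd_excess=0.02 * true_rate)
            sim = simulate_incubation(cfg, rng=rng)
            s = excess_13c_series(sim.record)
            res = classify_and_finalize(fit_linear_rate(s), s)
            if res.kinetic_class == "linear_significant":
                recovered.append(res.net_rate)
        assert len(recovered) >= 0.8 * 200
        assert np.median(recovered) == pytest.approx(true_rate, rel=0.10)
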