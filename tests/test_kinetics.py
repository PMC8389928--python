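"""Nucleation estimators: change-point, MFPT, TPM, scaling, classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from peptagg import (
    analyze_monomer_kinetics,
    change_point_lag,
    classify_mode,
    fit_mfpt,
    mfpt_curve,
    mfpt_model,
    scale_monomer_curve,
    tpm_analysis,
)
from peptagg.fixtures import markov_chain_series
from peptagg.kinetics import MonomerKinetics, NoAggregationSignal


def _nucleated_curve(t, t_star=300.0, n0=72.0, n_eq=12.0, rate=0.02, noise=0.0, seed=0):
    """Flat lag plateau then exponential relaxation to the equilibrium level."""
    y = np.where(t < t_star, n0, n_eq + (n0 - n_eq) * np.exp(-rate * (t - t_star)))
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(t))
    return y


class TestChangePoint:
    def test_flat_then_ramp_breakpoint_recovered(self):
        t = np.arange(0.0, 400.0, 1.0)
        y = np.where(t < 100.0, 72.0, 72.0 - 0.3 * (t - 100.0))
        y += np.random.default_rng(1).normal(0, 1.0, len(t))  # mild noise
        cp = change_point_lag(t, y)
        assert cp.fired
        assert cp.t_star == pytest.approx(100.0, abs=5.0)  # a few grid points

    def test_flat_noisy_curve_has_no_change_point(self):
        t = np.arange(0.0, 200.0, 1.0)
        y = 72.0 + np.random.default_rng(2).normal(0, 1.0, len(t))
        cp = change_point_lag(t, y)
        assert cp.t_star is None and not cp.fired

    def test_decay_from_origin_is_downhill(self):
        t = np.arange(0.0, 200.0, 1.0)
        y = 72.0 * np.exp(-0.02 * t)
        cp = change_point_lag(t, y)
        assert not cp.fired
        assert cp.t_star == pytest.approx(0.0, abs=1e-12)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            change_point_lag(np.arange(5.0), np.arange(5.0))

    @pytest.mark.parametrize("t_break", [50.0, 150.0, 250.0])
    def test_bias_within_one_stride_at_high_snr(self, t_break):
        stride = 2.0
        t = np.arange(0.0, 400.0, stride)
        y = np.where(t < t_break, 60.0, 60.0 - 0.5 * (t - t_break))
        y += np.random.default_rng(3).normal(0, 0.2, len(t))
        cp = change_point_lag(t, y)
        assert cp.fired
        assert abs(cp.t_star - t_break) <= stride


class TestMonomerScaling:
    def test_scaling_endpoints(self):
        t = np.arange(0.0, 1000.0, 2.0)
        y = _nucleated_curve(t)
        km = analyze_monomer_kinetics(t, y)
        assert km.n_m_eq <= km.n_m_lag
        st_, sc = scale_monomer_curve(km)
        assert sc[0] == pytest.approx(1.0, abs=0.02)  # lag plateau -> 1
        assert sc[-1] == pytest.approx(0.0, abs=0.02)  # equilibrium -> 0

    def test_half_time_definition(self):
        t = np.arange(0.0, 1000.0, 2.0)
        km = analyze_monomer_kinetics(t, _nucleated_curve(t))
        # first time the mean curve falls to half the lag plateau, after t*
        assert km.t_half is not None and km.t_half > km.t_star
        i = np.searchsorted(t, km.t_half)
        assert km.n_m_mean[i] <= 0.5 * km.n_m_lag < km.n_m_mean[i - 1]

    def test_affinely_related_curves_collapse(self):
        t = np.arange(0.0, 2000.0, 2.0)
        curves = []
        for t_star, n0 in ((200.0, 72.0), (600.0, 40.0)):
            y = _nucleated_curve(t, t_star=t_star, n0=n0, n_eq=0.1 * n0, rate=0.01)
            km = analyze_monomer_kinetics(t, y)
            curves.append(scale_monomer_curve(km))
        # compare on the overlapping scaled-time range
        lo = max(curves[0][0][0], curves[1][0][0])
        hi = min(curves[0][0][-1], curves[1][0][-1])
        grid = np.linspace(lo, hi, 200)
        y0 = np.interp(grid, *curves[0])
        y1 = np.interp(grid, *curves[1])
        np.testing.assert_allclose(y0, y1, atol=0.05)

    def test_no_aggregation_scaling_undefined(self):
        km = MonomerKinetics(
            times=np.arange(10.0),
            n_m_mean=np.full(10, 72.0),
            n_m_lag=72.0,
            n_m_eq=72.0,
            t_star=None,
            t_half=None,
        )
        with pytest.raises(NoAggregationSignal):
            scale_monomer_curve(km)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_scaled_curve_invariant_under_affine_maps(self, gain, offset):
        """Scaling is exactly invariant to y -> gain*y + offset."""
        t = np.arange(0.0, 1000.0, 2.0)
        y = _nucleated_curve(t)
        km0 = analyze_monomer_kinetics(t, y)
        km1 = analyze_monomer_kinetics(t, gain * y + offset)
        _, s0 = scale_monomer_curve(km0)
        _, s1 = scale_monomer_curve(km1)
        np.testing.assert_allclose(s0, s1, atol=1e-9)


class TestMFPT:
    def test_deterministic_staircase(self):
        t = np.arange(0.0, 20.0, 1.0)
        m = np.floor(t).astype(int) + 1
        curve = mfpt_curve([(t, m)])
        np.testing.assert_allclose(
            curve["tau"].to_numpy(), curve["m"].to_numpy() - 1.0
        )

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_tau_nondecreasing_for_any_series(self, seed):
        rng = np.random.default_rng(seed)
        m = np.maximum.reduce(
            [np.ones(50, dtype=int), rng.integers(1, 20, size=50)]
        )
        curve = mfpt_curve([(np.arange(50.0), m)])
        assert np.all(np.diff(curve["tau"].to_numpy()) >= 0)

    def test_repeats_not_reaching_a_size_are_excluded(self):
        t = np.arange(0.0, 10.0, 1.0)
        full = np.arange(1, 11)
        stuck = np.minimum(np.arange(1, 11), 4)
        curve = mfpt_curve([(t, full), (t, stuck)]).set_index("m")
        assert curve.loc[4, "n_reached"] == 2
        assert curve.loc[5, "n_reached"] == 1
        assert curve.loc[5, "tau"] == 4.0  # only the full repeat contributes

    def test_model_value_at_critical_size(self):
        # erf(0) = 0: the nucleation term contributes tau*/2 at m = m*
        assert mfpt_model(8.0, 8.0, 0.05, 0.2, 500.0) == pytest.approx(250.0)

    def test_tail_slope_is_inverse_growth_rate(self):
        g = 0.04
        m = np.array([100.0, 101.0])
        tau = mfpt_model(m, 8.0, g, 0.2, 500.0)
        assert (tau[1] - tau[0]) == pytest.approx(1.0 / g, rel=1e-6)

    def test_exact_recovery_on_noiseless_curve(self):
        m = np.arange(2, 40, dtype=float)
        truth = (8.0, 0.05, 0.2, 500.0)
        fit = fit_mfpt(m, mfpt_model(m, *truth))
        for got, want in zip(fit, truth):
            assert got == pytest.approx(want, rel=0.01)

    @pytest.mark.parametrize("m_star", [4.0, 8.0, 12.0, 16.0])
    @pytest.mark.parametrize("z", [0.05, 0.2, 0.5])
    def test_recovery_across_parameter_grid(self, m_star, z):
        m = np.arange(2, 40, dtype=float)
        truth = (m_star, 0.08, z, 800.0)
        fit = fit_mfpt(m, mfpt_model(m, *truth))
        for got, want in zip(fit, truth):
            assert got == pytest.approx(want, rel=0.01)


class TestTPM:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        series = markov_chain_series(
            np.full(11, 0.3), np.full(11, 0.3), 2000, 5, rng
        )
        res = tpm_analysis(series)
        np.testing.assert_allclose(res.matrix.sum(axis=1), 1.0)

    def test_uniform_up_bias_gives_smallest_state(self):
        rng = np.random.default_rng(6)
        series = markov_chain_series(
            np.full(21, 0.7), np.full(21, 0.1), 3000, 2, rng
        )
        res = tpm_analysis(series)
        table = res.table[res.table["n_transitions"] >= 20]  # well-sampled states
        assert np.all(table["P_growth"].to_numpy()[table["m"] < 20] > 0)
        assert res.m_star == max(2, int(res.table["m"].min()))

    def test_birth_death_barrier_crossing_at_eight(self):
        # down-bias below m = 8, up-bias at and above -> m* = 8
        top = 14
        p_up = np.where(np.arange(top + 1) < 8, 0.15, 0.6)
        p_down = np.where(np.arange(top + 1) < 8, 0.6, 0.15)
        rng = np.random.default_rng(7)
        series = [
            markov_chain_series(p_up, p_down, 400, m0, rng)
            for m0 in range(2, top)
            for _ in range(30)
        ]
        res = tpm_analysis(series)
        assert res.m_star == 8

    @pytest.mark.parametrize("seed", range(8))
    def test_crossing_point_matches_construction(self, seed):
        """m* equals the designed drift sign change for random chains."""
        rng = np.random.default_rng(seed)
        top = int(rng.integers(10, 18))
        m_star = int(rng.integers(4, top - 2))
        margin = 0.2
        p_up = np.where(np.arange(top + 1) < m_star, 0.4 - margin, 0.4 + margin)
        p_down = np.where(np.arange(top + 1) < m_star, 0.4 + margin, 0.4 - margin)
        series = [
            markov_chain_series(p_up, p_down, 300, m0, rng)
            for m0 in range(2, top)
            for _ in range(40)
        ]
        res = tpm_analysis(series)
        assert res.m_star == m_star

    def test_coalescence_jumps_dilute_but_do_not_enter_pf_pb(self):
        series = np.array([3, 4, 3, 4, 3, 7, 3, 4, 3, 4])
        res = tpm_analysis(series)
        row3 = res.table.set_index("m").loc[3]
        # 5 exits from state 3: four to 4, one jump to 7
        assert row3["n_transitions"] == 5
        assert row3["P_f"] == pytest.approx(4 / 5)
        sign = tpm_analysis(series, count_jumps="sign").table.set_index("m").loc[3]
        assert sign["P_f"] == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            tpm_analysis(np.array([3]))


class TestClassifier:
    def _times(self):
        return np.arange(0.0, 1000.0, 2.0)

    def test_flat_monomers_no_aggregation(self):
        t = self._times()
        rng = np.random.default_rng(8)
        n_m = 72.0 + rng.normal(0, 1.5, (3, len(t)))
        m_max = np.clip(rng.poisson(1.5, (3, len(t))), 1, 3).astype(float)
        res = classify_mode(t, n_m, m_max, 72)
        assert res.mode == "no-aggregation"

    def test_plateau_then_decay_nucleated(self):
        t = self._times()
        n_m = _nucleated_curve(t, t_star=400.0, noise=1.0)[None, :]
        m_max = np.where(t < 400.0, 2.0, np.minimum(2 + 0.1 * (t - 400.0), 40))[None, :]
        res = classify_mode(t, n_m, m_max, 72)
        assert res.mode == "nucleated"
        assert res.change_point.t_star == pytest.approx(400.0, abs=20.0)

    def test_decay_from_origin_downhill(self):
        t = self._times()
        n_m = (72.0 * np.exp(-0.01 * t))[None, :]
        m_max = np.minimum(1 + 0.08 * t, 50)[None, :]
        res = classify_mode(t, n_m, m_max, 72)
        assert res.mode == "downhill"

    def test_transient_oligomers_without_stable_cluster_not_aggregation(self):
        """Fast monomer/oligomer equilibration alone must not read as downhill."""
        t = self._times()
        rng = np.random.default_rng(9)
        n_m = np.where(t < 30, 72 - t, 42.0) + rng.normal(0, 2.0, len(t))
        m_max = np.clip(rng.poisson(2.0, len(t)), 1, 4).astype(float)
        res = classify_mode(t, n_m[None, :], m_max[None, :], 72)
        assert res.mode == "no-aggregation"
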