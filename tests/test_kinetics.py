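"""Haldane rate law, peak, dominance, crossover, fitting and grid search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paok import (
    DegenerateCurvesError,
    DominanceObservation,
    KineticParams,
    crossover_concentrations,
    crossover_quadratic,
    dominant_label,
    fit_params,
    peak_concentration,
    rate_curve,
    search_explaining_params,
    specific_rate,
)
from conftest import random_params

params_strategy = st.builds(
    KineticParams,
    label=st.just("X"),
    vmax=st.floats(0.1, 10.0),
    km=st.floats(0.01, 100.0),
    ki=st.floats(1.0, 1e5),
)


class TestSpecificRate:
    def test_zero_substrate_gives_zero_rate(self, type_i):
        assert specific_rate(type_i, 0.0) == 0.0

    def test_hand_evaluated_value(self, type_ii):
        # 1.0*0.5 / ((0.5+0.5)*(1+0.5/300))
        assert specific_rate(type_ii, 0.5) == pytest.approx(0.4992, abs=5e-5)

    def test_michaelis_menten_limit(self):
        params = KineticParams("X", vmax=1.0, km=0.5, ki=1e12)
        assert specific_rate(params, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_negative_concentration_rejected(self, type_i):
        with pytest.raises(ValueError):
            specific_rate(type_i, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(params=params_strategy, s=st.floats(1e-6, 1e6))
    def test_rate_positive_and_below_vmax(self, params, s):
        nu = specific_rate(params, s)
        assert 0.0 < nu < params.vmax

    @settings(derandomize=True, max_examples=30)
    @given(params=params_strategy, s=st.floats(0.0, 1000.0))
    def test_large_ki_reduces_to_michaelis_menten(self, params, s):
        # the relaxed-inhibition bound holds over the working 0-1000 mg/L range
        relaxed = KineticParams(params.label, params.vmax, params.km, 1e9)
        mm = params.vmax * s / (params.km + s)
        assert abs(specific_rate(relaxed, s) - mm) < 1e-6 * params.vmax


class TestPeakConcentration:
    @pytest.mark.parametrize(
        "km, ki, expected",
        [(0.5, 300.0, 12.247448), (0.48, 2000.0, 30.983867), (1.0, 1.0, 1.0)],
    )
    def test_closed_form(self, km, ki, expected):
        params = KineticParams("X", vmax=1.0, km=km, ki=ki)
        assert peak_concentration(params) == pytest.approx(expected, rel=1e-6)

    @settings(derandomize=True, max_examples=25)
    @given(params=params_strategy)
    def test_matches_grid_argmax(self, params):
        peak = peak_concentration(params)
        grid = np.geomspace(peak / 100, peak * 100, 10_000)
        argmax = grid[np.argmax(specific_rate(params, grid))]
        step = grid[1] / grid[0]  # log-spacing ratio
        assert peak / step <= argmax <= peak * step

    def test_unimodal_around_peak(self, type_ii):
        peak = peak_concentration(type_ii)
        rising = np.linspace(1e-6, peak, 10_000)
        falling = np.linspace(peak, 50 * peak, 10_000)
        assert np.all(np.diff(specific_rate(type_ii, rising)) > 0)
        assert np.all(np.diff(specific_rate(type_ii, falling)) < 0)


class TestRateCurve:
    def test_rank_swaps_across_the_concentration_range(self, reference_pair):
        curve = rate_curve(reference_pair, [0.05, 0.5, 5, 50, 500])
        nu_i, nu_ii = curve.rates["Type I"], curve.rates["Type II"]
        assert nu_ii[1] > nu_i[1] and nu_ii[2] > nu_i[2]  # 0.5 and 5
        assert nu_i[3] > nu_ii[3] and nu_i[4] > nu_ii[4]  # 50 and 500

    def test_single_population_zero_grid(self, type_i):
        curve = rate_curve([type_i], [0.0])
        assert curve.rates["Type I"][0] == 0.0

    def test_empty_grid_rejected(self, reference_pair):
        with pytest.raises(ValueError):
            rate_curve(reference_pair, [])

    def test_duplicate_labels_rejected(self, type_i):
        with pytest.raises(ValueError):
            rate_curve([type_i, type_i], [1.0])


class TestDominantLabel:
    @pytest.mark.parametrize("s, winner", [(50.0, "Type I"), (5.0, "Type II")])
    def test_reference_pair_outcomes(self, reference_pair, s, winner):
        assert dominant_label(reference_pair, s) == winner

    def test_identical_populations_tie(self, type_i):
        clone = KineticParams("Copy", type_i.vmax, type_i.km, type_i.ki)
        assert dominant_label([type_i, clone], 7.0) == "tie"

    def test_antisymmetric_in_population_order(self, reference_pair):
        a, b = reference_pair
        for s in (0.5, 5.0, 50.0, 500.0):
            assert dominant_label([a, b], s) == dominant_label([b, a], s)

    def test_negative_concentration_rejected(self, reference_pair):
        with pytest.raises(ValueError):
            dominant_label(reference_pair, -0.1)


def brute_force_crossovers(a, b, lo=1e-3, hi=1000.0, step=1e-3):
    """Independent oracle: sign-change scan of the rate difference on a
    uniformly spaced grid."""
    grid = np.arange(lo, hi + step, step)
    diff = specific_rate(a, grid) - specific_rate(b, grid)
    idx = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
    return [(grid[i] + grid[i + 1]) / 2 for i in idx]


class TestCrossover:
    def test_reference_pair_root(self, reference_pair):
        roots = crossover_concentrations(*reference_pair)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(18.348, abs=1e-2)
        oracle = brute_force_crossovers(*reference_pair)
        assert abs(roots[0] - oracle[0]) < 1e-3

    def test_agrees_with_closed_form_quadratic(self, reference_pair):
        numeric = crossover_concentrations(*reference_pair)
        analytic = [r for r in crossover_quadratic(*reference_pair) if r <= 1000]
        assert numeric == pytest.approx(analytic, rel=1e-8)

    def test_identical_curves_degenerate(self, type_i):
        clone = KineticParams("Copy", type_i.vmax, type_i.km, type_i.ki)
        with pytest.raises(DegenerateCurvesError):
            crossover_concentrations(type_i, clone)

    def test_vmax_only_difference_never_crosses(self):
        a = KineticParams("A", vmax=1.0, km=0.5, ki=300.0)
        b = KineticParams("B", vmax=1.2, km=0.5, ki=300.0)
        assert crossover_concentrations(a, b) == []

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = random_params(rng, "A")
            b = random_params(rng, "B")
            found = crossover_concentrations(a, b)
            oracle = brute_force_crossovers(a, b)
            assert len(found) == len(oracle)
            for root, approx in zip(found, sorted(oracle)):
                assert abs(root - approx) < 1e-3


class TestFitParams:
    def test_noiseless_recovery_is_exact(self, type_ii):
        s_grid = np.geomspace(0.05, 500, 8)
        obs = [(s, specific_rate(type_ii, s)) for s in s_grid]
        init = KineticParams("Type II", vmax=0.5, km=1.0, ki=1000.0)
        result = fit_params(obs, init)
        assert result.converged
        for name in ("vmax", "km", "ki"):
            truth = getattr(type_ii, name)
            est = getattr(result.params, name)
            assert abs(est - truth) / truth <= 1e-6

    def test_log_loss_noiseless_recovery(self, type_i):
        s_grid = np.geomspace(0.05, 500, 8)
        obs = [(s, specific_rate(type_i, s)) for s in s_grid]
        init = KineticParams("Type I", vmax=0.5, km=1.0, ki=1000.0)
        result = fit_params(obs, init, loss="log")
        assert result.converged
        assert result.params.km == pytest.approx(type_i.km, rel=1e-5)

    def test_too_few_observations_rejected(self, type_i):
        obs = [(s, specific_rate(type_i, s)) for s in (0.1, 1.0, 10.0)]
        with pytest.raises(ValueError):
            fit_params(obs, type_i)

    def test_single_design_point_rejected(self, type_i):
        obs = [(1.0, 0.5)] * 5
        with pytest.raises(ValueError):
            fit_params(obs, type_i)


class TestSearchExplainingParams:
    GRID = {
        "Type I": {"vmax": [0.95], "km": [0.48, 0.6], "ki": [2000.0, 300.0]},
        "Type II": {"vmax": [1.0], "km": [0.5], "ki": [300.0, 2000.0]},
    }
    OBSERVED = [
        DominanceObservation(0.5, "Type II"),
        DominanceObservation(5.0, "Type II"),
        DominanceObservation(50.0, "Type I"),
        DominanceObservation(500.0, "Type I"),
    ]

    def test_reference_pair_is_retained(self, reference_pair):
        retained = search_explaining_params(self.OBSERVED, self.GRID)
        assert tuple(reference_pair) in retained

    def test_contradictory_observations_yield_nothing(self):
        contradictory = [
            DominanceObservation(5.0, "Type I"),
            DominanceObservation(5.0, "Type II"),
        ]
        assert search_explaining_params(contradictory, self.GRID) == []

    def test_single_matching_pair_grid(self, reference_pair):
        grid = {
            "Type I": {"vmax": [0.95], "km": [0.48], "ki": [2000.0]},
            "Type II": {"vmax": [1.0], "km": [0.5], "ki": [300.0]},
        }
        retained = search_explaining_params(
            [DominanceObservation(50.0, "Type I")], grid
        )
        assert retained == [tuple(reference_pair)]
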