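"""Numerical curve analysis: inflection detection against closed forms,
intersection against brute force, grid convergence and P50 root finding."""

import numpy as np
import pytest

from hbcurve import (
    DissociationCurve,
    NoInflectionError,
    NoIntersectionError,
    find_inflection,
    find_intersection,
    find_p50,
    in_vitro_curve,
    make_grid,
    p50,
)
from hbcurve.curves import DEFAULT_GRID_STEP

from conftest import random_states


def hill_curve(n=2.8, p50_=26.8, step=DEFAULT_GRID_STEP, lo=0.0, hi=100.0):
    grid = make_grid(lo, hi, step)
    vals = grid**n / (grid**n + p50_**n)
    return DissociationCurve(grid, vals, label="ODC")


def hill_inflection_closed_form(n, p50_):
    # zero of the second derivative of x^n/(x^n + p^n)
    return p50_ * ((n - 1.0) / (n + 1.0)) ** (1.0 / n)


class TestFindInflection:
    def test_hill_curve_matches_closed_form(self):
        curve = hill_curve()
        expected = hill_inflection_closed_form(2.8, 26.8)
        infl = find_inflection(curve)
        assert infl.PO2 == pytest.approx(expected, abs=2 * curve.step)
        assert infl.second_derivative_bracket[0] < infl.PO2 < infl.second_derivative_bracket[1]

    def test_straight_line_has_no_inflection(self):
        grid = make_grid()
        with pytest.raises(NoInflectionError):
            find_inflection(DissociationCurve(grid, grid / 100.0))

    def test_centered_cubic_inflects_at_center(self):
        # decreasing cubic, concave-up below 30 and concave-down above
        grid = make_grid(0.0, 60.0)
        vals = (27000.0 - (grid - 30.0) ** 3) / 54000.0  # rescaled into [0,1]
        infl = find_inflection(DissociationCurve(grid, vals), window=(2.0, 58.0))
        assert infl.PO2 == pytest.approx(30.0, abs=2 * 0.05)

    def test_grid_refinement_moves_result_below_tolerance(self):
        results = {}
        for step in (0.05, 0.025):
            state_curve = hill_curve(step=step)
            results[step] = find_inflection(state_curve).PO2
        assert abs(results[0.05] - results[0.025]) < 0.01

    def test_model_odc_inflection_grid_convergence(self, standard_state):
        results = {}
        for step in (0.05, 0.025):
            curve = in_vitro_curve(standard_state, "ODC", grid=make_grid(step=step))
            results[step] = find_inflection(curve).PO2
        assert abs(results[0.05] - results[0.025]) < 0.01


class TestFindIntersection:
    def test_crossing_straight_lines(self):
        grid = make_grid()
        a = DissociationCurve(grid, grid / 100.0)
        b = DissociationCurve(grid, 1.0 - grid / 100.0)
        assert find_intersection(a, b) == pytest.approx(50.0, abs=1e-9)

    def test_identical_curves_raise(self):
        grid = make_grid()
        a = DissociationCurve(grid, grid / 100.0)
        with pytest.raises(NoIntersectionError):
            find_intersection(a, DissociationCurve(grid, grid / 100.0))

    def test_two_hill_curves_against_brute_force(self):
        a = hill_curve(n=2.8, p50_=26.8)
        b = hill_curve(n=1.9, p50_=32.0)
        found = find_intersection(a, b, window=(1.0, 100.0))

        def diff(x):
            return np.abs(
                x**2.8 / (x**2.8 + 26.8**2.8) - x**1.9 / (x**1.9 + 32.0**1.9)
            )

        # brute-force oracle on the exact functions: coarse 1e-3 scan, then a
        # local 1e-6 scan around the coarse minimum
        coarse = np.arange(1.0, 100.0, 1e-3)
        x0 = coarse[np.argmin(diff(coarse))]
        fine = np.arange(x0 - 2e-3, x0 + 2e-3, 1e-6)
        brute = fine[np.argmin(diff(fine))]
        # agreement limited by linear interpolation of the sampled curves
        assert found == pytest.approx(brute, abs=a.step)

    def test_symmetric_in_arguments(self):
        a = hill_curve(n=2.8, p50_=26.8)
        b = hill_curve(n=1.9, p50_=32.0)
        assert find_intersection(a, b, window=(1.0, 100.0)) == pytest.approx(
            find_intersection(b, a, window=(1.0, 100.0)), abs=1e-9
        )

    def test_grid_refinement_stability(self):
        results = {}
        for step in (0.05, 0.025):
            a = hill_curve(n=2.8, p50_=26.8, step=step)
            b = hill_curve(n=1.9, p50_=32.0, step=step)
            results[step] = find_intersection(a, b, window=(1.0, 100.0))
        assert abs(results[0.05] - results[0.025]) < 0.01


class TestFindP50:
    def test_standard_state(self, standard_state):
        assert find_p50(standard_state) == pytest.approx(26.8, abs=1e-6)

    def test_agrees_with_closed_form_on_random_states(self):
        for state in random_states(100, seed=21):
            assert find_p50(state) == pytest.approx(p50(state), abs=1e-6)

    def test_acidosis_moves_root_right(self, standard_state):
        acidotic = standard_state.replace(pH_rbc=standard_state.pH_rbc - 0.2)
        assert find_p50(acidotic) > find_p50(standard_state)


class TestInVitroCurves:
    def test_odc_fixed_points(self, standard_state):
        curve = in_vitro_curve(standard_state, "ODC")
        assert curve.values[0] == 0.0
        assert float(curve(26.8)) == pytest.approx(0.5, abs=1e-4)

    def test_cdc_haldane_direction(self, standard_state):
        curve = in_vitro_curve(standard_state, "CDC")
        assert np.all(np.diff(curve.values[1:]) < 0)

    def test_hdc_variants_ordered(self, standard_state):
        total = in_vitro_curve(standard_state, "HDC")
        deoxy = in_vitro_curve(standard_state, "HDC_deoxy")
        assert np.all(total.values >= deoxy.values)

    def test_csv_round_trip(self, standard_state, tmp_path):
        curve = in_vitro_curve(standard_state, "ODC")
        path = tmp_path / "odc.csv"
        curve.to_csv(path)
        back = DissociationCurve.from_csv(path)
        np.testing.assert_allclose(back.grid, curve.grid, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.values, curve.values, rtol=0, atol=1e-12)
        assert back.label == "ODC" and back.provenance == "in_vitro"

    def test_validation_rejects_bad_curves(self):
        with pytest.raises(ValueError):
            DissociationCurve(np.arange(10.0), np.zeros(10))  # too few points
        grid = make_grid()
        with pytest.raises(ValueError):
            DissociationCurve(grid, np.full(grid.size, 1.5))  # out of [0,1]
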