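"""G-cross estimation: closed form, estimators vs brute-force oracle, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from timescape.spatial import (
    EmptyTypeError,
    GCrossCurve,
    Window,
    default_radii,
    gcross_arrays,
    gcross_at,
    gcross_auc,
    gcross_empirical,
    gcross_theoretical,
    gcross_within_neighborhood,
)
from conftest import gcross_bruteforce


class TestTheoretical:
    def test_zero_radius_and_empty_process(self):
        assert gcross_theoretical(0.01, 0.0) == 0.0
        assert gcross_theoretical(0.0, 55.0) == 0.0

    def test_half_probability_at_inverted_closed_form(self):
        # alpha * pi * r^2 = ln 2  =>  G = 1/2
        alpha = np.log(2) / (100 * np.pi)
        assert gcross_theoretical(alpha, 10.0) == pytest.approx(0.5, abs=1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            gcross_theoretical(-0.1, 10.0)
        with pytest.raises(ValueError):
            gcross_theoretical(0.1, -1.0)


class TestEmpirical:
    def test_single_pair_345_distance(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "x_um": [50.0, 53.0], "y_um": [50.0, 54.0],
             "phenotype": ["i", "j"]}
        )
        w = Window(100, 100)
        radii = np.array([0.0, 4.9, 5.0, 10.0])
        curve = gcross_empirical(cells, "i", "j", radii, w, "raw")
        np.testing.assert_array_equal(curve.values, [0.0, 0.0, 1.0, 1.0])

    def test_border_correction_keeps_interior_reference(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "x_um": [50.0, 53.0], "y_um": [50.0, 54.0],
             "phenotype": ["i", "j"]}
        )
        curve = gcross_empirical(cells, "i", "j", np.array([5.0]), Window(100, 100), "border")
        assert curve.values[0] == 1.0

    def test_border_correction_undefined_when_all_censored(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "x_um": [1.0, 50.0], "y_um": [1.0, 50.0],
             "phenotype": ["i", "j"]}
        )
        curve = gcross_empirical(cells, "i", "j", np.array([10.0]), Window(100, 100), "border")
        assert np.isnan(curve.values[0])

    def test_missing_type_raises(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "x_um": [1.0], "y_um": [1.0], "phenotype": ["i"]}
        )
        with pytest.raises(EmptyTypeError):
            gcross_empirical(cells, "i", "j", np.array([5.0]), Window(100, 100))

    def test_coincident_points_count_at_every_radius(self):
        xy = np.array([[10.0, 10.0]])
        vals = gcross_arrays(xy, xy.copy(), np.array([0.0, 1.0]), Window(100, 100), "raw")
        np.testing.assert_array_equal(vals, [1.0, 1.0])

    def test_same_type_excludes_self(self):
        xy = np.array([[10.0, 10.0], [13.0, 14.0]])
        vals = gcross_arrays(xy, xy, np.array([0.0, 5.0]), Window(100, 100), "raw",
                             same_type=True)
        np.testing.assert_array_equal(vals, [0.0, 1.0])

    @pytest.mark.parametrize("correction", ["raw", "border"])
    def test_matches_bruteforce_oracle(self, correction):
        rng = np.random.default_rng(5)
        w = Window(200, 150)
        radii = np.arange(0.0, 81.0, 7.5)
        for _ in range(10):
            ni, nj = rng.integers(2, 60, 2)
            xi = rng.uniform([0, 0], [200, 150], (ni, 2))
            xj = rng.uniform([0, 0], [200, 150], (nj, 2))
            got = gcross_arrays(xi, xj, radii, w, correction)
            want = gcross_bruteforce(xi, xj, radii, w, correction)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)

    def test_exchange_asymmetry_both_match_oracle(self):
        # one isolated i-point far away makes G_{i,j} != G_{j,i}
        xi = np.array([[10.0, 10.0], [90.0, 90.0]])
        xj = np.array([[12.0, 10.0]])
        w = Window(100, 100)
        radii = np.array([5.0, 50.0])
        g_ij = gcross_arrays(xi, xj, radii, w, "raw")
        g_ji = gcross_arrays(xj, xi, radii, w, "raw")
        np.testing.assert_allclose(g_ij, gcross_bruteforce(xi, xj, radii, w))
        np.testing.assert_allclose(g_ji, gcross_bruteforce(xj, xi, radii, w))
        assert not np.allclose(g_ij, g_ji)

    @given(st.integers(0, 2**31 - 1))
    def test_raw_estimator_is_a_cdf(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        xi = rng.uniform(0, 100, (n, 2))
        xj = rng.uniform(0, 100, (max(1, n // 2), 2))
        vals = gcross_arrays(xi, xj, default_radii(100, 5), Window(100, 100), "raw")
        assert np.all(vals >= 0) and np.all(vals <= 1)
        assert np.all(np.diff(vals) >= 0)


class TestSummaries:
    def _curve(self, radii, values):
        return GCrossCurve("i", "j", np.asarray(radii, float),
                           np.asarray(values, float), "raw", 1, 1, 0.001)

    def test_interpolation_midpoint_and_grid_points(self):
        c = self._curve([0, 10], [0, 0.5])
        assert gcross_at(c, 5) == pytest.approx(0.25)
        assert gcross_at(c, 10) == 0.5
        with pytest.raises(ValueError):
            gcross_at(c, 11)

    @given(st.integers(0, 2**31 - 1))
    def test_interpolation_bounded_by_neighbors(self, seed):
        rng = np.random.default_rng(seed)
        radii = np.sort(rng.uniform(0, 80, 6))
        values = np.sort(rng.uniform(0, 1, 6))
        c = self._curve(radii, values)
        r = float(rng.uniform(radii[0], radii[-1]))
        k = np.searchsorted(radii, r, side="right") - 1
        k = min(k, len(radii) - 2)
        v = gcross_at(c, r)
        assert values[k] - 1e-12 <= v <= values[k + 1] + 1e-12

    def test_auc_constant_triangle_zero(self):
        radii = np.arange(0.0, 81.0)
        assert gcross_auc(self._curve(radii[:41], np.ones(41)), 40) == pytest.approx(40)
        assert gcross_auc(self._curve(radii, radii / 80), 80) == pytest.approx(40)
        assert gcross_auc(self._curve(radii, np.zeros(81)), 80) == 0.0

    def test_auc_respans_missing_values(self):
        values = np.array([0.0, np.nan, 1.0, 1.0])
        c = self._curve([0.0, 10.0, 20.0, 30.0], values)
        # trapezoid over (0,0)-(20,1)-(30,1)
        assert gcross_auc(c, 30) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            gcross_auc(self._curve([0.0], [np.nan]), 0.0)


class TestWithinNeighborhood:
    def _cells(self):
        rng = np.random.default_rng(12)
        n = 60
        return pd.DataFrame(
            {
                "sample_id": "s",
                "x_um": rng.uniform(0, 100, n),
                "y_um": rng.uniform(0, 100, n),
                "phenotype": rng.choice(["i", "j"], n),
            }
        )

    def test_full_membership_equals_global(self):
        cells = self._cells()
        mem = pd.DataFrame({"N": True}, index=cells.index)
        radii = np.arange(0.0, 41.0, 5)
        a = gcross_within_neighborhood(cells, mem, "N", "i", "j", radii, Window(100, 100))
        b = gcross_empirical(cells, "i", "j", radii, Window(100, 100))
        np.testing.assert_allclose(a.values, b.values, equal_nan=True)

    def test_no_members_raises(self):
        cells = self._cells()
        mem = pd.DataFrame({"N": False}, index=cells.index)
        with pytest.raises(EmptyTypeError):
            gcross_within_neighborhood(cells, mem, "N", "i", "j",
                                       np.array([10.0]), Window(100, 100))

    def test_eight_cell_configuration_matches_oracle(self):
        cells = pd.DataFrame(
            {
                "sample_id": "s",
                "x_um": [10, 20, 30, 40, 55, 60, 70, 85.0],
                "y_um": [10, 25, 35, 45, 50, 60, 75, 80.0],
                "phenotype": ["i", "i", "j", "i", "j", "j", "i", "j"],
            }
        )
        member = pd.DataFrame({"N": [True, False, True, True, True, False, False, True]},
                              index=cells.index)
        radii = np.arange(0.0, 51.0, 10)
        w = Window(100, 100)
        curve = gcross_within_neighborhood(cells, member, "N", "i", "j", radii, w, "raw")
        is_i = (cells["phenotype"] == "i") & member["N"]
        xi = cells.loc[is_i, ["x_um", "y_um"]].to_numpy(float)
        xj = cells.loc[cells["phenotype"] == "j", ["x_um", "y_um"]].to_numpy(float)
        np.testing.assert_allclose(curve.values, gcross_bruteforce(xi, xj, radii, w))
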