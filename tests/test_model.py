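"""Tests of the cylinder + paracrystalline-lattice intensity model.

Independent oracles: a power-series Bessel J1, a hand-written two-factor
lattice formula, and brute-force dense-grid averaging that never calls the
implementation's quadrature or psi grid.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilsas import model
from fibrilsas.model import (
    LatticeConfig,
    ModelParams,
    RadiusDistribution,
    cylinder_amplitude,
    i_cyl,
    lattice_factor,
    params_from_dict,
    psi_averaged_Z,
    radius_quadrature,
    reduced_turning_point,
    total_intensity,
    turning_point,
)


def j1_series(x: float, terms: int = 60) -> float:
    """Power-series oracle for the Bessel function J1."""
    total = 0.0
    for m in range(terms):
        total += ((-1) ** m / (math.factorial(m) * math.factorial(m + 1))
                  * (x / 2.0) ** (2 * m + 1))
    return total


class TestCylinderAmplitude:
    def test_forward_limit_is_disc_area(self):
        assert cylinder_amplitude(0.0, 10.0) == pytest.approx(np.pi * 100.0, rel=1e-12)
        # smooth approach to the limit
        assert cylinder_amplitude(1e-8, 10.0) == pytest.approx(np.pi * 100.0, rel=1e-9)

    def test_zero_at_first_bessel_zero(self):
        x0 = 3.8317059702075125
        assert abs(cylinder_amplitude(x0 / 7.0, 7.0)) < 1e-10

    def test_matches_series_oracle(self):
        q, R = 0.15, 12.5
        expected = np.pi * R**2 * 2.0 * j1_series(q * R) / (q * R)
        assert cylinder_amplitude(q, R) == pytest.approx(expected, rel=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            cylinder_amplitude(0.1, -1.0)


class TestRadiusQuadrature:
    def test_degenerate_distribution_single_node(self):
        nodes, w = radius_quadrature(RadiusDistribution(10.0, 0.0))
        assert nodes.tolist() == [10.0]
        assert w.tolist() == [1.0]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(mean=st.floats(1.0, 50.0), rel=st.floats(0.0, 0.5))
    def test_weights_normalized_nodes_nonnegative(self, mean, rel):
        nodes, w = radius_quadrature(RadiusDistribution(mean, rel * mean))
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(nodes >= 0.0)

    def test_clipped_interval_against_density_oracle(self):
        """Wide distribution: lower bound clips at 0, weights follow the density."""
        dist = RadiusDistribution(1.0, 2.0, n_points=11, truncation_k=3.0)
        nodes, w = radius_quadrature(dist)
        expected_nodes = np.linspace(0.0, 7.0, 11)
        dens = np.exp(-0.5 * ((expected_nodes - 1.0) / 2.0) ** 2)
        np.testing.assert_allclose(nodes, expected_nodes, atol=1e-14)
        np.testing.assert_allclose(w, dens / dens.sum(), rtol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            RadiusDistribution(10.0, -1.0)
        with pytest.raises(ValueError):
            RadiusDistribution(10.0, 1.0, n_points=4)


class TestLatticeFactor:
    def test_disorder_dominated_limit(self):
        lat = LatticeConfig(42.0, 11.3)
        psi = np.linspace(0, 2 * np.pi, 13)
        np.testing.assert_allclose(lattice_factor(5.0, psi, lat), 1.0, rtol=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(q=st.floats(0.02, 0.5), psi=st.floats(0.0, 2 * np.pi))
    def test_inversion_symmetry(self, q, psi):
        lat = LatticeConfig(42.0, 11.3)
        assert lattice_factor(q, psi, lat) == pytest.approx(
            lattice_factor(q, psi + np.pi, lat), rel=1e-12)

    def test_matches_independent_rederivation(self):
        q, psi, a, da = 0.15, 0.0, 42.0, 11.3
        g = math.exp(-(q * da) ** 2 / 2.0)

        def zk(psik):
            c = math.cos(q * a * math.cos(psi - psik))
            return (1 - g * g) / (1 - 2 * g * c + g * g)

        expected = zk(0.0) * zk(math.pi / 3.0)
        got = lattice_factor(q, psi, LatticeConfig(a, da))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got >= 0.0


class TestPsiAverage:
    def test_high_q_limit(self):
        for a, rel in [(42.0, 0.27), (10.0, 0.1), (60.0, 0.4)]:
            lat = LatticeConfig(a, rel * a)
            q = 250.0 / a  # q*a > 200
            assert psi_averaged_Z(q, lat) == pytest.approx(1.0, rel=0.01)

    def test_scale_invariance(self):
        lat1 = LatticeConfig(42.0, 0.27 * 42.0)
        lat2 = LatticeConfig(10.5, 0.27 * 10.5)  # s = 1/4
        q = np.array([0.05, 0.1, 0.15, 0.2])
        np.testing.assert_allclose(
            psi_averaged_Z(q, lat1), psi_averaged_Z(q * 4.0, lat2), rtol=1e-12)

    def test_principal_maximum_against_dense_scan(self):
        """Correlation maximum near q*a = 2 pi, confirmed on 10x finer grids."""
        a, rel = 42.0, 0.27
        lat = LatticeConfig(a, rel * a)
        q = np.linspace(0.08, 0.22, 281)
        z = psi_averaged_Z(q, lat)
        q_peak = q[np.argmax(z)]

        psi = np.linspace(0.0, 2 * np.pi, 10010, endpoint=False)
        qd = np.linspace(0.08, 0.22, 2801)
        g = np.exp(-0.5 * (qd * rel * a) ** 2)[:, None]
        qa = (qd * a)[:, None]
        z1 = (1 - g**2) / (1 - 2 * g * np.cos(qa * np.cos(psi)) + g**2)
        z2 = (1 - g**2) / (1 - 2 * g * np.cos(qa * np.cos(psi - np.pi / 3)) + g**2)
        dense = (z1 * z2).mean(axis=1)
        q_peak_oracle = qd[np.argmax(dense)]

        assert q_peak == pytest.approx(q_peak_oracle, abs=2 * (q[1] - q[0]))
        assert 0.8 * 2 * np.pi / a < q_peak < 1.2 * 2 * np.pi / a


class TestTurningPoint:
    def test_reduced_invariant_exact(self):
        tp1 = turning_point(LatticeConfig(10.0, 2.0))
        tp2 = turning_point(LatticeConfig(40.0, 8.0))
        assert tp1.q0 * 10.0 == pytest.approx(tp2.q0 * 40.0, rel=1e-12)
        assert tp1.plateau == pytest.approx(tp2.plateau, rel=1e-12)

    def test_against_brute_force_scan(self):
        """First minimum of the averaged factor for a = 10 A, da/a = 0.2."""
        a, rel = 10.0, 0.2
        psi = np.linspace(0.0, 2 * np.pi, 10010, endpoint=False)
        x = np.arange(0.5, 6.0, 1e-3)
        g = np.exp(-0.5 * (x * rel) ** 2)[:, None]
        xc = x[:, None]
        z1 = (1 - g**2) / (1 - 2 * g * np.cos(xc * np.cos(psi)) + g**2)
        z2 = (1 - g**2) / (1 - 2 * g * np.cos(xc * np.cos(psi - np.pi / 3)) + g**2)
        avg = (z1 * z2).mean(axis=1)
        interior = np.flatnonzero((avg[1:-1] < avg[:-2]) & (avg[1:-1] <= avg[2:])) + 1
        x0_oracle = x[interior[0]]

        tp = turning_point(LatticeConfig(a, rel * a))
        assert tp.q0 * a == pytest.approx(x0_oracle, abs=5e-3)
        assert tp.plateau == pytest.approx(avg[interior[0]], rel=1e-3)

    def test_broadening_trend_with_distortion(self):
        """More distortion fills in the minimum: the plateau rises monotonically."""
        plateaus = [reduced_turning_point(r)[1] for r in (0.1, 0.2, 0.3)]
        assert plateaus[0] < plateaus[1] < plateaus[2]
        q0s = [reduced_turning_point(r)[0] for r in (0.1, 0.2, 0.3)]
        assert all(2.0 < x < 3.5 for x in q0s)

    def test_zero_distortion_rejected(self):
        with pytest.raises(ValueError):
            turning_point(LatticeConfig(10.0, 0.0))


class TestICyl:
    def test_monodisperse_identity(self):
        """Zero polydispersity: I_cyl is exactly f^2 * Z~ (normalised)."""
        radius = RadiusDistribution(10.0, 0.0)
        lat = LatticeConfig(42.0, 11.3)
        tp = turning_point(lat)
        q = np.array([max(tp.q0 * 1.05, 0.08), 0.15, 0.25])
        f = cylinder_amplitude(q, 10.0)
        expected = f**2 * psi_averaged_Z(q, lat) / (np.pi * 100.0) ** 2
        np.testing.assert_allclose(i_cyl(q, radius, lat), expected, rtol=1e-12)

    def test_high_q_form_factor_limit(self):
        radius = RadiusDistribution(10.2, 2.04)
        lat = LatticeConfig(42.1, 11.4)
        q = 6.0  # q*a > 250
        nodes, w = radius_quadrature(radius)
        f2 = sum(wi * cylinder_amplitude(q, R) ** 2 for R, wi in zip(nodes, w))
        norm = sum(wi * (np.pi * R**2) ** 2 for R, wi in zip(nodes, w))
        assert i_cyl(q, radius, lat) == pytest.approx(f2 / norm, rel=0.01)

    def test_continuity_at_turning_point(self):
        radius = RadiusDistribution(10.2, 2.04)
        lat = LatticeConfig(42.1, 11.4)
        q0 = turning_point(lat).q0
        eps = 1e-9 * q0
        left = i_cyl(q0 - eps, radius, lat)
        right = i_cyl(q0 + eps, radius, lat)
        assert abs(left - right) / right < 1e-9

    def test_modification_only_below_q0(self):
        """Modified and unmodified lattice factors agree exactly for q >= q0."""
        lat = LatticeConfig(42.1, 11.4)
        tp = turning_point(lat)
        q_above = np.linspace(tp.q0, 0.3, 20)
        np.testing.assert_array_equal(
            model._modified_Z(q_above, lat), psi_averaged_Z(q_above, lat))
        q_below = np.linspace(0.005, tp.q0 * 0.99, 20)
        assert np.all(model._modified_Z(q_below, lat) == tp.plateau)
        assert np.all(psi_averaged_Z(q_below, lat) > tp.plateau)


class TestTotalIntensity:
    def test_reduces_to_i_cyl(self):
        p = params_from_dict({"scale_A": 1.0, "d_mean": 2.04, "dR_rel": 0.2,
                              "a": 4.21, "da_rel": 0.271, "scale_B": 0.0,
                              "scale_C": 0.0})
        q = np.geomspace(0.01, 0.3, 30)
        np.testing.assert_allclose(
            total_intensity(q, p), i_cyl(q, p.radius, p.lattice), rtol=1e-12)

    def test_pure_power_law_slope(self):
        p = params_from_dict({"scale_A": 0.0, "d_mean": 2.0, "a": 4.0,
                              "da_rel": 0.2, "scale_B": 0.0, "scale_C": 1.0,
                              "alpha": 4.0})
        q = np.geomspace(0.01, 0.3, 40)
        slope = np.gradient(np.log(total_intensity(q, p)), np.log(q))
        np.testing.assert_allclose(slope, -4.0, atol=1e-6)

    def test_correlation_peak_location_wet_softwood(self, sans_truth):
        """Wet-softwood parameters give a local maximum inside [0.12, 0.20]."""
        p = params_from_dict(sans_truth)
        q = np.linspace(0.10, 0.22, 601)
        inten = total_intensity(q, p)
        i = int(np.argmax(inten[(q >= 0.12) & (q <= 0.20)]))
        q_peak = q[(q >= 0.12) & (q <= 0.20)][i]
        assert 0.12 < q_peak < 0.20
        j = int(np.argmin(np.abs(q - q_peak)))
        assert inten[j] > inten[j - 5] and inten[j] > inten[j + 5]

    def test_positivity(self, sans_truth, saxs_truth):
        q = np.geomspace(0.005, 0.5, 100)
        for truth in (sans_truth, saxs_truth):
            assert np.all(total_intensity(q, params_from_dict(truth)) > 0)

    def test_q_zero_rejected(self, sans_truth):
        with pytest.raises(ValueError):
            total_intensity(np.array([0.0, 0.1]), params_from_dict(sans_truth))

    def test_scale_invariance_of_curve_shape(self):
        """Shapes depend only on q*a, q*R, da/a, dR/R: scaling all lengths by
        s and q by 1/s leaves the cylinder term unchanged."""
        base = {"scale_A": 1.0, "d_mean": 2.0, "dR_rel": 0.2, "a": 4.0,
                "da_rel": 0.25, "scale_B": 0.0, "scale_C": 0.0}
        scaled = dict(base, d_mean=2.0 * 2.5, a=4.0 * 2.5)
        q = np.geomspace(0.02, 0.3, 40)
        np.testing.assert_allclose(
            total_intensity(q, params_from_dict(base)),
            total_intensity(q / 2.5, params_from_dict(scaled)), rtol=1e-10)

    def test_param_dict_roundtrip(self, sans_truth):
        p = params_from_dict(sans_truth)
        d = model.params_to_dict(p)
        for k, v in sans_truth.items():
            assert d[k] == pytest.approx(v, rel=1e-12)
        np.testing.assert_allclose(
            model.evaluate(np.array([0.1, 0.15]), sans_truth),
            total_intensity(np.array([0.1, 0.15]), p), rtol=1e-12)
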