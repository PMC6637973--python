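import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from capsidcharge import (
    CapsidError,
    ChargeDensityModel,
    VDW_WIDTHS,
    read_aux,
    write_aux,
)

from conftest import make_structure
import oracles

# frozen from the 1-D quadrature oracle (see oracles.centered_shell_charge_quad)
CENTERED_Q_R1 = 0.08110858834532414
CENTERED_Q_R2 = 0.4275932955291202
RHO0_UNIT = 0.022448390265645816  # (4π)^(−3/2)


class TestDensity:
    def test_peak_density_of_unit_charge(self, single_unit_charge_model):
        assert single_unit_charge_model.density_at([0.0, 0.0, 0.0]) == pytest.approx(
            RHO0_UNIT, abs=1e-15
        )

    def test_each_gaussian_integrates_to_its_charge(self):
        """The normalisation contract behind the (4πa²)^(−3/2) prefactor."""
        for a in (0.5, 1.0, 2.3):
            m = ChargeDensityModel(
                make_structure([[0.0, 0.0, 0.0]], charges=[1.0]), width_a=a
            )
            val, _ = integrate.quad(
                lambda r: 4 * math.pi * r * r * m.density_at([r, 0.0, 0.0]),
                0,
                30 * a,
                epsabs=1e-12,
            )
            assert val == pytest.approx(1.0, abs=1e-9)

    def test_zero_charges_give_zero_density(self):
        struct = make_structure(np.random.default_rng(0).normal(size=(5, 3)),
                                charges=np.zeros(5))
        model = ChargeDensityModel(struct, width_a=1.0)
        pts = np.random.default_rng(1).normal(size=(10, 3))
        np.testing.assert_array_equal(model.density_at(pts), 0.0)

    def test_antisymmetric_pair_cancels_at_midpoint(self):
        struct = make_structure([[3.0, 0, 0], [-3.0, 0, 0]], charges=[1.0, -1.0])
        m = ChargeDensityModel(struct, width_a=1.0)
        assert m.density_at([0.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-15)

    def test_translation_covariance(self, small_random_model):
        shift = np.array([3.7, -1.2, 8.9])
        struct = small_random_model.structure
        shifted = ChargeDensityModel(
            make_structure(struct.positions + shift, charges=struct.charges),
            width_a=1.0,
        )
        pts = np.random.default_rng(5).uniform(-20, 20, size=(20, 3))
        a = small_random_model.density_at(pts)
        b = shifted.density_at(pts + shift)
        np.testing.assert_allclose(b, a, rtol=1e-12)


class TestShellCharge:
    def test_centered_gaussian_closed_form(self, single_unit_charge_model):
        q = single_unit_charge_model.shell_charge(0.0, 2.0).charge
        assert q == pytest.approx(CENTERED_Q_R2, abs=1e-12)
        assert q == pytest.approx(
            oracles.centered_shell_charge_quad(2.0), abs=1e-10
        )

    def test_total_charge_conservation(self, small_random_model):
        m = small_random_model
        total = m.shell_charge(0.0, m.r_max).charge
        assert total == pytest.approx(float(np.sum(m.charges)), abs=1e-6)

    def test_paper_shell_pair_additivity(self, small_random_model):
        m = small_random_model
        q_7_10 = m.shell_charge(7.0, 10.0).charge
        assert q_7_10 == pytest.approx(
            m.shell_charge(0.0, 10.0).charge - m.shell_charge(0.0, 7.0).charge,
            abs=1e-9,
        )

    @given(
        r=st.tuples(
            st.floats(0.0, 40.0), st.floats(0.0, 40.0), st.floats(0.0, 40.0)
        ).filter(lambda t: len({round(x, 6) for x in t}) == 3)
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shell_additivity_property(self, r):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-15, 15, size=(10, 3))
        m = ChargeDensityModel(
            make_structure(pts, charges=rng.uniform(-1, 1, 10)), width_a=1.0
        )
        r1, r2, r3 = sorted(r)
        q13 = m.shell_charge(r1, r3).charge
        q12 = m.shell_charge(r1, r2).charge
        q23 = m.shell_charge(r2, r3).charge
        assert q13 == pytest.approx(q12 + q23, abs=1e-9)

    def test_domain_errors(self, single_unit_charge_model):
        with pytest.raises(CapsidError):
            single_unit_charge_model.shell_charge(5.0, 3.0)
        with pytest.raises(CapsidError):
            single_unit_charge_model.shell_charge(-1.0, 3.0)

    def test_point_charge_limit(self):
        """At a → 0 the shell charge is plain charge counting."""
        rng = np.random.default_rng(13)
        edges = np.array([0.0, 5.0, 10.0, 20.0, 25.0])
        radii = rng.uniform(2.0, 28.0, size=120)
        radii = radii[np.min(np.abs(radii[:, None] - edges), axis=1) > 0.15][:40]
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        charges = rng.uniform(-1, 1, size=40)
        m = ChargeDensityModel(
            make_structure(dirs * radii[:, None], charges=charges), width_a=0.01
        )
        for r1, r2 in [(0.0, 10.0), (10.0, 20.0), (5.0, 25.0)]:
            inside = (radii > r1) & (radii < r2)
            # atoms land ≥0.1 Å from shell edges with these draws
            assert min(np.min(np.abs(radii - r1)), np.min(np.abs(radii - r2))) > 0.1
            assert m.shell_charge(r1, r2).charge == pytest.approx(
                float(np.sum(charges[inside])), abs=1e-9
            )


class TestSurfaceChargeDensity:
    def test_zero_at_origin(self, small_random_model):
        assert small_random_model.surface_charge_density(0.0) == 0.0

    def test_integrates_to_total_charge(self, small_random_model):
        m = small_random_model
        val, _ = integrate.quad(
            lambda r: m.surface_charge_density(r), 0.0, m.r_max, limit=200
        )
        assert val == pytest.approx(float(np.sum(m.charges)), abs=1e-6)

    def test_peak_near_atom_radius(self):
        """σ peaks just outside the atom's radius: the r² solid-angle factor
        shifts the mode of the radial density to d + 2a²/d (Monte-Carlo
        verified); for d ≫ a the shell through the atom carries the peak."""
        m = ChargeDensityModel(
            make_structure([[0.0, 0.0, 5.0]], charges=[1.0]), width_a=1.0
        )
        r = np.linspace(0.0, 12.0, 4801)
        sigma = m.surface_charge_density(r)
        peak = r[np.argmax(sigma)]
        assert peak == pytest.approx(5.0 + 2.0 / 5.0, abs=0.05)
        # far from the centre the shift vanishes: d = 50 peaks within 0.1 Å
        m_far = ChargeDensityModel(
            make_structure([[0.0, 0.0, 50.0]], charges=[1.0]), width_a=1.0
        )
        r = np.linspace(45.0, 55.0, 4001)
        peak_far = r[np.argmax(m_far.surface_charge_density(r))]
        assert abs(peak_far - 50.0) <= 0.1

    def test_matches_derivative_of_cumulative_charge(self, small_random_model):
        """σ(r) is the radial derivative of Q(0, r)."""
        m = small_random_model
        for r in (3.0, 11.0, 22.0):
            h = 1e-5
            numeric = (m.cumulative_charge(r + h) - m.cumulative_charge(r - h)) / (2 * h)
            assert m.surface_charge_density(r) == pytest.approx(numeric, abs=1e-7)

    def test_shell_charge_equals_integral_of_sigma(self, small_random_model):
        m = small_random_model
        for r1, r2 in [(0.0, 10.0), (7.0, 10.0), (12.5, 31.0)]:
            val, _ = integrate.quad(
                lambda r: m.surface_charge_density(r), r1, r2, limit=200
            )
            assert m.shell_charge(r1, r2).charge == pytest.approx(val, abs=1e-6)

    def test_negative_radius_rejected(self, small_random_model):
        with pytest.raises(CapsidError):
            small_random_model.surface_charge_density(-1.0)


class TestQuadratureAndMonteCarloOracles:
    def test_analytic_matches_adaptive_quadrature(self, small_random_model):
        m = small_random_model
        q = m.shell_charge(10.0, 20.0).charge
        assert q == pytest.approx(
            oracles.shell_charge_quadrature(m, 10.0, 20.0), abs=1e-6
        )

    def test_analytic_matches_monte_carlo(self, small_random_model):
        m = small_random_model
        q = m.shell_charge(10.0, 20.0).charge
        est, se = oracles.shell_charge_montecarlo(
            m, 10.0, 20.0, 200_000, np.random.default_rng(99)
        )
        assert abs(q - est) <= 3 * se


class TestPlanarDensityMap:
    def test_midplane_peak_at_center(self, single_unit_charge_model):
        grid = single_unit_charge_model.planar_density_map(
            (0, 0, 1), extent=5.0, spacing=0.5
        )
        n = grid.values.shape[0]
        assert n == math.ceil(2 * 5.0 / 0.5) + 1
        assert np.unravel_index(np.argmax(grid.values), grid.values.shape) == (
            n // 2,
            n // 2,
        )

    def test_zero_charges_give_zero_grid(self):
        m = ChargeDensityModel(
            make_structure(np.eye(3) * 2.0, charges=np.zeros(3)), width_a=1.0
        )
        grid = m.planar_density_map((0, 0, 1), extent=4.0, spacing=1.0)
        np.testing.assert_array_equal(grid.values, 0.0)

    def test_plane_sum_matches_2d_quadrature(self, small_random_model):
        m = small_random_model
        extent, spacing = 35.0, 0.5
        grid = m.planar_density_map((0, 0, 1), extent=extent, spacing=spacing)
        riemann = float(np.sum(grid.values)) * spacing**2
        exact = oracles.planar_integral_quadrature(m, extent)
        assert riemann == pytest.approx(exact, rel=0.01, abs=1e-6)

    def test_zero_normal_rejected(self, single_unit_charge_model):
        with pytest.raises(CapsidError):
            single_unit_charge_model.planar_density_map((0, 0, 0))

    def test_text_export_roundtrip(self, single_unit_charge_model, tmp_path):
        grid = single_unit_charge_model.planar_density_map(
            (0, 0, 1), extent=3.0, spacing=1.0
        )
        out = tmp_path / "map.txt"
        grid.write_text(out)
        lines = out.read_text().splitlines()
        meta = json.loads(lines[0].lstrip("# "))
        assert meta["spacing"] == 1.0
        values = np.loadtxt(out)
        np.testing.assert_allclose(values, grid.values, rtol=1e-9)


class TestWidths:
    def test_per_element_widths_conserve_charge(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(-10, 10, size=(20, 3))
        names = ["N", "CA", "O", "H"] * 5
        m = ChargeDensityModel(
            make_structure(pts, charges=rng.uniform(-1, 1, 20), names=names),
            width_a=1.0,
            per_atom_widths=VDW_WIDTHS,
        )
        assert set(np.round(np.unique(m.widths), 2)) <= {1.20, 1.70, 1.55, 1.52}
        assert m.shell_charge(0.0, m.r_max).charge == pytest.approx(
            float(np.sum(m.charges)), abs=1e-6
        )

    def test_invalid_width_rejected(self):
        s = make_structure([[0, 0, 0]], charges=[1.0])
        with pytest.raises(CapsidError):
            ChargeDensityModel(s, width_a=0.0)
        with pytest.raises(CapsidError):
            ChargeDensityModel(s, width_a=-1.0)

    def test_unset_charges_rejected(self):
        s = make_structure([[0, 0, 0]])  # nan charge sentinel
        with pytest.raises(CapsidError, match="unset charges"):
            ChargeDensityModel(s, width_a=1.0)


def test_aux_file_roundtrip(small_random_model, tmp_path):
    path = tmp_path / "capsid.aux"
    write_aux(small_random_model, path)
    back = read_aux(path)
    for r1, r2 in [(0.0, 15.0), (7.0, 10.0)]:
        assert back.shell_charge(r1, r2).charge == pytest.approx(
            small_random_model.shell_charge(r1, r2).charge, abs=1e-5
        )
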