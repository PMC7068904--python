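"""Elastic-foundation contact surrogate: stiffness, ligaments, equilibrium."""

import math

import numpy as np
import pytest

import tkaopt as tk
from tkaopt.contact import Material, _alignment_rotation


class TestFoundationModulus:
    def test_polyethylene_layer_stiffness(self):
        k = tk.foundation_modulus(tk.MATERIALS["polyethylene_liner"], 9.0)
        assert k == pytest.approx(163.095, abs=1e-3)

    def test_zero_poisson_reduces_to_e_over_t(self):
        m = Material("test", 100.0, 0.0)
        assert tk.foundation_modulus(m, 4.0) == pytest.approx(25.0)

    def test_doubling_thickness_halves_stiffness(self):
        m = tk.MATERIALS["polyethylene_liner"]
        assert tk.foundation_modulus(m, 18.0) == pytest.approx(
            tk.foundation_modulus(m, 9.0) / 2.0
        )

    def test_incompressible_layer_unsupported(self):
        with pytest.raises(ValueError):
            Material("rubber", 10.0, 0.5)
        # a dataclass cannot even carry nu >= 0.5; check the guard directly
        m = Material("near", 10.0, 0.49)
        assert tk.foundation_modulus(m, 1.0) > 0


class TestLigamentTension:
    LCL = tk.DEFAULT_LIGAMENTS[1]

    def test_zero_force_at_reference_stretch(self):
        assert tk.ligament_tension(self.LCL, 1.0) == 0.0

    def test_slack_below_reference(self):
        assert tk.ligament_tension(self.LCL, 0.9) == 0.0

    def test_tangent_modulus_at_reference_is_six_c1(self):
        # d(sigma)/d(lambda) at lambda=1 equals 6*C1 (= 36.36 MPa for C1=6.06)
        c1 = self.LCL.c1_mpa
        analytic = 6.0 * c1
        assert analytic == pytest.approx(36.36, abs=1e-9)
        eps = 1e-7
        sigma = lambda lam: 2.0 * c1 * (lam**2 - 1.0 / lam)
        numeric = (sigma(1.0 + eps) - sigma(1.0)) / eps
        assert numeric == pytest.approx(analytic, rel=1e-5)

    def test_tension_increasing_and_stress_convex_above_reference(self):
        lams = np.linspace(1.0, 1.3, 40)
        forces = np.array([tk.ligament_tension(self.LCL, l) for l in lams])
        assert np.all(np.diff(forces) > 0)
        # the Cauchy stress 2 C1 (lam^2 - 1/lam) is convex in the stretch
        # (the force carries a 1/lam current-area factor on top of it)
        sigma = 2.0 * self.LCL.c1_mpa * (lams**2 - 1.0 / lams)
        assert np.all(np.diff(sigma, 2) > 0)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            tk.ligament_tension(self.LCL, 0.0)


class TestAlignment:
    def test_effective_slope_adds_inherent_component_slope(self):
        a = tk.ImplantAlignment(cut_slope_deg=1.0)
        assert a.effective_slope_deg == 4.0

    def test_angles_beyond_bound_rejected(self):
        with pytest.raises(ValueError):
            tk.ImplantAlignment(varus_deg=90.0)
        with pytest.raises(ValueError):
            tk.ImplantAlignment(cut_slope_deg=13.0)  # effective 16

    def test_varus_drops_the_medial_side(self):
        q = _alignment_rotation(tk.ImplantAlignment(varus_deg=3.0, inherent_slope_deg=0.0))
        medial_point = q @ np.array([24.0, 0.0, 0.0])
        assert medial_point[2] < 0


class TestLinerSurface:
    def test_symmetric_geometry_has_equal_apex_heights(self, geometry):
        surf = tk.liner_surface(geometry, tk.ImplantAlignment(inherent_slope_deg=0.0))
        x = np.array([24.0, -24.0])
        y = np.zeros(2)
        z = surf.heights(x, y)
        assert z[0] == pytest.approx(z[1], abs=1e-12)

    def test_mirror_alignments_give_mirror_height_fields(self, geometry):
        xs = np.linspace(-35.0, 35.0, 141)
        ys = np.zeros_like(xs)
        zp = tk.liner_surface(geometry, tk.ImplantAlignment(varus_deg=3.0, inherent_slope_deg=0.0)).heights(xs, ys)
        zn = tk.liner_surface(geometry, tk.ImplantAlignment(varus_deg=-3.0, inherent_slope_deg=0.0)).heights(xs, ys)
        ok = ~np.isnan(zp)
        assert np.allclose(zp[ok], zn[::-1][ok], atol=1e-12)

    def test_coarse_grid_rejected(self):
        geom = tk.ArticularGeometry(
            compartments=tk.default_geometry().compartments, grid_spacing_mm=4.0
        )
        with pytest.raises(ValueError, match="coarse"):
            tk.liner_surface(geom, tk.ImplantAlignment())

    def test_extreme_rotation_rejected_by_alignment_bound(self):
        with pytest.raises(ValueError):
            tk.ImplantAlignment(external_rotation_deg=90.0)


def flat_single_condyle(spacing=0.25, radius=30.0):
    return tk.ArticularGeometry(
        compartments=(
            tk.Compartment(
                side="medial",
                center_ml_mm=0.0,
                condyle_radius_mm=radius,
                dish_radius_mm=math.inf,
                aperture_radius_mm=12.0,
            ),
        ),
        grid_spacing_mm=spacing,
    )


class TestSolveEquilibrium:
    def test_flat_foundation_matches_closed_form(self, liner_k):
        # single sphere (radius R) on a flat bed of springs: F = pi k R d^2,
        # peak = k d, with d the apex penetration
        radius = 30.0
        state, pmap = tk.solve_equilibrium(
            flat_single_condyle(spacing=0.25, radius=radius),
            tk.ImplantAlignment(inherent_slope_deg=0.0),
            ligaments=(),
            free_tilts=(),
        )
        d = state.settlement_mm
        closed_form = math.pi * liner_k * radius * d**2
        assert closed_form == pytest.approx(1150.0, rel=0.01)
        peak, comp, _ = tk.peak_pressure(pmap)
        assert peak == pytest.approx(liner_k * d, rel=0.01)
        assert pmap.total_load_n() == pytest.approx(1150.0, rel=5e-3)

    def test_closed_form_error_shrinks_with_grid_refinement(self, liner_k):
        errs = []
        for spacing in (1.0, 0.5, 0.25):
            state, _ = tk.solve_equilibrium(
                flat_single_condyle(spacing=spacing),
                tk.ImplantAlignment(inherent_slope_deg=0.0),
                ligaments=(),
                free_tilts=(),
            )
            f = math.pi * liner_k * 30.0 * state.settlement_mm**2
            errs.append(abs(f - 1150.0) / 1150.0)
        assert errs[2] < errs[0]

    def test_zero_misalignment_equal_compartment_peaks(self, geometry):
        _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment(inherent_slope_deg=0.0))
        med = float(pmap.pressure[pmap.compartment == 1].max())
        lat = float(pmap.pressure[pmap.compartment == 2].max())
        assert med == pytest.approx(lat, rel=1e-6)
        med_n, lat_n = tk.compartment_loads(pmap)
        assert med_n == pytest.approx(575.0, rel=5e-3)
        assert lat_n == pytest.approx(575.0, rel=5e-3)

    def test_total_load_balances_applied_plus_ligament(self, geometry):
        for varus in (-3.0, 0.0, 3.0):
            _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment(varus_deg=varus))
            balance = pmap.applied_load_n + pmap.ligament_load_n
            assert pmap.total_load_n() == pytest.approx(balance, rel=5e-3)

    def test_mirror_varus_maps_are_mirror_images(self, geometry, symmetric_ligaments):
        _, pp = tk.solve_equilibrium(
            geometry, tk.ImplantAlignment(varus_deg=3.0, inherent_slope_deg=0.0),
            ligaments=symmetric_ligaments, tol=1e-5,
        )
        _, pn = tk.solve_equilibrium(
            geometry, tk.ImplantAlignment(varus_deg=-3.0, inherent_slope_deg=0.0),
            ligaments=symmetric_ligaments, tol=1e-5,
        )
        peak = pp.pressure.max()
        assert np.abs(pp.pressure - pn.pressure[:, ::-1]).max() / peak < 1e-3

    def test_medial_load_strictly_increasing_in_varus(self, geometry):
        med_loads = []
        for varus in (-3.0, 0.0, 3.0):
            _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment(varus_deg=varus))
            med_loads.append(tk.compartment_loads(pmap)[0])
        assert med_loads[0] < med_loads[1] < med_loads[2]

    def test_unknown_tilt_dof_rejected(self, geometry):
        with pytest.raises(ValueError, match="tilt"):
            tk.solve_equilibrium(geometry, tk.ImplantAlignment(), free_tilts=("yaw",))


class TestPressureMapOps:
    def make_map(self, pressure, compartment=None):
        ny, nx = pressure.shape
        return tk.PressureMap(
            x=np.arange(nx, dtype=float),
            y=np.arange(ny, dtype=float),
            pressure=pressure,
            compartment=(
                compartment if compartment is not None else np.ones((ny, nx), dtype=np.int8)
            ),
            spacing_mm=1.0,
        )

    def test_single_nonzero_cell_is_the_peak(self):
        p = np.zeros((4, 5))
        p[2, 3] = 7.5
        val, comp, loc = tk.peak_pressure(self.make_map(p))
        assert (val, comp, loc) == (7.5, "medial", (3.0, 2.0))

    def test_symmetric_tie_resolves_to_medial(self):
        p = np.zeros((1, 4))
        p[0, 0] = p[0, 3] = 5.0
        comp = np.array([[2, 2, 1, 1]], dtype=np.int8)
        _, side, _ = tk.peak_pressure(self.make_map(p, comp))
        assert side == "medial"

    def test_peak_matches_brute_force_scan_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(0.0, 30.0, size=(15, 20))
            val, _, (x, y) = tk.peak_pressure(self.make_map(p))
            i, j = np.unravel_index(np.argmax(p), p.shape)
            assert val == p.max()
            assert (x, y) == (float(j), float(i))

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tk.peak_pressure(self.make_map(np.zeros((3, 3))))

    def test_compartment_loads_sum_to_total(self, geometry):
        _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment(varus_deg=3.0))
        med, lat = tk.compartment_loads(pmap)
        assert med + lat == pytest.approx(pmap.total_load_n(), rel=1e-12)

    def test_empty_lateral_contact_gives_zero_lateral_load(self):
        p = np.zeros((2, 2))
        p[0, 0] = 3.0
        med, lat = tk.compartment_loads(self.make_map(p))
        assert lat == 0.0
        assert med == 3.0


class TestPressureMapIO:
    def test_round_trip_is_bit_identical(self, geometry, tmp_path):
        _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment(varus_deg=3.0))
        path = tmp_path / "map.csv"
        tk.export_pressure_map(pmap, path)
        back = tk.read_pressure_map(path)
        assert np.array_equal(back.pressure, pmap.pressure)
        assert np.array_equal(back.compartment, pmap.compartment)
        assert np.array_equal(back.x, pmap.x)
        assert np.array_equal(back.y, pmap.y)
        assert back.spacing_mm == pmap.spacing_mm

    def test_metadata_and_reintegrated_load(self, geometry, tmp_path):
        _, pmap = tk.solve_equilibrium(geometry, tk.ImplantAlignment())
        path = tmp_path / "map.csv"
        tk.export_pressure_map(pmap, path)
        header = [l for l in path.read_text().splitlines() if l.startswith("#")]
        assert any("spacing_mm" in l for l in header)
        assert any("MPa" in l for l in header)
        back = tk.read_pressure_map(path)
        assert back.total_load_n() == pytest.approx(pmap.total_load_n(), rel=1e-12)
        assert back.applied_load_n == pmap.applied_load_n
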