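"""Elliptical-cantilever mechanics: closed forms, round trips, sweeps."""

import numpy as np
import pytest

from pillarforce.beam import (
    InvalidGeometryError,
    PillarGeometry,
    back_calculate_modulus,
    deflection_under_load,
    design_space_sweep,
    force_from_deflection,
    lateral_stiffness,
    second_moment_elliptical,
    shear_modulus,
    stiffness_summary,
    tip_deflection_numeric,
)


def numeric_second_moment(a_um: float, b_um: float, n: int = 2001) -> float:
    """Independent oracle: integrate y^2 over the elliptical area (SI units).

    Bending is about the axis perpendicular to the deflection direction, so
    the integrand coordinate runs along the bending-direction semi-axis b.
    """
    a, b = a_um * 1e-6, b_um * 1e-6
    y = np.linspace(-b, b, n)
    width = 2.0 * a * np.sqrt(np.clip(1.0 - (y / b) ** 2, 0.0, None))
    return float(np.trapezoid(y**2 * width, y))


class TestSecondMoment:
    def test_circular_limit_reduces_to_quarter_pi_r4(self):
        r = 250.0
        geom = PillarGeometry(semi_major_a_um=r, semi_minor_b_um=r)
        assert second_moment_elliptical(geom) == pytest.approx(
            np.pi * (r * 1e-6) ** 4 / 4.0, rel=1e-12
        )

    def test_default_geometry_matches_area_integral(self, default_geometry):
        I = second_moment_elliptical(default_geometry)
        assert I == pytest.approx(1.885e-15, rel=1e-3)
        assert I == pytest.approx(numeric_second_moment(300.0, 200.0), rel=1e-5)

    def test_vanishing_minor_axis_drives_I_to_zero_monotonically(self):
        bs = [200.0, 100.0, 50.0, 10.0, 1.0]
        Is = [
            second_moment_elliptical(PillarGeometry(semi_minor_b_um=b))
            for b in bs
        ]
        assert all(i1 > i2 > 0 for i1, i2 in zip(Is, Is[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"semi_minor_b_um": -1.0},
            {"semi_minor_b_um": 0.0},
            {"semi_major_a_um": 100.0, "semi_minor_b_um": 200.0},
            {"height_h_um": 0.0},
            {"youngs_modulus_mpa": -2.0},
            {"poisson_nu": 0.6},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidGeometryError):
            PillarGeometry(**kwargs)


class TestLateralStiffness:
    def test_default_geometry_value(self, default_geometry):
        assert lateral_stiffness(default_geometry) == pytest.approx(0.2133, abs=5e-4)

    def test_agrees_with_beam_ode_oracle_across_geometries(self, rng):
        """Closed-form k vs numerically integrated cantilever, 10 samples."""
        for _ in range(10):
            geom = PillarGeometry(
                semi_major_a_um=rng.uniform(150, 400),
                semi_minor_b_um=rng.uniform(75, 150),
                height_h_um=rng.uniform(3000, 5000),
                youngs_modulus_mpa=rng.uniform(1.0, 5.0),
            )
            F = 38.0
            delta_numeric = tip_deflection_numeric(geom, F)
            k_numeric = F / delta_numeric
            assert k_numeric == pytest.approx(lateral_stiffness(geom), rel=1e-3)

    def test_cubic_scaling_in_height(self, default_geometry):
        k1 = lateral_stiffness(default_geometry, load_height_um=2000.0)
        k2 = lateral_stiffness(default_geometry, load_height_um=4000.0)
        assert k1 / k2 == pytest.approx(8.0, rel=1e-12)

    def test_power_laws_on_log_grids(self):
        bs = np.logspace(np.log10(50), np.log10(200), 6)
        ks = np.array(
            [
                lateral_stiffness(
                    PillarGeometry(semi_major_a_um=300.0, semi_minor_b_um=b)
                )
                for b in bs
            ]
        )
        slope_b = np.polyfit(np.log(bs), np.log(ks), 1)[0]
        assert slope_b == pytest.approx(3.0, abs=1e-9)

        hs = np.logspace(np.log10(3000), np.log10(5000), 6)
        ks = np.array(
            [lateral_stiffness(PillarGeometry(height_h_um=h)) for h in hs]
        )
        slope_h = np.polyfit(np.log(hs), np.log(ks), 1)[0]
        assert slope_h == pytest.approx(-3.0, abs=1e-9)

    @pytest.mark.parametrize("height", [0.0, -1.0, 5000.0])
    def test_load_height_out_of_range_rejected(self, default_geometry, height):
        with pytest.raises(ValueError):
            lateral_stiffness(default_geometry, load_height_um=height)


class TestHookesLaw:
    def test_zero_deflection_zero_force(self):
        assert force_from_deflection(0.249, 0.0) == 0.0

    def test_calibrated_spring_constant_product(self):
        assert force_from_deflection(0.249, 100.0) == pytest.approx(24.9)

    def test_linearity_and_sign(self, rng):
        k = 0.37
        deltas = rng.uniform(-80, 80, 20)
        forces = force_from_deflection(k, deltas)
        np.testing.assert_allclose(forces, k * deltas, rtol=1e-12)
        np.testing.assert_allclose(
            force_from_deflection(k, 2 * deltas), 2 * forces, rtol=1e-12
        )

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError):
            force_from_deflection(0.0, 1.0)


class TestModulusBackCalculation:
    def test_round_trip_is_identity(self, default_geometry):
        k = lateral_stiffness(default_geometry)
        E = back_calculate_modulus(k, default_geometry)
        assert E == pytest.approx(default_geometry.youngs_modulus_mpa, rel=1e-12)

    def test_printed_stiffness_gives_printed_modulus(self, default_geometry):
        assert back_calculate_modulus(0.2133, default_geometry) == pytest.approx(
            2.414, rel=2e-3
        )

    def test_linearity_in_stiffness(self, default_geometry):
        E1 = back_calculate_modulus(0.1, default_geometry)
        E2 = back_calculate_modulus(0.2, default_geometry)
        assert E2 == pytest.approx(2 * E1, rel=1e-12)


class TestShearModulus:
    def test_platform_material_value(self):
        assert shear_modulus(2.414, 0.49) == pytest.approx(0.81, abs=5e-3)

    def test_limits(self):
        assert shear_modulus(2.0, 1e-9) == pytest.approx(1.0, rel=1e-6)
        assert shear_modulus(3.0, 0.5 - 1e-9) == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("nu", [-0.1, 0.0, 0.5, 0.7])
    def test_poisson_out_of_range_rejected(self, nu):
        with pytest.raises(ValueError):
            shear_modulus(2.414, nu)


class TestDeflectionUnderLoad:
    def test_inverse_of_hookes_law(self, default_geometry):
        k = lateral_stiffness(default_geometry)
        delta = deflection_under_load(default_geometry, 38.0)
        assert delta == pytest.approx(38.0 / k, rel=1e-12)
        assert force_from_deflection(k, delta) == pytest.approx(38.0, rel=1e-12)

    def test_zero_force_zero_deflection(self, default_geometry):
        assert deflection_under_load(default_geometry, 0.0) == 0.0

    def test_deflection_increases_with_height(self):
        deltas = [
            deflection_under_load(PillarGeometry(height_h_um=h), 10.0)
            for h in (3000.0, 3500.0, 4000.0, 4500.0, 5000.0)
        ]
        assert all(d2 > d1 for d1, d2 in zip(deltas, deltas[1:]))

    def test_large_deflection_flagged(self):
        soft = PillarGeometry(
            semi_major_a_um=120.0, semi_minor_b_um=80.0, height_h_um=5000.0
        )
        with pytest.warns(UserWarning, match="small-deflection"):
            deflection_under_load(soft, 38.0)


class TestDesignSpaceSweep:
    def test_printed_grid_has_twenty_rows(self):
        df = design_space_sweep(
            heights_mm=[3.0, 3.5, 4.0, 4.5, 5.0],
            semi_minor_axes_um=[150.0, 200.0, 250.0, 300.0],
        )
        assert len(df) == 20
        assert list(df.columns) == ["h_mm", "b_um", "k_uN_per_um", "delta_um"]

    def test_deflection_monotone_in_height_and_thickness(self):
        df = design_space_sweep(
            heights_mm=[3.0, 4.0, 5.0], semi_minor_axes_um=[150.0, 200.0, 300.0]
        )
        for b, grp in df.groupby("b_um"):
            assert grp.sort_values("h_mm")["delta_um"].is_monotonic_increasing
        for h, grp in df.groupby("h_mm"):
            assert grp.sort_values("b_um")["delta_um"].is_monotonic_decreasing

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            design_space_sweep(heights_mm=[], semi_minor_axes_um=[150.0])


def test_stiffness_summary_is_positive_and_consistent(default_geometry):
    res = stiffness_summary(default_geometry)
    assert res.stiffness_k_un_per_um == pytest.approx(
        lateral_stiffness(default_geometry)
    )
    assert res.shear_modulus_mu_mpa == pytest.approx(0.81, abs=5e-3)
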