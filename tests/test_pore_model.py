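"""Conical-pore conductance model: forward blockade, inversion, tip sizing."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from rtfast import (
    CylindricalOligomer,
    InfeasibleParticleError,
    PipetteGeometry,
    SaturatedBlockadeError,
    detectability_window,
    excess_resistance,
    oligomer_from_blockade,
    relative_blockade,
    size_from_volume,
    tip_radius_from_conductance,
)


def quadrature_excess_resistance(geom: PipetteGeometry, ro: float) -> float:
    """Independent oracle: adaptive quadrature of the annular-excess integrand."""
    rp, a, kappa = geom.tip_radius_nm, geom.cone_slope, geom.conductivity_S_per_m

    def integrand(x):
        r_cone_sq = (rp + a * x) ** 2
        return 1.0 / (kappa * math.pi * (r_cone_sq - ro**2)) - 1.0 / (
            kappa * math.pi * r_cone_sq
        )

    value, _err = quad(integrand, 0.0, 2.0 * ro, epsrel=1e-12)
    return value


class TestTipRadius:
    def test_pure_cone_limit(self):
        # G chosen so the cone term alone gives exactly 1 nm
        kappa, alpha = 10.0, 0.2
        g = kappa * math.pi * math.tan(alpha) * 1.0
        assert tip_radius_from_conductance(g, kappa, alpha, include_access=False) == pytest.approx(1.0)

    def test_linear_in_conductance(self):
        r1 = tip_radius_from_conductance(5.0, 8.6, 0.1)
        r2 = tip_radius_from_conductance(10.0, 8.6, 0.1)
        assert r2 == pytest.approx(2.0 * r1)

    def test_closed_form_value(self):
        # independent hand evaluation of (G/kappa) (1/(pi tan a) + 1/4)
        expected = (5.0 / 8.6) * (1.0 / (math.pi * math.tan(0.1)) + 0.25)
        assert tip_radius_from_conductance(5.0, 8.6, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_angle(self):
        radii = [tip_radius_from_conductance(5.0, 8.6, a) for a in (0.05, 0.1, 0.2, 0.5)]
        assert all(a > b for a, b in zip(radii, radii[1:]))

    @pytest.mark.parametrize("bad", [(-1, 8.6, 0.1), (5, 0, 0.1), (5, 8.6, -0.1), (5, 8.6, 2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            tip_radius_from_conductance(*bad)


@pytest.mark.parametrize("rp, expected", [(5.0, (5.0, 10.0)), (15.0, (15.0, 30.0)), (20.0, (20.0, 40.0))])
def test_detectability_window(rp, expected):
    geom = PipetteGeometry(rp, 0.1, 8.6, 10.0)
    assert detectability_window(geom) == pytest.approx(expected)


class TestExcessResistance:
    def test_vanishing_particle(self, geometry):
        tiny = excess_resistance(geometry, CylindricalOligomer(1e-6))
        assert 0 < tiny < 1e-10

    def test_matches_quadrature_spot(self):
        geom = PipetteGeometry(10.0, 0.05, 8.6, 30.0)
        got = excess_resistance(geom, CylindricalOligomer(4.0))
        assert got == pytest.approx(quadrature_excess_resistance(geom, 4.0), rel=1e-6)

    def test_matches_quadrature_random(self, rng):
        for _ in range(50):
            rp = rng.uniform(3.0, 40.0)
            geom = PipetteGeometry(
                rp, rng.uniform(0.02, 0.6), rng.uniform(1.0, 12.0), rng.uniform(1.0, 100.0)
            )
            ro = rng.uniform(0.05, 0.9) * rp
            got = excess_resistance(geom, CylindricalOligomer(ro))
            assert got == pytest.approx(quadrature_excess_resistance(geom, ro), rel=1e-6)

    def test_monotone_in_particle_radius(self, geometry):
        radii = np.linspace(0.5, 13.0, 30)
        values = [excess_resistance(geometry, CylindricalOligomer(r)) for r in radii]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_decreasing_in_tip_radius(self):
        values = [
            excess_resistance(PipetteGeometry(rp, 0.1, 8.6, 30.0), CylindricalOligomer(4.0))
            for rp in (6.0, 10.0, 20.0, 40.0)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_infeasible_particle(self, geometry):
        with pytest.raises(InfeasibleParticleError):
            excess_resistance(geometry, CylindricalOligomer(geometry.tip_radius_nm))


class TestRelativeBlockade:
    def test_series_resistance_identity(self, geometry):
        olig = CylindricalOligomer(6.0)
        r_max = excess_resistance(geometry, olig)
        g_inv = 1.0 / geometry.open_conductance_nS
        assert relative_blockade(geometry, olig) == pytest.approx(r_max / (g_inv + r_max))

    def test_equal_series_resistances_give_half(self, geometry):
        olig = CylindricalOligomer(6.0)
        r_max = excess_resistance(geometry, olig)
        balanced = replace(geometry, open_conductance_nS=1.0 / r_max)
        assert relative_blockade(balanced, olig) == pytest.approx(0.5)

    def test_bounded_and_monotone(self, geometry):
        radii = np.linspace(0.1, 0.9 * geometry.tip_radius_nm, 40)
        values = [relative_blockade(geometry, CylindricalOligomer(r)) for r in radii]
        assert all(0 < v < 1 for v in values)
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_thin_particle_excluded_area_scaling(self, geometry):
        # Excluded-area limit: blockade per unit particle length ~ r_o^2, so
        # doubling r_o quadruples dI/I0 per length (the total picks up an
        # extra factor of 2 because L_o = 2 r_o).
        rp = geometry.tip_radius_nm
        o1 = CylindricalOligomer(0.05 * rp)
        o2 = CylindricalOligomer(0.10 * rp)
        v1 = relative_blockade(geometry, o1) / o1.length_nm
        v2 = relative_blockade(geometry, o2) / o2.length_nm
        assert v2 / v1 == pytest.approx(4.0, rel=0.10)


class TestInversion:
    def test_roundtrip_random_geometries(self, rng):
        for _ in range(100):
            rp = rng.uniform(3.0, 40.0)
            geom = PipetteGeometry(
                rp, rng.uniform(0.02, 0.6), rng.uniform(1.0, 12.0), rng.uniform(1.0, 100.0)
            )
            ro = rng.uniform(0.05, 0.9) * rp
            rel = relative_blockade(geom, CylindricalOligomer(ro))
            recovered = oligomer_from_blockade(geom, rel)
            assert abs(recovered.radius_nm - ro) < 1e-3

    def test_small_blockade_gives_small_particle(self, geometry):
        assert oligomer_from_blockade(geometry, 1e-9).radius_nm < 0.1

    def test_saturation_error_names_bound(self, geometry):
        with pytest.raises(SaturatedBlockadeError, match="saturation"):
            oligomer_from_blockade(geometry, 0.999)

    def test_nonpositive_blockade_rejected(self, geometry):
        with pytest.raises(ValueError):
            oligomer_from_blockade(geometry, 0.0)


class TestSizeFromVolume:
    @pytest.mark.parametrize(
        "volume, size",
        [(50_000, 40), (10_000, 23), (30_000, 34), (6_000, 20), (200, 6), (2 * math.pi, 2)],
    )
    def test_printed_pairs(self, volume, size):
        assert round(size_from_volume(volume)) == size

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(r=st.floats(min_value=1e-3, max_value=1e3))
    def test_inverse_of_cylindrical_volume(self, r):
        assert size_from_volume(2.0 * math.pi * r**3) == pytest.approx(2.0 * r, rel=1e-12)

    def test_matches_oligomer_volume(self):
        olig = CylindricalOligomer(7.3)
        assert size_from_volume(olig.volume_nm3) == pytest.approx(olig.size_nm)

    def test_vectorized(self):
        out = size_from_volume([2 * math.pi, 16 * math.pi])
        assert out == pytest.approx([2.0, 4.0])

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            size_from_volume(-1.0)


def test_geometry_invariants_enforced():
    with pytest.raises(ValueError):
        PipetteGeometry(-1.0, 0.1, 8.6, 10.0)
    with pytest.raises(ValueError):
        PipetteGeometry(5.0, 2.0, 8.6, 10.0)
    with pytest.raises(ValueError):
        CylindricalOligomer(0.0)


def test_geometry_json_roundtrip(tmp_path, geometry):
    path = tmp_path / "geom.json"
    geometry.to_json(path)
    assert PipetteGeometry.from_json(path) == geometry
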