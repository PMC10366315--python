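"""Equivalent-body reduction and Hertzian reference quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkr_ehl.contact import (
    CompartmentGeometry,
    FluidModel,
    MaterialPair,
    Normalization,
    equivalent_modulus,
    equivalent_poisson,
    equivalent_radius,
    hertz_line_reference,
)

# frozen values computed beforehand by exact rational arithmetic on the
# implant constants (CoCr 240 GPa / 0.29 on UHMWPE 660 MPa / 0.46)
E_EQ_MPA = 363.3776204030547
NU_EQ = 0.45958793616196264
R_EQ = 0.022958333333333334


class TestEquivalentRadius:
    def test_implant_radii(self):
        assert equivalent_radius(0.038, 0.058) == pytest.approx(R_EQ, rel=1e-12)

    def test_flat_counterbody_limit(self):
        assert equivalent_radius(0.025, math.inf) == 0.025

    def test_equal_radii_halve(self):
        assert equivalent_radius(0.04, 0.04) == pytest.approx(0.02, rel=1e-14)

    @given(a=st.floats(1e-3, 1.0), b=st.floats(1e-3, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_commutative_and_below_min(self, a, b):
        r = equivalent_radius(a, b)
        assert r == equivalent_radius(b, a)
        assert r < min(a, b)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(-0.01, 0.05)


class TestEquivalentElasticity:
    def test_implant_constants(self):
        E = equivalent_modulus(240000e6, 0.29, 660e6, 0.46)
        nu = equivalent_poisson(240000e6, 0.29, 660e6, 0.46)
        assert E == pytest.approx(E_EQ_MPA * 1e6, rel=1e-12)
        assert nu == pytest.approx(NU_EQ, rel=1e-12)

    def test_identical_bodies_zero_poisson_gives_half(self):
        assert equivalent_modulus(1e9, 0.0, 1e9, 0.0) == pytest.approx(0.5e9, rel=1e-14)
        assert equivalent_poisson(1e9, 0.0, 1e9, 0.0) == 0.0

    def test_identical_bodies_reduction(self):
        # E (1+nu^2)^2 / (2 (1+nu)^2), frozen by rational arithmetic
        assert equivalent_modulus(1000e6, 0.3, 1000e6, 0.3) == pytest.approx(
            351.50887573964496e6, rel=1e-12
        )
        assert equivalent_poisson(1000e6, 0.3, 1000e6, 0.3) == pytest.approx(0.3, rel=1e-14)

    @given(k=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_modulus_homogeneous_of_degree_one(self, k):
        base = equivalent_modulus(240000e6, 0.29, 660e6, 0.46)
        assert equivalent_modulus(k * 240000e6, 0.29, k * 660e6, 0.46) == pytest.approx(
            k * base, rel=1e-12
        )

    def test_symmetric_under_body_exchange(self):
        args = (240000e6, 0.29, 660e6, 0.46)
        swapped = (660e6, 0.46, 240000e6, 0.29)
        assert equivalent_modulus(*args) == pytest.approx(
            equivalent_modulus(*swapped), rel=1e-14
        )
        assert equivalent_poisson(*args) == pytest.approx(
            equivalent_poisson(*swapped), rel=1e-14
        )

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            equivalent_modulus(-1.0, 0.3, 1e9, 0.3)
        with pytest.raises(ValueError):
            equivalent_poisson(1e9, 0.55, 1e9, 0.3)


class TestMaterialPairContainer:
    def test_derived_fields(self, materials):
        assert materials.E == pytest.approx(E_EQ_MPA * 1e6, rel=1e-12)
        assert materials.nu == pytest.approx(NU_EQ, rel=1e-12)
        assert materials.E_ps == pytest.approx(materials.E / (1 - materials.nu**2), rel=1e-14)

    def test_geometry_container(self, geometry):
        assert geometry.R == pytest.approx(R_EQ, rel=1e-12)
        with pytest.raises(ValueError):
            CompartmentGeometry(0.038, 0.058, -1.0)

    def test_fluid_validation(self):
        assert FluidModel().rho == 1000.0
        with pytest.raises(ValueError):
            FluidModel(rho=-1.0)


class TestHertzReference:
    def test_half_width_peak_pressure_identity(self, materials):
        hz = hertz_line_reference(2000.0, 0.0283, R_EQ, materials.E_ps)
        assert hz.p_H * math.pi * hz.a_H / 2 == pytest.approx(hz.w_ref, rel=1e-12)

    def test_implant_reference_values(self, materials):
        # cross-checked against the textbook line-contact formulas
        hz = hertz_line_reference(2000.0, 0.0283, R_EQ, materials.E_ps)
        assert hz.w_ref == pytest.approx(70671.3780918728, rel=1e-12)
        assert hz.a_H == pytest.approx(2.117608053354424e-3, rel=1e-9)
        assert hz.p_H == pytest.approx(21.246045302143186e6, rel=1e-9)

    def test_load_scaling_sqrt(self, materials):
        hz1 = hertz_line_reference(2000.0, 0.0283, R_EQ, materials.E_ps)
        hz2 = hertz_line_reference(4000.0, 0.0283, R_EQ, materials.E_ps)
        assert hz2.a_H / hz1.a_H == pytest.approx(math.sqrt(2), rel=1e-12)
        assert hz2.p_H / hz1.p_H == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_zero_length_rejected(self, materials):
        with pytest.raises(ValueError):
            hertz_line_reference(2000.0, 0.0, R_EQ, materials.E_ps)


@pytest.fixture(scope="module")
def norm(materials):
    hz = hertz_line_reference(2000.0, 0.0283, R_EQ, materials.E_ps, u_scale=0.15)
    return Normalization(hz, R_EQ)


class TestNormalization:

    def test_unit_maps(self, norm):
        assert norm.X(norm.hertz.a_H) == pytest.approx(1.0, rel=1e-14)
        assert norm.P(norm.hertz.p_H) == pytest.approx(1.0, rel=1e-14)

    @pytest.mark.parametrize("value", [1e-6, 0.3, 7.7])
    def test_round_trips_are_identity(self, norm, value):
        assert norm.x(norm.X(value)) == pytest.approx(value, rel=1e-14)
        assert norm.p(norm.P(value)) == pytest.approx(value, rel=1e-14)
        assert norm.h(norm.H(value)) == pytest.approx(value, rel=1e-14)
        assert norm.t(norm.T(value)) == pytest.approx(value, rel=1e-14)

    def test_film_scale(self, norm):
        h = 1.95e-6
        assert norm.H(h) == pytest.approx(h * R_EQ / norm.hertz.a_H**2, rel=1e-14)

    def test_arrays_supported(self, norm):
        x = np.array([0.0, 1e-3, 2e-3])
        np.testing.assert_allclose(norm.x(norm.X(x)), x, rtol=1e-14)
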