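"""Equivalent line-contact reduction and Hertzian reference scales.

A flat-on-flat knee-replacement compartment has curvature only in the
anterior-posterior direction, so the femoral component on the tibial inlay
is modelled as an infinite line contact: a rigid parabola of equivalent
radius ``R`` pressed onto an elastic half-plane of *equivalent* material.
Both bodies' elasticity is condensed into a single equivalent body with
Young's modulus ``E`` and Poisson's ratio ``nu``; the Hertzian half-width
``a_H`` and peak pressure ``p_H`` at a reference load provide the scales
used to non-dimensionalise the lubrication problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CompartmentGeometry",
    "MaterialPair",
    "FluidModel",
    "HertzReference",
    "Normalization",
    "equivalent_radius",
    "equivalent_modulus",
    "equivalent_poisson",
    "hertz_line_reference",
]


def equivalent_radius(R_f: float, R_t: float) -> float:
    """Harmonic-mean equivalent radius of two convex profiles, in metres.

    ``R = 1 / (1/R_f + 1/R_t)``.  ``math.inf`` is accepted for a flat
    counter-body, in which case ``R`` equals the other radius.
    """
    if R_f <= 0 or R_t <= 0:
        raise ValueError(f"radii must be positive, got R_f={R_f}, R_t={R_t}")
    if math.isinf(R_f):
        return R_t
    if math.isinf(R_t):
        return R_f
    return R_f * R_t / (R_f + R_t)


def _check_material(E: float, nu: float, tag: str) -> None:
    if E <= 0:
        raise ValueError(f"Young's modulus E_{tag} must be positive, got {E}")
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson ratio nu_{tag} must lie in [0, 0.5), got {nu}")


def equivalent_modulus(E_f: float, nu_f: float, E_t: float, nu_t: float) -> float:
    """Equivalent Young's modulus of the single-body reduction, in Pa.

    ``E = [E_f^2 E_t (1+nu_f^2)^2 + E_t^2 E_f (1+nu_t^2)^2]
    / [E_f (1+nu_t) + E_t (1+nu_f)]^2``.

    Symmetric under exchange of the two bodies; reduces to ``E/2`` for two
    identical bodies with ``nu = 0``.
    """
    _check_material(E_f, nu_f, "f")
    _check_material(E_t, nu_t, "t")
    num = E_f**2 * E_t * (1.0 + nu_f**2) ** 2 + E_t**2 * E_f * (1.0 + nu_t**2) ** 2
    den = (E_f * (1.0 + nu_t) + E_t * (1.0 + nu_f)) ** 2
    return num / den


def equivalent_poisson(E_f: float, nu_f: float, E_t: float, nu_t: float) -> float:
    """Equivalent Poisson's ratio of the single-body reduction.

    ``nu = [E_f nu_t (1+nu_t) + E_t nu_f (1+nu_f)]
    / [E_f (1+nu_t) + E_t (1+nu_f)]``.
    """
    _check_material(E_f, nu_f, "f")
    _check_material(E_t, nu_t, "t")
    num = E_f * nu_t * (1.0 + nu_t) + E_t * nu_f * (1.0 + nu_f)
    den = E_f * (1.0 + nu_t) + E_t * (1.0 + nu_f)
    return num / den


@dataclass(frozen=True)
class CompartmentGeometry:
    """Line-contact geometry of one compartment (medial or lateral).

    Parameters are the anterior-posterior femoral radius ``R_f`` and tibial
    radius ``R_t`` plus the contact length ``l`` in the medial-lateral
    direction; the equivalent radius ``R`` is derived.
    All lengths in metres.
    """

    R_f: float
    R_t: float
    l: float
    R: float = field(init=False)

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"contact length must be positive, got {self.l}")
        object.__setattr__(self, "R", equivalent_radius(self.R_f, self.R_t))


@dataclass(frozen=True)
class MaterialPair:
    """Elastic constants of femoral/tibial components and their reduction.

    ``E`` and ``nu`` are the equivalent-body constants; ``E_ps`` is the
    plane-strain modulus ``E / (1 - nu^2)`` of the equivalent body, the
    stiffness that enters the Hertzian scales.
    """

    E_f: float
    nu_f: float
    E_t: float
    nu_t: float
    E: float = field(init=False)
    nu: float = field(init=False)
    E_ps: float = field(init=False)

    def __post_init__(self) -> None:
        E = equivalent_modulus(self.E_f, self.nu_f, self.E_t, self.nu_t)
        nu = equivalent_poisson(self.E_f, self.nu_f, self.E_t, self.nu_t)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "E_ps", E / (1.0 - nu**2))


@dataclass(frozen=True)
class FluidModel:
    """Iso-viscous, incompressible synovial-fluid model.

    rho: density [kg/m^3]; eta: dynamic viscosity [Pa s].  In dimensionless
    form both reduce to unity (no piezo-viscosity, no compressibility).
    """

    rho: float = 1000.0
    eta: float = 0.1

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass(frozen=True)
class HertzReference:
    """Hertzian line-contact scales at a reference instant of the cycle.

    w_ref   load per unit length at the reference phase [N/m]
    a_H     Hertz half-width  sqrt(4 w_ref R / (pi E_ps)) [m]
    p_H     Hertz peak pressure  2 w_ref / (pi a_H) [Pa]
    u_scale velocity used for the time scale a_H/u_scale [m/s]
    """

    t_ref: float
    w_ref: float
    a_H: float
    p_H: float
    u_scale: float


def hertz_line_reference(
    F: float,
    l: float,
    R: float,
    E_ps: float,
    t_ref: float = 0.0,
    u_scale: float = 1.0,
) -> HertzReference:
    """Hertz reference quantities for load ``F`` on a contact of length ``l``.

    Satisfies the identity ``p_H * pi * a_H / 2 == w_ref`` exactly.
    """
    if l <= 0:
        raise ValueError(f"contact length must be positive, got {l}")
    if F <= 0 or R <= 0 or E_ps <= 0:
        raise ValueError("F, R and E_ps must be positive")
    if u_scale <= 0:
        raise ValueError("u_scale must be positive")
    w_ref = F / l
    a_H = math.sqrt(4.0 * w_ref * R / (math.pi * E_ps))
    p_H = 2.0 * w_ref / (math.pi * a_H)
    return HertzReference(t_ref=t_ref, w_ref=w_ref, a_H=a_H, p_H=p_H, u_scale=u_scale)


@dataclass(frozen=True)
class Normalization:
    """Hertzian non-dimensionalisation of the transient line-contact problem.

    X = x/a_H, Z = z/a_H, P = p/p_H, H = h R/a_H^2, delta_bar = delta R/a_H^2,
    T = t u_scale/a_H.  Each map has an exact inverse.
    """

    hertz: HertzReference
    R: float

    # -- lengths along the contact ------------------------------------
    def X(self, x):
        return x / self.hertz.a_H

    def x(self, X):
        return X * self.hertz.a_H

    # -- pressures ----------------------------------------------------
    def P(self, p):
        return p / self.hertz.p_H

    def p(self, P):
        return P * self.hertz.p_H

    # -- film / deflection --------------------------------------------
    def H(self, h):
        return h * self.R / self.hertz.a_H**2

    def h(self, H):
        return H * self.hertz.a_H**2 / self.R

    # -- time ---------------------------------------------------------
    def T(self, t):
        return t * self.hertz.u_scale / self.hertz.a_H

    def t(self, T):
        return T * self.hertz.a_H / self.hertz.u_scale
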