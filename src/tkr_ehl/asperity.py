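"""Statistical (Greenwood-Tripp) asperity contact pressure.

Mixed lubrication is handled stochastically: the mean solid contact
pressure carried by asperities of two nominally flat rough surfaces with
Gaussian summit heights is

    p_a(lambda) = K * E_gt * F_{5/2}(lambda),

where ``lambda = h / sigma`` is the film parameter (gap over combined RMS
roughness), ``E_gt`` an elastic modulus, and ``K`` the dimensionless
composite surface constant ``(16 sqrt(2) / 15) pi (eta_s beta sigma)^2
sqrt(sigma / beta)`` built from the summit density ``eta_s`` and summit
radius ``beta``.  ``F_{5/2}`` is the Gaussian tail moment

    F_{5/2}(lambda) = int_lambda^inf (s - lambda)^{5/2} phi(s) ds,

with ``phi`` the standard normal density.  The curve is pre-tabulated and
fed to the macro-scale lubrication model as a monotone interpolant that is
exactly zero beyond a cutoff film parameter (default 4, where the Gaussian
tail is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

__all__ = [
    "RoughnessModel",
    "AsperityTable",
    "gt_statistical_integral",
    "gt_pressure",
    "build_asperity_table",
    "film_parameter",
    "composite_gt_prefactor",
]

#: default composite surface parameters: eta_s * beta * sigma and sigma / beta
DEFAULT_ETA_BETA_SIGMA = 0.04
DEFAULT_SIGMA_OVER_BETA = 1e-3


def composite_gt_prefactor(
    eta_beta_sigma: float = DEFAULT_ETA_BETA_SIGMA,
    sigma_over_beta: float = DEFAULT_SIGMA_OVER_BETA,
) -> float:
    """Dimensionless Greenwood-Tripp prefactor K from composite parameters."""
    if eta_beta_sigma <= 0 or sigma_over_beta <= 0:
        raise ValueError("composite surface parameters must be positive")
    return (16.0 * math.sqrt(2.0) / 15.0) * math.pi * eta_beta_sigma**2 * math.sqrt(sigma_over_beta)


@dataclass(frozen=True)
class RoughnessModel:
    """Combined roughness and Greenwood-Tripp constants of the pairing.

    sigma:  combined RMS roughness [m]
    K:      composite dimensionless prefactor (see module docstring)
    E_gt:   elastic modulus entering the asperity pressure [Pa]; by default
            the plane-strain modulus of the equivalent body is used.
    lambda_cut: film parameter above which solid contact is taken as zero.
    """

    sigma: float
    E_gt: float
    K: float = field(default_factory=composite_gt_prefactor)
    lambda_cut: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"RMS roughness must be positive, got {self.sigma}")
        if self.K <= 0 or self.E_gt <= 0:
            raise ValueError("K and E_gt must be positive")
        if self.lambda_cut <= 0:
            raise ValueError("lambda_cut must be positive")


def film_parameter(h, sigma: float):
    """Film parameter ``lambda = h / sigma`` (both in metres)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("film thickness must be non-negative")
    lam = h / sigma
    return float(lam) if lam.ndim == 0 else lam


def gt_statistical_integral(lam: float) -> float:
    """Gaussian tail moment F_{5/2}(lambda), by adaptive quadrature.

    Absolute tolerance 1e-12; decays like exp(-lambda^2/2) so the integral
    is truncated at lambda + 40 where the integrand is far below tolerance.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")

    def integrand(s: float) -> float:
        return (s - lam) ** 2.5 * math.exp(-0.5 * s * s) / math.sqrt(2.0 * math.pi)

    val, _ = quad(integrand, lam, lam + 40.0, epsabs=1e-12, epsrel=1e-11, limit=200)
    return val


def gt_pressure(lam, model: RoughnessModel):
    """Mean asperity contact pressure p_a(lambda) [Pa].

    Zero at and beyond the cutoff; non-negative and non-increasing in
    lambda.  Accepts scalars or arrays.
    """
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be non-negative")
    out = np.zeros_like(lam_arr)
    inside = lam_arr < model.lambda_cut
    out[inside] = model.K * model.E_gt * np.array(
        [gt_statistical_integral(v) for v in lam_arr[inside]]
    )
    return float(out[0]) if np.isscalar(lam) or np.ndim(lam) == 0 else out


@dataclass(frozen=True)
class AsperityTable:
    """Tabulated p_a(lambda) curve with a monotone (PCHIP) interpolant.

    The interpolant is clamped to zero for lambda >= lambda_cut and never
    returns negative values, which keeps Newton iterations of the coupled
    solver free of spurious tensile asperity pressure.
    """

    lam: np.ndarray
    p_a: np.ndarray
    lambda_cut: float
    _interp: PchipInterpolator = field(repr=False)
    _deriv: PchipInterpolator = field(repr=False)

    def pressure(self, lam):
        """Interpolated asperity pressure [Pa] at film parameter ``lam``."""
        lam = np.asarray(lam, dtype=float)
        out = np.where(
            lam >= self.lambda_cut, 0.0, np.maximum(self._interp(np.clip(lam, 0.0, None)), 0.0)
        )
        return float(out) if out.ndim == 0 else out

    def derivative(self, lam):
        """d p_a / d lambda [Pa], zero beyond the cutoff."""
        lam = np.asarray(lam, dtype=float)
        out = np.where(lam >= self.lambda_cut, 0.0, self._deriv(np.clip(lam, 0.0, None)))
        return float(out) if out.ndim == 0 else out

    def __call__(self, lam):
        return self.pressure(lam)


def build_asperity_table(
    model: RoughnessModel, lambda_max: float | None = None, n_nodes: int = 200
) -> AsperityTable:
    """Tabulate p_a on [0, lambda_cut] and wrap a monotone interpolant.

    Node values come straight from quadrature; beyond the cutoff the curve
    is clamped to zero (the Gaussian tail there is below 1e-4 of the
    contact-onset value, so the jump is negligible against the curve scale).
    """
    if n_nodes < 50:
        raise ValueError(f"need at least 50 nodes for the asperity table, got {n_nodes}")
    cut = model.lambda_cut if lambda_max is None else min(lambda_max, model.lambda_cut)
    lam = np.linspace(0.0, cut, n_nodes)
    p = np.array([model.K * model.E_gt * gt_statistical_integral(v) for v in lam])
    interp = PchipInterpolator(lam, p, extrapolate=False)
    return AsperityTable(
        lam=lam, p_a=p, lambda_cut=cut, _interp=interp, _deriv=interp.derivative()
    )
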