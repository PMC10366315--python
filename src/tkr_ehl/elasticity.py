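"""Plane-strain elastic deflection of the equivalent body.

The equivalent body occupies a large rectangle below the contact line
(default 60 x 60 Hertzian half-widths).  Its linear-elastic response is
governed by div(C : eps(U)) = 0 with zero displacement on the bottom edge,
the total pressure applied as normal stress on the loaded top segment, and
traction-free remaining boundaries.  Because the operator is linear in the
applied pressure, the PDE is assembled and factorised once and condensed
into a compliance matrix mapping nodal contact pressures to surface
normal deflections; the coupled lubrication solver then applies it as a
dense operator.

Discretisation: bilinear quadrilaterals on a structured mesh, uniform in
the refined contact zone and geometrically graded towards the far field,
with a mean-dilatation (B-bar) formulation.  The equivalent material of a
metal-on-polyethylene pairing is nearly incompressible (nu ~ 0.46), where
plain displacement elements lock volumetrically; the B-bar treatment keeps
the surface compliance accurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = ["SolutionDomain", "compliance_matrix", "elastic_deflection", "solve_surface_displacement"]


@dataclass(frozen=True)
class SolutionDomain:
    """FEM domain in Hertz half-width units.

    The contact (lubrication) interval is [-x_c, x_c] on the top edge of an
    elasticity rectangle of ``width`` x ``depth``, centred on the contact.
    ``n_contact`` nodes span the contact interval uniformly; outside it the
    mesh spacing grows geometrically by ``growth`` per layer.
    """

    x_c: float = 4.5
    n_contact: int = 161
    width: float = 60.0
    depth: float = 60.0
    growth: float = 1.3

    def __post_init__(self) -> None:
        if self.n_contact < 11:
            raise ValueError("need at least 11 contact nodes")
        if self.width < 2 * self.x_c or self.depth <= 0:
            raise ValueError("elasticity rectangle must contain the contact interval")
        if self.growth <= 1.0:
            raise ValueError("grading ratio must exceed 1")

    @property
    def x_contact(self) -> np.ndarray:
        return np.linspace(-self.x_c, self.x_c, self.n_contact)

    @property
    def dx(self) -> float:
        return 2.0 * self.x_c / (self.n_contact - 1)

    def refined(self, factor: int = 2) -> "SolutionDomain":
        """Same domain with the contact mesh refined by an integer factor."""
        return SolutionDomain(
            x_c=self.x_c,
            n_contact=(self.n_contact - 1) * factor + 1,
            width=self.width,
            depth=self.depth,
            growth=self.growth,
        )


def _graded(start: float, target: float, h0: float, growth: float) -> np.ndarray:
    """Coordinates from ``start`` towards ``target`` with geometric spacings."""
    pts = [start]
    h = h0
    direction = 1.0 if target > start else -1.0
    while abs(pts[-1] - start) < abs(target - start) - 1e-12:
        nxt = pts[-1] + direction * h
        if abs(nxt - start) >= abs(target - start):
            nxt = target
        pts.append(nxt)
        h *= growth
    # avoid a sliver last element: merge if below 40% of its neighbour
    if len(pts) >= 3 and abs(pts[-1] - pts[-2]) < 0.4 * abs(pts[-2] - pts[-3]):
        del pts[-2]
    return np.array(pts[1:])


def _mesh_coordinates(domain: SolutionDomain) -> tuple[np.ndarray, np.ndarray]:
    dx = domain.dx
    xc = domain.x_contact
    right = _graded(domain.x_c, domain.width / 2.0, dx * domain.growth, domain.growth)
    x = np.concatenate([-right[::-1], xc, right])
    z = -np.concatenate([[0.0], _graded(0.0, domain.depth, dx, domain.growth)])[::-1]
    return x, z


def _plane_strain_D(nu: float, E: float = 1.0) -> np.ndarray:
    c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array(
        [
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, 0.5 * (1.0 - 2.0 * nu)],
        ]
    )


def _assemble_stiffness(x: np.ndarray, z: np.ndarray, nu: float) -> sp.csr_matrix:
    """Vectorised B-bar Q4 plane-strain stiffness on the structured grid.

    Node numbering: ``n = ix * nz + iz``; 2 dofs (u_x, u_z) per node.
    """
    nx, nz = x.size, z.size
    D = _plane_strain_D(nu)

    ix, iz = np.meshgrid(np.arange(nx - 1), np.arange(nz - 1), indexing="ij")
    ix = ix.ravel()
    iz = iz.ravel()
    n_el = ix.size
    a = (x[ix + 1] - x[ix])[:, None]  # element widths
    b = (z[iz + 1] - z[iz])[:, None]  # element heights

    # corner nodes, counter-clockwise in (x, z)
    n1 = ix * nz + iz
    n2 = (ix + 1) * nz + iz
    n3 = (ix + 1) * nz + iz + 1
    n4 = ix * nz + iz + 1
    conn = np.stack([n1, n2, n3, n4], axis=1)

    gp = 1.0 / np.sqrt(3.0)
    gauss = [(-gp, -gp), (gp, -gp), (gp, gp), (-gp, gp)]

    def grads(xi: float, eta: float):
        dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
        dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
        return dN_dxi, dN_deta

    def B_at(xi: float, eta: float) -> np.ndarray:
        dN_dxi, dN_deta = grads(xi, eta)
        dN_dx = dN_dxi[None, :] * (2.0 / a)  # (n_el, 4)
        dN_dz = dN_deta[None, :] * (2.0 / b)
        B = np.zeros((n_el, 3, 8))
        B[:, 0, 0::2] = dN_dx
        B[:, 1, 1::2] = dN_dz
        B[:, 2, 0::2] = dN_dz
        B[:, 2, 1::2] = dN_dx
        return B

    Bs = [B_at(xi, eta) for xi, eta in gauss]
    # mean-dilatation: replace the volumetric operator by its element mean
    bvol = [B[:, 0, :] + B[:, 1, :] for B in Bs]
    bvol_mean = sum(bvol) / 4.0
    ke = np.zeros((n_el, 8, 8))
    detJ = (a * b / 4.0)[:, :, None]
    for B, bv in zip(Bs, bvol):
        Bbar = B.copy()
        corr = 0.5 * (bvol_mean - bv)
        Bbar[:, 0, :] += corr
        Bbar[:, 1, :] += corr
        ke += np.einsum("eia,ij,ejb->eab", Bbar, D, Bbar) * detJ

    dofs = np.empty((n_el, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(2 * nx * nz, 2 * nx * nz))
    return K.tocsr()


def _contact_mass_1d(x_contact: np.ndarray) -> np.ndarray:
    """Consistent 1-D mass matrix of linear elements on the contact grid."""
    n = x_contact.size
    M = np.zeros((n, n))
    h = np.diff(x_contact)
    for e in range(n - 1):
        M[e : e + 2, e : e + 2] += h[e] / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
    return M


class _ComplianceSolver:
    """Factorised FEM operator returning surface motion under contact loads."""

    def __init__(self, domain: SolutionDomain, nu: float):
        x, z = _mesh_coordinates(domain)
        self.x, self.z = x, z
        nx, nz = x.size, z.size
        K = _assemble_stiffness(x, z, nu)

        fixed = np.zeros(2 * nx * nz, dtype=bool)
        bottom_nodes = np.arange(nx) * nz + 0  # z[0] = -depth
        fixed[2 * bottom_nodes] = True
        fixed[2 * bottom_nodes + 1] = True
        self.free = np.flatnonzero(~fixed)
        self.lu = splu(K[self.free][:, self.free].tocsc())

        i0 = int(np.searchsorted(x, -domain.x_c - 1e-12))
        self.contact_nodes = (np.arange(i0, i0 + domain.n_contact)) * nz + (nz - 1)
        assert np.allclose(x[i0 : i0 + domain.n_contact], domain.x_contact, atol=1e-10)
        self.n_dof = 2 * nx * nz
        self.M1d = _contact_mass_1d(domain.x_contact)

    def surface_uz(self, P: np.ndarray) -> np.ndarray:
        """u_z at contact nodes for nodal pressure P (downward load)."""
        f = np.zeros(self.n_dof)
        f[2 * self.contact_nodes + 1] = -self.M1d @ P
        u = np.zeros(self.n_dof)
        u[self.free] = self.lu.solve(f[self.free])
        return u[2 * self.contact_nodes + 1]

    def compliance(self) -> np.ndarray:
        n_c = self.contact_nodes.size
        F = np.zeros((self.n_dof, n_c))
        F[2 * self.contact_nodes + 1, :] = -self.M1d
        U = np.zeros_like(F)
        U[self.free] = self.lu.solve(F[self.free])
        return -U[2 * self.contact_nodes + 1, :]  # deflection positive into body


@lru_cache(maxsize=8)
def _cached_solver(domain: SolutionDomain, nu_key: float) -> _ComplianceSolver:
    return _ComplianceSolver(domain, nu_key)


def compliance_matrix(domain: SolutionDomain, nu: float) -> np.ndarray:
    """Dense matrix C with delta = C @ P on the contact grid (unit modulus).

    ``P`` are nodal pressures (dimensionless amplitude) on the contact
    nodes and ``delta`` the surface normal deflection, positive into the
    body, for a material of unit Young's modulus and Poisson ratio ``nu``.
    Dimensional use scales by pressure over modulus and by length.
    Cached per (domain, nu).
    """
    return _cached_solver(domain, round(nu, 12)).compliance()


def solve_surface_displacement(domain: SolutionDomain, nu: float, P: np.ndarray) -> np.ndarray:
    """Surface deflection (positive into the body) for nodal pressures P."""
    return -_cached_solver(domain, round(nu, 12)).surface_uz(np.asarray(P, dtype=float))


def elastic_deflection(P_total: np.ndarray, domain: SolutionDomain, nu: float) -> np.ndarray:
    """Deflection of the contact surface under a total-pressure field.

    Thin wrapper over the precomputed compliance operator: linear in the
    applied pressure by construction.
    """
    P_total = np.asarray(P_total, dtype=float)
    if P_total.shape != (domain.n_contact,):
        raise ValueError("pressure field must live on the contact nodes")
    if not np.all(np.isfinite(P_total)):
        raise ValueError("pressure field contains non-finite values")
    return compliance_matrix(domain, nu) @ P_total
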