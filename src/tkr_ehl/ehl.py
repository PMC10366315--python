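"""Coupled transient mixed-lubrication solver for the equivalent line contact.

The dimensionless system solved on the contact interval Omega_c is

  d/dX( eps * H^3 * dP/dX ) - d/dX( H * U ) - dH/dT = 0        (Reynolds)
  H(X) = H0 + X^2/2 + delta_bar(X)                             (film)
  delta_bar = kappa * C @ (P + P_a)                            (elasticity)
  P_a = p_a( lambda(H) ) / p_H                                 (asperities)
  int (P + P_a) dX = (pi/2) * w(t) / w_ref                     (load balance)

with X = x/a_H, P = p/p_H, H = h R/a_H^2, T = t u_scale/a_H and the
Poiseuille coefficient eps = a_H^3 p_H / (12 eta u_scale R^2) induced by
the Hertzian normalisation at the reference instant.  U = u_m/u_scale is
the instantaneous entrainment velocity.  The fluid is iso-viscous and
incompressible (rho_bar = eta_bar = 1); piezo-viscous, thermal and
shear-thinning effects are out of model scope.

Cavitation is handled by a penalty that drives sub-ambient pressure
towards zero; the time derivative uses an implicit second-order backward
differentiation formula (BDF1 on the first step); the full set of
unknowns (nodal pressure, rigid-body separation) is solved monolithically
by a damped Newton method with an analytic Jacobian, with the elastic
deflection eliminated through the precomputed compliance operator and the
asperity pressure re-evaluated from the film inside every iteration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .asperity import AsperityTable, RoughnessModel, build_asperity_table
from .contact import (
    CompartmentGeometry,
    FluidModel,
    HertzReference,
    MaterialPair,
    Normalization,
    hertz_line_reference,
)
from .elasticity import SolutionDomain, compliance_matrix
from .profiles import GaitProfile, resample_profile

__all__ = [
    "CompartmentSetup",
    "SimulationConfig",
    "EHLState",
    "GaitSolution",
    "SolverError",
    "LineContactSolver",
    "film_thickness",
    "cavitation_penalty",
    "load_balance_residual",
    "hertz_pressure_profile",
]

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Newton divergence or non-finite fields; carries an iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# small free-standing pieces of the model
# ---------------------------------------------------------------------------

def film_thickness(H0: float, X: np.ndarray, delta_bar: np.ndarray) -> np.ndarray:
    """Dimensionless film H = H0 + X^2/2 + delta_bar."""
    return H0 + 0.5 * np.asarray(X) ** 2 + np.asarray(delta_bar)


def cavitation_penalty(P: np.ndarray, xi: float) -> np.ndarray:
    """Penalty contribution xi * min(P, 0): inactive wherever P >= 0."""
    if xi <= 0:
        raise ValueError("penalty coefficient must be positive")
    return xi * np.minimum(np.asarray(P, dtype=float), 0.0)


def load_balance_residual(
    P: np.ndarray, P_a: np.ndarray, w: float, hertz: HertzReference, X: np.ndarray
) -> float:
    """Relative load-balance residual of the dimensionless equilibrium.

    int (P + P_a) dX must equal (pi/2) w / w_ref; returns the relative
    defect, -1 for identically zero pressure.
    """
    integral = float(np.trapezoid(np.asarray(P) + np.asarray(P_a), np.asarray(X)))
    if w == 0.0:
        return math.nan if integral else 0.0
    target = 0.5 * math.pi * w / hertz.w_ref
    return integral / target - 1.0


def hertz_pressure_profile(X: np.ndarray, w_over_wref: float = 1.0) -> np.ndarray:
    """Hertzian semi-ellipse carrying ``w_over_wref`` times the reference load.

    Half-width and amplitude both scale with sqrt(w/w_ref) so the integral
    equals (pi/2) w/w_ref exactly.
    """
    s = math.sqrt(w_over_wref)
    return s * np.sqrt(np.clip(1.0 - (np.asarray(X) / s) ** 2, 0.0, None))


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentSetup:
    """Everything the solver needs about one compartment.

    roughness=None disables solid asperity contact entirely (pure EHL).
    """

    geometry: CompartmentGeometry
    materials: MaterialPair
    fluid: FluidModel = field(default_factory=FluidModel)
    roughness: RoughnessModel | None = None

    def asperity_table(self, n_nodes: int = 200) -> AsperityTable | None:
        if self.roughness is None:
            return None
        return build_asperity_table(self.roughness, n_nodes=n_nodes)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical controls of the transient solver.

    steps_per_cycle  time steps over one gait cycle (>= 50)
    n_cycles         cycles to simulate; with cyclic_convergence the loop
                     repeats until the cycle-integrated asperity-friction
                     integrand changes by less than cyclic_tol
    newton_tol       dimensionless residual and update tolerance
    xi               cavitation penalty coefficient
    upwind           donor-cell upwinding of the Couette (film-transport)
                     term; the default convection stabilisation.  The
                     central alternative (upwind=False) is second-order but
                     fragile at a strongly pinched film
    stab_coeff       additional isotropic-diffusion constant (0 = off)
    h_reg_lambda     film parameter below which the Poiseuille mobility is
                     linearised (residual inter-asperity leakage in the
                     boundary-contact limit, where a smooth-film Reynolds
                     description no longer holds; also removes the
                     trapped-pocket degeneracy of a vanishing film)
    lambda_contact   film parameter below which a unilateral gap penalty
                     transfers load directly between the solids.  The
                     statistical asperity curve built from the configured
                     surface constants is far too compliant on a polymer
                     counterface to arrest film collapse; without a contact
                     barrier the drained stance phases have no positive-gap
                     solution.  The penalty pressure is reported separately
                     from the asperity pressure and is excluded from the
                     frictional-power metric
    contact_penalty  dimensionless stiffness of that barrier (units of the
                     Hertz reference pressure at full gap closure)
    t_ref_phase      reference phase for the Hertzian scales; None = phase
                     of maximum compartment load
    u_scale_policy   'max_abs' (default, max |u_m| over the cycle) or
                     't_ref' (|u_m| at the reference phase, the literal
                     normalisation choice; degenerate when the reference
                     phase sits at a motion reversal)
    lambda_init      initial film parameter seeding the first film guess
    """

    steps_per_cycle: int = 200
    n_cycles: int = 1
    cyclic_convergence: bool = False
    cyclic_tol: float = 0.01
    max_cycles: int = 8
    newton_tol: float = 1e-6
    newton_max_iter: int = 30
    xi: float = 1e4
    upwind: bool = True
    stab_coeff: float = 0.0
    h_reg_lambda: float = 0.1
    lambda_contact: float = 0.05
    contact_penalty: float = 30.0
    t_ref_phase: float | None = None
    u_scale_policy: str = "max_abs"
    lambda_init: float = 1.5
    record_fields: bool = True

    def __post_init__(self) -> None:
        if self.steps_per_cycle < 50:
            raise ValueError("need at least 50 steps per cycle")
        if self.newton_tol <= 0 or self.xi <= 0:
            raise ValueError("tolerances and penalty coefficient must be positive")
        if self.u_scale_policy not in ("max_abs", "t_ref"):
            raise ValueError(f"unknown u_scale policy {self.u_scale_policy!r}")


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class EHLState:
    """Converged fields of one time step (dimensionless + dimensional)."""

    T: float
    phase: float
    H0: float
    P: np.ndarray
    P_a: np.ndarray
    H: np.ndarray
    delta_bar: np.ndarray
    w: float
    u_m: float
    u_s: float = 0.0  # sliding velocity, metadata only
    P_c: np.ndarray | None = None  # unilateral gap-penalty pressure
    newton_iters: int = 0
    load_residual: float = 0.0
    # dimensional mirrors, filled by the solver
    p: np.ndarray | None = None
    p_a: np.ndarray | None = None
    p_c: np.ndarray | None = None
    h: np.ndarray | None = None
    delta: np.ndarray | None = None

    @property
    def p_total(self) -> np.ndarray:
        """Total contact pressure: fluid + asperity + gap penalty [Pa]."""
        out = self.p + self.p_a
        if self.p_c is not None:
            out = out + self.p_c
        return out


@dataclass
class GaitSolution:
    """Ordered converged states over the simulated cycle plus derived traces."""

    phase: np.ndarray
    time: np.ndarray
    states: list[EHLState]
    hertz: HertzReference
    norm: Normalization
    setup: CompartmentSetup
    config: SimulationConfig
    domain: SolutionDomain
    X: np.ndarray
    cycles_run: int = 1
    # traces (same length as phase)
    p_max: np.ndarray | None = None
    p_a_max: np.ndarray | None = None
    h_min: np.ndarray | None = None
    lambda_min: np.ndarray | None = None
    asperity_load_share: np.ndarray | None = None

    def compute_traces(self) -> None:
        """(Re)derive all per-phase traces from the stored states."""
        sigma = self.setup.roughness.sigma if self.setup.roughness else None
        p_max, pa_max, h_min, lam_min, share = [], [], [], [], []
        for st in self.states:
            p_max.append(st.p_total.max())
            pa_max.append(st.p_a.max())
            h_min.append(st.h.min())
            lam_min.append(st.h.min() / sigma if sigma else np.inf)
            total = float(np.trapezoid(st.p_total, self.X))
            share.append(float(np.trapezoid(st.p_a, self.X) / total) if total > 0 else 0.0)
        self.p_max = np.array(p_max)
        self.p_a_max = np.array(pa_max)
        self.h_min = np.array(h_min)
        self.lambda_min = np.array(lam_min)
        self.asperity_load_share = np.array(share)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

class LineContactSolver:
    """Monolithic Newton solver for the coupled transient problem.

    Scales (Hertz reference, Poiseuille coefficient, compliance operator)
    are fixed once in :meth:`prepare`; individual states are then advanced
    with :meth:`solve_time_step` / :meth:`solve_steady`, or a whole cycle
    with :meth:`run_gait`.
    """

    def __init__(
        self,
        setup: CompartmentSetup,
        domain: SolutionDomain | None = None,
        config: SimulationConfig | None = None,
    ):
        self.setup = setup
        self.domain = domain or SolutionDomain()
        self.config = config or SimulationConfig()
        self.X = self.domain.x_contact
        self.dX = self.domain.dx
        n = self.X.size
        # trapezoid / lumped-mass weights
        self.m_w = np.full(n, self.dX)
        self.m_w[0] = self.m_w[-1] = 0.5 * self.dX
        # consistent mass (tridiagonal) as dense bands
        self._mass_main = np.full(n, 2.0 * self.dX / 3.0)
        self._mass_main[0] = self._mass_main[-1] = self.dX / 3.0
        self._mass_off = np.full(n - 1, self.dX / 6.0)
        self.hertz: HertzReference | None = None
        self.table: AsperityTable | None = None

    # -- scale setup ----------------------------------------------------
    def prepare(self, w_ref: float, u_scale: float, t_ref: float = 0.0) -> None:
        g = self.setup.geometry
        m = self.setup.materials
        f = self.setup.fluid
        self.hertz = hertz_line_reference(
            w_ref * g.l, g.l, g.R, m.E_ps, t_ref=t_ref, u_scale=u_scale
        )
        self.norm = Normalization(self.hertz, g.R)
        a_H, p_H = self.hertz.a_H, self.hertz.p_H
        self.eps = a_H**3 * p_H / (12.0 * f.eta * u_scale * g.R**2)
        # deflection scale of the unit-modulus compliance operator
        self.kappa = p_H * g.R / (a_H * m.E)
        self.C = compliance_matrix(self.domain, m.nu)
        self.h_scale = a_H**2 / g.R  # metres per unit H
        self.table = self.setup.asperity_table()
        if self.setup.roughness is not None:
            sigma_H = self.setup.roughness.sigma / self.h_scale
            self.H_reg = self.config.h_reg_lambda * sigma_H
            self.H_c = self.config.lambda_contact * sigma_H
        else:
            self.H_reg = 5e-4
            self.H_c = self.H_reg

    def _require_prepared(self) -> None:
        if self.hertz is None:
            raise RuntimeError("call prepare() before solving")

    # -- asperity coupling ---------------------------------------------
    def _g(self, H: np.ndarray) -> np.ndarray:
        """Dimensionless asperity pressure P_a as a function of H."""
        if self.table is None:
            return np.zeros_like(H)
        lam = np.clip(H, 0.0, None) * self.h_scale / self.setup.roughness.sigma
        return self.table.pressure(lam) / self.hertz.p_H

    def _g_prime(self, H: np.ndarray) -> np.ndarray:
        if self.table is None:
            return np.zeros_like(H)
        fac = self.h_scale / self.setup.roughness.sigma
        lam = np.clip(H, 0.0, None) * fac
        return self.table.derivative(lam) * fac / self.hertz.p_H

    def _gc(self, H: np.ndarray) -> np.ndarray:
        """Unilateral gap-penalty pressure (dimensionless), C^1 in H."""
        z = np.maximum(0.0, (self.H_c - H) / self.H_c)
        return self.config.contact_penalty * z**2

    def _gc_prime(self, H: np.ndarray) -> np.ndarray:
        z = np.maximum(0.0, (self.H_c - H) / self.H_c)
        return -2.0 * self.config.contact_penalty * z / self.H_c

    def _g_solid(self, H: np.ndarray) -> np.ndarray:
        """Total solid-borne pressure: statistical asperities + gap penalty."""
        return self._g(H) + self._gc(H)

    def _g_solid_prime(self, H: np.ndarray) -> np.ndarray:
        return self._g_prime(H) + self._gc_prime(H)

    # -- film elimination ----------------------------------------------
    def _solve_film(self, P: np.ndarray, H0: float, H_guess: np.ndarray | None = None):
        """Solve H = H0 + X^2/2 + kappa C (P + g(H)) for H (inner Newton).

        g(H) is the total solid-borne pressure (statistical asperity curve
        plus the unilateral gap penalty).
        """
        base = H0 + 0.5 * self.X**2
        CP = self.kappa * (self.C @ P)
        H = H_guess.copy() if H_guess is not None else base + CP
        if self.kappa == 0.0:
            return base + CP
        for _ in range(50):
            r = H - base - CP - self.kappa * (self.C @ self._g_solid(H))
            if np.abs(r).max() < 1e-13 * max(1.0, np.abs(H).max()):
                break
            J = np.eye(H.size) - self.kappa * self.C * self._g_solid_prime(H)[None, :]
            H = H - np.linalg.solve(J, r)
        return H

    # -- residual assembly ---------------------------------------------
    def _residual_terms(self, P, H, H_hist, c_dt, dT, Ubar):
        """Poiseuille, Couette, squeeze and penalty residual vectors.

        c_dt are BDF weights (c0, c1, c2) applied to (H, H_prev, H_prev2);
        pass (0, 0, 0) for a steady solve.
        """
        dX = self.dX
        Hbar = 0.5 * (H[:-1] + H[1:])
        coef = self.eps * self._pois_coef(Hbar) + (
            self.config.stab_coeff * abs(Ubar) * self.kappa * dX / 2.0
        )
        dP = np.diff(P) / dX
        flux = coef * dP  # eps H^3 dP/dX per element (+ stabilising diffusion)
        pois = np.zeros_like(P)
        pois[:-1] += flux
        pois[1:] -= flux
        # Couette: int H U dphi_i/dX, with the transported film taken either
        # centred or from the upwind node of each element
        if self.config.upwind and Ubar != 0.0:
            Hc = H[:-1] if Ubar > 0 else H[1:]
        else:
            Hc = Hbar
        cou = np.zeros_like(P)
        cou[:-1] -= Ubar * Hc
        cou[1:] += Ubar * Hc
        # squeeze: -M @ dH/dT with BDF weights
        if dT > 0 and any(c_dt):
            Hdot = (c_dt[0] * H + c_dt[1] * H_hist[0] + c_dt[2] * H_hist[1]) / dT
            sq = -self._mass_apply(Hdot)
        else:
            sq = np.zeros_like(P)
        pen = -self.m_w * cavitation_penalty(P, self.config.xi)
        return pois, cou, sq, pen

    def _pois_coef(self, Hbar: np.ndarray) -> np.ndarray:
        """Poiseuille mobility H^3, linearised below the regularisation gap.

        For films below H_reg (boundary-contact regime, where the smooth
        Reynolds description has broken down) the cubic mobility is replaced
        by H_reg^2 * H: continuous at H_reg and vanishing with the gap, so
        a draining film decays exponentially instead of reaching zero in
        finite time.
        """
        return np.where(
            Hbar >= self.H_reg,
            Hbar**3,
            self.H_reg**2 * np.maximum(Hbar, 0.0),
        )

    def _pois_coef_deriv(self, Hbar: np.ndarray) -> np.ndarray:
        return np.where(
            Hbar >= self.H_reg, 3.0 * Hbar**2, self.H_reg**2 * (Hbar > 0.0)
        )

    def _mass_apply(self, v: np.ndarray) -> np.ndarray:
        out = self._mass_main * v
        out[:-1] += self._mass_off * v[1:]
        out[1:] += self._mass_off * v[:-1]
        return out

    def reynolds_residual(self, P, H, H_hist=None, c_dt=(0.0, 0.0, 0.0), dT=0.0, Ubar=0.0):
        """Weak-form residual field (zero rows at the Dirichlet ends)."""
        if dT < 0:
            raise ValueError("time step must be positive")
        terms = self._residual_terms(P, H, H_hist, c_dt, dT, Ubar)
        R = sum(terms)
        R[0] = P[0]
        R[-1] = P[-1]
        return R

    # -- monolithic Newton ----------------------------------------------
    def _newton(
        self,
        P0,
        H0_0,
        w,
        Ubar,
        dT,
        c_dt,
        H_hist,
        prescribed_H0=None,
        H_guess=None,
    ):
        cfg = self.config
        n = self.X.size
        target = 0.5 * math.pi * w / self.hertz.w_ref if prescribed_H0 is None else None
        P = P0.copy()
        H0 = float(prescribed_H0 if prescribed_H0 is not None else H0_0)
        H = None
        trace = []

        def assemble(P, H0, H_guess):
            H = self._solve_film(P, H0, H_guess)
            pois, cou, sq, pen = self._residual_terms(P, H, H_hist, c_dt, dT, Ubar)
            R = pois + cou + sq + pen
            R[0] = P[0]
            R[-1] = P[-1]
            if target is None:
                return R, H
            Rl = float(self.m_w @ (P + self._g_solid(H)) - target)
            return np.append(R, Rl), H

        def jacobian(P, H):
            dX = self.dX
            Hbar = 0.5 * (H[:-1] + H[1:])
            coef = self.eps * self._pois_coef(Hbar) + (
                cfg.stab_coeff * abs(Ubar) * self.kappa * dX / 2.0
            )
            gp = self._g_solid_prime(H)
            # dH/dP and dH/dH0 through the film equation
            S = np.eye(n) - self.kappa * self.C * gp[None, :]
            S_inv_kC = np.linalg.solve(S, self.kappa * self.C)
            b = np.linalg.solve(S, np.ones(n))
            # direct pressure part: -K(coef) - penalty
            J_pp = np.zeros((n, n))
            idx = np.arange(n - 1)
            np.add.at(J_pp, (idx, idx), -coef / dX)
            np.add.at(J_pp, (idx, idx + 1), coef / dX)
            np.add.at(J_pp, (idx + 1, idx), coef / dX)
            np.add.at(J_pp, (idx + 1, idx + 1), -coef / dX)
            J_pp[np.arange(n), np.arange(n)] -= (
                cfg.xi * self.m_w * (P < 0.0).astype(float)
            )
            # film-mediated part
            J_ph = np.zeros((n, n))
            dP = np.diff(P) / dX
            # d(pois)/dH_node = 0.5 * d(mobility)/dHbar * dP/dX
            v = 0.5 * self.eps * self._pois_coef_deriv(Hbar) * dP
            np.add.at(J_ph, (idx, idx), v)
            np.add.at(J_ph, (idx, idx + 1), v)
            np.add.at(J_ph, (idx + 1, idx), -v)
            np.add.at(J_ph, (idx + 1, idx + 1), -v)
            if cfg.upwind and Ubar != 0.0:
                col = idx if Ubar > 0 else idx + 1
                np.add.at(J_ph, (idx, col), -Ubar)
                np.add.at(J_ph, (idx + 1, col), Ubar)
            else:
                u = 0.5 * Ubar
                np.add.at(J_ph, (idx, idx), -u)
                np.add.at(J_ph, (idx, idx + 1), -u)
                np.add.at(J_ph, (idx + 1, idx), u)
                np.add.at(J_ph, (idx + 1, idx + 1), u)
            if dT > 0 and any(c_dt):
                c0 = c_dt[0] / dT
                J_ph[np.arange(n), np.arange(n)] -= c0 * self._mass_main
                J_ph[np.arange(n - 1), np.arange(1, n)] -= c0 * self._mass_off
                J_ph[np.arange(1, n), np.arange(n - 1)] -= c0 * self._mass_off
            J = J_pp + J_ph @ S_inv_kC
            J[0, :] = 0.0
            J[0, 0] = 1.0
            J[-1, :] = 0.0
            J[-1, -1] = 1.0
            if target is None:
                return J
            full = np.zeros((n + 1, n + 1))
            full[:n, :n] = J
            Jh0 = J_ph @ b
            Jh0[0] = Jh0[-1] = 0.0
            full[:n, n] = Jh0
            mg = self.m_w * gp
            full[n, :n] = self.m_w + mg @ S_inv_kC
            full[n, n] = float(mg @ b)
            return full

        R, H = assemble(P, H0, H_guess)
        res_norm = float(np.linalg.norm(R))
        res0 = res_norm
        # all iterates must keep the film above 2% of its value at the
        # start of the step; a root below that is reached by sub-stepping
        h_floor = 0.02 * float(H.min()) if H.min() > 0 else 0.0
        for it in range(cfg.newton_max_iter):
            if not np.all(np.isfinite(R)):
                raise SolverError("non-finite residual in Newton iteration", trace)
            if np.abs(R).max() < cfg.newton_tol:
                break
            if it >= 3 and res_norm > 3.0 * res0:
                raise SolverError(
                    f"Newton diverging: residual {res_norm:.3e} vs initial {res0:.3e}",
                    trace,
                )
            J = jacobian(P, H)
            try:
                du = np.linalg.solve(J, -R)
            except np.linalg.LinAlgError as exc:
                raise SolverError(f"singular Jacobian: {exc}", trace) from exc
            # step control: first cut the step back to keep the film
            # positive (fraction-to-the-boundary), then Armijo-damp on the
            # 2-norm, accepting the last trial if damping bottoms out
            # (non-monotone escape from penalty/film kinks)
            alpha = 1.0
            best = None
            for _ in range(14):
                P_new = P + alpha * du[:n]
                H0_new = H0 + (alpha * du[n] if target is not None else 0.0)
                R_new, H_new = assemble(P_new, H0_new, H)
                if not np.all(np.isfinite(R_new)) or H_new.min() <= h_floor:
                    factor = 0.25
                    if np.all(np.isfinite(H_new)) and np.any(H_new <= h_floor):
                        bad = H_new <= h_floor
                        frac = float(
                            ((H[bad] - h_floor) / (H[bad] - H_new[bad] + 1e-300)).min()
                        )
                        factor = min(max(0.9 * frac, 0.05), 0.5)
                    alpha *= factor
                    continue
                r_new = float(np.linalg.norm(R_new))
                if best is None or r_new < best[-1]:
                    best = (P_new, H0_new, R_new, H_new, alpha, r_new)
                if r_new < res_norm * (1.0 - 1e-4 * alpha):
                    break
                alpha *= 0.5
            if best is None:
                raise SolverError("could not find a positive-film step", trace)
            P, H0, R, H, alpha, _ = best
            res_norm = float(np.linalg.norm(R))
            trace.append((it, res_norm, alpha))
        else:
            raise SolverError(
                f"Newton failed to converge: residual {res_norm:.3e} after "
                f"{cfg.newton_max_iter} iterations",
                trace,
            )
        if np.any(H <= 0):
            raise SolverError("non-positive film thickness in converged state", trace)
        return P, H0, H, len(trace)

    # -- public solves ---------------------------------------------------
    def initialize_reference(self, w: float, phase: float = 0.0, T: float = 0.0) -> EHLState:
        """Hertzian initial state for load-per-length ``w``.

        Pressure is the dry Hertz semi-ellipse for ``w``, asperity pressure
        zero, deflection from the elastic operator, and the rigid-body
        offset places the minimum film at the configured seed value.
        """
        self._require_prepared()
        P = hertz_pressure_profile(self.X, w / self.hertz.w_ref)
        delta = self.kappa * (self.C @ P)
        if self.setup.roughness is not None:
            h_seed = self.config.lambda_init * self.setup.roughness.sigma
            H_seed = h_seed / self.h_scale
        else:
            H_seed = 0.02
        H0 = H_seed - float((0.5 * self.X**2 + delta).min())
        H = film_thickness(H0, self.X, delta)
        state = EHLState(
            T=T, phase=phase, H0=H0, P=P, P_a=np.zeros_like(P), H=H,
            delta_bar=delta, w=w, u_m=0.0,
        )
        self._dimensionalize(state)
        return state

    def solve_steady(
        self,
        w: float,
        u_m: float,
        init: EHLState | None = None,
        phase: float = 0.0,
        prescribed_H0: float | None = None,
    ) -> EHLState:
        """Stationary solve (squeeze term off) at constant load and speed.

        With ``prescribed_H0`` the rigid-body separation is fixed and the
        load-balance equation dropped (the carried load becomes an output).
        """
        self._require_prepared()
        if init is None:
            init = self.initialize_reference(max(w, self.hertz.w_ref * 1e-3), phase=phase)
        Ubar = u_m / self.hertz.u_scale
        P, H0, H, iters = self._newton(
            init.P, init.H0, w, Ubar, dT=0.0, c_dt=(0.0, 0.0, 0.0), H_hist=None,
            H_guess=init.H, prescribed_H0=prescribed_H0,
        )
        return self._make_state(0.0, phase, P, H0, H, w, u_m, iters)

    def solve_time_step(
        self,
        prev: EHLState,
        w: float,
        u_m: float,
        dT: float,
        prev2: EHLState | None = None,
        phase: float = 0.0,
        prescribed_H0: float | None = None,
    ) -> EHLState:
        """Advance one implicit step (BDF2 when ``prev2`` given, else BDF1)."""
        self._require_prepared()
        if dT <= 0:
            raise ValueError("time step must be positive")
        Ubar = u_m / self.hertz.u_scale
        if prev2 is None:
            c_dt = (1.0, -1.0, 0.0)
            H_hist = (prev.H, np.zeros_like(prev.H))
        else:
            c_dt = (1.5, -2.0, 0.5)
            H_hist = (prev.H, prev2.H)
        P, H0, H, iters = self._newton(
            prev.P, prev.H0, w, Ubar, dT=dT, c_dt=c_dt, H_hist=H_hist,
            prescribed_H0=prescribed_H0, H_guess=prev.H,
        )
        return self._make_state(prev.T + dT, phase, P, H0, H, w, u_m, iters)

    def _make_state(self, T, phase, P, H0, H, w, u_m, iters) -> EHLState:
        delta = H - H0 - 0.5 * self.X**2
        Pa = self._g(H)
        Pc = self._gc(H)
        state = EHLState(
            T=T, phase=phase, H0=H0, P=P, P_a=Pa, P_c=Pc, H=H, delta_bar=delta,
            w=w, u_m=u_m, newton_iters=iters,
            load_residual=load_balance_residual(P, Pa + Pc, w, self.hertz, self.X),
        )
        self._dimensionalize(state)
        return state

    def _dimensionalize(self, st: EHLState) -> None:
        st.p = st.P * self.hertz.p_H
        st.p_a = st.P_a * self.hertz.p_H
        st.p_c = (st.P_c if st.P_c is not None else np.zeros_like(st.P)) * self.hertz.p_H
        st.h = st.H * self.h_scale
        st.delta = st.delta_bar * self.h_scale

    def _substep(
        self, prev: EHLState, w0: float, w1: float, u0: float, u1: float,
        dT: float, phase: float, cycle: int,
    ) -> EHLState:
        """Cross a stiff time interval with refined first-order sub-steps."""
        last_exc: SolverError | None = None
        for m in (4, 16, 64):
            st = prev
            try:
                for j in range(1, m + 1):
                    f = j / m
                    st = self.solve_time_step(
                        st, (1 - f) * w0 + f * w1, (1 - f) * u0 + f * u1,
                        dT / m, prev2=None, phase=phase,
                    )
                log.info("phase %.3f crossed with %d sub-steps", phase, m)
                return st
            except SolverError as exc:
                last_exc = exc
        raise SolverError(
            f"time step failed at cycle {cycle + 1}, phase {phase:.3f} "
            f"even with 64 sub-steps: {last_exc}",
            last_exc.trace if last_exc else [],
        )

    # -- gait loop -------------------------------------------------------
    def run_gait(self, profile: GaitProfile, compartment: str) -> GaitSolution:
        """Simulate the gait cycle for one compartment.

        The profile is resampled to the configured step grid; scales are
        fixed at the reference phase (maximum compartment load unless
        overridden); the loop runs for ``n_cycles`` cycles (or until the
        cycle-integrated asperity-friction integrand is cyclically
        converged) and the states of the last simulated cycle are kept.
        """
        cfg = self.config
        steps = cfg.steps_per_cycle
        prof = resample_profile(profile, steps)
        F = prof.force(compartment)
        u_m = prof.entrainment(compartment)
        u_s = prof.u_fem(compartment) - prof.u_tib(compartment)
        l = self.setup.geometry.l
        w_tab = F / l

        if cfg.t_ref_phase is None:
            i_ref = int(np.argmax(F[:-1]))
        else:
            i_ref = int(np.argmin(np.abs(prof.phase[:-1] - cfg.t_ref_phase)))
        u_scale = (
            float(np.abs(u_m).max())
            if cfg.u_scale_policy == "max_abs"
            else max(abs(float(u_m[i_ref])), 1e-9)
        )
        self.prepare(w_ref=w_tab[i_ref], u_scale=u_scale, t_ref=prof.phase[i_ref])

        dt = prof.cycle_duration / steps
        dT = self.norm.T(dt)
        state_prev = self.initialize_reference(w_tab[0], phase=0.0)
        state_prev2 = None

        Pf_prev_cycle = None
        states: list[EHLState] = []
        cycles_run = 0
        max_cycles = cfg.max_cycles if cfg.cyclic_convergence else cfg.n_cycles
        for cycle in range(max_cycles):
            states = []
            for k in range(1, steps + 1):
                phase_k = prof.phase[k]
                try:
                    st = self.solve_time_step(
                        state_prev, w_tab[k], float(u_m[k]), dT,
                        prev2=state_prev2, phase=phase_k,
                    )
                except SolverError:
                    # stiff interval (film collapse / reformation): retry
                    # with first-order sub-steps and interpolated inputs
                    st = self._substep(
                        state_prev, w_tab[k - 1], w_tab[k], float(u_m[k - 1]),
                        float(u_m[k]), dT, phase_k, cycle,
                    )
                st.u_s = float(u_s[k])
                log.info(
                    "cycle %d phase %.3f: %d Newton its, load res %.1e, "
                    "h_min %.3f um, p_max %.2f MPa",
                    cycle + 1, phase_k, st.newton_iters, st.load_residual,
                    st.h.min() * 1e6, st.p_total.max() / 1e6,
                )
                states.append(st)
                state_prev2, state_prev = state_prev, st
            cycles_run = cycle + 1
            # cycle-integrated asperity friction integrand (mu-free part)
            Pf_cycle = sum(float(np.trapezoid(st.p_a, self.norm.x(self.X))) for st in states) * dt
            if cfg.cyclic_convergence and Pf_prev_cycle is not None:
                denom = max(abs(Pf_prev_cycle), 1e-300)
                if abs(Pf_cycle - Pf_prev_cycle) / denom < cfg.cyclic_tol:
                    break
            Pf_prev_cycle = Pf_cycle
            if not cfg.cyclic_convergence and cycles_run >= cfg.n_cycles:
                break

        sol = GaitSolution(
            phase=prof.phase[1:].copy(),
            time=prof.phase[1:] * prof.cycle_duration,
            states=states,
            hertz=self.hertz,
            norm=self.norm,
            setup=self.setup,
            config=cfg,
            domain=self.domain,
            X=self.X.copy(),
            cycles_run=cycles_run,
        )
        sol.compute_traces()
        return sol


# convenience wrappers matching the operation-level API ----------------------

def run_gait_simulation(
    profile: GaitProfile,
    setup: CompartmentSetup,
    compartment: str = "medial",
    domain: SolutionDomain | None = None,
    config: SimulationConfig | None = None,
) -> GaitSolution:
    """One-call transient simulation of a compartment over the gait cycle."""
    return LineContactSolver(setup, domain, config).run_gait(profile, compartment)
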