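"""Shared fixtures: reference materials, domains, and demo gait runs."""

from __future__ import annotations

import numpy as np
import pytest

from tkr_ehl.asperity import RoughnessModel
from tkr_ehl.contact import CompartmentGeometry, FluidModel, MaterialPair
from tkr_ehl.ehl import CompartmentSetup, LineContactSolver, SimulationConfig
from tkr_ehl.elasticity import SolutionDomain
from tkr_ehl.metrics import FrictionSpec, build_report
from tkr_ehl.profiles import GRAVITY, GaitShapeSpec, generate_gait_profile

# the three demo subjects: body mass [kg], (first, second) stance peak [BW]
SUBJECTS = {
    "S1": (63.5, (3.2, 2.4)),
    "S2": (70.0, (2.7, 3.3)),
    "S3": (103.0, (2.6, 3.7)),
}
LENGTHS = {"medial": 0.0283, "lateral": 0.0273}


@pytest.fixture(scope="session")
def materials() -> MaterialPair:
    """CoCr femoral component on UHMWPE inlay."""
    return MaterialPair(E_f=240000e6, nu_f=0.29, E_t=660e6, nu_t=0.46)


@pytest.fixture(scope="session")
def geometry() -> CompartmentGeometry:
    return CompartmentGeometry(R_f=0.038, R_t=0.058, l=0.0283)


@pytest.fixture(scope="session")
def smooth_setup(geometry, materials) -> CompartmentSetup:
    """Pure-EHL setup (no asperity model)."""
    return CompartmentSetup(geometry, materials, FluidModel())


@pytest.fixture(scope="session")
def rough_setup(geometry, materials) -> CompartmentSetup:
    rough = RoughnessModel(sigma=1.95e-6, E_gt=materials.E_ps)
    return CompartmentSetup(geometry, materials, FluidModel(), rough)


@pytest.fixture(scope="session")
def domain() -> SolutionDomain:
    return SolutionDomain(n_contact=161)


@pytest.fixture(scope="session")
def domain_coarse() -> SolutionDomain:
    return SolutionDomain(n_contact=121)


def make_solver(setup, domain, **cfg) -> LineContactSolver:
    defaults = dict(newton_tol=1e-8, newton_max_iter=60)
    defaults.update(cfg)
    return LineContactSolver(setup, domain, SimulationConfig(**defaults))


def rigid(solver: LineContactSolver) -> LineContactSolver:
    """Disable elastic deflection once prepared (rigid-surface oracle)."""
    orig_prepare = solver.prepare

    def prepare_rigid(*args, **kwargs):
        orig_prepare(*args, **kwargs)
        solver.kappa = 0.0
        solver.C = np.zeros_like(solver.C)

    solver.prepare = prepare_rigid
    return solver


@pytest.fixture(scope="session")
def s1_profile():
    mass, peaks = SUBJECTS["S1"]
    return generate_gait_profile(
        GaitShapeSpec(body_weight=mass * GRAVITY, peak_magnitudes_bw=peaks), 201
    )


@pytest.fixture(scope="session")
def demo_solutions(materials, domain):
    """Gait solutions for all subjects and compartments (150 steps/cycle)."""
    rough = RoughnessModel(sigma=1.95e-6, E_gt=materials.E_ps)
    fluid = FluidModel()
    out = {}
    for name, (mass, peaks) in SUBJECTS.items():
        profile = generate_gait_profile(
            GaitShapeSpec(body_weight=mass * GRAVITY, peak_magnitudes_bw=peaks), 201
        )
        for comp, l in LENGTHS.items():
            setup = CompartmentSetup(
                CompartmentGeometry(0.038, 0.058, l), materials, fluid, rough
            )
            solver = LineContactSolver(
                setup, domain, SimulationConfig(steps_per_cycle=150, newton_max_iter=60)
            )
            out[(name, comp)] = solver.run_gait(profile, comp)
    return out


@pytest.fixture(scope="session")
def demo_reports(demo_solutions):
    return {
        key: build_report(sol, FrictionSpec(mu=0.25), compartment=key[1])
        for key, sol in demo_solutions.items()
    }
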