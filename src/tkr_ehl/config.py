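"""Run configuration: defaults, YAML overlay, CLI overrides, validation.

Interface units are human-readable (mm, MPa, um, body-weight multiples,
kg); everything is converted to SI when the solver objects are built.
Precedence is defaults < YAML file < explicit overrides.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .asperity import RoughnessModel, composite_gt_prefactor
from .contact import CompartmentGeometry, FluidModel, MaterialPair
from .ehl import CompartmentSetup, SimulationConfig
from .elasticity import SolutionDomain
from .profiles import GRAVITY, GaitShapeSpec

__all__ = [
    "DEFAULTS",
    "ConfigError",
    "load_config",
    "config_hash",
    "build_setup",
    "build_domain",
    "build_sim_config",
    "build_shape_spec",
    "build_friction",
    "DEMO_SUBJECTS",
]

#: demo subject tags: body mass [kg] and (first, second) stance peak in BW
DEMO_SUBJECTS = {
    "S1": {"mass_kg": 63.5, "peaks_bw": (3.2, 2.4)},
    "S2": {"mass_kg": 70.0, "peaks_bw": (2.7, 3.3)},
    "S3": {"mass_kg": 103.0, "peaks_bw": (2.6, 3.7)},
}

DEFAULTS: dict = {
    "geometry": {
        "R_f_mm": 38.0,
        "R_t_mm": 58.0,
        "l_med_mm": 28.3,
        "l_lat_mm": 27.3,
    },
    "materials": {
        "E_f_MPa": 240000.0,
        "nu_f": 0.29,
        "E_t_MPa": 660.0,
        "nu_t": 0.46,
    },
    "fluid": {"rho": 1000.0, "eta": 0.1},
    "roughness": {
        "enabled": True,
        "sigma_um": 1.95,
        "K": None,  # None -> composite default prefactor
        "eta_beta_sigma": 0.04,
        "sigma_over_beta": 1e-3,
        "E_gt_MPa": None,  # None -> equivalent-body plane-strain modulus
        "lambda_cut": 4.0,
    },
    "solver": {
        "steps_per_cycle": 200,
        "n_cycles": 1,
        "cyclic_convergence": False,
        "cyclic_tol": 0.01,
        "newton_tol": 1e-6,
        "newton_max_iter": 60,
        "xi": 1e4,
        "upwind": True,
        "stab_coeff": 0.0,
        "h_reg_lambda": 0.1,
        "lambda_contact": 0.05,
        "contact_penalty": 30.0,
        "n_contact": 161,
        "x_c": 4.5,
        "domain_width": 60.0,
        "domain_depth": 60.0,
        "t_ref_phase": None,
        "u_scale_policy": "max_abs",
        "lambda_init": 1.5,
    },
    "metrics": {"mu": 0.25, "include_sliding": False},
    "profile": {
        "mass_kg": 63.5,
        "peaks_bw": [3.2, 2.4],
        "peak_phases": [0.15, 0.50],
        "minima_bw": [0.15, 0.12],
        "minima_phases": [0.65, 0.90],
        "medial_share": 0.6,
        "velocity_amplitude": 0.18,
        "velocity_zero_phases": [0.20, 0.55, 0.80],
        "lateral_velocity_factor": 0.85,
        "slide_roll_ratio": 1.0,
        "noise_amplitude_bw": 0.0,
        "cycle_duration_s": 1.1,
        "n_samples": 201,
    },
    "seed": 0,
}


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


def _deep_merge(base: dict, overlay: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in overlay.items():
        if key not in base:
            raise ConfigError([f"unknown configuration key {path + key!r}"])
        if isinstance(val, dict) and isinstance(base[key], dict):
            out[key] = _deep_merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def _validate(cfg: dict) -> None:
    errs = []

    def positive(section, key):
        v = cfg[section][key]
        if v is None or not isinstance(v, (int, float)) or v <= 0:
            errs.append(f"{section}.{key} must be a positive number, got {v!r}")

    for key in ("R_f_mm", "R_t_mm", "l_med_mm", "l_lat_mm"):
        positive("geometry", key)
    for key in ("E_f_MPa", "E_t_MPa"):
        positive("materials", key)
    for key in ("nu_f", "nu_t"):
        v = cfg["materials"][key]
        if not 0 <= v < 0.5:
            errs.append(f"materials.{key} must lie in [0, 0.5), got {v!r}")
    positive("fluid", "rho")
    positive("fluid", "eta")
    if cfg["roughness"]["enabled"]:
        positive("roughness", "sigma_um")
        positive("roughness", "lambda_cut")
    positive("solver", "steps_per_cycle")
    if cfg["solver"]["steps_per_cycle"] < 50:
        errs.append("solver.steps_per_cycle must be >= 50")
    positive("solver", "newton_tol")
    positive("solver", "xi")
    positive("metrics", "mu")
    positive("profile", "mass_kg")
    if not 0 < cfg["profile"]["medial_share"] < 1:
        errs.append("profile.medial_share must lie in (0, 1)")
    if errs:
        raise ConfigError(errs)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merged, validated configuration dictionary."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            file_cfg = yaml.safe_load(fh) or {}
        if not isinstance(file_cfg, dict):
            raise ConfigError([f"config file {path} is not a mapping"])
        cfg = _deep_merge(cfg, file_cfg)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for run provenance logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_setup(cfg: dict, compartment: str) -> CompartmentSetup:
    g = cfg["geometry"]
    m = cfg["materials"]
    length = {"medial": g["l_med_mm"], "lateral": g["l_lat_mm"]}[compartment]
    geometry = CompartmentGeometry(
        R_f=g["R_f_mm"] * 1e-3, R_t=g["R_t_mm"] * 1e-3, l=length * 1e-3
    )
    materials = MaterialPair(
        E_f=m["E_f_MPa"] * 1e6, nu_f=m["nu_f"], E_t=m["E_t_MPa"] * 1e6, nu_t=m["nu_t"]
    )
    fluid = FluidModel(rho=cfg["fluid"]["rho"], eta=cfg["fluid"]["eta"])
    r = cfg["roughness"]
    roughness = None
    if r["enabled"]:
        K = r["K"]
        if K is None:
            K = composite_gt_prefactor(r["eta_beta_sigma"], r["sigma_over_beta"])
        E_gt = r["E_gt_MPa"] * 1e6 if r["E_gt_MPa"] is not None else materials.E_ps
        roughness = RoughnessModel(
            sigma=r["sigma_um"] * 1e-6, E_gt=E_gt, K=K, lambda_cut=r["lambda_cut"]
        )
    return CompartmentSetup(geometry, materials, fluid, roughness)


def build_domain(cfg: dict) -> SolutionDomain:
    s = cfg["solver"]
    return SolutionDomain(
        x_c=s["x_c"],
        n_contact=s["n_contact"],
        width=s["domain_width"],
        depth=s["domain_depth"],
    )


def build_sim_config(cfg: dict) -> SimulationConfig:
    s = cfg["solver"]
    return SimulationConfig(
        steps_per_cycle=s["steps_per_cycle"],
        n_cycles=s["n_cycles"],
        cyclic_convergence=s["cyclic_convergence"],
        cyclic_tol=s["cyclic_tol"],
        newton_tol=s["newton_tol"],
        newton_max_iter=s["newton_max_iter"],
        xi=s["xi"],
        upwind=s["upwind"],
        stab_coeff=s["stab_coeff"],
        h_reg_lambda=s["h_reg_lambda"],
        lambda_contact=s["lambda_contact"],
        contact_penalty=s["contact_penalty"],
        t_ref_phase=s["t_ref_phase"],
        u_scale_policy=s["u_scale_policy"],
        lambda_init=s["lambda_init"],
    )


def build_shape_spec(cfg: dict, seed: int | None = None) -> GaitShapeSpec:
    p = cfg["profile"]
    return GaitShapeSpec(
        body_weight=p["mass_kg"] * GRAVITY,
        peak_phases=tuple(p["peak_phases"]),
        peak_magnitudes_bw=tuple(p["peaks_bw"]),
        minima_phases=tuple(p["minima_phases"]),
        minima_magnitudes_bw=tuple(p["minima_bw"]),
        medial_share=p["medial_share"],
        velocity_amplitude=p["velocity_amplitude"],
        velocity_zero_phases=tuple(p["velocity_zero_phases"]),
        lateral_velocity_factor=p["lateral_velocity_factor"],
        slide_roll_ratio=p["slide_roll_ratio"],
        noise_amplitude_bw=p["noise_amplitude_bw"],
        seed=cfg["seed"] if seed is None else seed,
        cycle_duration=p["cycle_duration_s"],
    )


def build_friction(cfg: dict):
    from .metrics import FrictionSpec

    return FrictionSpec(
        mu=cfg["metrics"]["mu"], include_sliding=cfg["metrics"]["include_sliding"]
    )
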