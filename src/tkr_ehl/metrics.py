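"""Derived per-cycle quantities: pressure and film traces, frictional power.

The wear-susceptibility indicator is the solid frictional power

    P_f = int_t int_{Omega_c} mu * p_a(x, t) * l dx dt,

the cycle integral of the statistical asperity contact pressure weighted by
the solid-solid friction coefficient ``mu`` and the contact length ``l``.
As printed the integrand carries no sliding velocity, so the raw quantity
has units of N s; an optional flag adds the |u_fem - u_tib| factor (then
the result is in J).  Because ``mu`` only scales P_f, cross-compartment and
cross-subject comparisons use values normalised to the data-set maximum,
which are mu-invariant by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ehl import GaitSolution

__all__ = [
    "FrictionSpec",
    "MetricsReport",
    "max_total_pressure_trace",
    "min_film_parameter_trace",
    "solid_frictional_power",
    "normalize_powers",
    "compare_compartments",
    "build_report",
    "export_results",
    "read_traces",
]

TRACE_COLUMNS = (
    "phase",
    "p_max_MPa",
    "p_a_max_MPa",
    "h_min_um",
    "lambda_min",
    "asperity_load_share",
)


@dataclass(frozen=True)
class FrictionSpec:
    """Solid-solid friction coefficient and integration options."""

    mu: float = 0.25
    include_sliding: bool = False

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"friction coefficient must be positive, got {self.mu}")


@dataclass
class MetricsReport:
    """Cycle summary of one compartment run."""

    compartment: str
    p_max_MPa_range: tuple[float, float]
    lambda_min_range: tuple[float, float]
    h_min_um_range: tuple[float, float]
    asperity_load_share_max: float
    P_f: float
    mu: float
    P_f_normalized: float | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def max_total_pressure_trace(solution: GaitSolution) -> pd.Series:
    """Per-phase maximum of the total contact pressure, in MPa."""
    vals = [st.p_total.max() / 1e6 for st in solution.states]
    return pd.Series(vals, index=pd.Index(solution.phase, name="phase"), name="p_max_MPa")


def min_film_parameter_trace(solution: GaitSolution, sigma: float) -> pd.Series:
    """Per-phase minimum film parameter lambda = h/sigma (dimensionless)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    vals = [st.h.min() / sigma for st in solution.states]
    return pd.Series(vals, index=pd.Index(solution.phase, name="phase"), name="lambda_min")


def solid_frictional_power(
    solution: GaitSolution, spec: FrictionSpec, l: float | None = None
) -> float:
    """Cycle-integrated solid frictional power indicator.

    Spatial integration uses the solver's trapezoidal quadrature on the
    contact grid; temporal integration is the trapezoidal rule on the
    periodic cycle (states sample one full period, so the rule reduces to
    dt times the sum over steps).  Only the statistical asperity pressure
    enters; the numerical gap-penalty pressure is excluded.
    """
    if l is None:
        l = solution.setup.geometry.l
    x = solution.norm.x(solution.X)
    t = solution.time
    dt = float(t[1] - t[0])
    total = 0.0
    for st in solution.states:
        line = float(np.trapezoid(st.p_a, x))
        if spec.include_sliding:
            line *= abs(st.u_s)
        total += line * dt
    return spec.mu * l * total


def normalize_powers(values) -> list[float]:
    """Divide each frictional power by the data-set maximum (max maps to 1)."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty power list")
    vmax = max(vals)
    if vmax <= 0:
        raise ValueError("normalisation requires at least one positive value")
    return [v / vmax for v in vals]


def compare_compartments(report_med: MetricsReport, report_lat: MetricsReport) -> dict:
    """Lateral/medial frictional-power ratio and medial pressure excess.

    The excess is (p_med - p_lat) / p_lat * 100 evaluated on the cycle
    maxima of the two compartments.
    """
    if report_med.P_f <= 0:
        raise ValueError("medial frictional power must be positive for the ratio")
    p_med = report_med.p_max_MPa_range[1]
    p_lat = report_lat.p_max_MPa_range[1]
    return {
        "P_f_lateral_over_medial": report_lat.P_f / report_med.P_f,
        "medial_pressure_excess_pct": (p_med - p_lat) / p_lat * 100.0,
    }


def build_report(
    solution: GaitSolution, friction: FrictionSpec | None = None, compartment: str = ""
) -> MetricsReport:
    friction = friction or FrictionSpec()
    if solution.p_max is None:
        solution.compute_traces()
    return MetricsReport(
        compartment=compartment,
        p_max_MPa_range=(float(solution.p_max.min() / 1e6), float(solution.p_max.max() / 1e6)),
        lambda_min_range=(float(solution.lambda_min.min()), float(solution.lambda_min.max())),
        h_min_um_range=(float(solution.h_min.min() * 1e6), float(solution.h_min.max() * 1e6)),
        asperity_load_share_max=float(solution.asperity_load_share.max()),
        P_f=solid_frictional_power(solution, friction),
        mu=friction.mu,
        meta={
            "cycles_run": solution.cycles_run,
            "steps_per_cycle": solution.config.steps_per_cycle,
            "a_H_mm": solution.hertz.a_H * 1e3,
            "p_H_MPa": solution.hertz.p_H / 1e6,
        },
    )


def _traces_frame(solution: GaitSolution) -> pd.DataFrame:
    """Trace table over the closed cycle (phase 0 row repeats phase 1)."""
    if solution.p_max is None:
        solution.compute_traces()
    phase = np.concatenate([[0.0], solution.phase])
    def closed(a):
        return np.concatenate([[a[-1]], a])
    return pd.DataFrame(
        {
            "phase": phase,
            "p_max_MPa": closed(solution.p_max) / 1e6,
            "p_a_max_MPa": closed(solution.p_a_max) / 1e6,
            "h_min_um": closed(solution.h_min) * 1e6,
            "lambda_min": closed(solution.lambda_min),
            "asperity_load_share": closed(solution.asperity_load_share),
        }
    )


def export_results(
    solution: GaitSolution,
    report: MetricsReport,
    out_dir,
    dump_fields: bool = False,
) -> dict[str, Path]:
    """Write traces.csv and report.json (optionally per-phase field dumps).

    traces.csv has ``steps_per_cycle + 1`` rows (the closed cycle) with the
    documented column schema; report.json is the MetricsReport dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    traces = out / "traces.csv"
    _traces_frame(solution).to_csv(traces, index=False, float_format="%.17g")
    paths["traces"] = traces
    rep = out / "report.json"
    rep.write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
    paths["report"] = rep
    if dump_fields:
        fields = out / "fields"
        fields.mkdir(exist_ok=True)
        for i, st in enumerate(solution.states):
            df = pd.DataFrame(
                {
                    "X": solution.X,
                    "P": st.P,
                    "Pa": st.P_a,
                    "H": st.H,
                    "delta_bar": st.delta_bar,
                }
            )
            df.to_csv(fields / f"phase_{st.phase:.4f}_{i:04d}.csv", index=False)
        paths["fields"] = fields
    return paths


def read_traces(path) -> pd.DataFrame:
    """Read a traces.csv written by :func:`export_results`."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traces file missing columns: {missing}")
    return df
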