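"""Gait-cycle load and velocity profiles for the two tibiofemoral compartments.

The lubrication solver is driven by tabular inputs: normal contact force
and femoral/tibial surface velocities in the medial and lateral
compartments versus gait-cycle phase.  Subject-specific profiles from
musculoskeletal simulation are typically not at hand, so this module also
provides a synthetic generator that emulates their characteristic
structure: a two-peak stance loading (peaks near 15% and 50% of the
cycle), load minima near 65% and 90%, anterior-posterior velocity
reversals near 20%, 55% and 80% of the cycle, and a medial-dominant
load/velocity split.

The generator interpolates control points (peaks, minima, zero crossings)
with a periodic shape-preserving cubic (PCHIP on a triple-period
extension), so specified extrema are attained exactly, the curve never
overshoots its control points, and the seam at phase 0/1 is continuously
differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

__all__ = [
    "GaitProfile",
    "GaitShapeSpec",
    "ProfileValidationError",
    "generate_gait_profile",
    "read_gait_profile",
    "write_gait_profile",
    "resample_profile",
    "entrainment_velocity",
    "sliding_velocity",
    "CSV_COLUMNS",
]

GRAVITY = 9.81  # m/s^2

CSV_COLUMNS = (
    "phase",
    "F_med_N",
    "F_lat_N",
    "u_fem_med_mps",
    "u_tib_med_mps",
    "u_fem_lat_mps",
    "u_tib_lat_mps",
)

COMPARTMENTS = ("medial", "lateral")


class ProfileValidationError(ValueError):
    """Raised when a gait profile violates its invariants.

    Collects every violated invariant in ``violations``.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid gait profile:\n  - " + "\n  - ".join(self.violations))


def entrainment_velocity(u_fem, u_tib):
    """Entrainment (effective) velocity: mean of the two surface velocities."""
    return 0.5 * (np.asarray(u_fem, dtype=float) + np.asarray(u_tib, dtype=float))


def sliding_velocity(u_fem, u_tib):
    """Sliding velocity ``u_fem - u_tib`` (metadata only; unused by the core)."""
    return np.asarray(u_fem, dtype=float) - np.asarray(u_tib, dtype=float)


@dataclass(frozen=True)
class GaitProfile:
    """Per-compartment normal force and surface velocities over one cycle.

    All channels share a strictly increasing ``phase`` grid spanning [0, 1]
    with equal values at both ends (periodicity).  Forces in N, velocities
    in m/s, cycle duration in s, body weight in N.
    """

    phase: np.ndarray
    cycle_duration: float
    body_weight: float
    F_med: np.ndarray
    F_lat: np.ndarray
    u_fem_med: np.ndarray
    u_tib_med: np.ndarray
    u_fem_lat: np.ndarray
    u_tib_lat: np.ndarray

    def force(self, compartment: str) -> np.ndarray:
        return {"medial": self.F_med, "lateral": self.F_lat}[compartment]

    def u_fem(self, compartment: str) -> np.ndarray:
        return {"medial": self.u_fem_med, "lateral": self.u_fem_lat}[compartment]

    def u_tib(self, compartment: str) -> np.ndarray:
        return {"medial": self.u_tib_med, "lateral": self.u_tib_lat}[compartment]

    def entrainment(self, compartment: str) -> np.ndarray:
        return entrainment_velocity(self.u_fem(compartment), self.u_tib(compartment))

    @property
    def time(self) -> np.ndarray:
        """Physical time grid [s] corresponding to ``phase``."""
        return self.phase * self.cycle_duration

    @property
    def n_samples(self) -> int:
        return self.phase.size

    def validate(self) -> None:
        """Check all profile invariants, raising ProfileValidationError."""
        violations: list[str] = []
        phase = self.phase
        channels = {
            "F_med_N": self.F_med,
            "F_lat_N": self.F_lat,
            "u_fem_med_mps": self.u_fem_med,
            "u_tib_med_mps": self.u_tib_med,
            "u_fem_lat_mps": self.u_fem_lat,
            "u_tib_lat_mps": self.u_tib_lat,
        }
        if phase.ndim != 1 or phase.size < 3:
            violations.append("phase grid must be 1-D with at least 3 samples")
        else:
            if not np.all(np.diff(phase) > 0):
                violations.append("phase not strictly increasing")
            if not (abs(phase[0]) < 1e-12 and abs(phase[-1] - 1.0) < 1e-12):
                violations.append("phase grid must span [0, 1]")
        if not np.isfinite(self.cycle_duration) or self.cycle_duration <= 0:
            violations.append("cycle_duration must be positive")
        if not np.isfinite(self.body_weight) or self.body_weight <= 0:
            violations.append("body_weight must be positive")
        for name, ch in channels.items():
            if ch.shape != phase.shape:
                violations.append(f"channel {name} does not share the phase grid")
                continue
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                violations.append(f"channel {name} has non-finite value at row {bad[0]}")
                continue
            if phase.size >= 2 and abs(ch[0] - ch[-1]) > 1e-9 * max(1.0, np.abs(ch).max()):
                violations.append(f"channel {name} not periodic (phase 0 vs 1 differ)")
        for name in ("F_med_N", "F_lat_N"):
            ch = channels[name]
            if ch.shape == phase.shape:
                bad = np.flatnonzero(ch <= 0)
                if bad.size:
                    violations.append(
                        f"non-positive force in column {name} at row {bad[0]}"
                    )
        if violations:
            raise ProfileValidationError(violations)

    def scaled(self, body_weight: float) -> "GaitProfile":
        """Same profile with forces rescaled to a new body weight [N]."""
        k = body_weight / self.body_weight
        return replace(
            self, body_weight=body_weight, F_med=self.F_med * k, F_lat=self.F_lat * k
        )


@dataclass(frozen=True)
class GaitShapeSpec:
    """Shape parameters of the synthetic gait profile.

    Force control points are given in body-weight multiples at fixed
    phases; velocity control points place the motion-reversal (zero) phases
    and the signed lobe amplitudes between them.  The medial compartment
    receives a fixed share of the total load and a fixed multiple of the
    velocity.  Smoothness is inherent to the PCHIP construction; optional
    low-order Fourier noise emulates inter-cycle variability.
    """

    body_weight: float = 63.5 * GRAVITY
    # total-force control points, phases in [0,1), magnitudes in BW
    peak_phases: tuple[float, float] = (0.15, 0.50)
    peak_magnitudes_bw: tuple[float, float] = (3.2, 2.4)
    minima_phases: tuple[float, float] = (0.65, 0.90)
    minima_magnitudes_bw: tuple[float, float] = (0.15, 0.12)
    heel_strike_bw: float = 0.9
    midstance_bw: float = 1.8
    swing_bump_bw: float = 0.35
    force_floor_bw: float = 0.05
    medial_share: float = 0.6
    # entrainment-velocity construction
    velocity_amplitude: float = 0.18
    velocity_zero_phases: tuple[float, float, float] = (0.20, 0.55, 0.80)
    lobe_scale: tuple[float, float, float, float] = (0.30, 0.45, 1.00, 0.65)
    lateral_velocity_factor: float = 0.85
    slide_roll_ratio: float = 1.0
    # noise and timing
    noise_amplitude_bw: float = 0.0
    noise_harmonics: int = 6
    seed: int = 0
    cycle_duration: float = 1.1

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        if not 0.0 < self.medial_share < 1.0:
            raise ValueError(f"medial share must lie in (0, 1), got {self.medial_share}")
        for name in ("peak_magnitudes_bw", "minima_magnitudes_bw"):
            if any(m <= 0 for m in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        for name in ("peak_phases", "minima_phases", "velocity_zero_phases"):
            ph = getattr(self, name)
            if any(not 0.0 <= p < 1.0 for p in ph) or any(
                b <= a for a, b in zip(ph, ph[1:])
            ):
                raise ValueError(f"{name} must be strictly increasing within [0, 1)")
        if self.velocity_amplitude <= 0:
            raise ValueError("velocity amplitude must be positive")
        if any(m < self.force_floor_bw for m in self.minima_magnitudes_bw):
            raise ValueError("swing minima must not drop below the force floor")


def _periodic_pchip(phases: np.ndarray, values: np.ndarray) -> PchipInterpolator:
    """Shape-preserving periodic interpolant via triple-period extension.

    The centre period sees identical neighbour data on both sides, so the
    derivative at phase 0 equals the derivative at phase 1 exactly.
    """
    ph = np.concatenate([phases - 1.0, phases, phases + 1.0])
    va = np.concatenate([values, values, values])
    return PchipInterpolator(ph, va, extrapolate=False)


def _total_force_interp(spec: GaitShapeSpec) -> PchipInterpolator:
    pts = {0.0: spec.heel_strike_bw}
    pts[spec.peak_phases[0]] = spec.peak_magnitudes_bw[0]
    mid_phase = 0.5 * (spec.peak_phases[0] + spec.peak_phases[1])
    pts[mid_phase] = spec.midstance_bw
    pts[spec.peak_phases[1]] = spec.peak_magnitudes_bw[1]
    pts[spec.minima_phases[0]] = spec.minima_magnitudes_bw[0]
    bump_phase = 0.5 * (spec.minima_phases[0] + spec.minima_phases[1])
    pts[bump_phase] = spec.swing_bump_bw
    pts[spec.minima_phases[1]] = spec.minima_magnitudes_bw[1]
    phases = np.array(sorted(pts))
    values = np.array([pts[p] for p in phases])
    return _periodic_pchip(phases, values)


def _entrainment_interp(spec: GaitShapeSpec) -> PchipInterpolator:
    """Entrainment velocity with zeros at {0} U velocity_zero_phases.

    The velocity vanishes at heel strike (phase 0) and at the specified
    reversal phases; between consecutive zeros one signed lobe is placed,
    alternating + - + - so the profile is periodic and changes sign exactly
    at the reversal points.  PCHIP keeps each lobe one-signed.
    """
    zeros = (0.0,) + tuple(spec.velocity_zero_phases)
    bounds = zeros + (1.0,)
    phases = [0.0]
    values = [0.0]
    sign = 1.0
    for k in range(len(bounds) - 1):
        mid = 0.5 * (bounds[k] + bounds[k + 1])
        phases.append(mid)
        values.append(sign * spec.velocity_amplitude * spec.lobe_scale[k])
        if k + 1 < len(bounds) - 1:
            phases.append(bounds[k + 1])
            values.append(0.0)
        sign = -sign
    return _periodic_pchip(np.array(phases), np.array(values))


def _fourier_noise(phase: np.ndarray, amplitude: float, harmonics: int, rng) -> np.ndarray:
    """Smooth zero-mean periodic noise from a few random harmonics."""
    if amplitude == 0.0:
        return np.zeros_like(phase)
    coeff = rng.standard_normal((harmonics, 2))
    coeff /= np.sqrt((coeff**2).sum()) or 1.0
    out = np.zeros_like(phase)
    for k in range(1, harmonics + 1):
        out += coeff[k - 1, 0] * np.sin(2 * np.pi * k * phase)
        out += coeff[k - 1, 1] * np.cos(2 * np.pi * k * phase)
    return amplitude * out


def generate_gait_profile(spec: GaitShapeSpec, n_samples: int = 201) -> GaitProfile:
    """Synthesize a periodic gait profile on ``n_samples`` phase points.

    Deterministic for a fixed ``spec.seed``.  The total force is split
    between compartments in proportion ``medial_share : 1 - medial_share``
    at every phase; the lateral velocity is a fixed fraction of the medial
    one, so reversal phases coincide in both compartments.
    """
    if n_samples < 50:
        raise ValueError(f"need at least 50 samples, got {n_samples}")
    rng = np.random.default_rng(spec.seed)
    phase = np.linspace(0.0, 1.0, n_samples)

    F_bw = _total_force_interp(spec)(phase)
    F_bw = F_bw + _fourier_noise(phase, spec.noise_amplitude_bw, spec.noise_harmonics, rng)
    F_bw = np.maximum(F_bw, spec.force_floor_bw)
    F_total = F_bw * spec.body_weight
    F_med = spec.medial_share * F_total
    F_lat = (1.0 - spec.medial_share) * F_total

    u_m_med = _entrainment_interp(spec)(phase)
    vel_noise = 1.0 + _fourier_noise(
        phase, 0.0 if spec.noise_amplitude_bw == 0.0 else 0.05, spec.noise_harmonics, rng
    )
    u_m_med = u_m_med * vel_noise
    u_m_lat = spec.lateral_velocity_factor * u_m_med

    # split entrainment into surfaces with a fixed slide-to-roll ratio
    # u_s / u_m: u_fem = u_m (1 + r/2), u_tib = u_m (1 - r/2)
    r = spec.slide_roll_ratio
    profile = GaitProfile(
        phase=phase,
        cycle_duration=spec.cycle_duration,
        body_weight=spec.body_weight,
        F_med=F_med,
        F_lat=F_lat,
        u_fem_med=u_m_med * (1.0 + 0.5 * r),
        u_tib_med=u_m_med * (1.0 - 0.5 * r),
        u_fem_lat=u_m_lat * (1.0 + 0.5 * r),
        u_tib_lat=u_m_lat * (1.0 - 0.5 * r),
    )
    profile.validate()
    return profile


def write_gait_profile(profile: GaitProfile, path) -> None:
    """Write a profile as CSV (documented schema, full float precision).

    Two comment lines carry cycle duration and body weight; the header and
    column order follow ``CSV_COLUMNS``.  LF line endings, UTF-8.
    """
    df = pd.DataFrame(
        {
            "phase": profile.phase,
            "F_med_N": profile.F_med,
            "F_lat_N": profile.F_lat,
            "u_fem_med_mps": profile.u_fem_med,
            "u_tib_med_mps": profile.u_tib_med,
            "u_fem_lat_mps": profile.u_fem_lat,
            "u_tib_lat_mps": profile.u_tib_lat,
        }
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# cycle_duration_s = {profile.cycle_duration!r}\n")
        fh.write(f"# body_weight_N = {profile.body_weight!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_gait_profile(path) -> GaitProfile:
    """Read a profile CSV written by :func:`write_gait_profile`.

    Raises ``ProfileValidationError`` listing every violated invariant
    (missing columns, non-monotone phase, NaN cells, non-positive forces).
    """
    meta = {"cycle_duration_s": 1.1, "body_weight_N": np.nan}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            try:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = float(val)
            except ValueError:
                pass
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")

    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileValidationError([f"missing column {c}" for c in missing])
    try:
        arrays = {c: df[c].to_numpy(dtype=float) for c in CSV_COLUMNS}
    except (TypeError, ValueError) as exc:
        raise ProfileValidationError([f"non-numeric data: {exc}"]) from exc

    bw = meta["body_weight_N"]
    if not np.isfinite(bw):
        # fall back: BW unknown, use peak total force as a stand-in scale
        bw = float(np.nanmax(arrays["F_med_N"] + arrays["F_lat_N"]))
    profile = GaitProfile(
        phase=arrays["phase"],
        cycle_duration=float(meta["cycle_duration_s"]),
        body_weight=bw,
        F_med=arrays["F_med_N"],
        F_lat=arrays["F_lat_N"],
        u_fem_med=arrays["u_fem_med_mps"],
        u_tib_med=arrays["u_tib_med_mps"],
        u_fem_lat=arrays["u_fem_lat_mps"],
        u_tib_lat=arrays["u_tib_lat_mps"],
    )
    profile.validate()
    return profile


def resample_profile(profile: GaitProfile, n_steps: int) -> GaitProfile:
    """Resample all channels to ``n_steps + 1`` points via periodic splines.

    ``n_steps`` is the number of intervals over the cycle; the returned
    grid is uniform and includes both endpoints.  Values at original nodes
    are reproduced (interpolation), and periodicity is preserved exactly.
    """
    if n_steps < 10:
        raise ValueError(f"need at least 10 steps, got {n_steps}")
    new_phase = np.linspace(0.0, 1.0, n_steps + 1)

    def interp(vals: np.ndarray) -> np.ndarray:
        # enforce an exactly periodic endpoint for the spline
        v = vals.copy()
        v[-1] = v[0]
        cs = CubicSpline(profile.phase, v, bc_type="periodic")
        out = cs(new_phase)
        out[-1] = out[0]
        return out

    return GaitProfile(
        phase=new_phase,
        cycle_duration=profile.cycle_duration,
        body_weight=profile.body_weight,
        F_med=interp(profile.F_med),
        F_lat=interp(profile.F_lat),
        u_fem_med=interp(profile.u_fem_med),
        u_tib_med=interp(profile.u_tib_med),
        u_fem_lat=interp(profile.u_fem_lat),
        u_tib_lat=interp(profile.u_tib_lat),
    )
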