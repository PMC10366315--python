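"""Gait-profile generator, CSV round trip, resampling, and velocity helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkr_ehl.profiles import (
    GRAVITY,
    GaitShapeSpec,
    ProfileValidationError,
    entrainment_velocity,
    generate_gait_profile,
    read_gait_profile,
    resample_profile,
    sliding_velocity,
    write_gait_profile,
)


@pytest.fixture(scope="module")
def default_profile():
    return generate_gait_profile(GaitShapeSpec(), 201)


class TestGeneration:
    def test_peaks_attained_at_specified_phases(self):
        for mass, peaks in ((63.5, (3.2, 2.4)), (103.0, (2.6, 3.7))):
            bw = mass * GRAVITY
            prof = generate_gait_profile(
                GaitShapeSpec(body_weight=bw, peak_magnitudes_bw=peaks), 401
            )
            total = prof.F_med + prof.F_lat
            # first peak: max over a window around the nominal phase
            for phase0, mag in zip((0.15, 0.50), peaks):
                win = np.abs(prof.phase - phase0) < 0.08
                assert abs(total[win].max() - mag * bw) < 0.01 * bw

    def test_minima_attained(self, default_profile):
        prof = default_profile
        bw = prof.body_weight
        total = prof.F_med + prof.F_lat
        for phase0, mag in zip((0.65, 0.90), (0.15, 0.12)):
            win = np.abs(prof.phase - phase0) < 0.05
            assert abs(total[win].min() - mag * bw) < 0.01 * bw

    def test_periodic_endpoints_exact(self, default_profile):
        prof = default_profile
        for ch in (prof.F_med, prof.F_lat, prof.u_fem_med, prof.u_tib_lat):
            assert ch[0] == pytest.approx(ch[-1], abs=1e-12 * max(1, abs(ch[0])))

    def test_velocity_changes_sign_three_times(self, default_profile):
        u = default_profile.entrainment("medial")
        interior = u[1:-1]  # exclude the zero anchored at the seam
        signs = np.sign(interior[np.abs(interior) > 1e-12])
        flips = int(np.sum(np.diff(signs) != 0))
        assert flips == 3

    def test_zero_crossings_at_specified_phases(self, default_profile):
        prof = default_profile
        u = prof.entrainment("medial")
        for z in (0.20, 0.55, 0.80):
            i = int(np.argmin(np.abs(prof.phase - z)))
            assert abs(u[i]) < 1e-10

    def test_medial_dominates_lateral(self, default_profile):
        prof = default_profile
        assert np.all(prof.F_med >= prof.F_lat)
        assert np.all(
            np.abs(prof.entrainment("medial")) >= np.abs(prof.entrainment("lateral")) - 1e-15
        )

    def test_force_floor_respected(self, default_profile):
        prof = default_profile
        floor = 0.05 * prof.body_weight
        assert (prof.F_med + prof.F_lat).min() >= floor * (1 - 1e-12)

    def test_medial_share_constant_across_phases(self, default_profile):
        prof = default_profile
        share = prof.F_med / (prof.F_med + prof.F_lat)
        assert np.allclose(share, 0.6, atol=1e-12)

    def test_seam_is_continuously_differentiable(self):
        # derivative of the periodic interpolants at both ends of the seam
        from tkr_ehl.profiles import _entrainment_interp, _total_force_interp

        spec = GaitShapeSpec()
        for interp in (_total_force_interp(spec), _entrainment_interp(spec)):
            d = interp.derivative()
            grid = np.linspace(0, 1, 2001)
            max_slope = np.abs(d(grid)).max()
            assert abs(d(0.0) - d(1.0)) < 1e-6 * max_slope

    def test_deterministic_for_fixed_seed(self):
        a = generate_gait_profile(GaitShapeSpec(noise_amplitude_bw=0.05, seed=7), 101)
        b = generate_gait_profile(GaitShapeSpec(noise_amplitude_bw=0.05, seed=7), 101)
        assert np.array_equal(a.F_med, b.F_med)
        assert np.array_equal(a.u_fem_lat, b.u_fem_lat)

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_body_weight_scaling_is_exact(self, k):
        base = GaitShapeSpec()
        a = generate_gait_profile(base, 101)
        import dataclasses

        b = generate_gait_profile(
            dataclasses.replace(base, body_weight=k * base.body_weight), 101
        )
        np.testing.assert_allclose(b.F_med, k * a.F_med, rtol=1e-12)
        np.testing.assert_array_equal(b.u_fem_med, a.u_fem_med)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(peak_magnitudes_bw=(-1.0, 2.0)),
            dict(medial_share=1.5),
            dict(peak_phases=(0.5, 0.15)),
            dict(velocity_zero_phases=(0.2, 0.2, 0.8)),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            GaitShapeSpec(**bad)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_gait_profile(GaitShapeSpec(), 20)


class TestCsvRoundTrip:
    def test_round_trip_bit_identical(self, default_profile, tmp_path):
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_gait_profile(default_profile, p1)
        prof2 = read_gait_profile(p1)
        write_gait_profile(prof2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(default_profile.F_med, prof2.F_med)

    def test_header_schema(self, default_profile, tmp_path):
        path = tmp_path / "p.csv"
        write_gait_profile(default_profile, path)
        lines = path.read_text().splitlines()
        header = [ln for ln in lines if not ln.startswith("#")][0]
        assert header == (
            "phase,F_med_N,F_lat_N,u_fem_med_mps,u_tib_med_mps,"
            "u_fem_lat_mps,u_tib_lat_mps"
        )
        assert len([ln for ln in lines if not ln.startswith("#")]) == 201 + 1

    def test_negative_force_cell_reported(self, default_profile, tmp_path):
        path = tmp_path / "bad.csv"
        prof = default_profile
        F = prof.F_med.copy()
        F[5] = -1.0
        import dataclasses

        write_gait_profile(dataclasses.replace(prof, F_med=F), path)
        with pytest.raises(ProfileValidationError, match="row 5") as err:
            read_gait_profile(path)
        assert any("F_med_N" in v for v in err.value.violations)

    def test_unsorted_phase_reported(self, default_profile, tmp_path):
        path = tmp_path / "bad.csv"
        prof = default_profile
        ph = prof.phase.copy()
        ph[3], ph[4] = ph[4], ph[3]
        import dataclasses

        write_gait_profile(dataclasses.replace(prof, phase=ph), path)
        with pytest.raises(ProfileValidationError, match="phase not strictly increasing"):
            read_gait_profile(path)

    def test_missing_column_reported(self, default_profile, tmp_path):
        path = tmp_path / "bad.csv"
        write_gait_profile(default_profile, path)
        text = path.read_text().replace("F_lat_N", "F_other")
        path.write_text(text)
        with pytest.raises(ProfileValidationError, match="missing column F_lat_N"):
            read_gait_profile(path)


class TestResampling:
    def test_identity_on_same_grid(self, default_profile):
        out = resample_profile(default_profile, default_profile.n_samples - 1)
        np.testing.assert_allclose(out.F_med, default_profile.F_med, atol=1e-12)

    def test_double_then_halve_returns_node_values(self, default_profile):
        doubled = resample_profile(default_profile, 2 * (default_profile.n_samples - 1))
        halved = resample_profile(doubled, default_profile.n_samples - 1)
        np.testing.assert_allclose(halved.F_med, default_profile.F_med, atol=1e-9)

    def test_constant_channel_stays_constant(self, default_profile):
        import dataclasses

        prof = dataclasses.replace(
            default_profile, F_med=np.full_like(default_profile.phase, 500.0)
        )
        out = resample_profile(prof, 77)
        np.testing.assert_allclose(out.F_med, 500.0, rtol=1e-12)

    def test_too_few_steps_rejected(self, default_profile):
        with pytest.raises(ValueError):
            resample_profile(default_profile, 5)

    def test_periodicity_preserved(self, default_profile):
        out = resample_profile(default_profile, 133)
        assert out.u_fem_med[0] == out.u_fem_med[-1]


class TestVelocities:
    @pytest.mark.parametrize(
        "uf,ut,expected",
        [(0.1, 0.1, 0.1), (0.2, -0.2, 0.0), (0.06, 0.02, 0.04)],
    )
    def test_entrainment_is_mean(self, uf, ut, expected):
        assert entrainment_velocity(uf, ut) == pytest.approx(expected, abs=1e-15)

    def test_sliding_is_difference(self):
        assert sliding_velocity(0.06, 0.02) == pytest.approx(0.04)
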