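"""Unit and property tests of the linear FDTD solver: derived coefficients,
CFL bound, propagation accuracy, PML absorption, phasor extraction,
reciprocity, grid convergence and stability."""

import numpy as np
import pytest

from tcfus.acoustic import (
    AcousticSimulation,
    cfl_timestep,
    cfl_timestep_anisotropic,
    effective_attenuation,
    phasor_from_series,
)
from tcfus.analysis import on_axis_piston_reference
from tcfus.media import AcousticMedium, build_material_volume, uniform_volume

WATER = AcousticMedium(c=1482.3, rho=1000.0, a_per_f=0.025)
WATERISH = AcousticMedium(c=1500.0, rho=1000.0)


class TestEffectiveAttenuation:
    def test_zero_attenuation(self):
        assert effective_attenuation(0.0, 1500.0, 1e6) == 0.0

    def test_water_small_a_limit(self):
        # a = 0.0125 Np/m at 0.5 MHz: a²c⁴/(4π²f²) ≪ c² so ã ≈ 2ac = 37.06
        val = effective_attenuation(0.0125, 1482.3, 0.5e6)
        assert val == pytest.approx(2 * 0.0125 * 1482.3, rel=1e-6)
        assert val == pytest.approx(37.06, abs=0.01)

    def test_linear_in_a_for_small_a(self):
        v1 = effective_attenuation(0.0125, 1482.3, 0.5e6)
        v2 = effective_attenuation(0.025, 1482.3, 0.5e6)
        assert v2 / v1 == pytest.approx(2.0, rel=1e-3)

    def test_exact_plane_wave_decay_rate(self):
        """ã is chosen so the damped dispersion relation decays at rate a."""
        a, c, f = 30.0, 1600.0, 1e6
        atilde = effective_attenuation(a, c, f)
        w = 2 * np.pi * f
        k = np.sqrt(w**2 / c**2 + 1j * w * atilde / c**2 + 0j)
        assert k.imag == pytest.approx(a, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_attenuation(1.0, 1500.0, 0.0)
        with pytest.raises(ValueError):
            effective_attenuation(-1.0, 1500.0, 1e6)


class TestCFL:
    def test_uniform_reference_value(self):
        dt = cfl_timestep(0.25e-3, 1500.0, safety=0.95)
        assert dt == pytest.approx(0.95 * 0.25e-3 / (1500 * np.sqrt(3)),
                                   rel=1e-12)
        assert dt == pytest.approx(9.14e-8, rel=0.01)

    def test_halves_when_speed_doubles(self):
        assert cfl_timestep(0.25e-3, 3000.0) == pytest.approx(
            cfl_timestep(0.25e-3, 1500.0) / 2)

    def test_anisotropic_matches_isotropic_for_cubes(self):
        assert cfl_timestep_anisotropic([1e-3] * 3, 1500.0) == pytest.approx(
            cfl_timestep(1e-3, 1500.0))

    def test_anisotropic_dominated_by_finest_axis(self):
        dt_aniso = cfl_timestep_anisotropic([3e-4, 3e-4, 2e-4], 1500.0)
        assert dt_aniso > cfl_timestep(2e-4, 1500.0)  # sharper than min-step
        assert dt_aniso < cfl_timestep(2e-4, 1500.0, ndim=1)

    def test_solver_rejects_overlong_dt(self):
        vol = uniform_volume((8, 8, 8), 1e-3, WATERISH)
        with pytest.raises(ValueError):
            AcousticSimulation(vol, 1e6, dt=1e-5)


class TestBasicStepping:
    def test_zero_field_no_sources_stays_zero(self):
        vol = uniform_volume((12, 10, 14), 1e-3, WATERISH)
        sim = AcousticSimulation(vol, 500e3, pml_layers=0)
        sim.run(n_steps=50)
        assert np.all(sim.p == 0.0)

    def test_source_in_pml_rejected(self):
        vol = uniform_volume((64, 1, 1), 1e-3, WATERISH)
        sim = AcousticSimulation(vol, 500e3, pml_layers=16)
        with pytest.raises(ValueError):
            sim.add_point_source((4, 0, 0))

    def test_1d_propagation_speed_within_1pct(self):
        f = 500e3
        lam = WATERISH.c / f
        dz = lam / 10
        n = 300
        vol = uniform_volume((n, 1, 1), dz, WATERISH)
        sim = AcousticSimulation(vol, f)
        src = 20
        sim.add_source_voxels(
            [(src, 0, 0)], sim.sheet_source_scale(0, (src, 0, 0)))
        ph = sim.run_to_steady_state(n_periods=60)
        phase = np.unwrap(ph.phase[src + 20: n - 40, 0, 0])
        k_meas = -np.polyfit(np.arange(len(phase)) * dz, phase, 1)[0]
        c_meas = 2 * np.pi * f / k_meas
        assert c_meas == pytest.approx(WATERISH.c, rel=0.01)

    def test_point_source_spherical_spreading(self):
        f = 500e3
        lam = WATERISH.c / f
        h = lam / 10
        n = 101
        vol = uniform_volume((n, n, n), h, WATERISH)
        sim = AcousticSimulation(vol, f, dtype=np.float32)
        c0 = n // 2
        sim.add_point_source((c0, c0, c0))
        ph = sim.run_to_steady_state(n_periods=25)
        amp = ph.amplitude[c0, c0, c0:]
        r = np.arange(amp.size) * h
        sel = (r >= 2 * lam) & (r <= (n // 2 - 18) * h)
        prod = amp[sel] * r[sel]
        assert np.ptp(prod) / prod.mean() < 0.05

    def test_nan_detection_aborts(self):
        vol = uniform_volume((40, 1, 1), 1e-3, WATERISH)
        sim = AcousticSimulation(vol, 500e3, pml_layers=0)
        sim.add_point_source((20, 0, 0), amplitude=1.0)
        sim.p[15, 0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            sim.run(n_steps=400, check_every=100)


class TestPhasorExtraction:
    def test_projection_recovers_synthetic_sinusoid(self):
        f, dt = 1e6, 1 / (1e6 * 20)
        t = (np.arange(200) + 1) * dt
        series = 3.5 * np.cos(2 * np.pi * f * t + 0.7)
        P = phasor_from_series(series, dt, f)
        assert abs(P) == pytest.approx(3.5, rel=1e-9)
        assert np.angle(P) == pytest.approx(0.7, abs=1e-9)

    def test_receiver_series_matches_field_projection(self):
        f = 500e3
        vol = uniform_volume((200, 1, 1), 3e-4, WATERISH)
        sim = AcousticSimulation(vol, f)
        sim.add_source_voxels(
            [(20, 0, 0)], sim.sheet_source_scale(0, (20, 0, 0)))
        rec_idx = (120, 0, 0)
        sim.add_receivers([rec_idx])
        series = sim.run(n_periods=50, project_periods=2)
        P_series = phasor_from_series(series[0], sim.dt, f)
        P_field = sim.phasor_field.phasor[rec_idx]
        assert abs(P_series - P_field) / abs(P_field) < 0.005

    def test_projection_window_validation(self):
        with pytest.raises(ValueError):
            phasor_from_series(np.zeros(5), 1e-7, 1e6)


class TestPML:
    @staticmethod
    def _reflection_1d(pml_layers, n=400, f=500e3):
        """Standing-wave ripple beyond the source as a reflection gauge."""
        lam = WATERISH.c / f
        dz = lam / 15
        vol = uniform_volume((n, 1, 1), dz, WATERISH)
        sim = AcousticSimulation(vol, f, pml_layers=max(pml_layers, 0))
        src = 30
        sim.add_source_voxels(
            [(src, 0, 0)], sim.sheet_source_scale(0, (src, 0, 0)))
        sim.run_to_steady_state(n_periods=100)
        a = sim.phasor_field.amplitude[:, 0, 0]
        window = a[n - 40 - 30: n - 40]  # two wavelengths near the far end
        return float((window.max() - window.min())
                     / (window.max() + window.min()))

    def test_16_layers_below_1pct(self):
        assert self._reflection_1d(16) < 0.01

    def test_hard_wall_reflects_fully(self):
        assert self._reflection_1d(0) > 0.8

    def test_reflection_decreases_with_layers(self):
        r8 = self._reflection_1d(8)
        r16 = self._reflection_1d(16)
        assert r16 < r8 < 0.05

    def test_air_voxels_become_pressure_release(self):
        air = AcousticMedium(c=343.0, rho=1.2, a_per_f=0.04)
        labels = np.zeros((200, 1, 1), dtype=np.int16)
        labels[120:] = 1
        vol = build_material_volume(labels, 3e-4, {0: WATERISH, 1: air})
        sim = AcousticSimulation(vol, 500e3, air_mode="pressure_release")
        sim.add_source_voxels(
            [(20, 0, 0)], sim.sheet_source_scale(0, (20, 0, 0)))
        sim.run_to_steady_state(n_periods=80)
        assert np.all(sim.phasor_field.amplitude[120:, 0, 0] < 1e-6)
        # near-total reflection: strong standing wave in the water side
        a = sim.phasor_field.amplitude[60:110, 0, 0]
        assert (a.max() - a.min()) / (a.max() + a.min()) > 0.8


class TestReciprocity:
    def test_heterogeneous_swap_within_1pct(self):
        """Monopole-normalized point sources: p(B←A) = p(A←B)."""
        f = 500e3
        h = WATERISH.c / f / 10
        n = 72
        other = AcousticMedium(c=2200.0, rho=1700.0)
        labels = np.zeros((n, n, n), dtype=np.int16)
        labels[:, :, n // 2:] = 1  # half-space of stiffer material
        vol = build_material_volume(labels, h, {0: WATERISH, 1: other})
        A = (n // 2 - 6, n // 2 + 4, n // 2 - 10)
        B = (n // 2 + 5, n // 2 - 3, n // 2 + 9)

        def record(src, rec):
            sim = AcousticSimulation(vol, f, dtype=np.float32)
            rho_c2 = float(sim.rho[src] * sim.c[src] ** 2)
            sim.add_point_source(src, amplitude=rho_c2)
            sim.add_receivers([rec])
            series = sim.run(n_periods=30)
            return phasor_from_series(series, sim.dt, f)[0]

        p_ba = record(A, B)
        p_ab = record(B, A)
        assert abs(p_ba - p_ab) / abs(p_ab) < 0.01


class TestConvergence:
    def test_second_order_against_piston_closed_form(self):
        """Halving the spacing cuts the on-axis error by roughly 4x."""
        f = 500e3
        a = 4e-3
        errors = {}
        for frac in (6, 12):
            h = WATERISH.c / f / frac
            nx = int(round(24e-3 / h))
            nz = int(round(30e-3 / h))
            labels = np.zeros((nx, nx, nz), dtype=np.int16)
            vol = build_material_volume(labels, h, {0: WATERISH})
            sim = AcousticSimulation(vol, f, dtype=np.float32, pml_layers=12)
            ix = nx // 2
            x = (np.arange(nx) - ix) * h
            xx, yy = np.meshgrid(x, x, indexing="ij")
            disk = np.argwhere(xx**2 + yy**2 <= a**2)
            ks = 14
            idx = np.concatenate(
                [disk, np.full((len(disk), 1), ks, dtype=np.int64)], axis=1)
            sim.add_source_voxels(idx, sim.sheet_source_scale(2, (ix, ix, ks)))
            ph = sim.run_to_steady_state(n_periods=30)
            zs = np.arange(ks + 2, nz - 14)
            z = (zs - ks) * h
            prof = ph.amplitude[ix, ix, zs]
            ref = on_axis_piston_reference(z, a, f, WATERISH, 1.0)
            # remove the overall source-calibration scale: measure shape error
            s = np.dot(prof, ref) / np.dot(prof, prof)
            errors[frac] = np.linalg.norm(s * prof - ref) / np.linalg.norm(ref)
        ratio = errors[6] / errors[12]
        assert 2.0 < ratio < 8.0

    def test_nonuniform_axis_preserves_transit_phase(self):
        """A graded (ratio ≤ 1.2) axis propagates with the correct phase."""
        f = 500e3
        lam = WATERISH.c / f
        fine, coarse = lam / 16, lam / 10
        steps = [fine] * 80
        while steps[-1] < coarse:
            steps.append(min(steps[-1] * 1.15, coarse))
        steps += [coarse] * 120
        x = np.concatenate([[0.0], np.cumsum(steps)])
        vol = build_material_volume(
            np.zeros((len(x), 1, 1), dtype=np.int16), fine, {0: WATERISH})
        sim = AcousticSimulation(vol, f, axes=(x, np.zeros(1), np.zeros(1)))
        src = 20
        sim.add_source_voxels(
            [(src, 0, 0)], sim.sheet_source_scale(0, (src, 0, 0)))
        ph = sim.run_to_steady_state(n_periods=80)
        i1, i2 = 40, len(x) - 40
        dphi = np.angle(ph.phasor[i1, 0, 0] / ph.phasor[i2, 0, 0])
        k = 2 * np.pi * f / WATERISH.c
        expected = k * (x[i2] - x[i1])
        n_wrap = round((expected - dphi) / (2 * np.pi))
        assert dphi + 2 * np.pi * n_wrap == pytest.approx(expected, rel=0.01)


class TestStability:
    def test_lossless_energy_bounded_over_100_periods(self):
        f = 500e3
        lam = WATERISH.c / f
        vol = uniform_volume((160, 1, 1), lam / 12, WATERISH)
        sim = AcousticSimulation(vol, f, pml_layers=0)
        sim.add_point_source((80, 0, 0))
        sim.run(n_periods=5)  # build up a field, then free evolution
        sim._src_amp[:] = 0.0
        peak0 = float(np.abs(sim.p).max())
        peaks = []
        for _ in range(10):
            sim.run(n_periods=10)
            peaks.append(float(np.abs(sim.p).max()))
        assert max(peaks) < 3.0 * peak0
        assert np.isfinite(sim.p).all()
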