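"""Bioheat solver: analytic steady states, conduction kernel accuracy,
boundary conditions, perfusion shutdown, and the treatment protocol."""

import numpy as np
import pytest
from scipy.special import erf

from tcfus.media import (
    AcousticMedium,
    BloodProperties,
    ThermalMedium,
    build_material_volume,
    perfusion_mlminkg_to_si,
)
from tcfus.thermal import (
    BioheatSimulation,
    BoundarySpec,
    PerfusionModel,
    acoustic_heat_source,
    perfusion_factor,
    run_treatment_protocol,
)

AC = AcousticMedium(c=1500.0, rho=1000.0)
BLOOD = BloodProperties()


def _volume(shape, spacing, thermal, labels=None, extra=None):
    if labels is None:
        labels = np.zeros(shape, dtype=np.int16)
    table = {0: (AC, thermal)}
    if extra:
        table.update(extra)
    return build_material_volume(labels, spacing, table)


class TestPerfusionFactor:
    @pytest.mark.parametrize("T, expect", [
        (37.0, 1.0), (50.0, 1.0), (50.5, 0.5), (51.0, 0.0), (60.0, 0.0),
    ])
    def test_linear_shutdown_values(self, T, expect):
        assert perfusion_factor(T, PerfusionModel()) == pytest.approx(expect)

    def test_disabled_model_keeps_full_perfusion(self):
        m = PerfusionModel(enabled=False)
        assert perfusion_factor(80.0, m) == 1.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            PerfusionModel(shutdown_start=51.0, shutdown_end=50.0)


class TestHeatSource:
    def test_no_absorption_no_heating(self):
        assert acoustic_heat_source(1e6, 0.0, 1000.0, 1500.0) == 0.0

    def test_brain_voxel_formula_value(self):
        # 1 MPa in brain at 230 kHz: ρS must equal a·p²/(ρc) = 2α·I
        a = 8.6 * 0.23
        rho, c = 1046.0, 1565.0
        S = acoustic_heat_source(1e6, a, rho, c)
        assert rho * S == pytest.approx(a * 1e12 / (rho * c), rel=1e-12)

    def test_quadratic_in_pressure(self):
        s1 = acoustic_heat_source(1e6, 2.0, 1000.0, 1500.0)
        s2 = acoustic_heat_source(2e6, 2.0, 1000.0, 1500.0)
        assert s2 == pytest.approx(4 * s1)


class TestEquilibriumAndSteadyStates:
    def test_uniform_body_temperature_is_stationary(self):
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1050,
                           omega=perfusion_mlminkg_to_si(500))
        sim = BioheatSimulation(_volume((6, 6, 6), 1e-3, th), blood=BLOOD)
        T0 = sim.state.T.copy()
        sim.run(30.0)
        assert np.allclose(sim.state.T, T0, atol=1e-10)

    def test_perfused_steady_state_delta_T(self):
        """Constant S against perfusion only: ΔT∞ = S/(ρ_b·c_b·ω)."""
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1050,
                           omega=perfusion_mlminkg_to_si(559))
        sim = BioheatSimulation(_volume((6, 6, 6), 1e-3, th), blood=BLOOD)
        S = np.full((6, 6, 6), 10.0)
        sim.run(900.0, S=S)  # about nine perfusion time constants
        dT = sim.state.T - 37.0
        expect = 10.0 / (BLOOD.rho_b * BLOOD.c_b * th.omega)
        assert dT == pytest.approx(np.full_like(dT, expect), rel=0.01)

    def test_perfusion_always_pulls_toward_blood_temperature(self, rng):
        th = ThermalMedium(C_heat=3600, k_cond=0.0, rho=1050,
                           omega=perfusion_mlminkg_to_si(400))
        sim = BioheatSimulation(_volume((8, 8, 8), 1e-3, th), blood=BLOOD)
        sim.state.T[:] = 37.0 + rng.uniform(-5, 5, size=(8, 8, 8))
        before = sim.state.T.copy()
        sim.step(sim.dt_stable)
        moved = sim.state.T - before
        assert np.all(np.sign(moved[before != 37.0])
                      == -np.sign(before[before != 37.0] - 37.0))


class TestConduction:
    def test_1d_step_response_matches_heat_kernel(self):
        """Dirichlet step at one end of a long rod: erf profile within 1%."""
        th = ThermalMedium(C_heat=4000, k_cond=0.6, rho=1000)
        labels = np.zeros((200, 1, 1), dtype=np.int16)
        labels[0] = 1
        vol = _volume((200, 1, 1), 1e-3, th, labels=labels,
                      extra={1: (AC, th)})
        sim = BioheatSimulation(
            vol, boundaries=(BoundarySpec(0, 1, "dirichlet", T_boundary=57.0),),
            T_initial=37.0)
        t_end = 2000.0
        sim.run(t_end)
        alpha = 0.6 / (1000 * 4000)
        x = np.arange(200) * 1e-3  # distance from the pinned node
        exact = 57.0 + (37.0 - 57.0) * erf(x / (2 * np.sqrt(alpha * t_end)))
        err = np.abs(sim.state.T[2:120, 0, 0] - exact[2:120]) / 20.0
        assert err.max() < 0.01

    def test_insulated_energy_conservation(self, rng):
        th = ThermalMedium(C_heat=4000, k_cond=0.6, rho=1000)
        sim = BioheatSimulation(_volume((12, 12, 12), 1e-3, th))
        sim.state.T += rng.random((12, 12, 12))
        e0 = sim.state.T.sum()
        for _ in range(200):
            sim.step(sim.dt_stable)
        assert abs(sim.state.T.sum() / e0 - 1) < 1e-6

    def test_unstable_dt_rejected(self):
        th = ThermalMedium(C_heat=4000, k_cond=0.6, rho=1000)
        sim = BioheatSimulation(_volume((8, 8, 8), 1e-3, th))
        with pytest.raises(ValueError):
            sim.step(sim.dt_stable * 3)


class TestBoundaries:
    def test_dirichlet_pins_boundary_voxels(self):
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1000)
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[:, :, :2] = 1  # water bolus region
        vol = _volume((10, 10, 10), 1e-3, th, labels=labels,
                      extra={1: (AC, th)})
        sim = BioheatSimulation(
            vol, boundaries=(BoundarySpec(0, 1, "dirichlet", T_boundary=16.0),))
        sim.run(10.0)
        assert np.all(sim.state.T[:, :, :2] == 16.0)
        # tissue adjacent to the bolus cools below core temperature
        assert sim.state.T[5, 5, 2] < 37.0

    def test_convective_end_approaches_outside_temperature(self):
        """A thin rod with a convective end equilibrates to T_outside."""
        th = ThermalMedium(C_heat=3600, k_cond=5.0, rho=1000)
        labels = np.zeros((30, 1, 1), dtype=np.int16)
        labels[-1] = 1
        vol = _volume((30, 1, 1), 1e-3, th, labels=labels,
                      extra={1: (AC, th)})
        sim = BioheatSimulation(
            vol, boundaries=(BoundarySpec(0, 1, "convective", h=500.0,
                                          T_outside=20.0),),
            T_initial=37.0)
        sim.run(3000.0)
        assert sim.state.T[-2, 0, 0] == pytest.approx(20.0, abs=0.1)
        assert np.all(np.diff(sim.state.T[:-1, 0, 0]) <= 1e-9)

    def test_convective_h0_reduces_to_neumann(self):
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1000)
        labels = np.zeros((20, 1, 1), dtype=np.int16)
        labels[-1] = 1
        vol = _volume((20, 1, 1), 1e-3, th, labels=labels,
                      extra={1: (AC, th)})
        Ts = []
        for bc in (BoundarySpec(0, 1, "convective", h=0.0, T_outside=99.0,
                                F_boundary=50.0),
                   BoundarySpec(0, 1, "neumann", F_boundary=50.0)):
            sim = BioheatSimulation(vol, boundaries=(bc,))
            sim.run(50.0)
            Ts.append(sim.state.T.copy())
        assert np.allclose(Ts[0], Ts[1])

    def test_instability_detected_and_aborted(self):
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1000)
        sim = BioheatSimulation(_volume((6, 6, 6), 1e-3, th))
        with pytest.raises(FloatingPointError):
            sim.run(10.0, S=np.full((6, 6, 6), 1e9))


class TestProtocolAndShutdown:
    @pytest.fixture()
    def heated_setup(self):
        th = ThermalMedium(C_heat=3600, k_cond=0.5, rho=1050,
                           omega=perfusion_mlminkg_to_si(559))
        vol = _volume((15, 15, 15), 1e-3, th)
        S = np.zeros((15, 15, 15))
        S[6:9, 6:9, 6:9] = 4000.0  # focal heating, W/kg
        return vol, S

    def test_zero_power_second_phase_is_identity(self, heated_setup):
        vol, _ = heated_setup
        eq, post = run_treatment_protocol(
            vol, None, equilibration=60.0, sonication=5.0)
        assert np.allclose(eq.T, post.T)

    def test_peak_dT_grows_monotonically_during_sonication(self, heated_setup):
        vol, S = heated_setup
        sim = BioheatSimulation(vol)
        peaks = []
        for _ in range(5):
            sim.run(2.0, S=S)
            peaks.append(sim.state.T.max())
        assert np.all(np.diff(peaks) > 0)

    def test_vascular_shutdown_heats_faster(self, heated_setup):
        """Losing perfusion above 50 °C steepens the temperature rise."""
        vol, S = heated_setup
        peaks = {}
        for enabled in (False, True):
            sim = BioheatSimulation(
                vol, perfusion=PerfusionModel(enabled=enabled))
            sim.run(40.0, S=1.6 * S)
            peaks[enabled] = sim.state.T.max()
        assert peaks[False] > 50.0  # the shutdown window was actually entered
        assert peaks[True] > peaks[False]

    def test_protocol_returns_both_states(self, heated_setup):
        vol, S = heated_setup
        eq, post = run_treatment_protocol(
            vol, S, equilibration=30.0, sonication=10.0)
        assert post.t == pytest.approx(40.0)
        assert post.T.max() > eq.T.max()
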