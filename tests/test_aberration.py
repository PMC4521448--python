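"""Aberration-correction strategies: formula-level behavior and ray tracing.

The end-to-end refocusing behavior (forward runs through the skull
phantom) is exercised by the water-consistency and acceptance suites; here
the per-element algebra and the ray tracer are checked against closed
forms.
"""

import numpy as np
import pytest

from tcfus.aberration import (
    dpc,
    rtpc,
    spac,
    spac_normalization,
    spc,
    trace_rays,
)
from tcfus.media import acoustic_tissue_table
from tcfus.phantoms import make_skull_phantom, shell_chord_length
from tcfus.transducers import make_hemispherical_array

WATER = acoustic_tissue_table()["Water"]
BONE = acoustic_tissue_table()["Bone"]


@pytest.fixture(scope="module")
def small_array():
    return make_hemispherical_array(
        n_elements=48, diameter=28e-3, element_area=4e-6, f=500e3)


@pytest.fixture(scope="module")
def shell_phantom():
    return make_skull_phantom(
        (101, 101, 101), 0.3e-3, outer_radius=8e-3, thickness=2.1e-3)


class TestDPC:
    def test_geometric_focus_gives_equal_phases(self, small_array):
        d = dpc(small_array, small_array.geometric_focus, WATER.c, 1e5)
        assert np.ptp(d.phases) < 1e-9
        assert np.all(d.amplitudes == 1e5)

    def test_half_wavelength_path_difference_is_pi(self, small_array):
        lam = WATER.c / small_array.frequency
        # two synthetic elements at distances d and d + λ/2 from the target
        from tcfus.transducers import TransducerArray

        arr = TransducerArray(
            centers=[[0, 0, -10e-3], [0, 0, -10e-3 - lam / 2]],
            normals=[[0, 0, 1], [0, 0, 1]], areas=[1e-6, 1e-6],
            geometric_focus=[0, 0, 0], frequency=small_array.frequency)
        d = dpc(arr, (0, 0, 0), WATER.c, 1.0)
        dphi = np.angle(np.exp(1j * (d.phases[1] - d.phases[0])))
        assert abs(dphi) == pytest.approx(np.pi, abs=1e-9)


class TestTraceRays:
    def test_water_only_path(self, small_array):
        ph = make_skull_phantom((81, 81, 81), 0.4e-3, outer_radius=8e-3,
                                thickness=0.0)
        rays = trace_rays(small_array, (0, 0, 0), ph.volume, bone_label=1)
        assert np.all(rays.bone_lengths == 0.0)
        assert rays.total_lengths == pytest.approx(
            small_array.focus_distances((0, 0, 0)))

    def test_uniform_shell_center_target(self, small_array, shell_phantom):
        rays = trace_rays(small_array, (0, 0, 0), shell_phantom.volume,
                          bone_label=1)
        diag = np.sqrt(3) * 0.3e-3
        assert np.all(np.abs(rays.bone_lengths - 2.1e-3) <= diag)

    def test_oblique_rays_match_chord_oracle(self, small_array,
                                             shell_phantom):
        target = np.array([2e-3, -1.5e-3, 1e-3])
        rays = trace_rays(small_array, target, shell_phantom.volume,
                          bone_label=1)
        diag = np.sqrt(3) * 0.3e-3
        for e in range(small_array.n_elements):
            expect = shell_chord_length(
                small_array.centers[e], target, (0, 0, 0), 8e-3, 2.1e-3)
            assert abs(rays.bone_lengths[e] - expect) <= diag


class TestRTPC:
    def test_no_bone_reduces_to_dpc(self, small_array):
        ph = make_skull_phantom((81, 81, 81), 0.4e-3, outer_radius=8e-3,
                                thickness=0.0)
        a = dpc(small_array, (0, 0, 0), WATER.c, 2e5)
        b = rtpc(small_array, (0, 0, 0), ph.volume, 2e5, 1, WATER.c, BONE.c)
        assert np.allclose(np.angle(np.exp(1j * (a.phases - b.phases))), 0,
                           atol=1e-9)

    def test_uniform_bone_path_is_constant_offset(self, small_array,
                                                  shell_phantom):
        """A concentric shell shifts all phases by a focus-irrelevant
        constant relative to the water-path corrections."""
        a = dpc(small_array, (0, 0, 0), WATER.c, 1.0)
        b = rtpc(small_array, (0, 0, 0), shell_phantom.volume, 1.0, 1,
                 WATER.c, BONE.c)
        diff = np.angle(np.exp(1j * (b.phases - a.phases)))
        # spread bounded by the ±1-voxel staircase of the voxelized shell
        jitter = (2 * np.pi * small_array.frequency
                  * (1 / WATER.c - 1 / BONE.c)
                  * 2 * np.sqrt(3) * 0.3e-3)
        assert np.ptp(diff) < jitter
        assert np.abs(diff).min() > 1.0  # clearly nonzero common offset

    def test_thicker_bone_shifts_phase_by_formula(self, small_array,
                                                  shell_phantom):
        from tcfus.aberration import RayTraceResult

        target = (0, 0, 0)
        rays = trace_rays(small_array, target, shell_phantom.volume, 1)
        thicker = RayTraceResult(
            total_lengths=rays.total_lengths,
            bone_lengths=rays.bone_lengths + 1e-3)
        f = small_array.frequency
        b0 = rtpc(small_array, target, shell_phantom.volume, 1.0, 1,
                  WATER.c, BONE.c, rays=rays)
        b1 = rtpc(small_array, target, shell_phantom.volume, 1.0, 1,
                  WATER.c, BONE.c, rays=thicker)
        expect = 2 * np.pi * f * 1e-3 * (1 / BONE.c - 1 / WATER.c)
        diff = np.angle(np.exp(1j * (b1.phases - b0.phases)))
        assert diff == pytest.approx(expect, abs=1e-9)


class TestSPC:
    def test_phases_are_conjugated(self):
        cap = np.array([np.exp(0.3j), 2 * np.exp(-1.2j), 0.5 * np.exp(2.0j)])
        d = spc(cap, 1e5)
        assert d.phases == pytest.approx([-0.3, 1.2, -2.0])
        assert np.all(d.amplitudes == 1e5)

    def test_zero_phase_capture_gives_zero_drive_phase(self):
        d = spc(np.array([1.0 + 0j, 2.0 + 0j]), 1.0)
        assert np.all(d.phases == 0.0)

    def test_dead_element_deactivated_with_warning(self):
        cap = np.array([1.0 + 0j, 1e-9 + 0j, 1.0j])
        with pytest.warns(UserWarning, match="deactivated"):
            d = spc(cap, 1e5)
        assert list(d.active) == [True, False, True]
        assert d.amplitudes[1] == 0.0

    def test_all_zero_capture_rejected(self):
        with pytest.raises(ValueError):
            spc(np.zeros(4, complex), 1.0)


class TestSPAC:
    def test_equal_captures_leave_amplitudes_unchanged(self):
        p_el = 120.31e3  # 1000 W, 1024 elements, 1 cm²
        cap = p_el * np.exp(1j * np.linspace(0, 3, 1024))
        d = spac(cap, 1000.0, 1e-4)
        assert d.amplitudes == pytest.approx(np.full(1024, p_el), rel=1e-3)

    def test_doubled_captures_halve_normalization(self):
        assert spac_normalization(np.full(16, 2.0), 1.0) == pytest.approx(0.5)

    def test_power_identity_random_captures(self, rng):
        """Σ amplitudes² = N·p²_element exactly, any capture distribution."""
        from tcfus.transducers import element_surface_pressure

        n = 256
        cap = rng.gamma(2.0, 1.0, n) * np.exp(1j * rng.uniform(0, 2 * np.pi, n))
        P = 750.0
        d = spac(cap, P, 1e-4)
        p_el = element_surface_pressure(P, n, 1e-4)
        assert np.sum(d.amplitudes**2) == pytest.approx(n * p_el**2,
                                                        rel=1e-12)

    def test_phases_match_spc(self, rng):
        cap = rng.normal(size=8) + 1j * rng.normal(size=8)
        assert spac(cap, 10.0, 1e-4).phases == pytest.approx(
            spc(cap, 1.0).phases)


class TestGlobalPhaseInvariance:
    def test_constant_phase_offset_preserves_amplitude_field(self):
        """Forward fields from drives differing by a global phase constant
        are identical in |p| (checked on a tiny water run)."""
        from tcfus.acoustic import AcousticSimulation
        from tcfus.media import uniform_volume

        f = 500e3
        h = WATER.c / f / 8
        vol = uniform_volume((81, 81, 61), h, WATER,
                             origin=(-40 * h, -40 * h, -45 * h))
        amps = None
        for offset in (0.0, 1.23):
            sim = AcousticSimulation(vol, f, dtype=np.float32, pml_layers=10)
            for (i, ph) in [((40, 30, 12), 0.5), ((40, 50, 12), 2.2),
                            ((30, 40, 12), 4.0)]:
                sim.add_point_source((i), amplitude=1.0, phase=ph + offset)
            field = sim.run_to_steady_state(n_periods=20).amplitude
            if amps is None:
                amps = field
            else:
                scale = np.abs(amps).max()
                assert np.abs(field - amps).max() / scale < 0.005
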