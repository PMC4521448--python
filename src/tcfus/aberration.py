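"""Skull-aberration correction strategies for phased-array focusing.

Four strategies compute per-element phase (and optionally amplitude)
corrections that refocus the array at a target despite the skull:

* DPC  — distance-based phase corrections: pure water-path delays from
  element-center → target distances; the skull is ignored.
* RTPC — ray-traced phase corrections: straight rays element → target are
  intersected with the bone map and the bone path is retimed at the bone
  sound speed (no refraction).
* SPC  — simulation-based phase conjugation: a virtual point source at the
  target is propagated backwards through the full heterogeneous model; the
  phases recorded at the elements are conjugated, amplitudes kept uniform.
* SPAC — as SPC, but the recorded amplitudes are also used, rescaled to
  the prescribed acoustic input power.

Sign convention: the drive phase is the *negative* of the propagation
phase delay, so a wave driven as cos(ωt + φ_i) arrives cophasal at the
target.  Adding any global constant to all phases leaves the focus
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .media import MaterialVolume
from .transducers import DriveVector, TransducerArray

__all__ = [
    "RayTraceResult",
    "dpc",
    "trace_rays",
    "rtpc",
    "spc",
    "spac",
    "spac_normalization",
    "CAPTURE_AMPLITUDE_FLOOR",
]

#: captures below this fraction of the maximum deactivate the element
CAPTURE_AMPLITUDE_FLOOR = 1e-6


@dataclass
class RayTraceResult:
    """Straight-ray element → target path decomposition."""

    total_lengths: np.ndarray  # m
    bone_lengths: np.ndarray  # m

    def __post_init__(self) -> None:
        self.total_lengths = np.atleast_1d(np.asarray(self.total_lengths, float))
        self.bone_lengths = np.atleast_1d(np.asarray(self.bone_lengths, float))
        if np.any(self.bone_lengths < -1e-12) or np.any(
            self.bone_lengths > self.total_lengths + 1e-9
        ):
            raise ValueError("need 0 <= bone path <= total path")


def dpc(
    array: TransducerArray,
    target,
    c_water: float,
    p_element: float,
) -> DriveVector:
    """Distance-based phase corrections (homogeneous-water assumption).

    φ_i = +2πf·d_i/c_water (mod 2π) with d_i the element → target distance;
    all amplitudes are fixed at ``p_element``.
    """
    d = array.focus_distances(target)
    phases = np.mod(2 * np.pi * array.frequency * d / c_water, 2 * np.pi)
    return DriveVector(
        amplitudes=np.full(array.n_elements, float(p_element)), phases=phases
    )


def trace_rays(
    array: TransducerArray,
    target,
    volume: MaterialVolume,
    bone_label: int,
    step_frac: float = 0.25,
) -> RayTraceResult:
    """Bone path length of each straight element-center → target segment.

    The segment is sampled every ``step_frac``·min(spacing) and the bone
    path is the measure of samples landing on ``bone_label`` voxels
    (midpoint rule); no refraction is applied.  Accurate to about one voxel
    diagonal.
    """
    target = np.asarray(target, float)
    spacing = np.asarray(volume.spacing)
    ds = float(spacing.min()) * step_frac
    origin = np.asarray(volume.origin)
    shape = volume.shape
    labels = volume.labels

    totals = array.focus_distances(target)
    bones = np.zeros(array.n_elements)
    for e in range(array.n_elements):
        L = totals[e]
        n_samp = max(int(np.ceil(L / ds)), 1)
        s = (np.arange(n_samp) + 0.5) / n_samp
        pts = array.centers[e] + np.outer(s, target - array.centers[e])
        idx = np.round((pts - origin) / spacing).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        hit = np.zeros(n_samp, dtype=bool)
        hit[ok] = labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]] == bone_label
        bones[e] = hit.sum() * (L / n_samp)
    return RayTraceResult(total_lengths=totals, bone_lengths=bones)


def rtpc(
    array: TransducerArray,
    target,
    volume: MaterialVolume,
    p_element: float,
    bone_label: int,
    c_water: float,
    c_bone: float,
    rays: RayTraceResult | None = None,
) -> DriveVector:
    """Ray-traced phase corrections: water path + bone path retimed.

    φ_i = 2πf·[(d_i − b_i)/c_water + b_i/c_bone] (mod 2π) with b_i the bone
    path of element i's straight ray; amplitudes fixed at ``p_element``.
    Degenerates to DPC when no ray crosses bone.
    """
    if rays is None:
        rays = trace_rays(array, target, volume, bone_label)
    tof = (rays.total_lengths - rays.bone_lengths) / c_water \
        + rays.bone_lengths / c_bone
    phases = np.mod(2 * np.pi * array.frequency * tof, 2 * np.pi)
    return DriveVector(
        amplitudes=np.full(array.n_elements, float(p_element)), phases=phases
    )


def _active_mask(captured: np.ndarray) -> np.ndarray:
    amp = np.abs(captured)
    peak = amp.max()
    if peak == 0:
        raise ValueError("all captured amplitudes are zero")
    active = amp > CAPTURE_AMPLITUDE_FLOOR * peak
    if not active.all():
        warnings.warn(
            f"{(~active).sum()} element(s) captured no signal "
            "(no line of sight) and were deactivated", stacklevel=3)
    return active

def spc(captured: np.ndarray, p_element: float) -> DriveVector:
    """Simulation-based phase conjugation with uniform amplitudes.

    φ_i = −arg(p_captured,i); amplitudes fixed at ``p_element``.  Elements
    that recorded (essentially) zero amplitude carry no phase information
    and are deactivated with a warning.
    """
    captured = np.atleast_1d(np.asarray(captured, complex))
    active = _active_mask(captured)
    phases = np.where(active, -np.angle(captured), 0.0)
    amps = np.where(active, float(p_element), 0.0)
    return DriveVector(amplitudes=amps, phases=phases, active=active)


def spac_normalization(captured_amplitudes: np.ndarray,
                       p_element: float) -> float:
    """Power normalization factor f = √(N·p²_element / Σ p²_captured,i).

    Scaling the captured amplitudes by f makes the summed squared drive
    amplitudes equal N·p²_element, i.e. the same total acoustic input power
    as uniform driving at ``p_element``.
    """
    amps = np.asarray(captured_amplitudes, float)
    ssum = float(np.sum(amps**2))
    if ssum == 0:
        raise ValueError("all captured amplitudes are zero")
    return float(np.sqrt(len(amps) * p_element**2 / ssum))


def spac(captured: np.ndarray, P_total: float, A_element: float,
         Z_water: float | None = None) -> DriveVector:
    """Simulation-based phase and amplitude corrections.

    Phases as in :func:`spc`; amplitudes are the captured amplitudes
    rescaled so the drive carries the acoustic input power ``P_total``
    (uniform-power equivalence over the active elements).
    """
    from .transducers import Z_WATER, element_surface_pressure

    captured = np.atleast_1d(np.asarray(captured, complex))
    active = _active_mask(captured)
    n_act = int(active.sum())
    p_el = element_surface_pressure(
        P_total, n_act, A_element, Z_WATER if Z_water is None else Z_water)
    amp_cap = np.abs(captured[active])
    f_norm = spac_normalization(amp_cap, p_el)
    amps = np.zeros(len(captured))
    amps[active] = f_norm * amp_cap
    phases = np.where(active, -np.angle(captured), 0.0)
    return DriveVector(amplitudes=amps, phases=phases, active=active)
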