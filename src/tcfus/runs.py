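"""End-to-end scenario runners: validation protocols and focus studies.

These functions tie phantoms, solvers, aberration strategies and analysis
into single reproducible runs; the command-line interface is a thin wrapper
around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import aberration as ab
from .acoustic import AcousticSimulation, inverse_propagate
from .analysis import (
    FocalMetrics,
    analytic_coefficients,
    focal_metrics,
    measure_coefficients,
    nsd,
    rayleigh_axis_reference,
)
from .media import (
    AcousticMedium,
    MaterialVolume,
    acoustic_tissue_table,
    build_material_volume,
    uniform_volume,
)
from .phantoms import InterfaceSetup, PistonSetup, make_interface_setup, make_piston_setup, make_skull_phantom
from .transducers import (
    TransducerArray,
    DriveVector,
    element_surface_pressure,
    make_hemispherical_array,
    voxelize_elements,
)

__all__ = [
    "InterfaceResult",
    "run_interface_case",
    "INTERFACE_VALIDATION_CASES",
    "calibrate_sheet_amplitude",
    "PistonResult",
    "run_piston_case",
    "PISTON_VALIDATION_CASES",
    "steady_state_change",
    "FocusScenario",
    "make_focus_scenario",
    "run_focus_comparison",
    "StrategyResult",
]


# ---------------------------------------------------------------------------
# Plane-interface reflection/transmission validation
# ---------------------------------------------------------------------------

#: (cB, rhoB, theta_i) triplets of the nine-interface validation protocol:
#: a 1 MHz plane wave from water-like medium A (1500, 1000) onto three
#: media at 0°, 15° and 30° incidence.
INTERFACE_VALIDATION_CASES: tuple[tuple[float, float, float], ...] = tuple(
    (cB, rhoB, th)
    for th in (0.0, 15.0, 30.0)
    for cB, rhoB in ((2000.0, 1900.0), (1400.0, 600.0), (1200.0, 600.0))
)


@dataclass
class InterfaceResult:
    """Analytic and FDTD-measured coefficients for one interface case."""

    setup: InterfaceSetup
    R_analytic: float
    T_analytic: float
    theta_t: float
    R_measured: float
    T_measured: float


def run_interface_case(
    cB: float,
    rhoB: float,
    theta_i: float,
    cA: float = 1500.0,
    rhoA: float = 1000.0,
    f: float = 1e6,
    n_periods: int = 60,
    dtype=np.float32,
    **setup_kw,
) -> InterfaceResult:
    """Measure R and T for one plane-interface case and compare to theory.

    Two runs share sources and time step: the interface domain and an
    all-medium-A reference.  The incident phasor is the reference field at
    a probe just below the interface; the reflected phasor is the
    difference between the two runs there; the transmitted phasor is read
    just above the interface.  All three are phase-referred to the
    interface plane before forming the signed amplitude ratios.
    """
    setup = make_interface_setup(cA, rhoA, cB, rhoB, theta_i, f, **setup_kw)
    vol = setup.volume
    vol_hom = build_material_volume(
        np.zeros_like(vol.labels), vol.spacing, {0: setup.medium_A})

    fields = {}
    dt_shared = None
    for name, v in (("interface", vol), ("reference", vol_hom)):
        sim = AcousticSimulation(
            v, f, pml_layers=16, dtype=dtype, dt=dt_shared)
        dt_shared = sim.dt
        sim.add_plane_source(
            axis=2, index=setup.source_index, amplitude=1.0,
            theta_deg=theta_i, ramp_axis=0)
        fields[name] = sim.run_to_steady_state(n_periods=n_periods)

    w = 2 * np.pi * f
    thi = np.deg2rad(theta_i)
    # probes: central x strip with the oblique phase ramp removed
    nx = vol.shape[0]
    xs = np.arange(nx // 2 - 8, nx // 2 + 9)
    kx = w / cA * np.sin(thi)
    xc = vol.axes()[0][xs]
    deramp = np.exp(1j * kx * (xc - xc.mean()))

    zA, zB = setup.probe_A[2], setup.probe_B[2]
    P_inc = (fields["reference"].phasor[xs, 0, zA] * deramp).mean()
    P_tot = (fields["interface"].phasor[xs, 0, zA] * deramp).mean()
    P_B = (fields["interface"].phasor[xs, 0, zB] * deramp).mean()

    an = analytic_coefficients(setup.medium_A, setup.medium_B, theta_i)
    dz = vol.spacing[2]
    z_int = setup.k_interface - 0.5  # interface on the voxel face
    kAz = w / cA * np.cos(thi)
    dA = (z_int - zA) * dz
    if an.evanescent:
        P_t_int = complex("nan")
    else:
        kBz = w / cB * np.cos(np.deg2rad(an.theta_t))
        P_t_int = P_B * np.exp(1j * kBz * (zB - z_int) * dz)
    meas = measure_coefficients(
        P_inc * np.exp(-1j * kAz * dA),
        (P_tot - P_inc) * np.exp(1j * kAz * dA),
        P_t_int,
    )
    return InterfaceResult(
        setup=setup, R_analytic=an.R, T_analytic=an.T, theta_t=an.theta_t,
        R_measured=meas.R, T_measured=meas.T,
    )


# ---------------------------------------------------------------------------
# Piston near-field validation
# ---------------------------------------------------------------------------

#: the six piston validation cases: three apertures × lossless/lossy
PISTON_VALIDATION_CASES: tuple[tuple[str, bool], ...] = (
    ("circular", False), ("circular", True),
    ("rectangular", False), ("rectangular", True),
    ("ring", False), ("ring", True),
)

#: desk-scale grid: λ/10 transverse, λ/15 along the beam axis.  The axial
#: refinement controls the dominant (axial phase-dispersion) error at a
#: linear rather than quartic cost.
def piston_validation_spacing(f: float = 500e3, c: float = 1500.0):
    lam = c / f
    return (lam / 10.0, lam / 10.0, lam / 15.0)


def calibrate_sheet_amplitude(
    medium: AcousticMedium,
    dz: float,
    dt: float,
    f: float,
    n: int = 240,
    dtype=np.float32,
) -> float:
    """Emitted plane-wave amplitude of a unit-amplitude sheet source.

    Runs a cheap 1D column with the same axial spacing and time step as a
    3D run and measures the actual emitted amplitude (the nominal sheet
    scaling is exact only in the continuum limit).  For attenuating media
    the measured profile is corrected by e^{+αz} before averaging.  The
    returned amplitude feeds the Rayleigh-integral reference so that the
    comparison carries no free scale factor.
    """
    vol = uniform_volume((n, 1, 1), (dz, dz, dz), medium)
    sim = AcousticSimulation(vol, f, pml_layers=16, dtype=dtype, dt=dt)
    k0 = 18
    sim.add_source_voxels([(k0, 0, 0)], sim.sheet_source_scale(0, (k0, 0, 0)))
    transit_periods = n * dz / medium.c * f
    ph = sim.run_to_steady_state(n_periods=int(np.ceil(2.5 * transit_periods)))
    zs = np.arange(k0 + 20, n - 30)
    z = (zs - k0) * dz
    alpha = medium.attenuation(f)
    return float(np.exp(np.mean(np.log(ph.amplitude[zs, 0, 0]) + alpha * z)))


@dataclass
class PistonResult:
    """On-axis comparison of one piston case against the Rayleigh reference."""

    setup: PistonSetup
    z: np.ndarray  # axial distance from the source plane, m
    p_fdtd: np.ndarray  # FDTD steady-state |p| on axis (unit drive)
    p_ref: np.ndarray  # Rayleigh-integral reference |p|
    nsd_percent: float
    simulation: AcousticSimulation = field(repr=False, default=None)


def _build_piston_simulation(setup: PistonSetup, dtype=np.float32,
                             pml_layers: int = 16) -> AcousticSimulation:
    sim = AcousticSimulation(
        setup.volume, setup.frequency, pml_layers=pml_layers, dtype=dtype)
    idx2 = np.argwhere(setup.source_mask > 0)
    weights = setup.source_mask[idx2[:, 0], idx2[:, 1]]
    idx3 = np.concatenate(
        [idx2, np.full((len(idx2), 1), setup.k_source, dtype=np.int64)], axis=1)
    scale = sim.sheet_source_scale(2, tuple(idx3[0]))
    sim.add_source_voxels(idx3, scale * weights)
    return sim


def _axis_profile(setup: PistonSetup, sim: AcousticSimulation,
                  phasor: np.ndarray):
    ix, iy = setup.axis_indices
    npml = sim.grid.pml_layers
    ks = np.arange(setup.k_source + 2, setup.volume.shape[2] - npml - 2)
    z = (ks - setup.k_source) * setup.volume.spacing[2]
    return z, np.abs(phasor[ix, iy, ks])


def run_piston_case(
    kind: str,
    lossy: bool,
    f: float = 500e3,
    n_periods: int = 60,
    spacing=None,
    dtype=np.float32,
    keep_simulation: bool = False,
) -> PistonResult:
    """One piston validation case: FDTD steady state vs Rayleigh reference.

    Runs the LAPWE solver for ``n_periods`` periods, extracts the on-axis
    steady-state pressure magnitude, and compares (as a normalized standard
    deviation, percent) against the independently computed
    Rayleigh–Sommerfeld reference with the 1D-calibrated source amplitude.
    """
    if spacing is None:
        spacing = piston_validation_spacing(f)
    setup = _respace_piston(make_piston_setup(kind, f=f, lossy=lossy), spacing)
    sim = _build_piston_simulation(setup, dtype=dtype)
    ph = sim.run_to_steady_state(n_periods=n_periods)
    p0 = calibrate_sheet_amplitude(
        setup.medium, setup.volume.spacing[2], sim.dt, f, dtype=dtype)
    z, prof = _axis_profile(setup, sim, ph.amplitude)
    ref = rayleigh_axis_reference(
        z, setup.kind, setup.dims, f, setup.medium, p0, alpha=setup.alpha)
    return PistonResult(
        setup=setup, z=z, p_fdtd=prof, p_ref=ref,
        nsd_percent=nsd(prof, ref),
        simulation=sim if keep_simulation else None,
    )


def _respace_piston(setup: PistonSetup, spacing) -> PistonSetup:
    """Rebuild a piston setup on an anisotropic grid."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    dx, dy, dz = spacing
    nx = int(round(40e-3 / dx))
    ny = int(round(40e-3 / dy))
    nz = int(round(90e-3 / dz))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    vol = build_material_volume(labels, spacing, {0: setup.medium},
                                label_names={0: "Water"})
    ix, iy = nx // 2, ny // 2
    x = (np.arange(nx) - ix) * dx
    y = (np.arange(ny) - iy) * dy
    from .phantoms import piston_coverage_mask

    mask = piston_coverage_mask(setup.kind, setup.dims, x, y)
    return PistonSetup(
        kind=setup.kind, dims=setup.dims, frequency=setup.frequency,
        medium=setup.medium, alpha=setup.alpha, volume=vol, source_mask=mask,
        k_source=setup.k_source, axis_indices=(ix, iy),
    )


def steady_state_change(result: PistonResult, extra_periods: int = 30
                        ) -> float:
    """Percent change of the on-axis field when a run is extended.

    Continues the (kept) simulation of ``result`` by ``extra_periods``
    periods and returns 100·max|ΔA|/max(A) over the axis — the steady-state
    criterion compares 60- against 90-period runs.
    """
    sim = result.simulation
    if sim is None:
        raise ValueError("run_piston_case(..., keep_simulation=True) required")
    sim.run(n_periods=extra_periods, project_periods=2)
    _, prof2 = _axis_profile(result.setup, sim, sim.phasor_field.amplitude)
    return float(100.0 * np.max(np.abs(prof2 - result.p_fdtd))
                 / np.max(prof2))


# ---------------------------------------------------------------------------
# Skull-phantom focusing study
# ---------------------------------------------------------------------------


@dataclass
class FocusScenario:
    """Desk-scale transcranial focusing setup on a spherical-shell phantom."""

    volume: MaterialVolume
    array: TransducerArray
    element_voxels: list[np.ndarray]
    element_center_voxels: np.ndarray
    target: np.ndarray  # m
    target_index: tuple[int, int, int]
    frequency: float
    p_element: float
    P_total: float
    bone_label: int
    c_water: float
    c_bone: float
    seed: int


def make_focus_scenario(
    frequency: float = 500e3,
    array_radius: float = 16e-3,
    n_elements: int = 96,
    element_area: float = 9e-6,
    shell_outer_radius: float = 8e-3,
    shell_thickness: float = 2.5e-3,
    thickness_perturbation: float = 0.5,
    perturbation_max_freq: int = 1,
    target_offset=(1.5e-3, -1.0e-3, 1.0e-3),
    P_total: float = 1000.0,
    spacing: float | None = None,
    pml_layers: int = 16,
    seed: int = 0,
    no_skull: bool = False,
    water_only: bool = False,
) -> FocusScenario:
    """Assemble a scaled-down hemispherical-array + skull-shell scenario.

    The domain is a few wavelengths across (the anatomical-scale setup is
    not desk-computable); geometry is similar to the clinical arrangement:
    a water-filled hemispherical array opening toward +z, a perturbed
    spherical bone shell around the brain-like interior, and a target near
    the geometric focus.  Deterministic for a given ``seed``.
    """
    ac = acoustic_tissue_table()
    water, bone, brain = ac["Water"], ac["Bone"], ac["Brain"]
    if water_only:
        bone = brain = water
        no_skull = True
    lam = water.c / frequency
    if spacing is None:
        spacing = lam / 10.0

    margin = 2e-3
    half_xy = array_radius + margin
    z_lo, z_hi = -(array_radius + margin), 0.45 * array_radius
    pad = pml_layers * spacing
    nx = int(round(2 * (half_xy + pad) / spacing)) | 1  # odd: voxel at origin
    nz = int(round((z_hi - z_lo + 2 * pad) / spacing))
    origin = (-(nx - 1) / 2 * spacing, -(nx - 1) / 2 * spacing,
              z_lo - pad)

    phantom = make_skull_phantom(
        (nx, nx, nz), spacing,
        outer_radius=shell_outer_radius,
        thickness=0.0 if no_skull else shell_thickness,
        center=(0.0, 0.0, 0.0),
        skull_medium=bone, interior_medium=brain, exterior_medium=water,
        thickness_perturbation=thickness_perturbation,
        perturbation_max_freq=perturbation_max_freq,
        seed=seed, origin=origin,
    )
    vol = phantom.volume

    array = make_hemispherical_array(
        n_elements=n_elements, diameter=2 * array_radius,
        element_area=element_area, f=frequency, center=(0.0, 0.0, 0.0))
    element_voxels = voxelize_elements(array, vol)
    centers = np.array([vol.index_of(c) for c in array.centers])

    target = np.asarray(target_offset, float)
    target_index = vol.index_of(target)
    p_element = element_surface_pressure(P_total, n_elements, element_area)
    return FocusScenario(
        volume=vol, array=array, element_voxels=element_voxels,
        element_center_voxels=centers, target=target,
        target_index=target_index, frequency=frequency,
        p_element=p_element, P_total=P_total,
        bone_label=phantom.labels["Bone"], c_water=water.c, c_bone=bone.c,
        seed=seed,
    )


@dataclass
class StrategyResult:
    """Forward-run outcome of one aberration-correction strategy."""

    strategy: str
    drive: DriveVector
    amplitude_at_target: float
    metrics: FocalMetrics
    phasor_field: np.ndarray | None = field(repr=False, default=None)


def forward_run(
    scenario: FocusScenario,
    drive: DriveVector,
    n_periods: int = 35,
    dtype=np.float32,
    keep_field: bool = False,
) -> StrategyResult:
    """Drive the array with a steering vector and measure the focus."""
    sc = scenario
    sim = AcousticSimulation(sc.volume, sc.frequency, dtype=dtype)
    scale = sim.sheet_source_scale(
        2, tuple(sc.element_center_voxels[len(sc.element_center_voxels) // 2]))
    for e in range(sc.array.n_elements):
        if not drive.active[e] or drive.amplitudes[e] == 0:
            continue
        vox = sc.element_voxels[e]
        if len(vox) == 0:
            continue
        sim.add_source_voxels(
            vox, np.full(len(vox), drive.amplitudes[e] * scale),
            np.full(len(vox), drive.phases[e]))
    ph = sim.run_to_steady_state(n_periods=n_periods)
    amp = ph.amplitude
    interior = sim.interior_slices(margin=2)
    sub = np.zeros_like(amp)
    sub[interior] = amp[interior]
    m = focal_metrics(sub, sc.target_index, sc.volume.spacing)
    return StrategyResult(
        strategy="", drive=drive,
        amplitude_at_target=float(amp[sc.target_index]),
        metrics=m, phasor_field=ph.phasor if keep_field else None)


def compute_drive(scenario: FocusScenario, strategy: str,
                  captured: np.ndarray | None = None) -> DriveVector:
    """Steering vector for one of the four correction strategies."""
    sc = scenario
    if strategy == "dpc":
        return ab.dpc(sc.array, sc.target, sc.c_water, sc.p_element)
    if strategy == "rtpc":
        return ab.rtpc(sc.array, sc.target, sc.volume, sc.p_element,
                       sc.bone_label, sc.c_water, sc.c_bone)
    if captured is None:
        raise ValueError(f"strategy {strategy!r} needs captured phasors")
    if strategy == "spc":
        return ab.spc(captured, sc.p_element)
    if strategy == "spac":
        return ab.spac(captured, sc.P_total,
                       float(sc.array.areas[0]))
    raise ValueError(f"unknown strategy {strategy!r}")


def capture_phasors(scenario: FocusScenario, dtype=np.float32,
                    face_average: bool = True) -> np.ndarray:
    """Inverse propagation: point source at the target, record at elements.

    ``face_average`` averages the captured phasor over each element's voxel
    patch (the reciprocal counterpart of driving the whole face forward);
    otherwise the single surface-center voxel is sampled.
    """
    return inverse_propagate(
        scenario.volume, scenario.frequency, scenario.target_index,
        scenario.element_center_voxels, dtype=dtype,
        receiver_patches=scenario.element_voxels if face_average else None)


def run_focus_comparison(
    scenario: FocusScenario,
    strategies=("dpc", "rtpc", "spc", "spac"),
    n_periods: int = 35,
    dtype=np.float32,
) -> dict[str, StrategyResult]:
    """Inverse propagation plus one forward run per strategy."""
    captured = None
    if any(s in ("spc", "spac") for s in strategies):
        captured = capture_phasors(scenario, dtype=dtype)
    out = {}
    for s in strategies:
        drive = compute_drive(scenario, s, captured)
        res = forward_run(scenario, drive, n_periods=n_periods, dtype=dtype)
        res.strategy = s
        out[s] = res
    return out
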