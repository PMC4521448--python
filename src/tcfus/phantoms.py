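"""Synthetic simulation inputs: plane-interface setups, validation pistons,
water tanks, and spherical-shell skull phantoms.

All generators are pure functions of their parameters (and a seed where
perturbations are enabled).  Geometry is kept grid-aligned: oblique
incidence is realized by phase-ramped sheet sources rather than rotated
grids, so material interfaces never staircase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import snell_angle
from .media import AcousticMedium, MaterialVolume, ThermalMedium, build_material_volume

__all__ = [
    "InterfaceSetup",
    "PistonSetup",
    "SkullPhantom",
    "make_interface_setup",
    "make_piston_setup",
    "make_skull_phantom",
    "shell_chord_length",
]

#: lossy piston validation attenuation, Np m⁻¹ at 500 kHz
PISTON_LOSSY_ALPHA = 5.756
#: water-like validation medium of the piston cases
PISTON_MEDIUM = dict(c=1500.0, rho=1000.0)


# ---------------------------------------------------------------------------
# Plane-wave interface setups
# ---------------------------------------------------------------------------


@dataclass
class InterfaceSetup:
    """A plane interface normal to z with a tapered plane-wave source below.

    The domain is a thin slab (ny = 1) in the x–z plane of incidence; the
    interface lies exactly on a voxel-face plane between ``k_interface − 1``
    (medium A) and ``k_interface`` (medium B).
    """

    medium_A: AcousticMedium
    medium_B: AcousticMedium
    theta_i: float  # degrees
    frequency: float
    volume: MaterialVolume
    source_axis: int  # = 2
    source_index: int
    k_interface: int
    probe_A: tuple[int, int, int]
    probe_B: tuple[int, int, int]
    evanescent: bool

    @property
    def theta_t(self) -> float:
        return snell_angle(self.medium_A.c, self.medium_B.c, self.theta_i)


def make_interface_setup(
    cA: float,
    rhoA: float,
    cB: float,
    rhoB: float,
    theta_i: float,
    f: float,
    spacing: float | None = None,
    side_lambdas: float = 8.0,
    width_lambdas: float = 24.0,
    pml_layers: int = 16,
) -> InterfaceSetup:
    """Two-media slab domain for plane-wave reflection/transmission runs.

    The domain extends ``side_lambdas`` wavelengths (of medium A) on each
    side of the interface and ``width_lambdas`` across; default sampling is
    λ_A/15.  Incidence beyond the critical angle is flagged as evanescent.
    """
    if not 0.0 <= theta_i < 90.0:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    A = AcousticMedium(c=cA, rho=rhoA)
    B = AcousticMedium(c=cB, rho=rhoB)
    lam = cA / f
    if spacing is None:
        spacing = lam / 15.0
    evanescent = np.isnan(snell_angle(cA, cB, theta_i))

    side = side_lambdas * lam
    nz_side = int(round(side / spacing))
    nx = int(round(width_lambdas * lam / spacing)) + 2 * pml_layers
    nz = 2 * nz_side + 2 * pml_layers
    k_int = nz_side + pml_layers  # first voxel of medium B

    labels = np.zeros((nx, 1, nz), dtype=np.int16)
    labels[:, :, k_int:] = 1
    vol = build_material_volume(
        labels, spacing, {0: A, 1: B}, label_names={0: "A", 1: "B"}
    )
    k_src = pml_layers + 2
    probe_A = (nx // 2, 0, k_int - 2)
    probe_B = (nx // 2, 0, k_int + 1)
    return InterfaceSetup(
        medium_A=A, medium_B=B, theta_i=theta_i, frequency=f, volume=vol,
        source_axis=2, source_index=k_src, k_interface=k_int,
        probe_A=probe_A, probe_B=probe_B, evanescent=evanescent,
    )


# ---------------------------------------------------------------------------
# Piston validation setups
# ---------------------------------------------------------------------------


@dataclass
class PistonSetup:
    """A planar piston source in a homogeneous water-like tank."""

    kind: str  # circular | rectangular | ring
    dims: tuple[float, ...]
    frequency: float
    medium: AcousticMedium
    alpha: float  # attenuation at `frequency`, Np m⁻¹
    volume: MaterialVolume
    source_mask: np.ndarray  # area-coverage fractions over (nx, ny)
    k_source: int
    axis_indices: tuple[int, int]  # (ix, iy) of the beam axis


def piston_coverage_mask(kind: str, dims, x: np.ndarray, y: np.ndarray,
                         subsamples: int = 8) -> np.ndarray:
    """Sub-voxel area-coverage fractions of a piston face on a voxel grid.

    Each voxel is supersampled ``subsamples``² times; the returned mask
    holds the covered fraction in [0, 1].  Driving source voxels with these
    weights removes the staircase area bias of a boolean mask (up to ±2.4 %
    for the ring annulus at λ/10).
    """
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    cover = np.zeros((len(x), len(y)))
    for ox in off:
        for oy in off:
            xx, yy = np.meshgrid(x + ox * dx, y + oy * dy, indexing="ij")
            if kind == "circular":
                inside = xx**2 + yy**2 <= dims[0] ** 2
            elif kind == "rectangular":
                inside = (np.abs(xx) <= dims[0] / 2) & (np.abs(yy) <= dims[1] / 2)
            elif kind == "ring":
                rr = xx**2 + yy**2
                inside = (rr <= dims[1] ** 2) & (rr >= dims[0] ** 2)
            else:
                raise ValueError(f"unknown piston kind {kind!r}")
            cover += inside
    return cover / subsamples**2


def make_piston_setup(
    kind: str,
    dims=None,
    f: float = 500e3,
    lossy: bool = False,
    spacing: float | None = None,
    domain_mm: tuple[float, float, float] = (40.0, 40.0, 90.0),
    pml_layers: int = 16,
    pml_inside: bool = True,
) -> PistonSetup:
    """Water-tank domain with a planar piston on the z-min side.

    Default geometry replicates the validation protocol: a circular piston
    of 10 mm radius, a 20×20 mm rectangular piston, or a 7.5/10 mm planar
    ring, in a 40×40×90 mm water domain (c = 1500 m s⁻¹, ρ = 1000 kg m⁻³)
    at 500 kHz, lossless or with α = 5.756 Np m⁻¹.  ``pml_inside`` counts
    the 16 PML layers within the stated domain extents.
    """
    defaults = {
        "circular": (10e-3,),
        "rectangular": (20e-3, 20e-3),
        "ring": (7.5e-3, 10e-3),
    }
    if kind not in defaults:
        raise ValueError(f"unknown piston kind {kind!r}")
    dims = tuple(float(d) for d in (dims if dims is not None else defaults[kind]))
    if any(d <= 0 for d in dims) and not (kind == "ring" and dims[0] == 0):
        raise ValueError("piston dimensions must be positive")
    if kind == "ring" and dims[0] > dims[1]:
        raise ValueError("ring needs r_in <= r_out")

    med = AcousticMedium(**PISTON_MEDIUM)
    alpha = PISTON_LOSSY_ALPHA if lossy else 0.0
    if lossy:
        med = med.replace(a_per_f=alpha / (f / 1e6))
    lam = med.c / f
    if spacing is None:
        spacing = lam / 12.0

    pad = 0 if pml_inside else pml_layers
    nx = int(round(domain_mm[0] * 1e-3 / spacing)) + 2 * pad
    ny = int(round(domain_mm[1] * 1e-3 / spacing)) + 2 * pad
    nz = int(round(domain_mm[2] * 1e-3 / spacing)) + 2 * pad

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    vol = build_material_volume(labels, spacing, {0: med}, label_names={0: "Water"})

    k_src = pml_layers + 2
    ix, iy = nx // 2, ny // 2
    x = (np.arange(nx) - ix) * spacing
    y = (np.arange(ny) - iy) * spacing
    mask = piston_coverage_mask(kind, dims, x, y)
    return PistonSetup(
        kind=kind, dims=dims, frequency=f, medium=med, alpha=alpha,
        volume=vol, source_mask=mask, k_source=k_src, axis_indices=(ix, iy),
    )


# ---------------------------------------------------------------------------
# Spherical-shell skull phantom
# ---------------------------------------------------------------------------


@dataclass
class SkullPhantom:
    """Spherical bone shell between water (outside) and brain (inside)."""

    volume: MaterialVolume
    outer_radius: float
    thickness: float
    center: tuple[float, float, float]
    labels: dict[str, int]  # name -> label id


def _direction_perturbation(rng: np.random.Generator, n_modes: int = 6,
                            max_freq: int = 3):
    """Smooth random function of direction on the unit sphere, zero mean-ish.

    ``max_freq`` bounds the angular frequency of the modes; low values give
    the long-wavelength thickness variation characteristic of real skulls.
    """
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(0.5, 1.0, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    freqs = rng.integers(1, max_freq + 1, size=n_modes)

    def fn(nhat: np.ndarray) -> np.ndarray:
        acc = np.zeros(nhat.shape[:-1])
        for m in range(n_modes):
            acc += amps[m] * np.cos(freqs[m] * np.pi * (nhat @ dirs[m]) + phases[m])
        return acc / np.sum(amps)

    return fn


def make_skull_phantom(
    shape,
    spacing: float,
    outer_radius: float,
    thickness: float,
    center=None,
    skull_medium: AcousticMedium | None = None,
    interior_medium: AcousticMedium | None = None,
    exterior_medium: AcousticMedium | None = None,
    thermal_media: dict[str, ThermalMedium] | None = None,
    thickness_perturbation: float = 0.0,
    perturbation_max_freq: int = 3,
    seed: int | None = None,
    origin=None,
) -> SkullPhantom:
    """Three-region labeled volume: water exterior, bone shell, brain interior.

    The shell's outer surface is a sphere of ``outer_radius``; its local
    thickness is ``thickness·(1 + thickness_perturbation·g(n̂))`` where g is
    a smooth seeded random function of direction with values in [−1, 1].
    ``thickness = 0`` degenerates to a plain water/brain phantom.
    Deterministic under a fixed seed.
    """
    from .media import acoustic_tissue_table, thermal_tissue_table

    if not 0 <= thickness < outer_radius:
        raise ValueError("need 0 <= thickness < outer_radius")
    ac = acoustic_tissue_table()
    th = thermal_tissue_table()
    skull_medium = skull_medium or ac["Bone"]
    interior_medium = interior_medium or ac["Brain"]
    exterior_medium = exterior_medium or ac["Water"]
    thermal_media = thermal_media or {
        "Water": th["Water"], "Bone": th["Bone"], "Brain": th["Brain"]}

    shape = tuple(int(s) for s in shape)
    if origin is None:
        origin = tuple(-spacing * (s - 1) / 2 for s in shape)
    if center is None:
        center = (0.0, 0.0, 0.0)
    center = np.asarray(center, dtype=float)

    axes = [origin[ax] + spacing * np.arange(shape[ax]) for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    dx = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)
    r = np.linalg.norm(dx, axis=-1)
    if outer_radius > min(
        min(abs(axes[ax][0] - center[ax]), abs(axes[ax][-1] - center[ax]))
        for ax in range(3)
    ):
        raise ValueError("shell does not fit inside the domain")

    t_local = np.full(shape, float(thickness))
    if thickness_perturbation and thickness > 0:
        rng = np.random.default_rng(seed)
        g = _direction_perturbation(rng, max_freq=perturbation_max_freq)
        with np.errstate(invalid="ignore"):
            nhat = dx / np.where(r[..., None] == 0, 1.0, r[..., None])
        t_local = thickness * (1.0 + thickness_perturbation * g(nhat))
        t_local = np.clip(t_local, 0.0, outer_radius * 0.9)

    labels = np.zeros(shape, dtype=np.int16)  # 0 = water
    inside = r < outer_radius - t_local
    bone = (r <= outer_radius) & ~inside
    if thickness == 0:
        bone[:] = False
        inside = r <= outer_radius
    labels[bone] = 1
    labels[inside] = 2

    table = {
        0: (exterior_medium, thermal_media.get("Water")),
        1: (skull_medium, thermal_media.get("Bone")),
        2: (interior_medium, thermal_media.get("Brain")),
    }
    vol = build_material_volume(
        labels, spacing, table, origin=origin,
        label_names={0: "Water", 1: "Bone", 2: "Brain"},
    )
    return SkullPhantom(
        volume=vol, outer_radius=outer_radius, thickness=thickness,
        center=tuple(center), labels={"Water": 0, "Bone": 1, "Brain": 2},
    )


def shell_chord_length(
    p0: np.ndarray, p1: np.ndarray, center, outer_radius: float, thickness: float
) -> float:
    """Analytic length of segment p0→p1 inside a concentric spherical shell.

    Closed-form ray/sphere intersection; the reference oracle for ray-traced
    bone path lengths through an unperturbed shell.
    """
    center = np.asarray(center, dtype=float)

    def inside_len(radius: float) -> float:
        d = np.asarray(p1, float) - np.asarray(p0, float)
        L = np.linalg.norm(d)
        if L == 0:
            return 0.0
        u = d / L
        m = np.asarray(p0, float) - center
        b = m @ u
        disc = b * b - (m @ m - radius**2)
        if disc <= 0:
            return 0.0
        s = np.sqrt(disc)
        t0, t1 = np.clip([-b - s, -b + s], 0.0, L)
        return float(t1 - t0)

    return inside_len(outer_radius) - inside_len(outer_radius - thickness)
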