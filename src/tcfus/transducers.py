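"""Phased-array transducer geometry and element drive computation.

The hemispherical array model is an idealization of a 1024-element,
30 cm-diameter therapeutic array operating at 230 or 650 kHz: elements of
1 cm² are laid out quasi-uniformly on the hemisphere by Fibonacci-spiral
placement (the clinical grouping is proprietary), flat, tangent to the
sphere, and all focused at the sphere center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .media import MaterialVolume

__all__ = [
    "TransducerArray",
    "DriveVector",
    "make_hemispherical_array",
    "element_surface_pressure",
    "voxelize_elements",
    "Z_WATER",
]

#: characteristic impedance of water, kg m⁻² s⁻¹ (c = 1482.3, ρ = 1000)
Z_WATER = 1.4823e6


@dataclass
class TransducerArray:
    """Element geometry plus operating frequency.

    ``centers`` (N, 3) are element face centers, m; ``normals`` (N, 3) unit
    inward normals; ``areas`` (N,) face areas, m².
    """

    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    geometric_focus: np.ndarray
    frequency: float
    radius: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        self.areas = np.atleast_1d(np.asarray(self.areas, float))
        self.geometric_focus = np.asarray(self.geometric_focus, float)
        if not (len(self.centers) == len(self.normals) == len(self.areas)):
            raise ValueError("inconsistent element counts")
        if np.any(self.areas <= 0):
            raise ValueError("element areas must be positive")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit length")

    @property
    def n_elements(self) -> int:
        return len(self.centers)

    def focus_distances(self, target=None) -> np.ndarray:
        """Euclidean element-center → target distances, m."""
        tgt = self.geometric_focus if target is None else np.asarray(target, float)
        return np.linalg.norm(self.centers - tgt, axis=1)


@dataclass
class DriveVector:
    """Per-element drive state: amplitude (Pa), phase (rad), active mask."""

    amplitudes: np.ndarray
    phases: np.ndarray
    active: np.ndarray = None

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.phases = np.atleast_1d(np.asarray(self.phases, float))
        if self.active is None:
            self.active = np.ones(len(self.amplitudes), dtype=bool)
        self.active = np.atleast_1d(np.asarray(self.active, bool))
        if not (len(self.amplitudes) == len(self.phases) == len(self.active)):
            raise ValueError("inconsistent drive vector lengths")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.amplitudes)


def make_hemispherical_array(
    n_elements: int = 1024,
    diameter: float = 0.30,
    element_area: float = 1e-4,
    f: float = 230e3,
    center=(0.0, 0.0, 0.0),
    seed: int | None = None,
) -> TransducerArray:
    """Hemispherical array with Fibonacci-spiral element placement.

    The hemisphere opens toward +z: element centers lie on the sphere of
    radius ``diameter/2`` about ``center`` with z below the center, and the
    geometric focus is the sphere center.  A ``seed`` applies a random
    global azimuthal rotation (placement is otherwise deterministic).
    Raises if the requested elements cannot be packed without overlap.
    """
    R = diameter / 2.0
    cap_area = 2 * np.pi * R**2
    if n_elements * element_area > 0.9 * cap_area:
        raise ValueError(
            f"cannot pack {n_elements} elements of {element_area} m^2 "
            f"on a hemisphere of radius {R} m")

    i = np.arange(n_elements)
    # uniform in cos(polar): z/R in (−1, 0); the extra boundary offset
    # improves the worst-case (near-rim) spacing of the spiral lattice
    eps = 1.0
    zfrac = -(i + 0.5 + eps) / (n_elements + 2 * eps)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    if seed is not None:
        phi = phi + np.random.default_rng(seed).uniform(0, 2 * np.pi)
    rho = np.sqrt(1.0 - zfrac**2)
    centers = np.stack(
        [R * rho * np.cos(phi), R * rho * np.sin(phi), R * zfrac], axis=1
    ) + np.asarray(center, float)
    normals = (np.asarray(center, float) - centers)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return TransducerArray(
        centers=centers,
        normals=normals,
        areas=np.full(n_elements, element_area),
        geometric_focus=np.asarray(center, float),
        frequency=f,
        radius=R,
    )


def element_surface_pressure(
    P_total: float,
    N_elements: int,
    A_element: float,
    Z_water: float = Z_WATER,
) -> float:
    """Average element surface pressure for a given acoustic input power.

    p_element = √(P_total·Z_water/(N_elements·A_element)), Pa.  For 1000 W
    into 1024 elements of 1 cm² this evaluates to ≈ 120.31 kPa.
    """
    if P_total < 0:
        raise ValueError("acoustic power must be >= 0")
    if N_elements <= 0 or A_element <= 0 or Z_water <= 0:
        raise ValueError("element count, area and impedance must be positive")
    return float(np.sqrt(P_total * Z_water / (N_elements * A_element)))


def voxelize_elements(
    array: TransducerArray, volume: MaterialVolume
) -> list[np.ndarray]:
    """Map each element face to grid voxels; per-element sets are disjoint.

    A voxel belongs to an element when its center lies inside the tangent-
    plane slab of one-voxel L1 thickness (|d·n̂| ≤ Σᵢ|n̂ᵢ|hᵢ/2 — the thinnest
    slab that tiles the plane without holes at any orientation) and within
    the element radius of its center; contested voxels go to the nearest
    element.  The expected voxel count of an element of area A is
    A·Σᵢ|n̂ᵢ|hᵢ/(h₁h₂h₃).  Returns one (M_i, 3) integer index array per
    element; raises if any element center falls outside the grid.
    """
    spacing = np.asarray(volume.spacing)
    radii = np.sqrt(array.areas / np.pi)

    owner: dict[tuple[int, int, int], tuple[int, float]] = {}
    axes = volume.axes()
    for e in range(array.n_elements):
        c = array.centers[e]
        n = array.normals[e]
        r_e = radii[e]
        try:
            volume.index_of(c)
        except IndexError:
            raise ValueError(f"element {e} center outside the grid") from None
        lo, hi = [], []
        for ax in range(3):
            margin = r_e + spacing[ax]
            lo.append(np.searchsorted(axes[ax], c[ax] - margin))
            hi.append(np.searchsorted(axes[ax], c[ax] + margin) + 1)
        sub = np.meshgrid(
            *[np.arange(max(0, lo[ax]), min(volume.shape[ax], hi[ax]))
              for ax in range(3)],
            indexing="ij",
        )
        idx = np.stack([s.ravel() for s in sub], axis=1)
        pos = np.stack([axes[ax][idx[:, ax]] for ax in range(3)], axis=1)
        d = pos - c
        dn = d @ n
        half = 0.5 * float(np.abs(n) @ spacing)
        lat = np.linalg.norm(d - np.outer(dn, n), axis=1)
        keep = (np.abs(dn) <= half) & (lat <= r_e)
        for row, dist in zip(idx[keep], lat[keep]):
            key = tuple(int(v) for v in row)
            if key not in owner or dist < owner[key][1]:
                owner[key] = (e, float(dist))

    out: list[list] = [[] for _ in range(array.n_elements)]
    for key, (e, _d) in owner.items():
        out[e].append(key)
    return [
        np.array(sorted(v), dtype=np.int64).reshape(-1, 3) for v in out
    ]
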