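"""Acoustic and thermal material properties and labeled material volumes.

Materials are specified per tissue label.  Acoustic attenuation is stored as
a frequency slope ``a_per_f`` (Np m⁻¹ MHz⁻¹) and evaluated at the simulation
frequency with the linear law ``a(f) = a_per_f · f[MHz]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcousticMedium",
    "ThermalMedium",
    "BloodProperties",
    "MaterialVolume",
    "tissue_table",
    "acoustic_tissue_table",
    "thermal_tissue_table",
    "build_material_volume",
    "WATER",
    "BLOOD",
    "perfusion_mlminkg_to_si",
]


@dataclass(frozen=True)
class AcousticMedium:
    """Homogeneous acoustic material.

    Parameters
    ----------
    c : float
        Speed of sound, m s⁻¹.
    rho : float
        Mass density, kg m⁻³.
    a_per_f : float
        Attenuation coefficient slope, Np m⁻¹ MHz⁻¹.
    BoverA : float, optional
        Nonlinearity parameter B/A (dimensionless).  Only needed by the
        nonlinear solver; ``beta = 1 + B/(2A)``.
    alpha_abs : float, optional
        Absorption coefficient used for the sound diffusivity δ, Np m⁻¹ at
        the working frequency.  Defaults to the attenuation at that
        frequency when not given.
    """

    c: float
    rho: float
    a_per_f: float = 0.0
    BoverA: float | None = None
    alpha_abs: float | None = None

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"speed of sound must be positive, got {self.c}")
        if not self.rho > 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if self.a_per_f < 0:
            raise ValueError(f"attenuation slope must be >= 0, got {self.a_per_f}")

    @property
    def Z(self) -> float:
        """Characteristic acoustic impedance ρc, kg m⁻² s⁻¹ (Rayl)."""
        return self.rho * self.c

    def attenuation(self, f: float) -> float:
        """Attenuation coefficient a = a_per_f · f[MHz], Np m⁻¹, at ``f`` Hz."""
        return self.a_per_f * f / 1e6

    @property
    def beta(self) -> float:
        """Nonlinearity coefficient β = 1 + B/2A (0 when B/A unset)."""
        return 0.0 if self.BoverA is None else 1.0 + self.BoverA / 2.0

    def replace(self, **kw) -> "AcousticMedium":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ThermalMedium:
    """Homogeneous thermal material for the bioheat solver.

    ``omega`` is the blood perfusion rate in the mass-normalized form used by
    the bioheat sink term ρ_b·c_b·ρ·ω·(T − T_b), i.e. m³ kg⁻¹ s⁻¹.  Use
    :func:`perfusion_mlminkg_to_si` to convert the customary
    ml min⁻¹ kg⁻¹ figures.
    """

    C_heat: float  # specific heat capacity, J kg⁻¹ K⁻¹
    k_cond: float  # thermal conductivity, W m⁻¹ K⁻¹
    rho: float  # density, kg m⁻³
    Q_met: float = 0.0  # metabolic heat rate, W kg⁻¹
    omega: float = 0.0  # perfusion rate, m³ kg⁻¹ s⁻¹

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("density must be positive")
        for name in ("C_heat", "k_cond", "Q_met", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ThermalMedium":
        return dataclasses.replace(self, **kw)


def perfusion_mlminkg_to_si(w_mlminkg: float) -> float:
    """Convert perfusion from ml min⁻¹ kg⁻¹ to m³ kg⁻¹ s⁻¹."""
    return w_mlminkg * 1e-6 / 60.0


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood constants of the bioheat sink term."""

    rho_b: float = 1050.0  # kg m⁻³
    c_b: float = 3617.0  # J kg⁻¹ K⁻¹
    T_b: float = 37.0  # °C

    def __post_init__(self) -> None:
        if not (self.rho_b > 0 and self.c_b > 0):
            raise ValueError("blood density and heat capacity must be positive")


# ---------------------------------------------------------------------------
# Tissue property table
# ---------------------------------------------------------------------------
# Speed of sound c (m/s) and attenuation slope a/f (Np/m/MHz) for the tissues
# used in transcranial ultrasound runs.  Densities and thermal properties are
# representative values from the IT'IS Foundation tissue property database
# (https://itis.swiss/database); perfusion entries are given in
# ml min⁻¹ kg⁻¹ and converted.  Water/air use textbook values.

#: name -> (c, a_per_f, rho, C_heat, k_cond, Q_met [W/kg], perfusion [ml/min/kg])
_TISSUES: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "Air": (343.0, 0.04, 1.2, 1004.0, 0.026, 0.0, 0.0),
    "Blood": (1575.0, 1.7, 1050.0, 3617.0, 0.52, 0.0, 10000.0),
    "Bone": (3183.0, 164.0, 1908.0, 1313.0, 0.32, 0.15, 10.0),
    "Brain": (1565.0, 8.6, 1046.0, 3630.0, 0.51, 11.4, 559.0),
    "Eye (lens)": (1647.0, 9.0, 1076.0, 3133.0, 0.43, 0.0, 0.0),
    "Eye (aqueous humor)": (1537.0, 6.0, 1003.0, 4035.0, 0.58, 0.0, 0.0),
    "Eye (vitreous humor)": (1532.0, 5.0, 1005.0, 4047.0, 0.59, 0.0, 0.0),
    "Fat": (1478.0, 7.0, 911.0, 2348.0, 0.21, 0.51, 33.0),
    "Muscle": (1581.0, 11.0, 1090.0, 3421.0, 0.49, 0.96, 37.0),
    "Skin": (1720.0, 19.7, 1109.0, 3391.0, 0.37, 1.65, 106.0),
    "Tendon": (1750.0, 43.0, 1142.0, 3431.0, 0.47, 0.0, 0.0),
    "Water": (1482.3, 0.025, 1000.0, 4184.0, 0.60, 0.0, 0.0),
}

#: default B/A for water when the nonlinear solver is exercised; overridable.
WATER_B_OVER_A = 5.0


def acoustic_tissue_table(water_BoverA: float | None = None) -> dict[str, AcousticMedium]:
    """Acoustic media for all supported tissues plus water and air."""
    out = {}
    for name, (c, apf, rho, *_rest) in _TISSUES.items():
        bova = water_BoverA if (name == "Water" and water_BoverA is not None) else None
        out[name] = AcousticMedium(c=c, rho=rho, a_per_f=apf, BoverA=bova)
    return out


def thermal_tissue_table() -> dict[str, ThermalMedium]:
    """Thermal media for all supported tissues."""
    out = {}
    for name, (_c, _apf, rho, C, k, Q, w) in _TISSUES.items():
        out[name] = ThermalMedium(
            C_heat=C, k_cond=k, rho=rho, Q_met=Q, omega=perfusion_mlminkg_to_si(w)
        )
    return out


def tissue_table() -> dict[str, tuple[AcousticMedium, ThermalMedium]]:
    """Full (acoustic, thermal) property table keyed by tissue name.

    ``Air`` is included for completeness but is acoustically extreme
    (three-orders-of-magnitude density contrast); the acoustic solver treats
    air voxels as a pressure-release boundary by default.
    """
    ac = acoustic_tissue_table()
    th = thermal_tissue_table()
    return {name: (ac[name], th[name]) for name in _TISSUES}


WATER: AcousticMedium = acoustic_tissue_table()["Water"]
BLOOD = BloodProperties()


# ---------------------------------------------------------------------------
# Material volumes
# ---------------------------------------------------------------------------


@dataclass
class MaterialVolume:
    """Voxelized material map: 3D integer label grid plus a label table.

    ``spacing`` may be scalar-per-axis (uniform rectilinear) or per-axis
    coordinate steps; ``origin`` is the center of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_table: dict[int, tuple[AcousticMedium, ThermalMedium | None]]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        present = np.unique(self.labels)
        missing = [int(l) for l in present if int(l) not in self.label_table]
        if missing:
            raise KeyError(f"labels missing from label_table: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinate vectors, m."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax])
            for ax in range(3)
        )

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def _per_voxel(self, getter) -> np.ndarray:
        out = np.empty(self.shape, dtype=np.float64)
        for lab, pair in self.label_table.items():
            mask = self.labels == lab
            if mask.any():
                out[mask] = getter(pair)
        return out

    def density(self) -> np.ndarray:
        return self._per_voxel(lambda p: p[0].rho)

    def sound_speed(self) -> np.ndarray:
        return self._per_voxel(lambda p: p[0].c)

    def attenuation(self, f: float) -> np.ndarray:
        """Per-voxel attenuation coefficient at frequency ``f`` Hz, Np m⁻¹."""
        return self._per_voxel(lambda p: p[0].attenuation(f))

    def beta(self) -> np.ndarray:
        return self._per_voxel(lambda p: p[0].beta)

    def index_of(self, point) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point, m."""
        idx = []
        for ax in range(3):
            i = int(round((point[ax] - self.origin[ax]) / self.spacing[ax]))
            if not 0 <= i < self.shape[ax]:
                raise IndexError(f"point {point} outside volume on axis {ax}")
            idx.append(i)
        return tuple(idx)

    def point_of(self, index) -> np.ndarray:
        """Physical position (m) of a voxel index."""
        return np.array(
            [self.origin[ax] + self.spacing[ax] * index[ax] for ax in range(3)]
        )


def build_material_volume(
    labels: np.ndarray,
    spacing,
    label_table: dict[int, tuple[AcousticMedium, ThermalMedium | None]],
    origin=(0.0, 0.0, 0.0),
    label_names: dict[int, str] | None = None,
) -> MaterialVolume:
    """Validate and assemble a :class:`MaterialVolume`.

    Raises ``KeyError`` naming any grid label absent from ``label_table``.
    """
    labels = np.asarray(labels)
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    norm_table = {}
    for lab, entry in label_table.items():
        if isinstance(entry, AcousticMedium):
            entry = (entry, None)
        norm_table[int(lab)] = entry
    return MaterialVolume(
        labels=labels,
        spacing=spacing,
        label_table=norm_table,
        origin=tuple(float(o) for o in origin),
        label_names=dict(label_names or {}),
    )


def uniform_volume(
    shape,
    spacing,
    medium: AcousticMedium,
    thermal: ThermalMedium | None = None,
    origin=(0.0, 0.0, 0.0),
) -> MaterialVolume:
    """Single-material volume (e.g. a water tank)."""
    labels = np.zeros(shape, dtype=np.int16)
    return build_material_volume(labels, spacing, {0: (medium, thermal)}, origin)
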