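"""Analytic references and field-analysis metrics.

Contains the plane-interface reflection/transmission references (impedance
formulas plus Snell's law), the normalized-standard-deviation field
comparison metric, baffled-piston near-field references (closed form on axis
for the circular piston, Rayleigh–Sommerfeld integral otherwise), and the
thresholded connected-component focal/lesion metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .media import AcousticMedium

__all__ = [
    "CoefficientPair",
    "FocalMetrics",
    "analytic_coefficients",
    "snell_angle",
    "measure_coefficients",
    "nsd",
    "on_axis_piston_reference",
    "rayleigh_axis_reference",
    "focal_metrics",
]


# ---------------------------------------------------------------------------
# Plane-interface reflection and transmission
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoefficientPair:
    """Pressure reflection/transmission amplitude ratios at a plane interface."""

    R: float
    T: float
    theta_t: float  # transmission angle, degrees (NaN when evanescent)
    evanescent: bool = False


def snell_angle(cA: float, cB: float, theta_i: float) -> float:
    """Transmission angle (degrees) from Snell's law; NaN beyond critical."""
    s = np.sin(np.deg2rad(theta_i)) * cB / cA
    if abs(s) > 1.0:
        return float("nan")
    return float(np.rad2deg(np.arcsin(s)))


def analytic_coefficients(
    medium_A: AcousticMedium, medium_B: AcousticMedium, theta_i: float
) -> CoefficientPair:
    """Plane-wave pressure R and T at the A→B interface.

    R = (Z₂cosθᵢ − Z₁cosθₜ)/(Z₂cosθᵢ + Z₁cosθₜ),
    T = 2Z₂cosθᵢ/(Z₂cosθᵢ + Z₁cosθₜ), with θₜ from Snell's law.
    Beyond the critical angle the transmitted wave is evanescent and the
    pair is flagged (|R| = 1 in magnitude; T reported as NaN).
    """
    if not 0.0 <= theta_i < 90.0:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    Z1, Z2 = medium_A.Z, medium_B.Z
    theta_t = snell_angle(medium_A.c, medium_B.c, theta_i)
    if np.isnan(theta_t):
        return CoefficientPair(R=1.0, T=float("nan"), theta_t=theta_t, evanescent=True)
    ci, ct = np.cos(np.deg2rad(theta_i)), np.cos(np.deg2rad(theta_t))
    den = Z2 * ci + Z1 * ct
    return CoefficientPair(
        R=float((Z2 * ci - Z1 * ct) / den), T=float(2 * Z2 * ci / den), theta_t=theta_t
    )


def measure_coefficients(
    p_incident: complex, p_reflected: complex, p_transmitted: complex
) -> CoefficientPair:
    """R and T from measured incident/reflected/transmitted phasors.

    Amplitude ratios are signed by relative phase: a reflected wave more
    than 90° out of phase with the incident wave counts as inverted
    (negative R), matching the sign convention of the analytic formulas.
    """
    if abs(p_incident) == 0:
        raise ValueError("incident amplitude is zero")

    def signed_ratio(p: complex) -> float:
        r = p / p_incident
        return float(abs(r) if abs(np.angle(r)) <= np.pi / 2 else -abs(r))

    return CoefficientPair(
        R=signed_ratio(p_reflected),
        T=signed_ratio(p_transmitted),
        theta_t=float("nan"),
    )


# ---------------------------------------------------------------------------
# Field comparison
# ---------------------------------------------------------------------------


def nsd(p_test: np.ndarray, p_ref: np.ndarray) -> float:
    """Normalized standard deviation between two pressure profiles, percent.

    100 · ‖|p_test| − |p_ref|‖₂ / ‖|p_ref|‖₂, evaluated over identical
    sampling locations.
    """
    p_test = np.abs(np.asarray(p_test, dtype=float)).ravel()
    p_ref = np.abs(np.asarray(p_ref, dtype=float)).ravel()
    if p_test.shape != p_ref.shape:
        raise ValueError("profiles must share sampling locations")
    ref_norm = np.linalg.norm(p_ref)
    if ref_norm == 0:
        raise ValueError("reference profile has zero norm")
    return float(100.0 * np.linalg.norm(p_test - p_ref) / ref_norm)


# ---------------------------------------------------------------------------
# Baffled-piston references
# ---------------------------------------------------------------------------


def on_axis_piston_reference(
    z, radius: float, f: float, medium: AcousticMedium, p0: float
) -> np.ndarray:
    """On-axis |p| of a baffled circular piston in a lossless medium.

    Closed form |p(z)| = 2·p0·|sin(k(√(z²+a²) − z)/2)| with p0 = ρc·u0 the
    source-plane plane-wave pressure.
    """
    z = np.asarray(z, dtype=float)
    k = 2 * np.pi * f / medium.c
    return 2.0 * p0 * np.abs(np.sin(0.5 * k * (np.hypot(z, radius) - z)))


def _piston_patches(kind: str, dims, ds: float):
    """Quadrature patches (x, y, area) tiling a piston face."""
    if kind == "circular":
        (a,) = dims
        n = max(8, int(np.ceil(2 * a / ds)))
        x = (np.arange(n) - (n - 1) / 2) * (2 * a / n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        m = xx**2 + yy**2 <= a**2
        return xx[m], yy[m], (2 * a / n) ** 2
    if kind == "rectangular":
        lx, ly = dims
        nx = max(8, int(np.ceil(lx / ds)))
        ny = max(8, int(np.ceil(ly / ds)))
        x = (np.arange(nx) - (nx - 1) / 2) * (lx / nx)
        y = (np.arange(ny) - (ny - 1) / 2) * (ly / ny)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return xx.ravel(), yy.ravel(), (lx / nx) * (ly / ny)
    if kind == "ring":
        r_in, r_out = dims
        n = max(8, int(np.ceil(2 * r_out / ds)))
        x = (np.arange(n) - (n - 1) / 2) * (2 * r_out / n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        rr = xx**2 + yy**2
        m = (rr <= r_out**2) & (rr >= r_in**2)
        return xx[m], yy[m], (2 * r_out / n) ** 2
    raise ValueError(f"unknown piston kind {kind!r}")


def rayleigh_axis_reference(
    z,
    kind: str,
    dims,
    f: float,
    medium: AcousticMedium,
    p0: float,
    alpha: float = 0.0,
    ds: float | None = None,
) -> np.ndarray:
    """On-axis |p| of a baffled piston via the Rayleigh–Sommerfeld integral.

    p(z) = (p0·k)/(2πi) ∫ e^{i k̃ r}/r dS with complex wavenumber
    k̃ = k + iα for a homogeneous attenuating medium.  ``p0 = ρc·u0``.
    Supports ``circular`` (dims = (radius,)), ``rectangular``
    (dims = (lx, ly)) and ``ring`` (dims = (r_in, r_out)) faces.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = 2 * np.pi * f / medium.c
    if ds is None:
        ds = (medium.c / f) / 24.0
    sx, sy, dA = _piston_patches(kind, dims, ds)
    out = np.empty(z.shape, dtype=complex)
    kc = k + 1j * alpha
    for i, zi in enumerate(z):
        r = np.sqrt(sx**2 + sy**2 + zi**2)
        out[i] = np.sum(np.exp(1j * kc * r) / r) * dA
    return np.abs(out * p0 * k / (2j * np.pi))


# ---------------------------------------------------------------------------
# Focal / lesion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FocalMetrics:
    """Connected-component metrics of a focal spot or thermal lesion."""

    D: float  # distance target → component center, mm
    peak: float  # peak value in the component (Pa or °C)
    fwhm_xyz: tuple[float, float, float]  # component extent per axis, mm
    F_shape: float  # max/min extent ratio
    V: float  # component volume, mm³
    peak_index: tuple[int, int, int]  # voxel index of the selected maximum


def focal_metrics(
    field: np.ndarray,
    target_index,
    spacing,
    threshold_frac: float = 0.5,
    filter_size: int = 3,
) -> FocalMetrics:
    """Analyze the focal region nearest a target in a nonnegative 3D field.

    The field is box-filtered (``filter_size`` voxels), its local maxima are
    located, and the maximum nearest ``target_index`` is taken as the focal
    peak.  The filtered field is thresholded at ``threshold_frac`` of that
    peak and the 26-connected component containing it is measured: distance
    D from the target to the component centroid, per-axis bounding extents
    (FWHM at the default 50 % threshold), shape factor (max/min extent), and
    volume as the sum of member voxel volumes.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 3:
        raise ValueError("field must be 3D")
    if not np.any(field > 0):
        raise ValueError("field is empty (no positive values)")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = np.asarray(spacing, dtype=float)

    smooth = ndimage.uniform_filter(field, size=filter_size, mode="nearest")
    footprint = np.ones((3, 3, 3), bool)
    is_max = (smooth == ndimage.maximum_filter(smooth, footprint=footprint)) & (
        smooth > 0
    )
    maxima = np.argwhere(is_max)
    target = np.asarray(target_index, dtype=float)
    d2 = np.sum(((maxima - target) * spacing) ** 2, axis=1)
    peak_idx = tuple(int(v) for v in maxima[np.argmin(d2)])

    peak_val = smooth[peak_idx]
    mask = smooth >= threshold_frac * peak_val
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    comp = labels == labels[peak_idx]

    idx = np.argwhere(comp)
    centroid = idx.mean(axis=0)
    D_mm = float(np.linalg.norm((centroid - target) * spacing) * 1e3)
    extents = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing * 1e3
    V_mm3 = float(idx.shape[0] * np.prod(spacing) * 1e9)
    return FocalMetrics(
        D=D_mm,
        peak=float(field[comp].max()),
        fwhm_xyz=tuple(float(e) for e in extents),
        F_shape=float(extents.max() / extents.min()),
        V=V_mm3,
        peak_index=peak_idx,
    )
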