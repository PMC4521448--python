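"""Derived per-material coefficients of the wave-equation solvers."""

from __future__ import annotations

import numpy as np

__all__ = [
    "effective_attenuation",
    "sound_diffusivity",
    "nonlinearity_coefficient",
    "cfl_timestep",
]


def effective_attenuation(a, c, f):
    """Effective first-order damping coefficient ã, s⁻¹.

    ã = 2a·√(a²c⁴/(4π²f²) + c²) for attenuation ``a`` (Np m⁻¹) at frequency
    ``f`` (Hz).  With this choice the damped wave equation's plane-wave
    dispersion relation yields a spatial decay rate of exactly ``a`` at the
    working frequency; in the weak-attenuation limit ã → 2ac.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if f <= 0:
        raise ValueError("frequency must be positive")
    if np.any(a < 0) or np.any(c <= 0):
        raise ValueError("need a >= 0 and c > 0")
    w2 = (2.0 * np.pi * f) ** 2
    out = 2.0 * a * np.sqrt(a**2 * c**4 / w2 + c**2)
    return float(out) if out.ndim == 0 else out


def sound_diffusivity(alpha, c, f):
    """Sound diffusivity δ = 2αc³/(4π²f²), m² s⁻¹.

    ``alpha`` is the absorption coefficient (Np m⁻¹) at frequency ``f``; a
    thermoviscous fluid with this δ attenuates a plane wave at rate α.
    """
    alpha = np.asarray(alpha, dtype=float)
    c = np.asarray(c, dtype=float)
    out = 2.0 * alpha * c**3 / ((2.0 * np.pi * f) ** 2)
    return float(out) if out.ndim == 0 else out


def nonlinearity_coefficient(BoverA):
    """β = 1 + B/2A."""
    return 1.0 + np.asarray(BoverA, dtype=float) / 2.0


def cfl_timestep(min_spacing: float, c_max: float, safety: float = 0.95,
                 ndim: int = 3) -> float:
    """Largest stable explicit time step, dt = safety·Δmin/(c_max·√ndim).

    Isotropic form of the stability bound; for grids with different
    per-axis steps :func:`cfl_timestep_anisotropic` is sharper.
    """
    if not (0 < safety <= 1):
        raise ValueError("safety must be in (0, 1]")
    return safety * min_spacing / (c_max * np.sqrt(ndim))


def cfl_timestep_anisotropic(min_steps, c_max: float,
                             safety: float = 0.95) -> float:
    """Stability bound c·dt·√(Σᵢ 1/Δᵢ²) ≤ 1 for per-axis minimum steps.

    ``min_steps`` lists the smallest grid step of each active axis;
    reduces to the isotropic formula when all steps are equal.
    """
    if not (0 < safety <= 1):
        raise ValueError("safety must be in (0, 1]")
    min_steps = np.asarray(min_steps, dtype=float)
    if np.any(min_steps <= 0):
        raise ValueError("grid steps must be positive")
    return safety / (c_max * np.sqrt(np.sum(1.0 / min_steps**2)))
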