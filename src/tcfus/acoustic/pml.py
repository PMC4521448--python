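"""Convolutional perfectly-matched-layer (CPML) absorbing boundaries.

Stretched-coordinate PML for the second-order pressure wave equation: each
spatial derivative ∂/∂x inside the absorbing layer is replaced by
(1/κ)∂/∂x + ψ, where the memory variable ψ obeys the recursive
convolution ψⁿ⁺¹ = b·ψⁿ + a·(∂p/∂x)ⁿ⁺¹ with b = exp(−σ·dt).  The damping
profile σ is graded polynomially from zero at the inner PML edge to a
maximum at the outer boundary chosen for a theoretical normal-incidence
reflection ``target_reflection``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cpml_profiles"]


def _sigma_max(n_layers: int, spacing: float, c_ref: float, order: int,
               target_reflection: float) -> float:
    L = n_layers * spacing
    return -(order + 1) * c_ref * np.log(target_reflection) / (2.0 * L)


def cpml_profiles(
    n: int,
    coords: np.ndarray,
    n_layers: int,
    dt: float,
    c_ref: float,
    order: int = 3,
    target_reflection: float = 1e-4,
):
    """Per-axis CPML recursion coefficients at cell centers and faces.

    Returns ``(b_face, a_face, b_center, a_center)``; faces are the n−1
    midpoints between consecutive coordinates.  Outside the PML, b = 1 and
    a = 0 so the memory variables stay identically zero there.  Axes too
    short to host the layers (or with ``n_layers`` = 0) come back as
    pass-through profiles, which turns the boundary into a reflecting wall.
    """
    coords = np.asarray(coords, dtype=float)
    faces = 0.5 * (coords[1:] + coords[:-1]) if n > 1 else np.empty(0)

    def coeffs(pos: np.ndarray):
        b = np.ones_like(pos)
        a = np.zeros_like(pos)
        if n_layers <= 0 or n < 2 * n_layers + 4:
            return b, a
        # inner PML edges (positions of the first non-PML cell centers)
        x_lo = coords[n_layers]
        x_hi = coords[n - 1 - n_layers]
        spacing_lo = coords[1] - coords[0]
        spacing_hi = coords[-1] - coords[-2]
        for side, (edge, sp) in enumerate([(x_lo, spacing_lo), (x_hi, spacing_hi)]):
            L = n_layers * sp
            sig_max = _sigma_max(n_layers, sp, c_ref, order, target_reflection)
            depth = (edge - pos) if side == 0 else (pos - edge)
            m = depth > 0
            sigma = sig_max * np.clip(depth[m] / L, 0.0, 1.0) ** order
            b[m] = np.exp(-sigma * dt)
            a[m] = b[m] - 1.0
        return b, a

    b_f, a_f = coeffs(faces)
    b_c, a_c = coeffs(coords)
    return b_f, a_f, b_c, a_c
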