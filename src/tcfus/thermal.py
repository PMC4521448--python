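"""Pennes bioheat solver coupled to steady-state acoustic fields.

Integrates ρC·∂T/∂t = ∇·(k∇T) + ρQ + ρS − ρ_b·c_b·ρ·ω·(T − T_b) with an
explicit conservative finite-difference scheme (harmonic-mean face
conductivities), three boundary-condition types at tissue interfaces
(Dirichlet, Neumann, convective), optional temperature-dependent perfusion
shutdown, and the two-phase treatment protocol (cooling equilibration
followed by a short sonication).

The acoustic coupling term is the time-averaged relaxation-absorption heat
rate S = a·p²/(ρc) computed from a steady-state pressure-amplitude field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .media import BLOOD, BloodProperties, MaterialVolume

__all__ = [
    "ThermalState",
    "BoundarySpec",
    "PerfusionModel",
    "perfusion_factor",
    "acoustic_heat_source",
    "BioheatSimulation",
    "run_treatment_protocol",
]


@dataclass
class ThermalState:
    """Temperature grid (°C) at simulated time t (s)."""

    T: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary condition at the faces between two tissue labels.

    ``kind``:

    * ``dirichlet`` — the ``outside_label`` region is pinned at
      ``T_boundary`` and conducts normally (fixed interface temperature).
    * ``neumann`` — faces to ``outside_label`` receive the fixed inward
      flux ``F_boundary`` (W m⁻²); the outside region is excluded.
    * ``convective`` — faces receive h·(T_outside − T) + F_boundary; the
      outside region is excluded.
    """

    inside_label: int
    outside_label: int
    kind: str
    T_boundary: float | None = None
    F_boundary: float = 0.0
    h: float | None = None
    T_outside: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("dirichlet", "neumann", "convective"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "dirichlet" and self.T_boundary is None:
            raise ValueError("dirichlet boundary needs T_boundary")
        if self.kind == "convective":
            if self.h is None or self.h < 0 or self.T_outside is None:
                raise ValueError("convective boundary needs h >= 0 and T_outside")


@dataclass(frozen=True)
class PerfusionModel:
    """Linear vascular-shutdown model.

    Perfusion is unchanged below ``shutdown_start`` (°C), decreases
    linearly, and ceases entirely at/above ``shutdown_end``.
    """

    shutdown_start: float = 50.0
    shutdown_end: float = 51.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.shutdown_start < self.shutdown_end:
            raise ValueError("need shutdown_start < shutdown_end")


def perfusion_factor(T, model: PerfusionModel):
    """Perfusion multiplier in [0, 1] for tissue temperature ``T`` (°C)."""
    T = np.asarray(T, dtype=float)
    if not model.enabled:
        out = np.ones_like(T)
    else:
        out = np.clip(
            (model.shutdown_end - T)
            / (model.shutdown_end - model.shutdown_start),
            0.0,
            1.0,
        )
    return float(out) if out.ndim == 0 else out


def acoustic_heat_source(phasor_amplitude, a, rho, c):
    """Specific relaxation-absorption heating rate S, W kg⁻¹.

    The time-averaged volumetric power deposited by a steady sound field of
    pressure amplitude p is ρS = a·p²/(ρc) (twice the attenuation times
    the plane-wave intensity p²/2ρc); this returns S = a·p²/(ρ²c) so that
    the ρS term of the bioheat equation carries that volumetric rate.
    ``a`` is the attenuation at the working frequency, Np m⁻¹.
    """
    p = np.asarray(phasor_amplitude, dtype=float)
    a = np.asarray(a, dtype=float)
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(rho <= 0) or np.any(c <= 0):
        raise ValueError("density and sound speed must be positive")
    out = a * p**2 / (rho**2 * c)
    return float(out) if out.ndim == 0 else out


_SHIFTS = [
    (0, +1), (0, -1), (1, +1), (1, -1), (2, +1), (2, -1),
]


def _shift_slices(axis: int, sign: int):
    """(center, neighbor) slice tuples for a one-voxel shift."""
    sl_c = [slice(None)] * 3
    sl_n = [slice(None)] * 3
    if sign > 0:
        sl_c[axis] = slice(0, -1)
        sl_n[axis] = slice(1, None)
    else:
        sl_c[axis] = slice(1, None)
        sl_n[axis] = slice(0, -1)
    return tuple(sl_c), tuple(sl_n)


class BioheatSimulation:
    """Explicit bioheat solver on a labeled material volume.

    Voxels of labels named in Dirichlet specs stay pinned; labels named as
    the outside of Neumann/convective specs are excluded from conduction
    (their faces carry the prescribed flux instead).  Temperatures outside
    [0, 150] °C abort the run.
    """

    T_MIN, T_MAX = 0.0, 150.0

    def __init__(
        self,
        volume: MaterialVolume,
        blood: BloodProperties = BLOOD,
        boundaries: tuple[BoundarySpec, ...] = (),
        perfusion: PerfusionModel | None = None,
        dt_safety: float = 0.9,
        T_initial: float = 37.0,
    ):
        self.volume = volume
        self.blood = blood
        self.boundaries = tuple(boundaries)
        self.perfusion = perfusion
        self.spacing = np.asarray(volume.spacing)

        def th(getter):
            return volume._per_voxel(lambda pair: getter(pair[1]))

        for lab, pair in volume.label_table.items():
            if pair[1] is None and (volume.labels == lab).any():
                raise ValueError(f"label {lab} has no thermal medium")
        self.rho = volume._per_voxel(lambda p: p[1].rho)
        self.C = th(lambda m: m.C_heat)
        self.k = th(lambda m: m.k_cond)
        self.Q = th(lambda m: m.Q_met)
        self.omega = th(lambda m: m.omega)

        labels = volume.labels
        self.pinned = np.zeros(volume.shape, dtype=bool)
        self.pin_values = np.zeros(volume.shape)
        self.excluded = np.zeros(volume.shape, dtype=bool)
        for bc in self.boundaries:
            region = labels == bc.outside_label
            if bc.kind == "dirichlet":
                self.pinned |= region
                self.pin_values[region] = bc.T_boundary
            else:
                self.excluded |= region

        # harmonic-mean face conductivities, zeroed at excluded faces
        self._faces = []
        k = np.where(self.excluded, 0.0, self.k)
        for axis in (0, 1, 2):
            if volume.shape[axis] < 2:
                self._faces.append(None)
                continue
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            k1, k2 = k[tuple(sl_lo)], k[tuple(sl_hi)]
            with np.errstate(divide="ignore", invalid="ignore"):
                kf = np.where(k1 + k2 > 0, 2.0 * k1 * k2 / (k1 + k2), 0.0)
            self._faces.append(kf)

        # per-face boundary-condition masks
        self._bc_faces = []  # (mask_center, axis, h, T_out, F)
        for bc in self.boundaries:
            if bc.kind == "dirichlet":
                continue
            for axis, sign in _SHIFTS:
                if volume.shape[axis] < 2:
                    continue
                sl_c, sl_n = _shift_slices(axis, sign)
                m = np.zeros(volume.shape, dtype=bool)
                m[sl_c] = (labels[sl_c] == bc.inside_label) & (
                    labels[sl_n] == bc.outside_label)
                if m.any():
                    h = bc.h if bc.kind == "convective" else 0.0
                    T_out = bc.T_outside if bc.kind == "convective" else 0.0
                    self._bc_faces.append(
                        (m, axis, float(h or 0.0), float(T_out or 0.0),
                         float(bc.F_boundary)))

        self.active = ~self.excluded & ~self.pinned
        rc = self.rho * self.C
        with np.errstate(divide="ignore"):
            # explicit-diffusion bound plus the perfusion relaxation rate
            rate = (2.0 * self.k * np.sum(1.0 / self.spacing**2)
                    + blood.rho_b * blood.c_b * self.rho * self.omega)
            per_voxel_dt = rc / np.maximum(rate, 1e-30)
        self.dt_stable = float(dt_safety * per_voxel_dt[self.active].min()) \
            if self.active.any() else np.inf
        self._inv_rc = np.where(self.active, 1.0 / rc, 0.0)

        T0 = np.full(volume.shape, float(T_initial))
        T0[self.pinned] = self.pin_values[self.pinned]
        self.state = ThermalState(T=T0, t=0.0)

    # ------------------------------------------------------------------

    def power_density(self, T: np.ndarray, S: np.ndarray | None) -> np.ndarray:
        """Volumetric net power, W m⁻³ (conduction + sources − perfusion)."""
        q = np.zeros(self.volume.shape)
        # conduction divergence
        for axis in (0, 1, 2):
            kf = self._faces[axis]
            if kf is None:
                continue
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
            flux = kf * (T[sl_hi] - T[sl_lo]) / self.spacing[axis]
            q[sl_lo] += flux / self.spacing[axis]
            q[sl_hi] -= flux / self.spacing[axis]
        # boundary-condition face fluxes (per face area / voxel depth)
        for m, axis, h, T_out, F in self._bc_faces:
            q[m] += (h * (T_out - T[m]) + F) / self.spacing[axis]
        # metabolic + acoustic sources
        q += self.rho * self.Q
        if S is not None:
            q += self.rho * S
        # perfusion heat sink
        w = self.omega
        if self.perfusion is not None:
            w = w * perfusion_factor(T, self.perfusion)
        q -= self.blood.rho_b * self.blood.c_b * self.rho * w \
            * (T - self.blood.T_b)
        return q

    def step(self, dt: float, S: np.ndarray | None = None) -> ThermalState:
        """One explicit update; ``dt`` must respect the stability bound."""
        if dt > self.dt_stable * 1.0001:
            raise ValueError(
                f"dt={dt:g}s exceeds the diffusion stability bound "
                f"{self.dt_stable:g}s")
        T = self.state.T
        T_new = T + dt * self._inv_rc * self.power_density(T, S)
        T_new[self.pinned] = self.pin_values[self.pinned]
        T_new[self.excluded] = T[self.excluded]
        lo, hi = float(T_new.min()), float(T_new.max())
        if not np.isfinite(hi) or hi > self.T_MAX or lo < self.T_MIN:
            raise FloatingPointError(
                f"temperature out of physical bounds [{lo:.1f}, {hi:.1f}] °C "
                f"at t={self.state.t + dt:.3f}s (instability?)")
        self.state = ThermalState(T=T_new, t=self.state.t + dt)
        return self.state

    def run(self, duration: float, S: np.ndarray | None = None,
            dt: float | None = None) -> ThermalState:
        """Advance ``duration`` seconds in stability-bounded steps."""
        if dt is None:
            dt = self.dt_stable
        n = max(int(np.ceil(duration / dt)), 1)
        dt = duration / n
        for _ in range(n):
            self.step(dt, S)
        return self.state


def run_treatment_protocol(
    volume: MaterialVolume,
    S: np.ndarray | None,
    boundaries: tuple[BoundarySpec, ...] = (),
    blood: BloodProperties = BLOOD,
    perfusion: PerfusionModel | None = None,
    equilibration: float = 30 * 60.0,
    sonication: float = 20.0,
    T_initial: float = 37.0,
) -> tuple[ThermalState, ThermalState]:
    """Cooling equilibration followed by sonication heating.

    Phase 1 runs ``equilibration`` seconds with no acoustic source so the
    tissue equilibrates against the boundary conditions (a water bolus at
    16 °C, air at 25 °C in the transcranial setup); phase 2 adds the
    acoustic heat source ``S`` for ``sonication`` seconds.  Returns the
    states at the end of each phase.
    """
    sim = BioheatSimulation(
        volume, blood=blood, boundaries=boundaries, perfusion=perfusion,
        T_initial=T_initial)
    eq = sim.run(equilibration, S=None)
    eq = ThermalState(T=eq.T.copy(), t=eq.t)
    post = sim.run(sonication, S=S)
    return eq, ThermalState(T=post.T.copy(), t=post.t)
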