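"""Implicit finite-volume solver for thin-layer diffusion cyclic voltammetry.

The oxidized probe concentration c(z, t) obeys Fick's second law
dc/dt = D d2c/dz2 on [0, L].  At the electrode (z = 0) the Butler-Volmer
condition sets the surface flux from the instantaneous overpotential; at
z = L the far field holds c = c_b; initially c = c_b everywhere.  The
Faradaic current is i(t) = F * ECSA * D * dc/dz|0 with the IUPAC sign
convention (anodic positive).

Only the oxidized species is integrated: the reduced species' surface
concentration is c_b - c|0, which assumes equal diffusivities and a closed
surface mass balance.  There is no capacitive (double-layer) current and no
uncompensated resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .core import (
    FARADAY,
    CVProtocol,
    InterfaceParams,
    RedoxCouple,
    SpatialGrid,
    waveform,
)

#: default geometric working-electrode area (mm^2), used only for current density
DEFAULT_A_G_MM2 = 12.56


class SingularSystemError(np.linalg.LinAlgError):
    """A zero pivot was met while eliminating the tridiagonal system."""


class NumericalFailureError(RuntimeError):
    """The concentration field became non-finite during time marching."""


def solve_tridiagonal(lower, diag, upper, rhs) -> np.ndarray:
    """Solve A x = rhs for tridiagonal A by the Thomas algorithm.

    ``diag`` and ``rhs`` have length n; ``lower`` and ``upper`` length n-1.
    O(n) work, no fill-in.  Raises :class:`SingularSystemError` on a zero
    pivot (the algorithm does not pivot, so diagonal dominance or positive
    definiteness is expected from the caller).
    """
    diag = np.ascontiguousarray(diag, dtype=float)
    rhs = np.ascontiguousarray(rhs, dtype=float)
    n = diag.shape[0]
    if n == 0:
        return np.empty(0)
    if n == 1:
        lower = np.empty(0)
        upper = np.empty(0)
    else:
        lower = np.ascontiguousarray(lower, dtype=float)
        upper = np.ascontiguousarray(upper, dtype=float)
        if lower.shape[0] != n - 1 or upper.shape[0] != n - 1:
            raise ValueError("lower/upper must have length n-1")
    if rhs.shape[0] != n:
        raise ValueError("rhs must have the same length as diag")
    x, ok = _kernels.thomas(lower, diag, upper, rhs)
    if not ok:
        raise SingularSystemError("zero pivot encountered; system is singular")
    return x


@dataclass(frozen=True)
class MassBalance:
    """Discrete species accounting of one simulation, per unit electrode area.

    ``delta_moles`` is the change of the spatially integrated concentration
    (trapezoidal, mol/cm^2); ``flux_integral`` is the time integral of the
    boundary fluxes D*dc/dz at z=L minus z=0 (mol/cm^2).  The two agree up
    to boundary-cell discretization.
    """

    delta_moles: float
    flux_integral: float

    @property
    def mismatch(self) -> float:
        return self.delta_moles - self.flux_integral


@dataclass
class CVTrace:
    """A voltammogram: sampled time, potential, signed current and cycle index.

    Current follows the IUPAC convention (anodic positive).  ``i_density``
    reports uA/mm^2 over the geometric area ``A_g_mm2``.
    """

    t: np.ndarray
    E: np.ndarray
    i: np.ndarray
    cycle: np.ndarray
    A_g_mm2: float = DEFAULT_A_G_MM2
    metadata: dict = field(default_factory=dict)
    balance: Optional[MassBalance] = None
    c_final: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.cycle = np.asarray(self.cycle, dtype=int)
        n = self.t.shape[0]
        if not (self.E.shape[0] == self.i.shape[0] == self.cycle.shape[0] == n):
            raise ValueError("t, E, i and cycle must have equal lengths")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cycle < 0):
            raise ValueError("cycle indices must be nonnegative")

    @property
    def i_density(self) -> np.ndarray:
        """Current density in uA/mm^2 over the geometric electrode area."""
        return self.i * 1e6 / self.A_g_mm2

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max()) + 1 if self.cycle.size else 0


def _recorded_samples(protocol: CVProtocol) -> tuple[int, int, float]:
    """Recorded samples per cycle, total, and the recorded time step."""
    per_half = int(round(protocol.span / protocol.E_step))
    if per_half < 2:
        raise ValueError("E_step too coarse for the potential window")
    per_cycle = 2 * per_half
    dt_rec = protocol.period / per_cycle
    return per_cycle, per_cycle * protocol.n_cycles, dt_rec


def simulate_cv(
    interface: InterfaceParams,
    couple: RedoxCouple,
    protocol: CVProtocol,
    grid: SpatialGrid,
    substeps_per_Estep: int = 10,
    A_g_mm2: float = DEFAULT_A_G_MM2,
) -> CVTrace:
    """Simulate one cyclic voltammogram.

    The field starts uniform at c_b.  Each recorded potential step
    (duration E_step / v) is subdivided into ``substeps_per_Estep``
    backward-Euler substeps; the Butler-Volmer exponentials are evaluated
    at the new-step potential with the surface concentration implicit, so
    every substep is a single tridiagonal solve.  Samples are returned at
    every recorded step, plus the t = 0 point.

    The current uses A = ECSA (the learnable area); the geometric area
    ``A_g_mm2`` only scales the reported current density.
    """
    if substeps_per_Estep < 1:
        raise ValueError("substeps_per_Estep must be >= 1")
    per_cycle, n_rec, dt_rec = _recorded_samples(protocol)
    dt = dt_rec / substeps_per_Estep

    t_rec = np.arange(n_rec + 1) * dt_rec
    # potentials at the end of every substep (new time level)
    t_sub = np.arange(1, n_rec * substeps_per_Estep + 1) * dt
    # guard the final point against floating overshoot of the duration check
    t_sub[-1] = min(t_sub[-1], protocol.duration)
    E_sub = waveform(protocol, t_sub)

    flux_rec, c, flux0, fluxL, ok = _kernels.march_cv(
        np.ascontiguousarray(E_sub),
        substeps_per_Estep,
        grid.n_points,
        dt,
        grid.dz,
        interface.D,
        interface.k0,
        interface.alpha,
        couple.f_thermal,
        couple.E_f0,
        couple.c_b,
    )
    if not ok:
        bad = int(np.argmax(np.isnan(flux0)))
        raise NumericalFailureError(
            f"non-finite concentration field at substep {bad} "
            f"(t = {t_sub[min(bad, t_sub.size - 1)]:.4g} s)"
        )

    # cathodic sweep must give negative current (IUPAC): i = -F * A * J_BV,
    # where J_BV = D dc/dz|0 is the Butler-Volmer surface flux of the scheme
    i = np.empty(n_rec + 1)
    i[0] = 0.0
    i[1:] = -FARADAY * interface.ECSA * flux_rec

    E = waveform(protocol, np.minimum(t_rec, protocol.duration))
    cycle = np.clip((np.arange(n_rec + 1) - 1) // per_cycle, 0, protocol.n_cycles - 1)

    delta = float(np.trapezoid(c - couple.c_b, dx=grid.dz))
    balance = MassBalance(
        delta_moles=delta,
        flux_integral=float(dt * np.sum(fluxL - flux0)),
    )
    meta = {
        "scan_rate_V_s": protocol.v,
        "c_b_mol_cm3": couple.c_b,
        "A_g_mm2": A_g_mm2,
        "D_cm2_s": interface.D,
        "k0_cm_s": interface.k0,
        "alpha": interface.alpha,
        "ECSA_cm2": interface.ECSA,
    }
    return CVTrace(
        t=t_rec, E=E, i=i, cycle=cycle, A_g_mm2=A_g_mm2, metadata=meta,
        balance=balance, c_final=c,
    )
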