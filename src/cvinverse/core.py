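"""Domain types and geometric primitives for cyclic-voltammetry modelling.

All quantities use SI-with-cm units internally: current in A, potential in
V, time in s, length in cm, concentration in mol/cm^3.  Unit conversions
(mM, uA/mm^2, ...) happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Faraday constant (A s / mol).
FARADAY = 96485.0
#: Universal gas constant (J / mol / K).
GAS_CONSTANT = 8.314


class ConfigurationError(ValueError):
    """Raised when a domain object is constructed with invalid values."""


@dataclass(frozen=True)
class RedoxCouple:
    """A single-electron outer-sphere redox probe (e.g. [Ru(NH3)6]3+/2+).

    Parameters
    ----------
    c_b : float
        Bulk concentration of the oxidized species (mol/cm^3).
    E_f0 : float
        Formal potential of the couple vs the reference electrode (V).
    T : float
        Temperature (K).
    """

    c_b: float
    E_f0: float
    T: float = 298.0
    n_electrons: int = 1

    def __post_init__(self) -> None:
        if self.c_b < 0:
            raise ConfigurationError(f"bulk concentration must be >= 0, got {self.c_b}")
        if self.T <= 0:
            raise ConfigurationError(f"temperature must be > 0 K, got {self.T}")
        if self.n_electrons != 1:
            raise ConfigurationError("only single-electron transfer is modelled")

    @property
    def f_thermal(self) -> float:
        """F/(RT), the inverse thermal voltage (1/V)."""
        return FARADAY / (GAS_CONSTANT * self.T)


@dataclass(frozen=True)
class InterfaceParams:
    """The four learnable electrode-interface parameters.

    D : apparent diffusion coefficient of the probe (cm^2/s)
    k0 : standard heterogeneous rate constant (cm/s)
    alpha : charge-transfer coefficient (dimensionless, in (0, 1))
    ECSA : electrochemically active surface area (cm^2)
    """

    D: float
    k0: float
    alpha: float
    ECSA: float

    def __post_init__(self) -> None:
        for name in ("D", "k0", "ECSA"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.k0, self.alpha, self.ECSA])

    @staticmethod
    def names() -> tuple[str, str, str, str]:
        return ("D", "k0", "alpha", "ECSA")


@dataclass(frozen=True)
class CVProtocol:
    """Triangular potential program of a cyclic-voltammetry experiment.

    The potential starts at ``E_start`` and sweeps linearly at scan rate
    ``v`` in ``initial_direction``, reflecting at the window limits
    ``E_L`` (lower) and ``E_R`` (upper).  ``E_step`` is the recorded
    potential increment of the instrument.
    """

    E_start: float = 0.1
    E_L: float = -0.6
    E_R: float = 0.1
    v: float = 0.1
    E_step: float = 0.010
    n_cycles: int = 1
    initial_direction: str = "negative"

    def __post_init__(self) -> None:
        if not self.E_L < self.E_R:
            raise ConfigurationError("require E_L < E_R")
        if not (self.E_L <= self.E_start <= self.E_R):
            raise ConfigurationError("E_start must lie within [E_L, E_R]")
        if self.v <= 0:
            raise ConfigurationError("scan rate must be positive")
        if self.E_step <= 0:
            raise ConfigurationError("potential step must be positive")
        if self.n_cycles < 1:
            raise ConfigurationError("need at least one cycle")
        if self.initial_direction not in ("negative", "positive"):
            raise ConfigurationError("initial_direction must be 'negative' or 'positive'")

    @property
    def span(self) -> float:
        """Width of the potential window (V)."""
        return self.E_R - self.E_L

    @property
    def period(self) -> float:
        """Duration of one full cycle (s)."""
        return 2.0 * self.span / self.v

    @property
    def duration(self) -> float:
        """Total duration of the protocol (s)."""
        return self.n_cycles * self.period


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D grid from the electrode surface (z=0) to z=L."""

    L: float
    n_points: int = 500
    dz: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ConfigurationError("domain length must be positive")
        if self.n_points < 3:
            raise ConfigurationError("grid needs at least 3 points")
        object.__setattr__(self, "dz", self.L / (self.n_points - 1))

    @property
    def z(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_points)


def waveform(protocol: CVProtocol, t):
    """Instantaneous applied potential E(t) of the triangular sweep.

    Accepts a scalar or array of times within ``[0, protocol.duration]``.
    The wave starts at ``E_start``, moves with slope ``-v`` (negative
    initial direction) or ``+v``, and reflects at ``E_L`` and ``E_R``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > protocol.duration + 1e-12):
        raise ValueError(
            f"time outside protocol duration [0, {protocol.duration:g}] s"
        )
    span = protocol.span
    sign = -1.0 if protocol.initial_direction == "negative" else 1.0
    # distance travelled along the potential axis, folded onto the triangle
    x = (protocol.E_start - protocol.E_L) + sign * protocol.v * t_arr
    y = np.mod(x, 2.0 * span)
    E = protocol.E_L + span - np.abs(span - y)
    return float(E) if np.isscalar(t) or t_arr.ndim == 0 else E


def domain_length(D: float, protocol: CVProtocol) -> float:
    """Maximum diffusion-domain length L = 6*sqrt(2*D*|E_R - E_L| / v).

    Six diffusion lengths of the full sweep keep the far-field boundary
    out of reach of the depletion layer for a semi-infinite electrode.
    """
    if D <= 0:
        raise ValueError(f"diffusion coefficient must be positive, got {D}")
    return 6.0 * math.sqrt(2.0 * D * protocol.span / protocol.v)


def make_grid(L: float, n_points: int = 500) -> SpatialGrid:
    """Build the uniform 500-node (by default) spatial grid on [0, L]."""
    return SpatialGrid(L=L, n_points=n_points)
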