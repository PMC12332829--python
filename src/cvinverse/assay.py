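"""Assay-level statistics: 4PL calibration, IUPAC detection limit, SNR and
Brown-Anson surface concentration.

The dose-response of the immunosensor (and of a reference ELISA) is the
four-parameter logistic

    y = d + (a - d) / (1 + (x / c)**b)

with asymptotes a and d, Hill slope b and inflection point (EC50) c.  The
limit of detection follows the IUPAC convention: 3.3 times the response
standard deviation of the lowest concentration group that differs
significantly from the reference group, converted to concentration units
through the local slope of the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import FARADAY, GAS_CONSTANT


class FitFailureError(RuntimeError):
    """Nonlinear regression failed to converge."""


class LODUndefinedError(RuntimeError):
    """No concentration group differs significantly from the reference."""


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic y = d + (a - d)/(1 + (x/c)^b)."""

    a: float
    b: float
    c: float
    d: float
    r2: float = np.nan

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection point c must be positive")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        y = self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)
        return float(y) if y.ndim == 0 else y

    def slope(self, x):
        """dy/dx of the logistic at concentration x."""
        x = np.asarray(x, dtype=float)
        r = (x / self.c) ** self.b
        s = -(self.a - self.d) * self.b * r / (x * (1.0 + r) ** 2)
        return float(s) if s.ndim == 0 else s

    def flipped(self) -> "FourPLParams":
        """The equivalent parametrization (d, -b, c, a) of the same curve.

        The 4PL is invariant under swapping the asymptote labels while
        negating the Hill slope; a self-started fit may return either
        orientation.  c (the EC50) is invariant.
        """
        return FourPLParams(a=self.d, b=-self.b, c=self.c, d=self.a, r2=self.r2)


@dataclass
class CalibrationData:
    """Replicate responses grouped by analyte concentration.

    ``concentrations`` are the distinct group levels (pg/mL, positive);
    ``responses`` is the list of replicate arrays, one per group.
    """

    concentrations: np.ndarray
    responses: list[np.ndarray]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = [np.asarray(r, dtype=float).ravel() for r in self.responses]
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be one-dimensional")
        if len(self.responses) != self.concentrations.shape[0]:
            raise ValueError("one replicate group per concentration required")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if any(r.size < 1 for r in self.responses):
            raise ValueError("every group needs at least one replicate")
        if not np.all(np.diff(self.concentrations) > 0):
            order = np.argsort(self.concentrations)
            self.concentrations = self.concentrations[order]
            self.responses = [self.responses[j] for j in order]

    @property
    def means(self) -> np.ndarray:
        return np.array([r.mean() for r in self.responses])

    @property
    def sds(self) -> np.ndarray:
        return np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in self.responses])


@dataclass(frozen=True)
class AssaySignals:
    """Reduction peak currents entering the signal-to-noise ratio."""

    I_target: float
    I_background: float
    I_interferent: tuple[float, ...]

    def __post_init__(self) -> None:
        interf = self.I_interferent
        if np.isscalar(interf):
            object.__setattr__(self, "I_interferent", (float(interf),))
        else:
            object.__setattr__(self, "I_interferent", tuple(float(v) for v in interf))
        if any(v == self.I_background for v in self.I_interferent):
            raise ZeroDivisionError(
                "interferent response equals the background; SNR undefined"
            )


def _fourpl_logc(logx, a, b, logc, d):
    # fit on a log-concentration axis for conditioning
    return d + (a - d) / (1.0 + np.exp(b * (logx - logc)))


def fit_4pl(data: CalibrationData, init: FourPLParams | None = None) -> FourPLParams:
    """Least-squares 4PL fit on the group mean responses.

    Self-starting values come from the responses at the concentration
    extremes (the two asymptotes), the concentration nearest the
    mid-response (c) and a logit-linearized slope regression (b).  The fit
    runs on the log-concentration axis internally; parameters are reported
    on the natural scale.  R^2 is computed on the group means.
    """
    x = data.concentrations
    y = data.means
    if np.unique(x).size < 4:
        raise ValueError("a 4-parameter fit needs at least 4 distinct concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.ptp(y) == 0:
        raise FitFailureError("flat responses: slope and asymptotes unidentifiable")

    if init is None:
        a0, d0 = y[0], y[-1]
        if a0 == d0:
            a0, d0 = y.min(), y.max()
        mid = 0.5 * (a0 + d0)
        c0 = float(x[np.argmin(np.abs(y - mid))])
        # logit linearization: log((a - y)/(y - d)) = b * (log x - log c)
        eps = 1e-9 * max(abs(a0 - d0), 1.0)
        z = (a0 - y + np.sign(a0 - d0) * eps) / (y - d0 + np.sign(a0 - d0) * eps)
        ok = z > 0
        if ok.sum() >= 2:
            slope, _ = np.polyfit(np.log(x[ok]), np.log(z[ok]), 1)
            b0 = float(slope) if np.isfinite(slope) and slope != 0 else 1.0
        else:
            b0 = 1.0
    else:
        a0, b0, c0, d0 = init.a, init.b, init.c, init.d

    logx = np.log(x)
    last_err: Exception | None = None
    for b_try in (b0, -b0, 1.0, -1.0):
        try:
            popt, _ = optimize.curve_fit(
                _fourpl_logc, logx, y,
                p0=(a0, b_try, np.log(c0), d0),
                maxfev=20000,
            )
            a, b, logc, d = popt
            break
        except RuntimeError as exc:
            last_err = exc
    else:
        raise FitFailureError(f"4PL regression did not converge: {last_err}")

    params = FourPLParams(a=float(a), b=float(b), c=float(np.exp(logc)), d=float(d))
    resid = y - params.predict(x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return FourPLParams(a=params.a, b=params.b, c=params.c, d=params.d, r2=r2)


def invert_4pl(params: FourPLParams, y: float) -> float:
    """Concentration at response y: x = c * ((a - d)/(y - d) - 1)^(1/b).

    ``y`` must lie strictly between the asymptotes a and d.
    """
    lo, hi = min(params.a, params.d), max(params.a, params.d)
    if not lo < y < hi:
        raise ValueError(f"response {y} outside the open range ({lo}, {hi})")
    ratio = (params.a - params.d) / (y - params.d) - 1.0
    return float(params.c * ratio ** (1.0 / params.b))


def lod_iupac(data: CalibrationData, params: FourPLParams,
              alpha: float = 0.05) -> float:
    """IUPAC limit of detection in concentration units.

    Scans concentration groups in ascending order and Welch-tests each
    against the lowest-concentration (reference) group, two-sided.  The
    first group with p < alpha supplies the response standard deviation;
    the LOD is 3.3 * SD / |local 4PL slope| at that concentration.
    """
    if len(data.responses) < 2:
        raise ValueError("need a reference group plus at least one test group")
    ref = data.responses[0]
    for conc, resp in zip(data.concentrations[1:], data.responses[1:]):
        if ref.size < 2 or resp.size < 2:
            continue
        _, p = stats.ttest_ind(resp, ref, equal_var=False)
        if np.isfinite(p) and p < alpha:
            if resp.size < 3:
                continue
            sd = float(resp.std(ddof=1))
            m = params.slope(conc)
            if m == 0 or not np.isfinite(m):
                raise ZeroDivisionError(
                    f"zero calibration slope at {conc} pg/mL; LOD undefined"
                )
            return 3.3 * sd / abs(m)
    raise LODUndefinedError(
        f"no concentration group significant at p < {alpha} vs the reference"
    )


@dataclass(frozen=True)
class SNRResult:
    per_interferent: tuple[float, ...]
    mean: float


def snr(signals: AssaySignals) -> SNRResult:
    """Signal-to-noise ratio of the assay:

        SNR = (I_target - I_background) / (I_interferent - I_background)

    evaluated per interferent, with the mean over interferents reported as
    the headline figure.
    """
    num = signals.I_target - signals.I_background
    ratios = tuple(num / (v - signals.I_background) for v in signals.I_interferent)
    return SNRResult(per_interferent=ratios, mean=float(np.mean(ratios)))


@dataclass(frozen=True)
class BrownAnsonResult:
    """Surface concentration with the unit interpretation made explicit."""

    gamma_nmol_cm2: float
    interpretation: str


def brown_anson_gamma(
    I_ox: float, v: float, ECSA: float, A_g_mm2: float, T: float = 298.0,
) -> BrownAnsonResult:
    """Brown-Anson surface concentration gamma = 4*R*T*I_ox/(A_g*F^2*v*ECSA).

    ``I_ox`` is the oxidation peak current density in uA/mm^2 (the form in
    which voltammograms are reported); it is converted to total current in
    A through the geometric area ``A_g_mm2`` before substitution, and A_g
    enters the denominator in cm^2.  The result is returned in nmol/cm^2
    together with a statement of this unit interpretation, because the
    formula's value is sensitive to which current/area reading is used.
    """
    if I_ox < 0 or v <= 0 or ECSA <= 0 or A_g_mm2 <= 0 or T <= 0:
        raise ValueError("all Brown-Anson inputs must be positive (I_ox >= 0)")
    i_total_A = I_ox * 1e-6 * A_g_mm2
    A_g_cm2 = A_g_mm2 / 100.0
    gamma_mol_cm2 = 4.0 * GAS_CONSTANT * T * i_total_A / (A_g_cm2 * FARADAY**2 * v * ECSA)
    return BrownAnsonResult(
        gamma_nmol_cm2=gamma_mol_cm2 * 1e9,
        interpretation=(
            "I_ox supplied as current density (uA/mm^2), converted to total "
            "current (A) via A_g; A_g in cm^2 in the denominator; gamma in "
            "nmol/cm^2"
        ),
    )
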