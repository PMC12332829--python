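"""Peak-feature extraction from voltammograms and relative-error objectives.

The inverse problem compares three scalar features of a cyclic
voltammogram: the oxidation peak current I_ox (maximum on the anodic
sweep), the reduction peak current I_red (minimum on the cathodic sweep,
negative by the sign convention) and the peak-to-peak separation
E_pp = |E_ox - E_red|.  Misfit is expressed as signed percent relative
errors 100*(exp - sim)/exp in each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import CVTrace


class FeatureExtractionError(RuntimeError):
    """No usable interior peak was found on a sweep."""


@dataclass(frozen=True)
class CVFeatures:
    """The three-feature summary of a voltammogram (plus peak potentials).

    ``units`` tags the current scale ('A' for total current, 'uA/mm2'
    for density); both sides of a comparison must use the same tag.
    """

    I_ox: float
    I_red: float
    E_pp: float
    E_ox: float = np.nan
    E_red: float = np.nan
    units: str = "A"

    def __post_init__(self) -> None:
        if self.E_pp < 0:
            raise ValueError("E_pp must be nonnegative")
        if not (self.I_ox > 0 >= self.I_red):
            raise ValueError(
                "expected I_ox > 0 >= I_red under the anodic-positive convention"
            )


@dataclass(frozen=True)
class ErrorVector:
    """Signed percent relative errors (experimental vs simulated)."""

    dI_ox: float
    dI_red: float
    dE_pp: float

    def magnitudes(self) -> np.ndarray:
        return np.abs(np.array([self.dI_ox, self.dI_red, self.dE_pp]))

    @property
    def norm(self) -> float:
        """Euclidean distance from the origin of the 3-D error space."""
        return float(np.sqrt(self.dI_ox**2 + self.dI_red**2 + self.dE_pp**2))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(window - 1 - pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def _parabolic_refine(x: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """Vertex of the parabola through three points around index j.

    Reduces the bias of estimating a smooth peak from coarsely sampled
    potentials; falls back to the raw sample on a degenerate triple.
    """
    y0, y1, y2 = y[j - 1], y[j], y[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return x[j], y[j]
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1.0:  # neighbours not bracketing a vertex
        return x[j], y[j]
    x_pk = x[j] + delta * (x[j + 1] - x[j - 1]) / 2.0
    y_pk = y1 - 0.25 * (y0 - y2) * delta
    return float(x_pk), float(y_pk)


def _sweep_peak(E, i, maximize: bool, refine: bool) -> tuple[float, float]:
    if E.size < 3:
        raise FeatureExtractionError("sweep too short for peak detection")
    j = int(np.argmax(i)) if maximize else int(np.argmin(i))
    if j == 0 or j == E.size - 1:
        kind = "maximum" if maximize else "minimum"
        raise FeatureExtractionError(
            f"no interior {kind} on the sweep (monotonic current)"
        )
    if refine:
        sgn = 1.0 if maximize else -1.0
        E_pk, y_pk = _parabolic_refine(E, sgn * i, j)
        return E_pk, sgn * y_pk
    return float(E[j]), float(i[j])


def extract_features(
    trace: CVTrace,
    smooth_window: int = 0,
    refine_peaks: bool = True,
    use_density: bool = False,
) -> CVFeatures:
    """Extract (I_ox, I_red, E_pp) from a voltammogram.

    Per cycle, the anodic sweep (dE/dt > 0) contributes the current maximum
    and the cathodic sweep (dE/dt < 0) the minimum; features are averaged
    across cycles (experimentally the mean of three cycles is reported).
    ``smooth_window`` applies a moving average (in samples) before the
    extremum search, for noisy measured data.  ``refine_peaks`` replaces
    each sampled extremum by the vertex of a parabola through its three
    surrounding samples, removing the potential-step quantization of the
    peak estimates.  ``use_density`` extracts from uA/mm^2 instead of A.
    """
    current = trace.i_density if use_density else trace.i
    current = _moving_average(np.asarray(current, dtype=float), smooth_window)
    E = trace.E
    dE = np.diff(E)
    # direction of the segment ending at each sample
    direction = np.concatenate([[dE[0] if dE.size else 0.0], dE])

    ox_i, red_i, ox_E, red_E = [], [], [], []
    for c in np.unique(trace.cycle):
        mask = trace.cycle == c
        Ec, ic, dc = E[mask], current[mask], direction[mask]
        anodic = dc > 0
        cathodic = dc < 0
        if anodic.sum() < 3 or cathodic.sum() < 3:
            raise FeatureExtractionError(f"cycle {c} lacks a full sweep pair")
        E_ox, I_ox = _sweep_peak(Ec[anodic], ic[anodic], maximize=True, refine=refine_peaks)
        E_red, I_red = _sweep_peak(Ec[cathodic], ic[cathodic], maximize=False, refine=refine_peaks)
        ox_i.append(I_ox)
        red_i.append(I_red)
        ox_E.append(E_ox)
        red_E.append(E_red)

    E_ox_m = float(np.mean(ox_E))
    E_red_m = float(np.mean(red_E))
    return CVFeatures(
        I_ox=float(np.mean(ox_i)),
        I_red=float(np.mean(red_i)),
        E_pp=abs(E_ox_m - E_red_m),
        E_ox=E_ox_m,
        E_red=E_red_m,
        units="uA/mm2" if use_density else "A",
    )


def write_features_csv(features: dict[str, CVFeatures], path) -> None:
    """Export labelled feature rows (interface label + the three features)."""
    import pandas as pd

    rows = [
        {"label": label, "I_ox": f.I_ox, "I_red": f.I_red, "E_pp": f.E_pp,
         "E_ox": f.E_ox, "E_red": f.E_red, "units": f.units}
        for label, f in features.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path) -> dict[str, CVFeatures]:
    """Import labelled feature rows written by :func:`write_features_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["label"])] = CVFeatures(
            I_ox=float(row["I_ox"]), I_red=float(row["I_red"]),
            E_pp=float(row["E_pp"]),
            E_ox=float(row.get("E_ox", np.nan)), E_red=float(row.get("E_red", np.nan)),
            units=str(row.get("units", "A")),
        )
    return out


def error_vector(exp: CVFeatures, sim: CVFeatures) -> ErrorVector:
    """Signed percent relative errors 100*(exp - sim)/exp, componentwise.

    All three components use the percent scale so the multi-objective
    search treats them commensurately.
    """
    pairs = (
        ("I_ox", exp.I_ox, sim.I_ox),
        ("I_red", exp.I_red, sim.I_red),
        ("E_pp", exp.E_pp, sim.E_pp),
    )
    out = []
    for name, e, s in pairs:
        if e == 0:
            raise ZeroDivisionError(f"experimental {name} is zero; relative error undefined")
        out.append(100.0 * (e - s) / e)
    return ErrorVector(*out)
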