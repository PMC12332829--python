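"""Voltammogram and configuration I/O, plus the synthetic-trace generator.

Voltammograms travel as delimited text (comma by default, tab tolerated)
with the header ``time_s,potential_V,current_A,cycle`` and optional
``# key: value`` metadata lines, because potentiostat exports vary and a
plain-text interchange format keeps the tool vendor-agnostic.  Run
configurations are YAML mirroring :class:`RunConfig`; unknown keys are
rejected so a typo never silently falls back to a default.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CVProtocol, InterfaceParams, RedoxCouple, SpatialGrid
from .inversion import GAConfig, ParameterBounds
from .solver import DEFAULT_A_G_MM2, CVTrace, simulate_cv

logger = logging.getLogger(__name__)

_COLUMNS = ("time_s", "potential_V", "current_A", "cycle")


class VoltammogramParseError(ValueError):
    """A voltammogram file failed validation; the message names the line."""


def write_voltammogram(trace: CVTrace, path) -> None:
    """Write a trace as delimited text with full numeric precision."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"# A_g_mm2: {trace.A_g_mm2!r}\n")
        fh.write(",".join(_COLUMNS) + "\n")
        for t, E, i, c in zip(trace.t, trace.E, trace.i, trace.cycle):
            fh.write(f"{float(t)!r},{float(E)!r},{float(i)!r},{int(c)}\n")


def read_voltammogram(path) -> CVTrace:
    """Read a delimited-text voltammogram (comma or tab separated).

    Metadata lines start with ``#``; the numeric table must provide the
    columns ``time_s, potential_V, current_A, cycle``.  Malformed cells
    raise :class:`VoltammogramParseError` naming the offending line.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    data_lines: list[str] = []
    line_numbers: list[int] = []
    with path.open("r") as fh:  # universal newlines: CRLF == LF
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            data_lines.append(line)
            line_numbers.append(ln)
    if not data_lines:
        raise VoltammogramParseError(f"{path}: no data rows found")

    sep = "\t" if "\t" in data_lines[0] else ","
    try:
        df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep=sep,
                         float_precision="round_trip")
    except Exception as exc:
        raise VoltammogramParseError(f"{path}: cannot parse table: {exc}") from exc

    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise VoltammogramParseError(
            f"{path} line {line_numbers[0]}: missing column(s) {', '.join(missing)}"
        )
    for col in _COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(numeric.to_numpy(dtype=float)))[0]
        if bad.size:
            row = int(bad[0])
            raise VoltammogramParseError(
                f"{path} line {line_numbers[row + 1]}: "
                f"non-numeric value {df[col].iloc[row]!r} in column {col}"
            )
        df[col] = numeric

    A_g = float(metadata.get("A_g_mm2", DEFAULT_A_G_MM2))
    return CVTrace(
        t=df["time_s"].to_numpy(),
        E=df["potential_V"].to_numpy(),
        i=df["current_A"].to_numpy(),
        cycle=df["cycle"].to_numpy(dtype=int),
        A_g_mm2=A_g,
        metadata=metadata,
    )


def generate_synthetic_cv(
    interface: InterfaceParams,
    couple: RedoxCouple,
    protocol: CVProtocol,
    grid: SpatialGrid,
    noise_sd: float = 0.0,
    seed: int | None = None,
    substeps_per_Estep: int = 10,
    A_g_mm2: float = DEFAULT_A_G_MM2,
) -> CVTrace:
    """Simulate a voltammogram and add i.i.d. Gaussian current noise.

    With ``noise_sd = 0`` the result is bitwise identical to
    :func:`cvinverse.solver.simulate_cv`.  The noise emulates instrument
    noise on the measured current only; potential and time are exact.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    trace = simulate_cv(interface, couple, protocol, grid, substeps_per_Estep, A_g_mm2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace.i = trace.i + rng.normal(0.0, noise_sd, size=trace.i.shape)
        trace.metadata["noise_sd_A"] = noise_sd
        trace.metadata["noise_seed"] = seed
    return trace


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Full description of one run: probe, protocol, grid, geometry, GA, noise."""

    couple: RedoxCouple
    protocol: CVProtocol
    n_points: int = 500
    substeps_per_Estep: int = 10
    A_g_mm2: float = DEFAULT_A_G_MM2
    ga: GAConfig = GAConfig()
    bounds: ParameterBounds = ParameterBounds()
    noise_sd_A: float = 0.0

    def to_dict(self) -> dict:
        return {
            "couple": {
                "c_b_mol_cm3": self.couple.c_b,
                "E_f0_V": self.couple.E_f0,
                "T_K": self.couple.T,
            },
            "protocol": {
                "E_start_V": self.protocol.E_start,
                "E_L_V": self.protocol.E_L,
                "E_R_V": self.protocol.E_R,
                "v_V_s": self.protocol.v,
                "E_step_V": self.protocol.E_step,
                "n_cycles": self.protocol.n_cycles,
                "initial_direction": self.protocol.initial_direction,
            },
            "grid": {"n_points": self.n_points},
            "geometry": {"A_g_mm2": self.A_g_mm2},
            "solver": {"substeps_per_Estep": self.substeps_per_Estep},
            "ga": {
                "population": self.ga.population,
                "generations": self.ga.generations,
                "crossover_prob": self.ga.crossover_prob,
                "mutation_prob": self.ga.mutation_prob,
                "eta_crossover": self.ga.eta_crossover,
                "eta_mutation": self.ga.eta_mutation,
                "seed": self.ga.seed,
                "n_repeats": self.ga.n_repeats,
                "log_scale": list(self.ga.log_scale),
            },
            "bounds": {
                "D": list(self.bounds.D),
                "k0": list(self.bounds.k0),
                "alpha": list(self.bounds.alpha),
                "ECSA": list(self.bounds.ECSA),
            },
            "noise": {"sd_A": self.noise_sd_A},
        }

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_config() -> RunConfig:
    """The reference measurement conditions: 10 mM probe, 100 mV/s,
    -0.6..+0.1 V window, 10 mV steps, 500-node grid, 12.56 mm^2 electrode."""
    return RunConfig(
        couple=RedoxCouple(c_b=1e-5, E_f0=-0.25, T=298.0),
        protocol=CVProtocol(),
    )


def _take(section: dict, path: str, keys: dict[str, str]) -> dict:
    """Map YAML keys to constructor kwargs, rejecting unknown keys."""
    unknown = set(section) - set(keys)
    if unknown:
        raise ValueError(f"unknown key(s) in {path}: {', '.join(sorted(unknown))}")
    return {dest: section[src] for src, dest in keys.items() if src in section}


def config_from_dict(data: dict) -> RunConfig:
    sections = {"couple", "protocol", "grid", "geometry", "solver", "ga", "bounds", "noise"}
    unknown = set(data) - sections
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {', '.join(sorted(unknown))}")
    base = default_config()

    couple_kw = _take(data.get("couple", {}), "couple",
                      {"c_b_mol_cm3": "c_b", "E_f0_V": "E_f0", "T_K": "T"})
    couple = RedoxCouple(**{**{"c_b": base.couple.c_b, "E_f0": base.couple.E_f0,
                               "T": base.couple.T}, **couple_kw})

    proto_kw = _take(data.get("protocol", {}), "protocol",
                     {"E_start_V": "E_start", "E_L_V": "E_L", "E_R_V": "E_R",
                      "v_V_s": "v", "E_step_V": "E_step", "n_cycles": "n_cycles",
                      "initial_direction": "initial_direction"})
    protocol = CVProtocol(**proto_kw)

    grid_kw = _take(data.get("grid", {}), "grid", {"n_points": "n_points"})
    geom_kw = _take(data.get("geometry", {}), "geometry", {"A_g_mm2": "A_g_mm2"})
    solver_kw = _take(data.get("solver", {}), "solver",
                      {"substeps_per_Estep": "substeps_per_Estep"})

    ga_section = dict(data.get("ga", {}))
    if "log_scale" in ga_section:
        ga_section["log_scale"] = tuple(bool(v) for v in ga_section["log_scale"])
    ga_kw = _take(ga_section, "ga",
                  {k: k for k in ("population", "generations", "crossover_prob",
                                  "mutation_prob", "eta_crossover", "eta_mutation",
                                  "seed", "n_repeats", "log_scale")})
    ga = GAConfig(**ga_kw)

    bounds_section = data.get("bounds", {})
    bounds_kw = _take(bounds_section, "bounds", {k: k for k in ("D", "k0", "alpha", "ECSA")})
    bounds = ParameterBounds(**{k: tuple(v) for k, v in bounds_kw.items()})

    noise_kw = _take(data.get("noise", {}), "noise", {"sd_A": "noise_sd_A"})

    return RunConfig(
        couple=couple,
        protocol=protocol,
        ga=ga,
        bounds=bounds,
        **grid_kw, **geom_kw, **solver_kw, **noise_kw,
    )


def load_config(path) -> RunConfig:
    with Path(path).open("r") as fh:
        data = yaml.safe_load(fh) or {}
    cfg = config_from_dict(data)
    logger.info("loaded config %s (hash %s)", path, cfg.config_hash)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def grid_for(cfg: RunConfig, D: float) -> SpatialGrid:
    """Grid sized by the domain-length rule for diffusion coefficient D."""
    from .core import domain_length, make_grid

    return make_grid(domain_length(D, cfg.protocol), cfg.n_points)
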