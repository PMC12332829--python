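"""Multi-objective genetic-algorithm estimation of interface parameters.

Given an experimental voltammogram, the inverse problem is

    min over (D, k0, alpha, ECSA) of [|dI_ox|, |dI_red|, |dE_pp|]
    subject to box bounds on each parameter,

where the three objectives are the percent relative errors between the
experimental peak features and those of a forward simulation at the
candidate parameters.  An elitist non-dominated-sorting GA (NSGA-II style:
binary tournament on rank and crowding distance, simulated binary
crossover, polynomial mutation) evolves the population; after convergence
the Pareto-front member closest to the origin of the 3-D error space is
the elitist solution.  The search is repeated (three times by default) and
the per-parameter median of the repeats' elitists is the headline estimate.

D, k0 and ECSA are searched on a log10 scale since plausible values span
decades; alpha is searched linearly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import CVProtocol, InterfaceParams, RedoxCouple, SpatialGrid
from .features import CVFeatures, ErrorVector, error_vector, extract_features
from .solver import CVTrace, simulate_cv

logger = logging.getLogger(__name__)

_PARAM_NAMES = InterfaceParams.names()


class ConvergenceFailureError(RuntimeError):
    """Every candidate in a generation failed the forward simulation."""


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds (lower, upper) for each of D, k0, alpha, ECSA."""

    D: tuple[float, float] = (1e-7, 1e-3)
    k0: tuple[float, float] = (1e-5, 1.0)
    alpha: tuple[float, float] = (0.3, 0.7)
    ECSA: tuple[float, float] = (0.01, 1.0)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
            if name != "alpha" and lo <= 0:
                raise ValueError(f"{name}: bounds must be positive")
        a_lo, a_hi = self.alpha
        if not (0.0 < a_lo and a_hi < 1.0):
            raise ValueError("alpha bounds must lie within (0, 1)")

    def lowers(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in _PARAM_NAMES])

    def uppers(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in _PARAM_NAMES])

    @classmethod
    def around(cls, truth: InterfaceParams, decades: float = 1.0,
               alpha_bounds: tuple[float, float] = (0.3, 0.7)) -> "ParameterBounds":
        """Bounds one decade (by default) either side of a reference point."""
        f = 10.0**decades
        return cls(
            D=(truth.D / f, truth.D * f),
            k0=(truth.k0 / f, truth.k0 * f),
            alpha=alpha_bounds,
            ECSA=(truth.ECSA / f, truth.ECSA * f),
        )


@dataclass(frozen=True)
class GAConfig:
    """Budget and operator settings of the genetic search."""

    population: int = 32
    generations: int = 40
    crossover_prob: float = 0.9
    mutation_prob: float = 0.25
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    seed: int = 0
    n_repeats: int = 3
    log_scale: tuple[bool, bool, bool, bool] = (True, True, False, True)

    def __post_init__(self) -> None:
        if self.population < 8:
            raise ValueError("population must be at least 8")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")


@dataclass
class InversionResult:
    """Outcome of the repeated GA inversion.

    ``estimate`` is the per-parameter median of the per-run elitists (the
    headline value); ``elitist`` is the single front member nearest the
    origin of the error space across all repeats; ``dispersion`` is the
    max relative deviation of the repeats from the median, per parameter.
    """

    estimate: InterfaceParams
    elitist: InterfaceParams
    elitist_errors: ErrorVector
    pareto_front: list[tuple[InterfaceParams, ErrorVector]]
    per_run_elitists: list[tuple[InterfaceParams, ErrorVector]]
    dispersion: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotype <-> parameters

def _decode(x: np.ndarray, bounds: ParameterBounds, log_scale) -> InterfaceParams:
    lo, hi = bounds.lowers(), bounds.uppers()
    vals = np.empty(4)
    for j in range(4):
        if log_scale[j]:
            lg_lo, lg_hi = math.log10(lo[j]), math.log10(hi[j])
            vals[j] = 10.0 ** (lg_lo + x[j] * (lg_hi - lg_lo))
        else:
            vals[j] = lo[j] + x[j] * (hi[j] - lo[j])
    # clip away floating fuzz so reported parameters respect bounds exactly
    vals = np.minimum(np.maximum(vals, lo), hi)
    return InterfaceParams(*vals)


# ---------------------------------------------------------------------------
# NSGA-II machinery

def _nondominated_rank(F: np.ndarray) -> np.ndarray:
    """Fast non-dominated sorting; returns the front index of each row."""
    n = F.shape[0]
    dominated_by = [[] for _ in range(n)]
    n_dom = np.zeros(n, dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            le_ab = np.all(F[a] <= F[b])
            le_ba = np.all(F[b] <= F[a])
            if le_ab and not le_ba:
                dominated_by[a].append(b)
                n_dom[b] += 1
            elif le_ba and not le_ab:
                dominated_by[b].append(a)
                n_dom[a] += 1
    rank = np.full(n, -1, dtype=int)
    current = [i for i in range(n) if n_dom[i] == 0]
    r = 0
    while current:
        nxt = []
        for i in current:
            rank[i] = r
            for j in dominated_by[i]:
                n_dom[j] -= 1
                if n_dom[j] == 0:
                    nxt.append(j)
        current = nxt
        r += 1
    return rank


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        span = fk[-1] - fk[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and np.isfinite(span):
            d[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return d


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = _nondominated_rank(F)
    crowd = np.zeros(F.shape[0])
    for r in np.unique(rank):
        idx = np.where(rank == r)[0]
        crowd[idx] = _crowding_distance(F[idx])
    return rank, crowd


def _tournament(rng, rank, crowd) -> int:
    a, b = rng.integers(0, rank.shape[0], size=2)
    if rank[a] != rank[b]:
        return a if rank[a] < rank[b] else b
    if crowd[a] != crowd[b]:
        return a if crowd[a] > crowd[b] else b
    return a


def _sbx_pair(rng, p1, p2, eta, prob):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for j in range(p1.shape[0]):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
        x1, x2 = p1[j], p2[j]
        c1[j] = 0.5 * ((1 + beta) * x1 + (1 - beta) * x2)
        c2[j] = 0.5 * ((1 - beta) * x1 + (1 + beta) * x2)
    return np.clip(c1, 0.0, 1.0), np.clip(c2, 0.0, 1.0)


def _polynomial_mutation(rng, x, eta, prob):
    y = x.copy()
    for j in range(x.shape[0]):
        if rng.random() > prob:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
        else:
            delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
        y[j] = min(max(y[j] + delta, 0.0), 1.0)
    return y


# ---------------------------------------------------------------------------
# objective evaluation

def evaluate_candidate(
    params: InterfaceParams,
    exp_features: CVFeatures,
    couple: RedoxCouple,
    protocol: CVProtocol,
    grid: SpatialGrid,
    substeps_per_Estep: int = 10,
) -> ErrorVector:
    """Forward-simulate one candidate and return its signed error vector.

    Any simulator or feature-extraction failure yields an infinite-penalty
    error vector (with a logged warning) rather than aborting the search.
    """
    try:
        trace = simulate_cv(params, couple, protocol, grid, substeps_per_Estep)
        sim = extract_features(trace)
        return error_vector(exp_features, sim)
    except Exception as exc:  # noqa: BLE001 - penalty, never abort the GA
        logger.warning("candidate %s penalized: %s", params, exc)
        return ErrorVector(np.inf, np.inf, np.inf)


def select_elitist(
    front: list[tuple[InterfaceParams, ErrorVector]],
) -> tuple[InterfaceParams, ErrorVector]:
    """Front member closest to the origin of the 3-D error space.

    Ties are broken by smaller |dE_pp|, then by smaller D.
    """
    if not front:
        raise ValueError("empty Pareto front")
    return min(front, key=lambda pe: (pe[1].norm, abs(pe[1].dE_pp), pe[0].D))


def _run_single_ga(
    exp_features: CVFeatures,
    bounds: ParameterBounds,
    ga: GAConfig,
    couple: RedoxCouple,
    protocol: CVProtocol,
    grid: SpatialGrid,
    substeps_per_Estep: int,
    seed: int,
) -> list[tuple[InterfaceParams, ErrorVector]]:
    """One NSGA-II run; returns the final non-dominated front."""
    rng = np.random.default_rng(seed)
    pop = ga.population

    def eval_block(X):
        params = [_decode(x, bounds, ga.log_scale) for x in X]
        errors = [
            evaluate_candidate(p, exp_features, couple, protocol, grid, substeps_per_Estep)
            for p in params
        ]
        F = np.array([e.magnitudes() for e in errors])
        return params, errors, F

    X = rng.random((pop, 4))
    params, errors, F = eval_block(X)
    if not np.any(np.isfinite(F).all(axis=1)):
        raise ConvergenceFailureError(
            "all initial candidates penalized; check bounds and protocol "
            f"(bounds={bounds}, population={pop})"
        )

    for gen in range(ga.generations):
        rank, crowd = _rank_and_crowd(F)
        children = []
        while len(children) < pop:
            i1 = _tournament(rng, rank, crowd)
            i2 = _tournament(rng, rank, crowd)
            c1, c2 = _sbx_pair(rng, X[i1], X[i2], ga.eta_crossover, ga.crossover_prob)
            children.append(_polynomial_mutation(rng, c1, ga.eta_mutation, ga.mutation_prob))
            if len(children) < pop:
                children.append(_polynomial_mutation(rng, c2, ga.eta_mutation, ga.mutation_prob))
        Xc = np.array(children)
        params_c, errors_c, Fc = eval_block(Xc)

        X_all = np.vstack([X, Xc])
        F_all = np.vstack([F, Fc])
        params_all = params + params_c
        errors_all = errors + errors_c
        if not np.any(np.isfinite(F_all).all(axis=1)):
            raise ConvergenceFailureError(f"all candidates penalized at generation {gen}")

        rank_all, crowd_all = _rank_and_crowd(F_all)
        order = np.lexsort((-crowd_all, rank_all))[:pop]
        X = X_all[order]
        F = F_all[order]
        params = [params_all[i] for i in order]
        errors = [errors_all[i] for i in order]

        best = min(e.norm for e in errors)
        logger.debug("generation %d: best error norm %.4g %%", gen, best)

    rank, _ = _rank_and_crowd(F)
    front = [
        (params[i], errors[i])
        for i in range(pop)
        if rank[i] == 0 and np.isfinite(F[i]).all()
    ]
    # deduplicate identical parameter vectors
    seen, unique = set(), []
    for p, e in front:
        key = (p.D, p.k0, p.alpha, p.ECSA)
        if key not in seen:
            seen.add(key)
            unique.append((p, e))
    return unique


def invert_parameters(
    exp: CVTrace | CVFeatures,
    bounds: ParameterBounds,
    ga: GAConfig,
    couple: RedoxCouple,
    protocol: CVProtocol,
    grid: SpatialGrid,
    substeps_per_Estep: int = 10,
) -> InversionResult:
    """Estimate (D, k0, alpha, ECSA) from a voltammogram.

    Runs ``ga.n_repeats`` independent GA searches (repeat r is seeded with
    ``ga.seed + r``), takes the elitist of each final front, and reports
    the per-parameter median across repeats together with the run-to-run
    dispersion (max relative deviation from the median).
    """
    exp_features = exp if isinstance(exp, CVFeatures) else extract_features(exp)

    per_run: list[tuple[InterfaceParams, ErrorVector]] = []
    union: list[tuple[InterfaceParams, ErrorVector]] = []
    for r in range(ga.n_repeats):
        front = _run_single_ga(
            exp_features, bounds, ga, couple, protocol, grid,
            substeps_per_Estep, seed=ga.seed + r,
        )
        per_run.append(select_elitist(front))
        union.extend(front)
        logger.info(
            "repeat %d/%d: elitist %s, error norm %.4g %%",
            r + 1, ga.n_repeats, per_run[-1][0], per_run[-1][1].norm,
        )

    # non-dominated filter over the union of the per-run fronts
    F_union = np.array([e.magnitudes() for _, e in union])
    rank = _nondominated_rank(F_union)
    pareto = [union[i] for i in range(len(union)) if rank[i] == 0]
    elitist, elitist_errors = select_elitist(pareto)

    mat = np.array([p.as_array() for p, _ in per_run])
    med = np.median(mat, axis=0)
    estimate = InterfaceParams(*med)
    dispersion = {
        name: float(np.max(np.abs(mat[:, j] - med[j])) / abs(med[j]))
        for j, name in enumerate(_PARAM_NAMES)
    }
    return InversionResult(
        estimate=estimate,
        elitist=elitist,
        elitist_errors=elitist_errors,
        pareto_front=pareto,
        per_run_elitists=per_run,
        dispersion=dispersion,
    )
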