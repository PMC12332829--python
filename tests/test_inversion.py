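import itertools
import math

import numpy as np
import pytest

import cvinverse as cv
from cvinverse.inversion import _decode, _nondominated_rank

from conftest import BARE, grid_for


def coarse_setup(couple):
    """Reduced problem size for search tests: coarser grid and fewer substeps.

    The GA and its oracles compare candidates through the same forward
    model, so the conclusions are independent of the discretization level.
    """
    proto = cv.CVProtocol()
    grid = grid_for(BARE.D, proto, n_points=250)
    return proto, grid, 5  # substeps


class TestSelectElitist:
    def test_single_member_front(self):
        member = (BARE, cv.ErrorVector(1.0, 1.0, 1.0))
        assert cv.select_elitist([member]) == member

    def test_smaller_norm_wins(self):
        a = (BARE, cv.ErrorVector(1.0, 1.0, 1.0))          # norm sqrt(3)
        b = (BARE, cv.ErrorVector(2.0, 2.0, 2.0))          # norm 2*sqrt(3)
        assert cv.select_elitist([b, a]) == a

    def test_ties_broken_by_potential_error_then_D(self):
        p_lo = cv.InterfaceParams(D=1e-6, k0=1e-3, alpha=0.5, ECSA=0.1)
        p_hi = cv.InterfaceParams(D=1e-5, k0=1e-3, alpha=0.5, ECSA=0.1)
        same_norm = [
            (p_hi, cv.ErrorVector(0.0, 5.0, 0.0)),
            (p_lo, cv.ErrorVector(5.0, 0.0, 0.0)),
            (p_hi, cv.ErrorVector(5.0, 0.0, 0.0)),
        ]
        chosen = cv.select_elitist(same_norm)
        assert chosen[0] is p_lo  # |dE_pp| equal for 2nd/3rd, lowest D wins

    def test_agrees_with_brute_force_min_norm(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 50)
            errs = rng.uniform(0.01, 30.0, size=(n, 3))
            front = [
                (cv.InterfaceParams(D=10.0 ** rng.uniform(-6, -4), k0=1e-3,
                                    alpha=0.5, ECSA=0.1),
                 cv.ErrorVector(*e))
                for e in errs
            ]
            # independent oracle: exhaustive scan with scalar math
            best, best_norm = None, math.inf
            for p, e in front:
                norm = math.sqrt(e.dI_ox**2 + e.dI_red**2 + e.dE_pp**2)
                if norm < best_norm:
                    best, best_norm = (p, e), norm
            assert cv.select_elitist(front)[1].norm == pytest.approx(best_norm)

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            cv.select_elitist([])


class TestNondominatedRank:
    def test_matches_exhaustive_domination_check(self):
        rng = np.random.default_rng(1)
        F = rng.uniform(0, 1, size=(40, 3))
        rank = _nondominated_rank(F)
        # oracle: a point is rank 0 iff no other point weakly dominates it
        # with at least one strict improvement
        for i in range(40):
            dominated = any(
                np.all(F[j] <= F[i]) and np.any(F[j] < F[i]) for j in range(40)
            )
            assert (rank[i] == 0) == (not dominated)


class TestEvaluateCandidate:
    def test_truth_candidate_has_zero_error(self, couple):
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        exp = cv.extract_features(target)
        e = cv.evaluate_candidate(BARE, exp, couple, proto, grid, sub)
        assert e.norm == pytest.approx(0.0, abs=1e-9)

    def test_sluggish_kinetics_widen_peak_separation(self, couple):
        proto, grid, sub = coarse_setup(couple)
        reversible = cv.InterfaceParams(D=1e-5, k0=1.0, alpha=0.5, ECSA=0.1125)
        target = cv.simulate_cv(reversible, couple, proto, grid, sub)
        exp = cv.extract_features(target)
        slow = cv.InterfaceParams(D=1e-5, k0=1e-5, alpha=0.5, ECSA=0.1125)
        e = cv.evaluate_candidate(slow, exp, couple, proto, grid, sub)
        # quasi-reversibility widens E_pp: simulated E_pp >> experimental
        assert abs(e.dE_pp) > 100.0

    def test_degenerate_experiment_is_penalized_not_fatal(self, couple):
        proto, grid, sub = coarse_setup(couple)
        exp = cv.CVFeatures(I_ox=1e-4, I_red=-1e-4, E_pp=0.06)
        bad = cv.RedoxCouple(c_b=0.0, E_f0=-0.25)  # featureless simulation
        e = cv.evaluate_candidate(BARE, exp, bad, proto, grid, sub)
        assert not np.isfinite(e.norm)


class TestInvertParameters:
    def test_collapsed_bounds_return_that_point(self, couple):
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        bounds = cv.ParameterBounds(
            D=(BARE.D, BARE.D), k0=(BARE.k0, BARE.k0),
            alpha=(0.5, 0.5), ECSA=(BARE.ECSA, BARE.ECSA),
        )
        ga = cv.GAConfig(population=8, generations=1, n_repeats=1, seed=0)
        res = cv.invert_parameters(target, bounds, ga, couple, proto, grid, sub)
        assert res.estimate == BARE
        assert res.elitist_errors.norm == pytest.approx(0.0, abs=1e-9)
        assert len(res.pareto_front) == 1

    def test_deterministic_under_fixed_seed(self, couple):
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        bounds = cv.ParameterBounds.around(BARE, decades=0.5)
        ga = cv.GAConfig(population=8, generations=2, n_repeats=1, seed=123)
        r1 = cv.invert_parameters(target, bounds, ga, couple, proto, grid, sub)
        r2 = cv.invert_parameters(target, bounds, ga, couple, proto, grid, sub)
        assert r1.estimate == r2.estimate
        assert [p for p, _ in r1.pareto_front] == [p for p, _ in r2.pareto_front]

    def test_reported_parameters_respect_bounds(self, couple):
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        bounds = cv.ParameterBounds.around(BARE, decades=1.0)
        ga = cv.GAConfig(population=12, generations=3, n_repeats=2, seed=5)
        res = cv.invert_parameters(target, bounds, ga, couple, proto, grid, sub)
        lo, hi = bounds.lowers(), bounds.uppers()
        for p, _ in res.pareto_front + res.per_run_elitists:
            assert np.all(p.as_array() >= lo) and np.all(p.as_array() <= hi)
        assert all(v >= 0 for v in res.dispersion.values())

    def test_two_parameter_subproblem_matches_grid_search(self, couple):
        """With alpha and ECSA fixed at truth the (D, k0) problem is
        identifiable; the GA elitist must agree with an exhaustive 40x40
        log-grid scan to within one grid cell."""
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        exp = cv.extract_features(target)
        n_grid = 40
        d_vals = np.logspace(np.log10(BARE.D) - 1, np.log10(BARE.D) + 1, n_grid)
        k_vals = np.logspace(np.log10(BARE.k0) - 1, np.log10(BARE.k0) + 1, n_grid)
        best, best_norm = None, np.inf
        for D, k0 in itertools.product(d_vals, k_vals):
            p = cv.InterfaceParams(D=D, k0=k0, alpha=BARE.alpha, ECSA=BARE.ECSA)
            norm = cv.evaluate_candidate(p, exp, couple, proto, grid, sub).norm
            if norm < best_norm:
                best, best_norm = p, norm

        bounds = cv.ParameterBounds(
            D=(d_vals[0], d_vals[-1]), k0=(k_vals[0], k_vals[-1]),
            alpha=(BARE.alpha, BARE.alpha), ECSA=(BARE.ECSA, BARE.ECSA),
        )
        ga = cv.GAConfig(population=24, generations=25, n_repeats=1, seed=2)
        res = cv.invert_parameters(exp, bounds, ga, couple, proto, grid, sub)
        cell = 2.0 / (n_grid - 1)  # log10 width of one grid cell
        assert abs(np.log10(res.elitist.D) - np.log10(best.D)) <= cell
        assert abs(np.log10(res.elitist.k0) - np.log10(best.k0)) <= cell

    def test_error_norm_improves_with_budget(self, couple):
        proto, grid, sub = coarse_setup(couple)
        target = cv.simulate_cv(BARE, couple, proto, grid, sub)
        bounds = cv.ParameterBounds.around(BARE, decades=1.0)
        norms = []
        for gens in (2, 10):
            ga = cv.GAConfig(population=16, generations=gens, n_repeats=1, seed=9)
            res = cv.invert_parameters(target, bounds, ga, couple, proto, grid, sub)
            norms.append(res.elitist_errors.norm)
        assert norms[1] <= norms[0] + 1e-12


class TestBoundsAndDecode:
    def test_log_decode_spans_the_box(self):
        bounds = cv.ParameterBounds()
        ga = cv.GAConfig()
        lo = _decode(np.zeros(4), bounds, ga.log_scale)
        hi = _decode(np.ones(4), bounds, ga.log_scale)
        assert (lo.D, lo.k0, lo.alpha, lo.ECSA) == pytest.approx(bounds.lowers())
        assert (hi.D, hi.k0, hi.alpha, hi.ECSA) == pytest.approx(bounds.uppers())

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            cv.ParameterBounds(D=(1e-3, 1e-7))
        with pytest.raises(ValueError):
            cv.ParameterBounds(alpha=(0.0, 0.7))
        with pytest.raises(ValueError):
            cv.ParameterBounds(k0=(-1.0, 1.0))

    def test_ga_config_budget_validation(self):
        with pytest.raises(ValueError):
            cv.GAConfig(population=4)
        with pytest.raises(ValueError):
            cv.GAConfig(generations=0)
        with pytest.raises(ValueError):
            cv.GAConfig(n_repeats=0)
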