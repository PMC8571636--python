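"""Equilibrium solving and extinction pruning.

Equilibria are roots of the per-capita growth equations of the species
assumed present (plus per-capita resource balance for MacArthur), found
by Broyden's quasi-Newton method with a Powell-hybrid fallback and
perturbed restarts. Extinction pruning repeats solve/remove rounds
against an abundance threshold expressed as a fraction of each species'
unstressed carrying capacity (1% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import models
from .models import (
    CommunityState,
    LVParams,
    MacArthurParams,
    ModelParams,
    StompParams,
)

__all__ = ["SolveReport", "solve_equilibrium", "prune_extinctions", "interior_guess"]

#: residual max-norm below which a root is accepted
RESIDUAL_TOL = 1e-10
MAX_ITER = 200


@dataclass
class SolveReport:
    state: CommunityState
    converged: bool
    residual_norm: float
    iterations: int
    pruned_species: list[int] = field(default_factory=list)


def _residual_fn(params: ModelParams):
    """Stacked per-capita equations whose root is an interior equilibrium."""
    if isinstance(params, LVParams):
        def fun(x):
            return params.mu - params.alpha @ x
        return fun, params.n
    if isinstance(params, MacArthurParams):
        n, r = params.n, params.r
        g = params.resource_growth

        def fun(x):
            N, R = x[:n], x[n:]
            consumer = params.w * (params.c @ R) - params.m
            resource = g.rate * (1.0 - R / g.capacity) - params.c.T @ N
            return np.concatenate([consumer, resource])
        return fun, n + r
    if isinstance(params, StompParams):
        def fun(x):
            return models.stomp_growth_extended(params, x)
        return fun, params.n
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def interior_guess(params: ModelParams) -> np.ndarray:
    """Cheap starting point for the interior-equilibrium root search."""
    if isinstance(params, LVParams):
        try:
            x = np.linalg.solve(params.alpha, params.mu)
            if np.all(np.isfinite(x)):
                return x
        except np.linalg.LinAlgError:
            pass
        return params.mu / np.diag(params.alpha) / params.n
    if isinstance(params, MacArthurParams):
        g = params.resource_growth
        N0 = np.full(params.n, 0.1)
        return np.concatenate([N0, 0.5 * g.capacity])
    if isinstance(params, StompParams):
        K = models.carrying_capacities(params)
        K = np.where(K > 0, K, np.max(K) if np.max(K) > 0 else 1.0)
        return K / params.n
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def _pack_state(params: ModelParams, state: CommunityState) -> np.ndarray:
    if isinstance(params, MacArthurParams):
        return np.concatenate([state.abundances, state.resources])
    return state.abundances.copy()


def _unpack_state(params: ModelParams, x: np.ndarray) -> CommunityState:
    if isinstance(params, MacArthurParams):
        return CommunityState(x[: params.n], x[params.n:])
    return CommunityState(x)


def solve_equilibrium(params: ModelParams,
                      initial_state: CommunityState | np.ndarray | None = None,
                      *, tol: float = RESIDUAL_TOL,
                      max_iter: int = MAX_ITER,
                      restarts: int = 3,
                      rng: np.random.Generator | None = None) -> SolveReport:
    """Root of the per-capita equations for all species in the community.

    The returned state may contain negative components when no feasible
    interior equilibrium exists; ``prune_extinctions`` treats those as
    extinctions. Non-convergence is reported through ``converged=False``,
    never raised.
    """
    fun, dim = _residual_fn(params)
    if initial_state is None:
        x0 = interior_guess(params)
    elif isinstance(initial_state, CommunityState):
        x0 = _pack_state(params, initial_state)
    else:
        x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (dim,):
        raise ValueError(f"initial state must have {dim} components")

    best_x, best_res, total_it = x0, np.inf, 0
    rng = rng or np.random.default_rng(0)
    starts = [x0] + [x0 * rng.uniform(0.5, 1.5, size=dim) for _ in range(restarts)]
    for start in starts:
        for method in ("broyden1", "hybr"):
            x, nit = _try_root(fun, start, method, max_iter)
            total_it += nit
            res = float(np.max(np.abs(fun(x))))
            if res < best_res:
                best_x, best_res = x, res
            if best_res < tol:
                return SolveReport(_unpack_state(params, best_x), True,
                                   best_res, total_it)
    return SolveReport(_unpack_state(params, best_x), False, best_res, total_it)


def _try_root(fun, x0, method, max_iter):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if method == "broyden1":
                sol = optimize.root(fun, x0, method="broyden1",
                                    options={"maxiter": max_iter,
                                             "fatol": RESIDUAL_TOL / 10,
                                             "ftol": 0.0})
            else:
                sol = optimize.root(fun, x0, method="hybr",
                                    options={"xtol": 1e-13})
        except Exception:
            return x0, 0
    nit = int(getattr(sol, "nit", 0) or 0)
    return np.atleast_1d(sol.x), nit


def prune_extinctions(params: ModelParams, theta: np.ndarray | None = None,
                      threshold_fraction: float = 0.01, *,
                      carrying_capacities: np.ndarray | None = None,
                      initial_state: CommunityState | None = None,
                      tol: float = RESIDUAL_TOL,
                      max_rounds: int | None = None) -> SolveReport:
    """Solve, remove species below threshold, re-solve until stable.

    ``theta`` (if given) replaces the focal traits — the stressed
    community — while the extinction threshold stays expressed relative
    to carrying capacities in the *unstressed* environment (pass
    ``carrying_capacities`` to reuse cached values). Negative candidate
    abundances count as below threshold. The result is a fixed point of
    the procedure: re-running it changes nothing.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if carrying_capacities is None:
        carrying_capacities = models.carrying_capacities(params)
    K = np.asarray(carrying_capacities, dtype=float)
    if theta is not None:
        params = models.with_focal_traits(params, theta)
    n = params.n
    thresholds = threshold_fraction * K
    mask = np.ones(n, dtype=bool)
    max_rounds = max_rounds if max_rounds is not None else n + 2

    guess = None
    if initial_state is not None:
        guess = _pack_state(params, initial_state)

    last_report = None
    for _ in range(max_rounds):
        if not mask.any():
            state = _empty_state(params)
            return SolveReport(state, True, 0.0, 0,
                               pruned_species=list(np.where(~mask)[0]))
        sub = models.subset(params, mask)
        sub_guess = _subset_guess(params, sub, mask, guess)
        report = solve_equilibrium(sub, sub_guess, tol=tol)
        last_report = report
        if not report.converged:
            state = _embed(params, mask, report.state)
            return SolveReport(state, False, report.residual_norm,
                               report.iterations,
                               pruned_species=list(np.where(~mask)[0]))
        N_sub = report.state.abundances
        below = N_sub < thresholds[mask]
        if not below.any():
            state = _embed(params, mask, report.state)
            return SolveReport(state, True, report.residual_norm,
                               report.iterations,
                               pruned_species=list(np.where(~mask)[0]))
        idx = np.where(mask)[0]
        mask = mask.copy()
        mask[idx[below]] = False
        guess = None  # geometry changed; restart from interior guess
    # mask shrinks every round, so this is unreachable for max_rounds > n;
    # kept as a guard for user-supplied small max_rounds.
    state = _embed(params, mask, last_report.state)
    return SolveReport(state, False, last_report.residual_norm,
                       last_report.iterations,
                       pruned_species=list(np.where(~mask)[0]))


def _empty_state(params: ModelParams) -> CommunityState:
    if isinstance(params, MacArthurParams):
        return CommunityState(np.zeros(params.n),
                              params.resource_growth.capacity.copy())
    return CommunityState(np.zeros(params.n))


def _subset_guess(params, sub, mask, guess):
    if guess is None:
        return None
    if isinstance(params, MacArthurParams):
        return np.concatenate([guess[: params.n][mask], guess[params.n:]])
    return guess[mask]


def _embed(params: ModelParams, mask: np.ndarray,
           sub_state: CommunityState) -> CommunityState:
    N = np.zeros(params.n)
    N[mask] = np.clip(sub_state.abundances, 0.0, None)
    resources = sub_state.resources
    return CommunityState(N, resources, survivors=mask & (N > 0))
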