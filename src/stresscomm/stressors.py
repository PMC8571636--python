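"""Stressor algebra.

A stressor multiplies a species' focal trait by an effect epsilon in
(0, 1]. With n species and s stressors the effects form an n x s matrix
E. Total stressor intensity (TSI) is one minus the product of all
entries; the power rescaling ``rescale_to_fixed_tsi`` fixes that product
at a target d = 1 - TSI while preserving the proportional pattern of who
is hit by what. Pairwise trait-level stressor interactions eta make the
joint log-scale effect deviate from additivity (eta > 0 antagonistic,
eta < 0 synergistic). SCV, the coefficient of variation of the per-
species combined effects (row products of E), measures how unequally
stressors hit species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StressorField",
    "sample_effects",
    "sample_interactions",
    "total_stressor_intensity",
    "rescale_to_fixed_tsi",
    "apply_stressors",
    "stressor_cv",
    "row_products",
    "EFFECT_ALPHA",
    "EFFECT_BETA",
]

# Beta distribution of individual stressor effects: mild effects (near 1)
# are much more common than severe ones.
EFFECT_ALPHA = 6.5
EFFECT_BETA = 0.25


@dataclass(frozen=True)
class StressorField:
    """Effect matrix E, optional interaction tensor eta, and TSI target d."""

    E: np.ndarray
    eta: np.ndarray | None = None
    d: float | None = None  # 1 - TSI when intensity is fixed, else None

    def __post_init__(self):
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        _validate_effects(E)
        if self.eta is not None:
            eta = np.asarray(self.eta, dtype=float)
            n, s = E.shape
            if eta.shape != (n, s, s):
                raise ValueError("eta must have shape (n, s, s)")
            if np.any(np.abs(np.diagonal(eta, axis1=1, axis2=2)) > 0):
                raise ValueError("stressors do not interact with themselves")
            object.__setattr__(self, "eta", eta)
        if self.d is not None:
            if not 0 < self.d < 1:
                raise ValueError("d must lie in (0, 1)")
            if abs(np.exp(np.log(E).sum()) - self.d) > 1e-10:
                raise ValueError("E's product does not match the fixed target d")

    @property
    def s(self) -> int:
        return self.E.shape[1]

    @property
    def n(self) -> int:
        return self.E.shape[0]


def _validate_effects(E: np.ndarray) -> None:
    if E.ndim != 2:
        raise ValueError("E must be an n x s matrix")
    if np.any(E <= 0) or np.any(E > 1):
        raise ValueError("stressor effects must lie in (0, 1]")


def sample_effects(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Beta(6.5, 0.25) effect matrix; no cotolerance structure."""
    if n < 1 or s < 1:
        raise ValueError("need at least one species and one stressor")
    return rng.beta(EFFECT_ALPHA, EFFECT_BETA, size=(n, s))


def sample_interactions(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal pairwise interaction tensor, symmetric in (l1, l2).

    Diagonal (l1 == l2) is zero; for s < 2 there are no pairs and the
    tensor is identically zero.
    """
    if n < 1 or s < 1:
        raise ValueError("need at least one species and one stressor")
    eta = np.zeros((n, s, s))
    if s < 2:
        return eta
    iu = np.triu_indices(s, k=1)
    draws = rng.normal(0.0, 1.0, size=(n, iu[0].size))
    eta[:, iu[0], iu[1]] = draws
    eta[:, iu[1], iu[0]] = draws
    return eta


def row_products(E: np.ndarray) -> np.ndarray:
    """Combined stressor effect experienced by each species: prod_l eps_il."""
    E = np.asarray(E, dtype=float)
    _validate_effects(E)
    return np.exp(np.log(E).sum(axis=1))


def total_stressor_intensity(E: np.ndarray) -> float:
    """TSI = 1 - prod over all species and stressors of eps_il (in log space)."""
    E = np.asarray(E, dtype=float)
    _validate_effects(E)
    return float(1.0 - np.exp(np.log(E).sum()))


def rescale_to_fixed_tsi(E: np.ndarray, d: float) -> np.ndarray:
    """Power-rescale E so its grand product equals the target d = 1 - TSI.

    E' = E**k with k = log d / log(prod E). Rank order of entries is
    preserved and each species is still affected in a proportionally
    similar manner, only the overall intensity changes.
    """
    E = np.asarray(E, dtype=float)
    _validate_effects(E)
    if not 0 < d < 1:
        raise ValueError("d must lie in (0, 1)")
    log_total = np.log(E).sum()
    if log_total == 0.0:
        raise ValueError("cannot rescale a matrix whose entries are all 1")
    k = np.log(d) / log_total
    return E**k


def apply_stressors(theta0: np.ndarray, E: np.ndarray,
                    eta: np.ndarray | None = None, *, log_base: float = 10.0,
                    ordered_pairs: bool = True) -> np.ndarray:
    """Stressed trait vector theta from baseline theta0 and effect matrix E.

    log(theta_i) = log(theta0_i) + sum_l log(eps_il)
                   + sum_{l1} sum_{l2} log(eps_il1) log(eps_il2) eta_il1l2

    The interaction term uses base-10 logs by default (the base only
    matters when eta is nonzero, since the independent part is a pure
    product). ``ordered_pairs=True`` sums over both (l1, l2) orders as
    written, so a symmetric pair effectively counts twice; set False to
    count each unordered pair once.
    """
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    if np.any(theta0 <= 0):
        raise ValueError("baseline traits must be strictly positive")
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        return theta0.copy()
    if E.ndim == 1:
        E = E[None, :] if theta0.shape[0] == 1 else E[:, None]
    _validate_effects(E)
    if E.shape[0] != theta0.shape[0]:
        raise ValueError("E must have one row per species")
    theta = theta0 * row_products(E)
    if eta is not None:
        eta = np.asarray(eta, dtype=float)
        L = np.log(E) / np.log(log_base)
        interaction = np.einsum("is,ist,it->i", L, eta, L)
        if not ordered_pairs:
            interaction /= 2.0
        theta = theta * log_base**interaction
    return theta


def stressor_cv(E: np.ndarray, *, ddof: int = 1) -> float:
    """SCV: coefficient of variation of the row products of E.

    Sample (n-1) standard deviation by default. A single-species matrix
    has no among-species variation; 0 by convention.
    """
    p = row_products(E)
    if p.shape[0] < 2:
        return 0.0
    return float(np.std(p, ddof=ddof) / np.mean(p))
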