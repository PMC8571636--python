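"""Closed-form analytics for the symmetric two-species Lotka-Volterra case.

With symmetric interspecific competition alpha12 = alpha21 = alpha and
combined stressor effects e_i = prod_l eps_il on the growth rates, the
pair coexists iff

    alpha/alpha11 < (mu2 e2) / (mu1 e1) < alpha22/alpha.

Setting alpha11 = alpha22 = 1 and mu1 = mu2 = 1, the stressed/pristine
yield ratio is (e1 + e2)/2, and the selection share of the net
biodiversity effect depends only on rho = e2/e1 and alpha:

    S/DeltaY = alpha * (1/rho - 2 + rho) / (alpha - 1)^2,
    C/DeltaY = 1 - S/DeltaY.

``rho_experiment`` samples rho under growing stressor richness with and
without the total-intensity-fixing rescaling, which is what makes the
variance of log(rho) grow (unfixed) or shrink (fixed) with richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stressors import rescale_to_fixed_tsi, row_products, sample_effects

__all__ = [
    "TwoSpeciesSummary",
    "coexistence_test",
    "yield_ratio",
    "scaled_selection",
    "scaled_complementarity",
    "rho_experiment",
]


@dataclass(frozen=True)
class TwoSpeciesSummary:
    rho: float
    alpha: float
    coexists: bool
    yield_ratio: float
    scaled_selection: float
    scaled_complementarity: float


def coexistence_test(mu: np.ndarray, alpha_matrix: np.ndarray,
                     effect_products: np.ndarray) -> bool:
    """Strict double inequality for stressed two-species coexistence."""
    mu = np.asarray(mu, dtype=float)
    A = np.asarray(alpha_matrix, dtype=float)
    e = np.asarray(effect_products, dtype=float)
    if mu.shape != (2,) or A.shape != (2, 2) or e.shape != (2,):
        raise ValueError("two species only")
    if A[0, 1] != A[1, 0]:
        raise ValueError("interaction matrix must be symmetric (alpha12 = alpha21)")
    if np.any(mu <= 0) or np.any(e <= 0) or np.any(np.diag(A) <= 0) or A[0, 1] < 0:
        raise ValueError("all inputs must be positive")
    alpha = A[0, 1]
    middle = (mu[1] * e[1]) / (mu[0] * e[0])
    if alpha == 0.0:  # no competition: band is (0, inf)
        return True
    return bool(alpha / A[0, 0] < middle < A[1, 1] / alpha)


def yield_ratio(e1: float, e2: float) -> float:
    """Stressed over pristine total yield for a coexisting symmetric pair."""
    if not (0 < e1 <= 1 and 0 < e2 <= 1):
        raise ValueError("combined effects must lie in (0, 1]")
    return (e1 + e2) / 2.0


def scaled_selection(rho: float, alpha: float) -> float:
    """S/DeltaY = alpha (1/rho - 2 + rho) / (alpha - 1)^2; >= 0 on (0,1)."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    return alpha * (1.0 / rho - 2.0 + rho) / (alpha - 1.0) ** 2


def scaled_complementarity(rho: float, alpha: float) -> float:
    """C/DeltaY = 1 - S/DeltaY; maximal (=1) at rho = 1, falls as rho departs."""
    return 1.0 - scaled_selection(rho, alpha)


def rho_experiment(s_values, tsi_mode: str, d: float = 0.1,
                   iterations: int = 1000,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Distribution of log(rho) across stressor richness levels.

    For each s, draws ``iterations`` 2 x s Beta(6.5, 0.25) effect
    matrices, rescales them to the fixed product d when
    ``tsi_mode == "fixed"``, and summarizes log(rho) = log(e2/e1) by its
    mean, variance, and 10th/90th percentiles.
    """
    if tsi_mode not in ("unfixed", "fixed"):
        raise ValueError("tsi_mode must be 'unfixed' or 'fixed'")
    if iterations < 2:
        raise ValueError("need at least two iterations")
    rng = rng or np.random.default_rng()
    rows = []
    for s in s_values:
        log_rho = np.empty(iterations)
        for i in range(iterations):
            E = sample_effects(2, int(s), rng)
            if tsi_mode == "fixed":
                E = rescale_to_fixed_tsi(E, d)
            p = row_products(E)
            log_rho[i] = np.log(p[1]) - np.log(p[0])
        rows.append({
            "s": int(s), "tsi_mode": tsi_mode,
            "d": d if tsi_mode == "fixed" else np.nan,
            "mean_log_rho": log_rho.mean(),
            "var_log_rho": log_rho.var(ddof=1),
            "q10_log_rho": np.percentile(log_rho, 10),
            "q90_log_rho": np.percentile(log_rho, 90),
            "iterations": iterations,
        })
    return pd.DataFrame(rows)
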