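"""Community-level outcome metrics.

Four families: the ecosystem-function ratio (stressed over unstressed
total yield), species persistence, Bray-Curtis compositional resistance,
and the Loreau-Hector additive partition of the net biodiversity effect
into complementarity and selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial.distance import braycurtis

from .models import CommunityState

__all__ = [
    "MetricRecord",
    "BiodiversityEffects",
    "ecosystem_function",
    "persistence",
    "bray_curtis_similarity",
    "biodiversity_effects",
]


@dataclass
class MetricRecord:
    """One replicate's outcomes; rows of the long-format results table."""

    cell_id: str
    replicate: int
    seed: int
    function_ratio: float
    n_survivors: int
    persistence_fraction: float
    bray_curtis: float
    delta_y: float
    complementarity: float
    selection: float
    scaled_complementarity: float
    scaled_selection: float
    scv: float
    tsi: float

    COLUMNS = (
        "cell_id", "replicate", "seed", "function_ratio", "n_survivors",
        "persistence_fraction", "bray_curtis", "delta_y", "complementarity",
        "selection", "scaled_complementarity", "scaled_selection", "scv", "tsi",
    )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class BiodiversityEffects:
    delta_y: float
    complementarity: float
    selection: float
    scaled_complementarity: float  # NaN when delta_y == 0
    scaled_selection: float


def ecosystem_function(stressed_state: CommunityState,
                       unstressed_state: CommunityState) -> float:
    """Total surviving yield under stress over the unstressed total yield."""
    denom = unstressed_state.total_yield
    if denom <= 0:
        raise ValueError("unstressed community has zero yield")
    return stressed_state.total_yield / denom


def persistence(stressed_state: CommunityState,
                unstressed_state: CommunityState) -> tuple[int, float]:
    """Surviving-species count and its fraction of the initial richness."""
    n0 = int(unstressed_state.survivors.sum())
    if n0 == 0:
        raise ValueError("unstressed community has no species")
    count = int(stressed_state.survivors.sum())
    return count, count / n0


def bray_curtis_similarity(x_abundances: np.ndarray,
                           y_abundances: np.ndarray) -> float:
    """1 - sum|x-y| / sum(x+y); 1 means identical composition, 0 disjoint."""
    x = np.asarray(x_abundances, dtype=float)
    y = np.asarray(y_abundances, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return float(1.0 - braycurtis(x, y))


def biodiversity_effects(observed_yields: np.ndarray,
                         monoculture_yields: np.ndarray,
                         expected_relative_yield: float | None = None,
                         ) -> BiodiversityEffects:
    """Loreau-Hector partition of the net biodiversity effect.

    DeltaRY_i = observed_i / monoculture_i - expected; the partition is
    DeltaY = C + S with C = n * mean(DeltaRY) * mean(M) and
    S = n * cov(DeltaRY, M), population (1/n) covariance. Extinct species
    enter with observed yield 0 but keep their monoculture yield. The
    expected relative yield defaults to 1/n. Scaled effects divide by
    DeltaY and are NaN when DeltaY is 0.
    """
    obs = np.asarray(observed_yields, dtype=float)
    M = np.asarray(monoculture_yields, dtype=float)
    if obs.shape != M.shape or obs.ndim != 1:
        raise ValueError("observed and monoculture yields must be equal-length vectors")
    if np.any(M <= 0):
        raise ValueError("monoculture yields must be strictly positive")
    n = obs.shape[0]
    e = 1.0 / n if expected_relative_yield is None else float(expected_relative_yield)
    drys = obs / M - e
    C = n * drys.mean() * M.mean()
    S = n * float(np.cov(drys, M, bias=True)[0, 1]) if n > 1 else 0.0
    dY = C + S
    # a net effect indistinguishable from zero at float precision makes
    # the scaled shares meaningless; flag them as missing
    if abs(dY) <= 1e-12 * max(1.0, M.sum()):
        return BiodiversityEffects(dY, C, S, math.nan, math.nan)
    return BiodiversityEffects(dY, C, S, C / dY, S / dY)
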