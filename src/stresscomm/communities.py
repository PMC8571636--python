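"""Synthetic community generation.

Samples model parameters (focal traits log-normal, the remaining
parameters from documented default ranges) and screens candidate
communities so that every species persists at >= 1% of its carrying
capacity in the unstressed environment. The sampling ranges are this
package's own reconstructions of plausible coexistence-friendly
parameterizations; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import equilibrium, models
from .models import (
    CommunityState,
    LVParams,
    MacArthurParams,
    ModelParams,
    ResourceLogistic,
    StompParams,
)

__all__ = [
    "CommunitySpec",
    "SamplingConfig",
    "ScreenResult",
    "BatchResult",
    "sample_community",
    "screen_coexistence",
    "generate_batch",
    "MODELS",
]

MODELS = ("lotka_volterra", "macarthur", "stomp")


@dataclass(frozen=True)
class SamplingConfig:
    """Default parameter ranges for community generation.

    All values are package defaults chosen to produce communities that
    plausibly coexist unstressed; they are not taken from any published
    parameter table.
    """

    # focal trait theta ~ LogNormal(meanlog, sdlog)
    theta_meanlog: float = 0.0
    theta_sdlog: float = 0.25
    # Lotka-Volterra: alpha_ii = 1; alpha_ij ~ U(lo, hi) * alpha_ii / (n-1)
    lv_offdiag_lo: float = 0.1
    lv_offdiag_hi: float = 0.9
    # MacArthur: one resource per species; uptake dominated by the "own"
    # resource plus weaker shared uptake; maintenance a fraction of the
    # maximal intake rate at resource capacity
    mac_own_uptake: tuple[float, float] = (0.6, 1.0)
    mac_shared_uptake: tuple[float, float] = (0.0, 0.15)
    mac_maintenance_frac: tuple[float, float] = (0.2, 0.4)
    mac_resource_rate: float = 1.0
    mac_resource_capacity: float = 1.0
    # Stomp: Gaussian absorption bumps with staggered peaks on 400-700 nm
    stomp_peak_lo: float = 440.0
    stomp_peak_hi: float = 660.0
    stomp_peak_jitter: float = 10.0
    stomp_width: float = 40.0
    stomp_peak_absorption: float = 0.1
    stomp_depth: float = 10.0
    stomp_background: float = 0.05
    stomp_loss_frac: tuple[float, float] = (0.2, 0.4)
    stomp_n_wavelengths: int = 31
    stomp_n_depth: int = 51


@dataclass(frozen=True)
class CommunitySpec:
    model: str
    n_species: int
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.model == "stomp" and self.n_species != 4:
            raise ValueError(
                "the light-spectrum model supports only four-species communities"
            )


@dataclass
class ScreenResult:
    accept: bool
    state: CommunityState | None
    carrying_capacities: np.ndarray | None
    status: str  # "accepted" | "below_threshold" | "non_convergent" | "non_viable"


@dataclass
class BatchResult:
    communities: list[ModelParams]
    states: list[CommunityState]
    carrying_capacities: list[np.ndarray]
    seeds: list[int]
    attempts: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.communities) / self.attempts if self.attempts else 0.0


def sample_community(spec: CommunitySpec, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter set; no coexistence screening."""
    cfg = spec.sampling
    n = spec.n_species
    theta = rng.lognormal(cfg.theta_meanlog, cfg.theta_sdlog, size=n)
    if spec.model == "lotka_volterra":
        alpha = rng.uniform(cfg.lv_offdiag_lo, cfg.lv_offdiag_hi, size=(n, n))
        alpha /= max(n - 1, 1)
        np.fill_diagonal(alpha, 1.0)
        return LVParams(mu=theta, alpha=alpha)
    if spec.model == "macarthur":
        r = n  # one resource per species, overlapping uptake
        c = rng.uniform(*cfg.mac_shared_uptake, size=(n, r))
        c[np.arange(n), np.arange(n)] = rng.uniform(*cfg.mac_own_uptake, size=n)
        growth = ResourceLogistic(
            rate=np.full(r, cfg.mac_resource_rate),
            capacity=np.full(r, cfg.mac_resource_capacity),
        )
        max_intake = theta * (c @ growth.capacity)
        m = rng.uniform(*cfg.mac_maintenance_frac, size=n) * max_intake
        return MacArthurParams(w=theta, c=c, m=m, resource_growth=growth)
    # stomp
    wavelengths = np.linspace(400.0, 700.0, cfg.stomp_n_wavelengths)
    peaks = np.linspace(cfg.stomp_peak_lo, cfg.stomp_peak_hi, n)
    peaks = peaks + rng.uniform(-cfg.stomp_peak_jitter, cfg.stomp_peak_jitter, size=n)
    spectra = cfg.stomp_peak_absorption * np.exp(
        -((wavelengths[None, :] - peaks[:, None]) ** 2) / (2 * cfg.stomp_width**2)
    )
    incident = np.ones_like(wavelengths)
    background = np.full_like(wavelengths, cfg.stomp_background)
    params = StompParams(
        phi=theta, loss=np.ones(n), depth=cfg.stomp_depth,
        wavelengths=wavelengths, absorption_spectra=spectra,
        incident_spectrum=incident, background_attenuation=background,
        n_depth=cfg.stomp_n_depth,
    )
    # loss as a fraction of the growth capacity at zero abundance, so every
    # species can at least grow from rarity alone
    g0 = models.per_capita_growth(params, CommunityState(np.zeros(n))) + params.loss
    loss = rng.uniform(*cfg.stomp_loss_frac, size=n) * g0
    return StompParams(
        phi=theta, loss=loss, depth=cfg.stomp_depth,
        wavelengths=wavelengths, absorption_spectra=spectra,
        incident_spectrum=incident, background_attenuation=background,
        n_depth=cfg.stomp_n_depth,
    )


def screen_coexistence(params: ModelParams,
                       threshold_fraction: float = 0.01) -> ScreenResult:
    """Accept a community iff all species settle at >= threshold x capacity.

    Solves the unstressed equilibrium with extinction pruning; a community
    is accepted only when no species had to be pruned. Solver failures
    reject with a distinct status instead of raising.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    K = models.carrying_capacities(params)
    if np.any(K <= 0):
        return ScreenResult(False, None, None, "non_viable")
    report = equilibrium.prune_extinctions(
        params, threshold_fraction=threshold_fraction, carrying_capacities=K)
    if not report.converged:
        return ScreenResult(False, None, None, "non_convergent")
    if report.pruned_species or not report.state.survivors.all():
        return ScreenResult(False, None, None, "below_threshold")
    return ScreenResult(True, report.state, K, "accepted")


def generate_batch(spec: CommunitySpec, n_communities: int, *,
                   base_seed: int = 0, max_attempts: int | None = None,
                   threshold_fraction: float = 0.01,
                   min_acceptance: float = 0.001) -> BatchResult:
    """Rejection-sample exactly ``n_communities`` coexisting communities.

    Attempt i uses its own RNG stream seeded ``base_seed + i`` so any
    accepted community is reproducible in isolation from its recorded
    seed. Raises if the acceptance rate stays below ``min_acceptance``
    after ``max_attempts`` draws.
    """
    if n_communities < 1:
        raise ValueError("need at least one community")
    if max_attempts is None:
        max_attempts = max(1000, int(n_communities / min_acceptance))
    out = BatchResult([], [], [], [], 0)
    for i in range(max_attempts):
        seed = (base_seed + i) % 2**31
        rng = np.random.default_rng(seed)
        params = sample_community(spec, rng)
        out.attempts += 1
        res = screen_coexistence(params, threshold_fraction)
        if res.accept:
            out.communities.append(params)
            out.states.append(res.state)
            out.carrying_capacities.append(res.carrying_capacities)
            out.seeds.append(seed)
            if len(out.communities) == n_communities:
                return out
    raise RuntimeError(
        f"only {len(out.communities)}/{n_communities} communities accepted "
        f"after {out.attempts} attempts "
        f"(acceptance rate {out.acceptance_rate:.4f})"
    )
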