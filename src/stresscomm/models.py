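"""Community models: Lotka-Volterra, MacArthur consumer-resource, and
Stomp light-spectrum competition.

All three models are expressed through a common small surface:

* per-capita growth rates ``per_capita_growth(params, state)``,
* a focal trait vector ``focal_traits(params)`` that stressors multiply
  (mu for Lotka-Volterra, w for MacArthur, phi for Stomp),
* ``carrying_capacity(params, i)`` — the species' monoculture equilibrium
  in the given (possibly stressed) environment,
* ``subset(params, mask)`` to restrict a community to a survivor set.

Dynamics are deterministic throughout; stressors enter only by rescaling
the focal trait, never the state equations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LVParams",
    "MacArthurParams",
    "StompParams",
    "ResourceLogistic",
    "CommunityState",
    "per_capita_growth",
    "resource_dynamics",
    "absorbed_light_profile",
    "carrying_capacity",
    "carrying_capacities",
    "focal_traits",
    "with_focal_traits",
    "subset",
    "n_species",
    "n_resources",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LVParams:
    """Lotka-Volterra competition: dNi/dt / Ni = mu_i - sum_j alpha_ij N_j.

    The focal trait theta_i is the intrinsic growth rate mu_i.
    """

    mu: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        n = self.mu.shape[0]
        if self.alpha.shape != (n, n):
            raise ValueError("alpha must be n x n")
        if np.any(np.diag(self.alpha) <= 0):
            raise ValueError("diagonal alpha_ii must be positive")

    @property
    def n(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class ResourceLogistic:
    """Logistic self-renewal of resources: growth rate and capacity per resource."""

    rate: np.ndarray
    capacity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        object.__setattr__(self, "capacity", np.asarray(self.capacity, dtype=float))
        if np.any(self.capacity <= 0) or np.any(self.rate <= 0):
            raise ValueError("resource rates and capacities must be positive")


@dataclass(frozen=True)
class MacArthurParams:
    """MacArthur consumer-resource model.

    Per-capita consumer growth: sum_k w_i c_ik R_k - m_i. Resources renew
    logistically and are consumed by mass action (linear uptake):
    dR_k/dt = r_k R_k (1 - R_k/K_k) - sum_i c_ik N_i R_k.

    The focal trait theta_i is the resource value w_i (species-specific,
    so a stressor degrades how well species i converts any resource).
    """

    w: np.ndarray
    c: np.ndarray
    m: np.ndarray
    resource_growth: ResourceLogistic

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        n = self.w.shape[0]
        if self.c.shape[0] != n or self.m.shape[0] != n:
            raise ValueError("w, c, m must agree on species count")
        if self.c.shape[1] != self.resource_growth.rate.shape[0]:
            raise ValueError("c and resource_growth must agree on resource count")
        if np.any(self.c < 0):
            raise ValueError("uptake coefficients must be non-negative")
        if np.any(self.m <= 0) or np.any(self.w <= 0):
            raise ValueError("w and m must be positive")
        if np.any(self.c.sum(axis=1) == 0):
            raise ValueError("every species needs at least one positive uptake")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def r(self) -> int:
        return self.c.shape[1]


@dataclass(frozen=True)
class StompParams:
    """Phytoplankton competition for the light spectrum (Stomp-type model).

    Per-capita growth: (phi_i / z) * int_0^z gamma_i(z') dz' - loss_i,
    with gamma_i the photon flux absorbed per capita by species i at depth
    z', computed from species absorption spectra and Beer-Lambert
    attenuation through the whole community plus background.

    The focal trait theta_i is the photosynthetic efficiency phi_i.
    Wavelength grid spans 400-700 nm; integrals use the trapezoid rule on
    the wavelength grid and on ``n_depth`` evenly spaced depth points.
    """

    phi: np.ndarray
    loss: np.ndarray
    depth: float
    wavelengths: np.ndarray
    absorption_spectra: np.ndarray  # (n, n_wavelengths), per-capita
    incident_spectrum: np.ndarray  # (n_wavelengths,)
    background_attenuation: np.ndarray  # (n_wavelengths,)
    n_depth: int = 51

    def __post_init__(self):
        for name in ("phi", "loss", "wavelengths", "absorption_spectra",
                     "incident_spectrum", "background_attenuation"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.phi.shape[0]
        if n > 4:
            raise ValueError(
                "light-spectrum differentiation cannot support more than four species"
            )
        w = self.wavelengths.shape[0]
        if self.absorption_spectra.shape != (n, w):
            raise ValueError("absorption_spectra must be (n_species, n_wavelengths)")
        if self.incident_spectrum.shape != (w,) or self.background_attenuation.shape != (w,):
            raise ValueError("spectra must live on the common wavelength grid")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if np.any(self.phi <= 0) or np.any(self.loss <= 0):
            raise ValueError("phi and loss must be positive")
        if (np.any(self.absorption_spectra < 0) or np.any(self.incident_spectrum < 0)
                or np.any(self.background_attenuation < 0)):
            raise ValueError("spectra must be non-negative")

    @property
    def n(self) -> int:
        return self.phi.shape[0]


ModelParams = LVParams | MacArthurParams | StompParams


@dataclass
class CommunityState:
    """Abundances (and resources for MacArthur) with survivor flags."""

    abundances: np.ndarray
    resources: np.ndarray = field(default_factory=lambda: np.empty(0))
    survivors: np.ndarray | None = None

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.resources = np.asarray(self.resources, dtype=float)
        if self.survivors is None:
            self.survivors = self.abundances > 0
        else:
            self.survivors = np.asarray(self.survivors, dtype=bool)

    @property
    def total_yield(self) -> float:
        return float(self.abundances[self.survivors].sum())


# ---------------------------------------------------------------------------
# generic accessors
# ---------------------------------------------------------------------------


def n_species(params: ModelParams) -> int:
    return params.n


def n_resources(params: ModelParams) -> int:
    return params.r if isinstance(params, MacArthurParams) else 0


def focal_traits(params: ModelParams) -> np.ndarray:
    """The trait vector theta that stressors multiply."""
    if isinstance(params, LVParams):
        return params.mu
    if isinstance(params, MacArthurParams):
        return params.w
    if isinstance(params, StompParams):
        return params.phi
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def with_focal_traits(params: ModelParams, theta: np.ndarray) -> ModelParams:
    """Copy of ``params`` with the focal trait vector replaced by ``theta``."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (params.n,):
        raise ValueError("theta must have one entry per species")
    if np.any(theta <= 0):
        raise ValueError("traits must stay strictly positive")
    if isinstance(params, LVParams):
        return replace(params, mu=theta)
    if isinstance(params, MacArthurParams):
        return replace(params, w=theta)
    if isinstance(params, StompParams):
        return replace(params, phi=theta)
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def subset(params: ModelParams, mask: np.ndarray) -> ModelParams:
    """Restrict a community to the species where ``mask`` is True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (params.n,):
        raise ValueError("mask length must equal species count")
    if isinstance(params, LVParams):
        return LVParams(mu=params.mu[mask], alpha=params.alpha[np.ix_(mask, mask)])
    if isinstance(params, MacArthurParams):
        return replace(params, w=params.w[mask], c=params.c[mask], m=params.m[mask])
    if isinstance(params, StompParams):
        return replace(params, phi=params.phi[mask], loss=params.loss[mask],
                       absorption_spectra=params.absorption_spectra[mask])
    raise TypeError(f"unknown model parameters: {type(params)!r}")


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _check_state(params: ModelParams, state: CommunityState) -> None:
    if state.abundances.shape != (params.n,):
        raise ValueError("state abundances do not match species count")
    if np.any(state.abundances < 0):
        raise ValueError("abundances must be non-negative")
    if isinstance(params, MacArthurParams):
        if state.resources.shape != (params.r,):
            raise ValueError("state resources do not match resource count")
        if np.any(state.resources < 0):
            raise ValueError("resources must be non-negative")


def per_capita_growth(params: ModelParams, state: CommunityState) -> np.ndarray:
    """Per-capita growth dNi/dt / Ni at the given state.

    Evaluated from the per-capita expression directly, so it is finite at
    Ni = 0 (no 0/0).
    """
    _check_state(params, state)
    N = state.abundances
    if isinstance(params, LVParams):
        return params.mu - params.alpha @ N
    if isinstance(params, MacArthurParams):
        return params.w * (params.c @ state.resources) - params.m
    if isinstance(params, StompParams):
        integral = _stomp_depth_integral(params, N)
        return params.phi / params.depth * integral - params.loss
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def resource_dynamics(params: MacArthurParams, state: CommunityState) -> np.ndarray:
    """dR_k/dt: logistic renewal minus mass-action consumption."""
    if not isinstance(params, MacArthurParams):
        raise TypeError("resource_dynamics applies to the MacArthur model only")
    _check_state(params, state)
    R = state.resources
    g = params.resource_growth
    consumption = params.c.T @ state.abundances  # per unit resource
    return g.rate * R * (1.0 - R / g.capacity) - consumption * R


def absorbed_light_profile(params: StompParams, abundances: np.ndarray,
                           depth_point: float) -> np.ndarray:
    """Per-capita absorbed photon flux gamma_i(z) at one depth.

    The incident spectrum is attenuated by Beer-Lambert through the whole
    community plus the background; species i absorbs according to its own
    per-capita absorption spectrum. Integrated over the wavelength grid.
    """
    if not isinstance(params, StompParams):
        raise TypeError("absorbed_light_profile applies to the Stomp model only")
    if not (0.0 <= depth_point <= params.depth):
        raise ValueError("depth_point must lie within [0, depth]")
    N = np.asarray(abundances, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundances must be non-negative")
    atten = N @ params.absorption_spectra + params.background_attenuation
    flux = params.incident_spectrum * np.exp(-atten * depth_point)
    return np.trapezoid(params.absorption_spectra * flux, params.wavelengths, axis=1)


def stomp_growth_extended(params: StompParams, N: np.ndarray) -> np.ndarray:
    """Per-capita growth evaluated without the N >= 0 precondition.

    The analytic expression extends smoothly to mildly negative
    abundances (less attenuation), which is what quasi-Newton root
    finding needs to locate infeasible interior equilibria; the exponent
    is clamped to keep the extension bounded far from the feasible
    region.
    """
    integral = _stomp_depth_integral(params, np.asarray(N, dtype=float))
    return params.phi / params.depth * integral - params.loss


def _stomp_depth_integral(params: StompParams, N: np.ndarray) -> np.ndarray:
    """int_0^depth gamma_i(z) dz by the trapezoid rule on n_depth points."""
    atten = N @ params.absorption_spectra + params.background_attenuation  # (w,)
    z = np.linspace(0.0, params.depth, params.n_depth)
    trans = np.exp(np.clip(-np.outer(z, atten), None, 50.0))  # (n_depth, w)
    flux = params.incident_spectrum * trans
    # gamma: (n_depth, n)
    gamma = np.trapezoid(flux[:, None, :] * params.absorption_spectra[None, :, :],
                         params.wavelengths, axis=2)
    return np.trapezoid(gamma, z, axis=0)


# ---------------------------------------------------------------------------
# carrying capacities (monoculture equilibria)
# ---------------------------------------------------------------------------


def carrying_capacity(params: ModelParams, species_index: int) -> float:
    """Monoculture equilibrium abundance of one species.

    Lotka-Volterra: mu_i / alpha_ii in closed form. MacArthur and Stomp:
    the root of the monoculture per-capita growth, found by bracketed
    scalar root finding (growth is monotone decreasing in abundance).
    Returns 0.0 when the species cannot grow from rarity.
    """
    i = int(species_index)
    if not 0 <= i < params.n:
        raise IndexError("species index out of range")
    if isinstance(params, LVParams):
        return float(params.mu[i] / params.alpha[i, i])
    if isinstance(params, MacArthurParams):
        return _macarthur_monoculture(params, i)
    if isinstance(params, StompParams):
        return _stomp_monoculture(params, i)
    raise TypeError(f"unknown model parameters: {type(params)!r}")


def carrying_capacities(params: ModelParams) -> np.ndarray:
    return np.array([carrying_capacity(params, i) for i in range(params.n)])


def _macarthur_monoculture(params: MacArthurParams, i: int) -> float:
    """Monoculture equilibrium of consumer i.

    At equilibrium each resource with positive density satisfies
    r_k (1 - R_k/K_k) = c_ik N, i.e. R_k(N) = K_k max(0, 1 - c_ik N / r_k),
    which makes the consumer's per-capita growth a monotone decreasing
    piecewise-linear function of N; solved by brentq.
    """
    c = params.c[i]
    g = params.resource_growth

    def growth(N: float) -> float:
        R = g.capacity * np.clip(1.0 - c * N / g.rate, 0.0, None)
        return params.w[i] * float(c @ R) - params.m[i]

    if growth(0.0) <= 0:
        return 0.0
    hi = float(np.max(g.rate[c > 0] / c[c > 0])) * 1.001
    if growth(hi) >= 0:  # cannot happen for positive m, but guard
        return hi
    return float(brentq(growth, 0.0, hi, xtol=1e-12, rtol=1e-14))


def _stomp_monoculture(params: StompParams, i: int) -> float:
    """Monoculture equilibrium of phytoplankton species i by brentq.

    Per-capita growth is monotone decreasing in N (more self-shading),
    so a sign change brackets the unique root.
    """
    sub = subset(params, np.arange(params.n) == i)

    def growth(N: float) -> float:
        return float(per_capita_growth(sub, CommunityState(np.array([N])))[0])

    if growth(0.0) <= 0:
        return 0.0
    hi = 1.0
    for _ in range(80):
        if growth(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("monoculture equilibrium did not bracket")
    return float(brentq(growth, 0.0, hi, xtol=1e-12, rtol=1e-14))
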