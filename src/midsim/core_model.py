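"""Domain types and rate equations of the community-succession model.

The model couples ``M`` microbial species to ``m`` shared substrates.  Each
species grows on the substrate pool through Monod (saturating) kinetics and
loses biomass to intraspecific competition, interspecific (Lotka-Volterra)
competition and basal metabolism.  Substrates are produced by microbial
decomposition (saturating in abundance) and consumed in proportion to
realized growth.  Environmental disturbance enters as five additive
Gaussian perturbation channels applied to the kinetic parameters
(growth rate, intra- and interspecific competition coefficients,
substrate-production rate and substrate-consumption coefficient).

State variables:

* ``x_i`` — abundance of species ``i`` (dimensionless abundance units,
  nominally log10 CFU/ml);
* ``S_k`` — amount of substrate ``k`` in mg.

All rates are per hour.  The functions in this module are pure: they
evaluate instantaneous rates for a given state and a given realization of
the disturbance channels, without advancing time.

A disturbed effective parameter (e.g. ``mu + eps1``) may be floored at
zero before use ("clamped"); the per-channel policy is set by the
``clamp`` argument (see :data:`CLAMP_POLICIES`).  The default
``"stability"`` policy floors the competition, production and consumption
channels — whose sign reversal would make the dynamics non-dissipative
(negative quadratic self-limitation grows without bound) — while leaving
the growth channel free to reverse sign: a strongly negative growth draw
is a transient die-off event, the direct dynamical footprint of a
radiation burst.  Nonnegativity of the state itself is the integrator's
job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesParams",
    "SubstrateParams",
    "CommunitySpec",
    "NoiseSample",
    "StateDerivative",
    "DimensionError",
    "growth_rates",
    "intraspecific_rates",
    "interspecific_rates",
    "metabolism_rates",
    "substrate_production_rates",
    "substrate_consumption_rates",
    "rate_components",
    "derivatives",
]


class DimensionError(ValueError):
    """State or parameter vectors do not match the community's (M, m)."""


@dataclass(frozen=True)
class SpeciesParams:
    """Parameter vector of one species.

    Attributes
    ----------
    mu : float
        Specific growth rate, 1/h.
    alpha : float
        Intraspecific competition coefficient, 1/(abundance*h).
    beta : np.ndarray
        Interspecific competition coefficients ``beta[j]`` of species *j*
        on this species, length M; the own-index entry is 0 by convention.
    K : np.ndarray
        Half-saturation constants for growth on each substrate, mg;
        length m.
    d : float
        Metabolism (basal loss) coefficient, 1/h.
    c : float
        Maximum substrate-production rate, mg/h.
    gamma : float
        Substrate consumption per unit of realized growth, mg/abundance.
    Z : float
        Half-saturation abundance for substrate production.
    """

    mu: float
    alpha: float
    beta: np.ndarray
    K: np.ndarray
    d: float
    c: float
    gamma: float
    Z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        for name in ("mu", "alpha", "d", "c", "gamma", "Z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if np.any(self.beta < 0) or np.any(self.K < 0):
            raise ValueError("beta and K must be elementwise nonnegative")


@dataclass(frozen=True)
class SubstrateParams:
    """One substrate's share of total production (r) and consumption (h)."""

    r: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("r and h must lie in [0, 1]")


@dataclass
class CommunitySpec:
    """A ready-to-simulate community of M species and m substrates.

    Parameters are stored as dense arrays for fast rate evaluation:
    ``mu, alpha, d, c, gamma, Z`` have shape (M,), ``beta`` is (M, M) with
    zero diagonal, ``K`` is (M, m), and ``r, h`` have shape (m,) and each
    sum to 1 across the community.  ``x0`` (M,) and ``S0`` (m,) are the
    initial abundances and substrate amounts.
    """

    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    K: np.ndarray
    d: np.ndarray
    c: np.ndarray
    gamma: np.ndarray
    Z: np.ndarray
    r: np.ndarray
    h: np.ndarray
    x0: np.ndarray
    S0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu", "alpha", "beta", "K", "d", "c", "gamma", "Z",
                     "r", "h", "x0", "S0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        M, m = self.M, self.m
        if M < 1 or m < 1:
            raise ValueError("need at least one species and one substrate")
        if self.beta.shape != (M, M):
            raise DimensionError(f"beta must be ({M}, {M}), got {self.beta.shape}")
        if self.K.shape != (M, m):
            raise DimensionError(f"K must be ({M}, {m}), got {self.K.shape}")
        for name, n in (("alpha", M), ("d", M), ("c", M), ("gamma", M),
                        ("Z", M), ("r", m), ("h", m), ("x0", M), ("S0", m)):
            if getattr(self, name).shape != (n,):
                raise DimensionError(f"{name} must have length {n}")
        for name in ("mu", "alpha", "beta", "K", "d", "c", "gamma", "Z",
                     "r", "h", "x0", "S0"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be elementwise nonnegative")
        if np.any(self.r > 1) or np.any(self.h > 1):
            raise ValueError("r and h are pool shares and must be <= 1")

    @property
    def M(self) -> int:
        return int(self.mu.shape[0])

    @property
    def m(self) -> int:
        return int(self.r.shape[0])

    @classmethod
    def from_params(
        cls,
        species: list[SpeciesParams],
        substrates: list[SubstrateParams],
        x0,
        S0,
    ) -> "CommunitySpec":
        """Assemble a community from per-entity parameter objects."""
        return cls(
            mu=[sp.mu for sp in species],
            alpha=[sp.alpha for sp in species],
            beta=np.array([sp.beta for sp in species]),
            K=np.array([sp.K for sp in species]),
            d=[sp.d for sp in species],
            c=[sp.c for sp in species],
            gamma=[sp.gamma for sp in species],
            Z=[sp.Z for sp in species],
            r=[su.r for su in substrates],
            h=[su.h for su in substrates],
            x0=x0,
            S0=S0,
        )

    @property
    def species(self) -> list[SpeciesParams]:
        """Per-species parameter objects (view for inspection, not speed)."""
        return [
            SpeciesParams(
                mu=self.mu[i], alpha=self.alpha[i], beta=self.beta[i].copy(),
                K=self.K[i].copy(), d=self.d[i], c=self.c[i],
                gamma=self.gamma[i], Z=self.Z[i],
            )
            for i in range(self.M)
        ]

    @property
    def substrates(self) -> list[SubstrateParams]:
        return [SubstrateParams(r=self.r[k], h=self.h[k]) for k in range(self.m)]


@dataclass
class NoiseSample:
    """One realization of the five disturbance channels at a time step.

    ``eps1`` (growth), ``eps2`` (intraspecific), ``eps4`` (production) and
    ``eps5`` (consumption) are per-species vectors of length M; ``eps3``
    (interspecific) is an (M, M) matrix, one draw per ordered species pair,
    with zero diagonal.  Units match the parameter each channel perturbs.
    """

    eps1: np.ndarray
    eps2: np.ndarray
    eps3: np.ndarray
    eps4: np.ndarray
    eps5: np.ndarray

    @classmethod
    def zeros(cls, M: int) -> "NoiseSample":
        z = np.zeros(M)
        return cls(eps1=z, eps2=z.copy(), eps3=np.zeros((M, M)),
                   eps4=z.copy(), eps5=z.copy())


@dataclass
class StateDerivative:
    """Time derivatives dx/dt (length M, 1/h) and dS/dt (length m, mg/h)."""

    dx: np.ndarray
    dS: np.ndarray


def _check_state(x, S, community: CommunitySpec):
    x = np.asarray(x, dtype=float)
    S = np.asarray(S, dtype=float)
    if x.shape != (community.M,):
        raise DimensionError(f"x must have length {community.M}, got {x.shape}")
    if S.shape != (community.m,):
        raise DimensionError(f"S must have length {community.m}, got {S.shape}")
    if np.any(x < 0) or np.any(S < 0):
        raise ValueError("state must be elementwise nonnegative")
    return x, S


def _monod_sum(S: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Sum over substrates of S_k / (K_ik + S_k); shape (M,).

    The 0/0 case (S_k = K_ik = 0) is defined as 0: an absent substrate
    contributes no growth.
    """
    denom = K + S[np.newaxis, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, S[np.newaxis, :] / denom, 0.0)
    return frac.sum(axis=1)


def _eff(param: np.ndarray, eps: np.ndarray, clamp: bool) -> np.ndarray:
    """Disturbed effective parameter, optionally floored at zero."""
    out = param + eps
    return np.maximum(out, 0.0) if clamp else out


#: per-channel clamp policies: which of the five disturbance channels have
#: their effective parameter floored at zero.  "stability" flooring the
#: quadratic-competition and substrate channels (2-5) keeps the system
#: dissipative while leaving the growth channel free to reverse sign
#: (a die-off event); "all" floors every channel; "none" floors none.
CLAMP_POLICIES = {
    "none": (False, False, False, False, False),
    "all": (True, True, True, True, True),
    "stability": (False, True, True, True, True),
}


def resolve_clamp(clamp) -> tuple[bool, bool, bool, bool, bool]:
    """Normalize a clamp policy (name, bool, or 5-tuple) to per-channel flags."""
    if isinstance(clamp, str):
        try:
            return CLAMP_POLICIES[clamp]
        except KeyError:
            raise ValueError(f"unknown clamp policy {clamp!r}") from None
    if isinstance(clamp, bool):
        return CLAMP_POLICIES["all" if clamp else "none"]
    flags = tuple(bool(c) for c in clamp)
    if len(flags) != 5:
        raise ValueError("per-channel clamp needs five flags")
    return flags


def growth_rates(x, S, community: CommunitySpec, noise: NoiseSample,
                 clamp: bool = False) -> np.ndarray:
    """Monod growth rate v_b of each species on the shared substrate pool.

    v_bi = (mu_i + eps1_i) * x_i * sum_k S_k / (K_ik + S_k)
    """
    x, S = _check_state(x, S, community)
    c1 = resolve_clamp(clamp)[0]
    return _eff(community.mu, noise.eps1, c1) * x * _monod_sum(S, community.K)


def intraspecific_rates(x, community: CommunitySpec, noise: NoiseSample,
                        clamp: bool = False) -> np.ndarray:
    """Intraspecific competition loss v_ai = (alpha_i + eps2_i) * x_i^2."""
    x, _ = _check_state(x, community.S0, community)
    return _eff(community.alpha, noise.eps2, resolve_clamp(clamp)[1]) * x**2


def interspecific_rates(x, community: CommunitySpec, noise: NoiseSample,
                        clamp: bool = False) -> np.ndarray:
    """Lotka-Volterra interspecific loss v_ei = sum_{j!=i} (beta_ij+eps3_ij) x_i x_j."""
    x, _ = _check_state(x, community.S0, community)
    beta_eff = _eff(community.beta, noise.eps3, resolve_clamp(clamp)[2]).copy()
    np.fill_diagonal(beta_eff, 0.0)  # beta_ii = 0 by convention
    return x * (beta_eff @ x)


def metabolism_rates(x, community: CommunitySpec) -> np.ndarray:
    """Basal metabolic loss v_di = d_i * x_i (undisturbed)."""
    x, _ = _check_state(x, community.S0, community)
    return community.d * x


def _production_total(x: np.ndarray, community: CommunitySpec,
                      noise: NoiseSample, clamp=False) -> float:
    c_eff = _eff(community.c, noise.eps4, resolve_clamp(clamp)[3])
    denom = community.Z + x
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(denom > 0, x / denom, 0.0)
    return float(np.sum(c_eff * sat))


def substrate_production_rates(x, community: CommunitySpec,
                               noise: NoiseSample,
                               clamp: bool = False) -> np.ndarray:
    """Production rate of each substrate by microbial decomposition.

    v_pk = r_k * sum_i (c_i + eps4_i) * x_i / (Z_i + x_i)

    All species contribute to a common production pool which substrate k
    receives in proportion r_k.
    """
    x, _ = _check_state(x, community.S0, community)
    return community.r * _production_total(x, community, noise, clamp)


def substrate_consumption_rates(x, S, community: CommunitySpec,
                                noise: NoiseSample,
                                clamp: bool = False) -> np.ndarray:
    """Consumption rate of each substrate by the growing community.

    v_ck = h_k * sum_i (gamma_i + eps5_i) * v_bi, where v_bi uses the
    same eps1 realization as :func:`growth_rates` at this step (the growth
    disturbance propagates into consumption).
    """
    x, S = _check_state(x, S, community)
    v_b = growth_rates(x, S, community, noise, clamp)
    gamma_eff = _eff(community.gamma, noise.eps5, resolve_clamp(clamp)[4])
    return community.h * float(np.sum(gamma_eff * v_b))


def rate_components(x, S, community: CommunitySpec, noise: NoiseSample,
                    clamp: bool = False):
    """Per-capita growth/loss rates and substrate production/consumption.

    Returns ``(growth_pc, loss_pc, v_p, v_c)`` where ``growth_pc`` is the
    per-capita Monod growth rate (v_bi / x_i, defined for x_i = 0),
    ``loss_pc`` the per-capita loss rate from intra-/interspecific
    competition and metabolism, and ``v_p``, ``v_c`` the substrate
    production and consumption rate vectors.  The state derivatives are
    dx = (growth_pc - loss_pc) * x and dS = v_p - v_c; integrators use
    the split form for positivity-preserving stepping.
    """
    x, S = _check_state(x, S, community)
    flags = resolve_clamp(clamp)
    growth_pc = _eff(community.mu, noise.eps1, flags[0]) * _monod_sum(S, community.K)
    beta_eff = _eff(community.beta, noise.eps3, flags[2]).copy()
    np.fill_diagonal(beta_eff, 0.0)
    loss_pc = (_eff(community.alpha, noise.eps2, flags[1]) * x
               + beta_eff @ x + community.d)
    v_b = growth_pc * x
    gamma_eff = _eff(community.gamma, noise.eps5, flags[4])
    v_p = community.r * _production_total(x, community, noise, flags[3])
    v_c = community.h * float(np.sum(gamma_eff * v_b))
    return growth_pc, loss_pc, v_p, v_c


def derivatives(x, S, community: CommunitySpec, noise: NoiseSample,
                clamp: bool = False) -> StateDerivative:
    """Assembled state derivatives of the coupled species/substrate system.

    dx_i/dt = v_bi - v_ai - v_ei - v_di
    dS_k/dt = v_pk - v_ck
    """
    growth_pc, loss_pc, v_p, v_c = rate_components(x, S, community, noise,
                                                   clamp)
    x = np.asarray(x, dtype=float)
    dx = (growth_pc - loss_pc) * x
    dS = v_p - v_c
    if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dS))):
        raise FloatingPointError("non-finite derivative encountered")
    return StateDerivative(dx=dx, dS=dS)
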