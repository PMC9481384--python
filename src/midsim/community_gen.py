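"""Random community generation from kinetic-parameter intervals.

Species and substrates are "computer-generated": every kinetic parameter is
drawn uniformly and independently from a fixed interval, so a community is
fully specified by its dimensions (M species, m substrates), the interval
table and an RNG seed.  The default intervals are the model's reference
parameterization (growth rates of 0.24-1.36 per hour, competition
coefficients up to 1, half-saturation constants around 1.5e5 mg, etc.).

Substrate production/consumption shares r_k and h_k are drawn from
(0, 0.80) per substrate and then renormalized to sum to 1 across the
community, preserving their relative spread while keeping the "share of a
common pool" semantics the rate equations require.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .core_model import CommunitySpec

__all__ = ["ParameterIntervals", "sample_community", "validate_community",
           "community_to_json", "community_from_json"]

Interval = tuple[float, float]


@dataclass(frozen=True)
class ParameterIntervals:
    """(low, high) sampling interval per kinetic parameter.

    Defaults are the reference table: rates in 1/h, c in mg/h, K in mg,
    Z in abundance units, r/h as raw shares before normalization.
    ``x0`` and ``S0_each`` set the initial conditions: inocula are drawn
    uniformly from ``x0`` per species (small relative to the carrying
    capacities the competition coefficients imply, so succession starts
    from colonization rather than overshoot), and every substrate starts
    at ``S0_each`` mg, roughly 7% of the half-saturation scale — enough
    that the faster-growing half of the species pool has positive net
    growth at the outset.
    """

    mu: Interval = (0.24, 1.36)
    alpha: Interval = (0.05, 1.0)
    beta: Interval = (0.16, 1.0)
    c: Interval = (136.23, 518.76)
    gamma: Interval = (3.32, 12.55)
    K: Interval = (1.23e5, 1.82e5)
    d: Interval = (0.03, 0.58)
    Z: Interval = (42.0, 177.0)
    r: Interval = (0.0, 0.80)
    h: Interval = (0.0, 0.80)
    x0: Interval = (0.01, 0.1)
    S0_each: float = 1.0e4

    def __post_init__(self) -> None:
        for name in ("mu", "alpha", "beta", "c", "gamma", "K", "d", "Z",
                     "r", "h", "x0"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"interval {name}=({lo}, {hi}) invalid")
        if self.S0_each < 0:
            raise ValueError("S0_each must be nonnegative")


def sample_community(M: int, m: int,
                     intervals: ParameterIntervals | None = None,
                     rng: np.random.Generator | int | None = None) -> CommunitySpec:
    """Draw a full community parameterization.

    Parameters
    ----------
    M, m : int
        Species and substrate counts (the reference scenario uses
        20 <= M <= 50, 5 <= m <= 15 with M > m, but any M, m >= 1 is
        accepted).
    intervals : ParameterIntervals, optional
        Sampling intervals; defaults to the reference table.
    rng : numpy Generator or seed
        Source of randomness.

    Draw order is fixed (mu, alpha, beta row-major, K row-major, d, c,
    gamma, Z, r, h, x0) so a seed pins the community bit-for-bit.
    """
    if M < 1 or m < 1:
        raise ValueError("M and m must be >= 1")
    iv = intervals or ParameterIntervals()
    rng = np.random.default_rng(rng)

    def u(bounds: Interval, size) -> np.ndarray:
        return rng.uniform(bounds[0], bounds[1], size=size)

    beta = u(iv.beta, (M, M))
    np.fill_diagonal(beta, 0.0)
    r = u(iv.r, m)
    h = u(iv.h, m)
    # shares of a common pool: renormalize to sum to 1
    r = r / r.sum()
    h = h / h.sum()
    return CommunitySpec(
        mu=u(iv.mu, M),
        alpha=u(iv.alpha, M),
        beta=beta,
        K=u(iv.K, (M, m)),
        d=u(iv.d, M),
        c=u(iv.c, M),
        gamma=u(iv.gamma, M),
        Z=u(iv.Z, M),
        r=r,
        h=h,
        x0=u(iv.x0, M),
        S0=np.full(m, iv.S0_each),
    )


def validate_community(spec: CommunitySpec,
                       intervals: ParameterIntervals | None = None) -> list[str]:
    """Report every parameter outside its interval or violating invariants.

    Returns a list of human-readable violation strings; empty for any
    output of :func:`sample_community` under the same intervals.
    """
    iv = intervals or ParameterIntervals()
    report: list[str] = []

    def check_vec(name: str, values: np.ndarray, bounds: Interval,
                  label: str = "species") -> None:
        lo, hi = bounds
        for idx in np.flatnonzero((values < lo) | (values > hi)):
            report.append(
                f"{label} {idx}: parameter {name}={values[idx]:.6g} "
                f"outside [{lo:g}, {hi:g}]")

    check_vec("mu", spec.mu, iv.mu)
    check_vec("alpha", spec.alpha, iv.alpha)
    check_vec("d", spec.d, iv.d)
    check_vec("c", spec.c, iv.c)
    check_vec("gamma", spec.gamma, iv.gamma)
    check_vec("Z", spec.Z, iv.Z)
    off_diag = ~np.eye(spec.M, dtype=bool)
    bad_beta = off_diag & ((spec.beta < iv.beta[0]) | (spec.beta > iv.beta[1]))
    for i, j in zip(*np.nonzero(bad_beta)):
        report.append(f"species pair ({i},{j}): beta={spec.beta[i, j]:.6g} "
                      f"outside [{iv.beta[0]:g}, {iv.beta[1]:g}]")
    if np.any(np.diag(spec.beta) != 0):
        report.append("beta diagonal not identically zero")
    bad_K = (spec.K < iv.K[0]) | (spec.K > iv.K[1])
    for i, k in zip(*np.nonzero(bad_K)):
        report.append(f"species {i}, substrate {k}: K={spec.K[i, k]:.6g} "
                      f"outside [{iv.K[0]:g}, {iv.K[1]:g}]")
    for name, vec in (("r", spec.r), ("h", spec.h)):
        if abs(vec.sum() - 1.0) > 1e-12:
            report.append(f"{name} shares sum to {vec.sum():.15g}, not 1")
        if np.any(vec < 0) or np.any(vec > 1):
            report.append(f"{name} shares outside [0, 1]")
    if np.any(spec.x0 < 0):
        report.append("negative initial abundance")
    if np.any(spec.S0 < 0):
        report.append("negative initial substrate")
    return report


_ARRAY_FIELDS = ("mu", "alpha", "beta", "K", "d", "c", "gamma", "Z",
                 "r", "h", "x0", "S0")


def community_to_json(spec: CommunitySpec, path) -> None:
    """Write a community to JSON at full float precision for exact re-runs."""
    payload = {name: getattr(spec, name).tolist() for name in _ARRAY_FIELDS}
    payload["M"] = spec.M
    payload["m"] = spec.m
    with open(path, "w") as fh:
        json.dump(payload, fh)


def community_from_json(path) -> CommunitySpec:
    with open(path) as fh:
        payload = json.load(fh)
    return CommunitySpec(**{name: np.asarray(payload[name])
                            for name in _ARRAY_FIELDS})
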