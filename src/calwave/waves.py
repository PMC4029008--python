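"""Dimensionless wave parameters and regime classification for Ca2+ waves.

Calcium-induced calcium release fronts are characterized by two dimensionless
numbers: Gamma, the ratio of the concentration liberated per release event to
the firing threshold above basal, which controls how easily a wave ignites and
how fast it travels; and beta, which compares the diffusive coupling between
release sites to the release kinetics and decides whether the front is
saltatory (site-to-site hops limited by diffusion, v ~ D/d) or continuous
(release-limited Luther front, v ~ sqrt(D/tau)).

Units are fixed package-wide: lengths in um, times in s, concentrations in uM.

A note on the beta convention: the compact definition beta = (D/tau)/d^2 is
inconsistent with every worked numerical example in the source analysis
(e.g. D = 190 um^2/s, tau = 0.04 s, d = 2 um is quoted as beta = 1.9, which is
D*tau/d^2, not (D/tau)/d^2 = 1187.5). The default convention here is therefore
``worked_example`` (beta = D*tau/d^2); the literal form remains available as
``as_printed`` and is never silently substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "DimensionlessState",
    "WaveClassification",
    "RegimeConfig",
    "compute_gamma",
    "compute_beta",
    "saltatory_velocity",
    "continuous_velocity",
    "diffusion_from_velocity",
    "gamma_from_velocity",
    "classify_regime",
]

BetaConvention = Literal["worked_example", "as_printed"]
Regime = Literal["saltatory", "continuous", "mixed", "failure"]


@dataclass(frozen=True)
class DimensionlessState:
    """Dimensionless control parameters of a fire-diffuse-fire front."""

    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class WaveClassification:
    """Propagation regime plus the closed-form model velocity.

    ``geometry_factor`` stands in for the unspecified inverse functions
    g^-1 / f^-1 that multiply the leading-order velocity laws; it defaults
    to 1, matching the worked examples (v ~ D/d and v ~ sqrt(D/tau)).
    ``model_velocity`` is None when the regime is ``failure``.
    """

    regime: Regime
    model_velocity: float | None
    geometry_factor: float = 1.0


@dataclass(frozen=True)
class RegimeConfig:
    """Thresholds for regime classification.

    beta_lo/beta_hi bracket the saltatory/continuous transition ("beta >> 1"
    is only qualitative in the source analysis, so these are configurable);
    conduction fails outright for small D in the saltatory mode, large site
    spacing, or Gamma outside a physiological band.
    """

    beta_lo: float = 0.5
    beta_hi: float = 1.0
    gamma_min: float = 0.1
    gamma_max: float = 1000.0
    d_max: float = 3.0           # um; waves fail for d > 3 um
    D_min_saltatory: float = 10.0  # um^2/s; saltatory conduction fails below


def compute_gamma(sigma_conc: float, ca_threshold: float, ca_basal: float) -> float:
    """Gamma = (sigma/d^3) / ([Ca2+]_T - [Ca2+]_b).

    Parameters
    ----------
    sigma_conc:
        Concentration released per site event, sigma/d^3, in uM.
    ca_threshold, ca_basal:
        Firing threshold and basal cytosolic Ca2+, in uM.
    """
    if ca_threshold <= ca_basal:
        raise ValueError(
            f"ca_threshold ({ca_threshold}) must exceed ca_basal ({ca_basal})"
        )
    if sigma_conc < 0:
        raise ValueError("sigma_conc must be >= 0")
    return sigma_conc / (ca_threshold - ca_basal)


def compute_beta(
    D: float, tau: float, d: float, convention: BetaConvention = "worked_example"
) -> float:
    """Dimensionless propagation-mode parameter beta.

    ``worked_example`` (default): beta = D*tau/d^2, the form that reproduces
    all quoted numerical examples. ``as_printed``: beta = (D/tau)/d^2, the
    literal compact definition. See the module docstring for why both exist.
    """
    if D <= 0 or tau <= 0 or d <= 0:
        raise ValueError("D, tau and d must all be > 0")
    if convention == "worked_example":
        return D * tau / d**2
    if convention == "as_printed":
        return (D / tau) / d**2
    raise ValueError(f"unknown beta convention: {convention!r}")


def saltatory_velocity(D: float, d: float, geometry_factor: float = 1.0) -> float:
    """Saltatory front speed v = (D/d) * geometry_factor (linear in D)."""
    if d <= 0:
        raise ValueError("d must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    return (D / d) * geometry_factor


def continuous_velocity(D: float, tau: float, gamma_factor: float = 1.0) -> float:
    """Continuous (Luther) front speed v = gamma_factor * sqrt(D/tau).

    With gamma_factor = Gamma^(1/2) this is the Luther law v = (Gamma*D/tau)^(1/2);
    the default 1 matches the worked example v ~ sqrt(D/tau).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    return gamma_factor * math.sqrt(D / tau)


def diffusion_from_velocity(
    v: float,
    mode: Literal["saltatory", "continuous"],
    *,
    d: float | None = None,
    tau: float | None = None,
    gamma: float = 1.0,
    geometry_factor: float = 1.0,
) -> float:
    """Invert the velocity laws for the diffusion coefficient.

    saltatory:  D_S = v*d*g/Gamma
    continuous: D_C = tau*(v*f/Gamma)^2

    with g, f taken as ``geometry_factor``. These are exact algebraic
    inverses of :func:`saltatory_velocity` / :func:`continuous_velocity`
    when gamma/geometry_factor collapse consistently.
    """
    if v < 0:
        raise ValueError("v must be >= 0")
    if gamma == 0:
        raise ValueError("gamma must be nonzero")
    if mode == "saltatory":
        if d is None or d <= 0:
            raise ValueError("saltatory inversion requires d > 0")
        return v * d * geometry_factor / gamma
    if mode == "continuous":
        if tau is None or tau <= 0:
            raise ValueError("continuous inversion requires tau > 0")
        return tau * (v * geometry_factor / gamma) ** 2
    raise ValueError(f"unknown mode: {mode!r}")


def gamma_from_velocity(
    v: float,
    mode: Literal["saltatory", "continuous"],
    beta: float,
    *,
    d: float | None = None,
    tau: float | None = None,
    geometry_factor: float = 1.0,
) -> float:
    """Gamma index recovered from a measured front speed.

    Gamma_S = tau*v*g/(beta*d)   (saltatory)
    Gamma_C = v*f/(beta^(1/2)*d) (continuous)

    Convention caveat (documented, not reconciled): substituting the
    saltatory law v = (D/d)*Gamma/g recovers Gamma exactly when beta follows
    the ``worked_example`` convention, whereas substituting the Luther law
    v = Gamma^(1/2)*sqrt(D/tau) into Gamma_C recovers Gamma^(1/2) exactly
    under the ``as_printed`` convention (and Gamma^(1/2)/tau under
    ``worked_example``).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if v < 0:
        raise ValueError("v must be >= 0")
    if d is None or d <= 0:
        raise ValueError("d > 0 is required")
    if mode == "saltatory":
        if tau is None or tau <= 0:
            raise ValueError("saltatory Gamma recovery requires tau > 0")
        return tau * v * geometry_factor / (beta * d)
    if mode == "continuous":
        return v * geometry_factor / (math.sqrt(beta) * d)
    raise ValueError(f"unknown mode: {mode!r}")


def classify_regime(
    state: DimensionlessState,
    D: float,
    d: float,
    config: RegimeConfig | None = None,
    geometry_factor: float = 1.0,
) -> WaveClassification:
    """Classify a parameter point as saltatory / continuous / mixed / failure.

    Failure wins over mode: conduction fails when the point would be
    saltatory but D < D_min_saltatory, when d > d_max, or when Gamma lies
    outside the configured band. Otherwise beta >= beta_hi is continuous,
    beta <= beta_lo saltatory, anything between mixed.

    The model velocity uses the leading-order laws; for the continuous
    branch tau is recovered from beta via the worked-example convention
    (tau = beta*d^2/D), so classify + velocity need only (Gamma, beta, D, d).
    """
    cfg = config or RegimeConfig()
    beta, gamma = state.beta, state.gamma

    would_be_saltatory = beta <= cfg.beta_lo
    failed = (
        (would_be_saltatory and D < cfg.D_min_saltatory)
        or d > cfg.d_max
        or not (cfg.gamma_min <= gamma <= cfg.gamma_max)
    )
    if failed:
        return WaveClassification("failure", None, geometry_factor)

    if beta >= cfg.beta_hi:
        tau = beta * d**2 / D  # worked-example convention inverted
        v = continuous_velocity(D, tau, geometry_factor)
        return WaveClassification("continuous", v, geometry_factor)
    if would_be_saltatory:
        v = saltatory_velocity(D, d, geometry_factor)
        return WaveClassification("saltatory", v, geometry_factor)
    # between the thresholds: mixed front; report the slower (saltatory) law
    v = saltatory_velocity(D, d, geometry_factor)
    return WaveClassification("mixed", v, geometry_factor)
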