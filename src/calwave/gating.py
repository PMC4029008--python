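"""IP3 receptor gating: open probability and the flux-based Gamma.

The IP3R channel opens on co-binding of IP3 and Ca2+; cytosolic Ca2+ both
activates (high-affinity site) and inhibits (low-affinity site) the channel,
producing the classic bell-shaped open probability versus Ca2+ at fixed IP3.
The steady-state open probability used here is the cube of a single-subunit
occupancy factor (three of four monomers must be activated):

    p_O = [ ca*ip3*K_CaI / ((ca*ip3 + ip3*K_CaI + K_IP3_1*K_CaI
                              + ca*K_IP3_2) * (ca + K_CaA)) ]^3

The flux-based Gamma extends the release-only definition with re-uptake and
buffering sinks:

    Gamma = (Phi1 - Phi2 - Phi3) / ([Ca2+]_T - [Ca2+]_b)

    Phi1 = C_ER_C*(F_MO*p_O + F_L)*(ca_ER - ca_C)   release + leak
    Phi2 = F_U*ca_C^2/(ca_C^2 + A^2)                ER re-uptake (Hill n=2)
    Phi3 = K_B*ca_C*B_C                             cytosolic buffering

A negative Gamma (sinks dominate release) is returned as-is; downstream
classification treats it as conduction failure, since a wave cannot ignite.

Default constants are repo defaults with DeYoung-Keizer-style magnitudes,
NOT fitted values; supply measured constants for scientific use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GatingConstants",
    "FluxParameters",
    "open_probability",
    "phi_terms",
    "extended_gamma",
]


@dataclass(frozen=True)
class GatingConstants:
    """Dissociation constants of the IP3R gating model, all in uM.

    K_CaI : Ca2+ inhibition (low-affinity site)
    K_IP3_1, K_IP3_2 : IP3 binding
    K_CaA : Ca2+ activation (high-affinity site)

    Defaults are repo defaults (DeYoung-Keizer-style magnitudes).
    """

    K_CaI: float = 1.05
    K_IP3_1: float = 0.13
    K_IP3_2: float = 0.94
    K_CaA: float = 0.082

    def __post_init__(self) -> None:
        for name in ("K_CaI", "K_IP3_1", "K_IP3_2", "K_CaA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FluxParameters:
    """Release / re-uptake / buffering parameters of the flux-based Gamma.

    C_ER_C : ER/cytosol volume-ratio factor (dimensionless)
    F_MO : maximum outward IP3R flux scale, uM/s
    F_L : leak flux scale, uM/s
    F_U : maximum ER uptake, uM/s
    A : uptake-activation constant, uM
    K_B : buffer binding constant, 1/(uM*s)
    ca_ER, ca_C : free ER and cytosolic Ca2+, uM
    B_C : free buffer concentration, uM

    Defaults are repo defaults (DeYoung-Keizer-style magnitudes).
    """

    C_ER_C: float = 0.185
    F_MO: float = 6.0
    F_L: float = 0.11
    F_U: float = 0.9
    A: float = 0.1
    K_B: float = 5.0
    ca_ER: float = 250.0
    ca_C: float = 0.1
    B_C: float = 20.0

    def __post_init__(self) -> None:
        for name in ("C_ER_C", "F_MO", "F_L", "F_U", "A", "K_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ca_ER", "ca_C", "B_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")


def open_probability(ca, ip3, k: GatingConstants | None = None):
    """Steady-state IP3R open probability p_O in [0, 1].

    Accepts scalars or numpy arrays (broadcast). p_O = 0 whenever either
    ligand is absent, and the denominator strictly dominates the numerator
    for positive constants, so p_O < 1 always.
    """
    k = k or GatingConstants()
    ca = np.asarray(ca, dtype=float)
    ip3 = np.asarray(ip3, dtype=float)
    if np.any(ca < 0) or np.any(ip3 < 0):
        raise ValueError("ca and ip3 must be >= 0")
    num = ca * ip3 * k.K_CaI
    den = (ca * ip3 + ip3 * k.K_CaI + k.K_IP3_1 * k.K_CaI + ca * k.K_IP3_2) * (
        ca + k.K_CaA
    )
    frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    p = frac**3
    if p.ndim == 0:
        return float(p)
    return p


def phi_terms(f: FluxParameters, p_O: float) -> tuple[float, float, float]:
    """Release, re-uptake and buffering fluxes (Phi1, Phi2, Phi3)."""
    if not 0.0 <= p_O <= 1.0:
        raise ValueError("p_O must lie in [0, 1]")
    phi1 = f.C_ER_C * (f.F_MO * p_O + f.F_L) * (f.ca_ER - f.ca_C)
    if f.ca_C == 0.0 and f.A == 0.0:
        phi2 = 0.0
    else:
        phi2 = f.F_U * f.ca_C**2 / (f.ca_C**2 + f.A**2)
    phi3 = f.K_B * f.ca_C * f.B_C
    return (phi1, phi2, phi3)


def extended_gamma(
    f: FluxParameters,
    p_O: float,
    ca_threshold: float,
    ca_basal: float,
) -> float:
    """Flux-based Gamma = (Phi1 - Phi2 - Phi3) / ([Ca2+]_T - [Ca2+]_b).

    The threshold-activation denominator is taken as the threshold minus
    basal concentration difference (the source analysis equates its
    windowed notation to exactly this difference; that identification is an
    assumption documented in the methods note). May be negative when
    re-uptake plus buffering dominate release; negative values signal that
    no wave can ignite and map to regime "failure" downstream.
    """
    if ca_threshold <= ca_basal:
        raise ValueError("ca_threshold must exceed ca_basal")
    phi1, phi2, phi3 = phi_terms(f, p_O)
    return (phi1 - phi2 - phi3) / (ca_threshold - ca_basal)
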