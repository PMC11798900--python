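"""Steady-state C3 and C4 leaf photosynthesis and stomatal CO2 coupling.

The C3 model is the Farquhar / von Caemmerer biochemical skeleton: net
assimilation is the lesser of the Rubisco-limited (Wc) and electron-transport-
limited (Wj) carboxylation rates, discounted for photorespiration and dark
respiration.  The C4 model is the enzyme-limited skeleton of the NADP-ME
carbon-concentrating pathway: assimilation is PEP-carboxylation-limited at
low Ci (steep initial slope Vpmax/Kp) and Rubisco-capacity-limited at high
Ci; bundle-sheath leakiness and mesophyll resistance are treated as
non-limiting, reflecting the CCM's suppression of mesophyll CO2 draw-down.

``couple_diffusion`` closes either demand curve against the stomatal supply
line A = (gs/1.6)(Ca - Ci), the 1.6 being the water:CO2 stomatal diffusivity
ratio.  Kinetic constants are fixed at 25degC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "C3Params",
    "C4Params",
    "AirState",
    "c3_assimilation",
    "c4_assimilation",
    "assimilation",
    "couple_diffusion",
    "DEFAULT_C3",
    "DEFAULT_C4",
    "DEFAULT_AIR",
]

WATER_CO2_DIFFUSIVITY_RATIO = 1.6


@dataclass(frozen=True)
class C3Params:
    """Farquhar-model parameters at 25degC.

    Vcmax, J, Rd in umol m-2 s-1; Kc, gamma_star in umol mol-1; Ko, O in
    mmol mol-1.  J is the electron transport rate at the simulated
    irradiance.  Defaults are representative textbook values for a
    productive C3 grass (Bernacchi-style kinetics), not fits to any dataset.
    """

    Vcmax: float = 60.0
    J: float = 120.0
    Kc: float = 404.9
    Ko: float = 278.4
    O: float = 210.0
    gamma_star: float = 42.75
    Rd: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.Vcmax, self.J, self.Kc, self.Ko, self.O, self.gamma_star, self.Rd)
        if any(v <= 0 for v in vals):
            raise ValueError("all C3 parameters must be positive")
        if not self.gamma_star < self.Kc:
            raise ValueError("gamma_star must be below Kc")


@dataclass(frozen=True)
class C4Params:
    """Enzyme-limited C4 parameters at 25degC (umol m-2 s-1; Kp umol mol-1).

    Vpmax/Kp sets the steep initial slope of the A-Ci response; Vcmax is the
    Rubisco-capacity ceiling reached once the CCM saturates.  Representative
    values for a high-capacity NADP-ME grass (operating A is stomatal-supply
    limited well below the Vcmax ceiling); leakiness hook present but inert.
    """

    Vpmax: float = 120.0
    Kp: float = 80.0
    Vcmax: float = 90.0
    Rd: float = 1.0
    leakiness: float = 0.0  # reserved; not applied

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.Vpmax, self.Kp, self.Vcmax, self.Rd)):
            raise ValueError("all C4 parameters must be positive")


@dataclass(frozen=True)
class AirState:
    """Ambient CO2 (umol mol-1) and atmospheric pressure (kPa)."""

    Ca: float = 400.0
    Patm: float = 101.3

    def __post_init__(self) -> None:
        if self.Ca <= 0 or self.Patm <= 0:
            raise ValueError("Ca and Patm must be positive")


DEFAULT_C3 = C3Params()
DEFAULT_C4 = C4Params()
DEFAULT_AIR = AirState()


def c3_assimilation(Ci: float, p: C3Params = DEFAULT_C3) -> float:
    """Net C3 assimilation (umol m-2 s-1) at intercellular CO2 ``Ci``.

    A = min(Wc, Wj) * max(0, 1 - gamma_star/Ci) - Rd with
    Wc = Vcmax*Ci / (Ci + Kc*(1 + O/Ko)) and Wj = J*Ci / (4*Ci + 8*gamma_star).
    Below the photorespiratory compensation point (Ci <= gamma_star) gross
    assimilation is clamped at zero, so A = -Rd there (including Ci = 0),
    keeping A continuous and non-decreasing in Ci.
    """
    if Ci < 0:
        raise ValueError(f"Ci must be >= 0, got {Ci}")
    if Ci <= p.gamma_star:
        return -p.Rd
    Wc = p.Vcmax * Ci / (Ci + p.Kc * (1.0 + p.O / p.Ko))
    Wj = p.J * Ci / (4.0 * Ci + 8.0 * p.gamma_star)
    return min(Wc, Wj) * (1.0 - p.gamma_star / Ci) - p.Rd


def c4_assimilation(Ci: float, p: C4Params = DEFAULT_C4) -> float:
    """Net C4 assimilation: A = min(Vpmax*Ci/(Ci+Kp), Vcmax) - Rd."""
    if Ci < 0:
        raise ValueError(f"Ci must be >= 0, got {Ci}")
    Vp = p.Vpmax * Ci / (Ci + p.Kp)
    return min(Vp, p.Vcmax) - p.Rd


def assimilation(Ci: float, params, pathway: str) -> float:
    """Dispatch to the C3 or C4 demand curve."""
    if pathway == "C3":
        return c3_assimilation(Ci, params)
    if pathway == "C4":
        return c4_assimilation(Ci, params)
    raise ValueError(f"pathway must be C3 or C4, got {pathway!r}")


def _compensation_ci(params, pathway: str) -> float:
    """Ci at which net assimilation crosses zero (light, with Rd)."""
    f = lambda ci: assimilation(ci, params, pathway)
    lo, hi = 0.0, 1.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if f(hi) < 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10)


def couple_diffusion(
    gs: float,
    air: AirState = DEFAULT_AIR,
    params=DEFAULT_C3,
    pathway: str = "C3",
    tol: float = 1e-10,
) -> dict:
    """Intersect the A(Ci) demand curve with the stomatal CO2 supply line.

    Supply: A = (gs / 1.6) * (Ca - Ci) with gs the stomatal conductance to
    water vapor (mol m-2 s-1) and Ca, Ci in umol mol-1, giving A in
    umol m-2 s-1.  Returns ``{"A", "Ci"}`` at the unique intersection; the
    residual |A_demand - A_supply| is below 1e-8.

    gs = 0 closes the stomata: no net CO2 flux is possible, so A = 0 at the
    internal compensation state (Ci where the demand curve crosses zero).
    """
    if gs < 0:
        raise ValueError(f"gs must be >= 0, got {gs}")
    if gs == 0.0:
        ci0 = _compensation_ci(params, pathway)
        return {"A": 0.0, "Ci": float(ci0)}

    g_c = gs / WATER_CO2_DIFFUSIVITY_RATIO

    def resid(ci: float) -> float:
        return assimilation(ci, params, pathway) - g_c * (air.Ca - ci)

    # resid(0) = A(0) - g_c*Ca = -Rd - positive < 0.  If demand at Ca is
    # negative, the root sits above Ca (respiratory CO2 build-up); expand
    # the bracket until the supply deficit changes sign.
    hi = air.Ca
    while resid(hi) < 0:
        hi += air.Ca
        if hi > 100 * air.Ca:
            raise RuntimeError("couple_diffusion: no supply-demand intersection found")
    ci = brentq(resid, 0.0, hi, xtol=tol, rtol=8.9e-16)
    A = assimilation(ci, params, pathway)
    if abs(resid(ci)) > 1e-8:
        raise RuntimeError(
            f"couple_diffusion: residual {resid(ci):.3g} above tolerance"
        )
    return {"A": float(A), "Ci": float(ci)}
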