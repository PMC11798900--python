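"""Quasi-static soil dry-down simulation of the soil-plant-atmosphere path.

At each step the leaf water potential solves the steady-state water balance

    K_leaf(psi_leaf) * (psi_soil - psi_leaf)  =  E(psi_leaf)
    E = gs(psi_leaf) * VPD / Patm   (mol -> mmol m-2 s-1)

where stomatal conductance closes sigmoidally with declining psi_leaf,

    gs = g_max / (1 + exp((psi_gs50 - psi_leaf) / c)),

and leaf hydraulic conductance declines linearly (clamped at a small floor),

    K_leaf = max(K_max + a * psi_leaf, K_floor * K_max),     a > 0.

Transpiration then depletes a finite soil water bucket whose water potential
follows a Campbell power-law retention curve, and the balance is re-solved,
from field capacity until stomatal closure.  Net assimilation at each step
comes from coupling the solved gs to the C3 or C4 demand curve.

Four plant types are simulated at two vapour pressure deficits: reference C3
and C4 grasses, plus "ratio-swap" types in which K_max is rescaled so the
plant carries the other pathway's hydraulic supply per unit stomatal demand
(K_leaf:g_s), isolating the role of hydraulic hyper-efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .photosynthesis import (
    AirState,
    C3Params,
    C4Params,
    couple_diffusion,
)

__all__ = [
    "PlantScenario",
    "Environment",
    "SoilState",
    "DrydownTrajectory",
    "CalibrationError",
    "vpd_from_climate",
    "stomatal_response",
    "kleaf_response",
    "soil_water_potential",
    "theta_from_potential",
    "solve_steady_state",
    "calibrate_conductance",
    "run_dry_down",
    "scenario_suite",
    "default_scenarios",
    "default_environments",
]

MOL_TO_MMOL = 1e3


class CalibrationError(RuntimeError):
    """No conductance scale attains the target operating water potential."""


def vpd_from_climate(T_air: float, RH: float) -> float:
    """Vapour pressure deficit (kPa) from air temperature (degC) and RH.

    Saturation vapour pressure by the Tetens formula
    es = 0.6108 * exp(17.27 T / (T + 237.3)); VPD = es * (1 - RH).
    """
    if not -10.0 <= T_air <= 50.0:
        raise ValueError(f"T_air out of range [-10, 50] degC: {T_air}")
    if not 0.0 <= RH <= 1.0:
        raise ValueError(f"RH must be a fraction in [0, 1]: {RH}")
    es = 0.6108 * math.exp(17.27 * T_air / (T_air + 237.3))
    return es * (1.0 - RH)


@dataclass(frozen=True)
class Environment:
    """Atmospheric driving state; VPD derived from T_air and RH."""

    T_air: float = 20.0
    RH: float = 0.786
    Patm: float = 101.3
    Ca: float = 400.0

    @property
    def vpd(self) -> float:
        return vpd_from_climate(self.T_air, self.RH)

    @property
    def air(self) -> AirState:
        return AirState(Ca=self.Ca, Patm=self.Patm)


@dataclass(frozen=True)
class SoilState:
    """Campbell retention: psi_soil = psi_e * theta_rel^(-b).

    ``bucket_mol`` is the plant-available soil water per unit leaf area at
    field capacity (mol m-2); it sets the dry-down pace, not its endpoint.
    """

    psi_e: float = -0.002
    b: float = 5.0
    bucket_mol: float = 2000.0

    def __post_init__(self) -> None:
        if self.psi_e >= 0 or self.b <= 0 or self.bucket_mol <= 0:
            raise ValueError("need psi_e < 0, b > 0, bucket_mol > 0")


def soil_water_potential(theta_rel: float, soil: SoilState) -> float:
    """Soil water potential (MPa) at relative water content theta_rel."""
    if theta_rel <= 0 or theta_rel > 1:
        raise ValueError(f"theta_rel must be in (0, 1], got {theta_rel}")
    return soil.psi_e * theta_rel ** (-soil.b)


def theta_from_potential(psi_soil: float, soil: SoilState) -> float:
    """Inverse retention curve: theta_rel at a given psi_soil (<= psi_e)."""
    if psi_soil > soil.psi_e:
        raise ValueError("psi_soil cannot exceed the air-entry potential")
    return (psi_soil / soil.psi_e) ** (-1.0 / soil.b)


@dataclass(frozen=True)
class PlantScenario:
    """One simulated plant type.

    g_max (mol m-2 s-1), K_max (mmol m-2 s-1 MPa-1), psi_gs50 (MPa) the
    potential at 50% stomatal closure, c (MPa) the sigmoid steepness,
    vuln_slope (mmol m-2 s-1 MPa-2, stored positive) the linear K_leaf
    decline, K_floor the residual conductance fraction.
    """

    label: str
    pathway: str
    g_max: float
    K_max: float
    psi_gs50: float = -1.5
    c: float = 0.15
    vuln_slope: float = 3.333
    K_floor: float = 0.05
    photo_params: C3Params | C4Params = field(default_factory=C3Params)
    target_psi_leaf: float | None = None

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.K_max <= 0:
            raise ValueError("g_max and K_max must be > 0")
        if self.psi_gs50 >= 0:
            raise ValueError("psi_gs50 must be < 0")
        if self.c <= 0:
            raise ValueError("sigmoid steepness c must be > 0")
        if self.vuln_slope < 0:
            raise ValueError("vulnerability slope is stored positive")
        if not 0.0 <= self.K_floor <= 0.1:
            raise ValueError("K_floor must be in [0, 0.1]")
        if self.pathway not in ("C3", "C4"):
            raise ValueError(f"pathway must be C3 or C4, got {self.pathway!r}")

    @property
    def kleaf_gs_ratio(self) -> float:
        """Hydraulic supply per unit stomatal demand, K_max:g_max."""
        return self.K_max / self.g_max


def stomatal_response(psi_leaf: float, scenario: PlantScenario) -> float:
    """Sigmoidal stomatal closure with declining leaf water potential."""
    if psi_leaf > 0:
        raise ValueError(f"psi_leaf must be <= 0, got {psi_leaf}")
    z = (scenario.psi_gs50 - psi_leaf) / scenario.c
    # exp overflow guard: deep closure underflows to ~0 conductance
    if z > 700:
        return scenario.g_max / (1.0 + math.exp(700.0))
    return scenario.g_max / (1.0 + math.exp(z))


def kleaf_response(psi_leaf: float, scenario: PlantScenario) -> float:
    """Linear K_leaf decline clamped at the residual floor."""
    if psi_leaf > 0:
        raise ValueError(f"psi_leaf must be <= 0, got {psi_leaf}")
    return max(
        scenario.K_max - scenario.vuln_slope * abs(psi_leaf),
        scenario.K_floor * scenario.K_max,
    )


def _water_balance_residual(
    psi_leaf: float, psi_soil: float, env: Environment, scenario: PlantScenario
) -> float:
    """Supply minus demand (mmol m-2 s-1) at a candidate psi_leaf."""
    supply = kleaf_response(psi_leaf, scenario) * (psi_soil - psi_leaf)
    demand = (
        stomatal_response(psi_leaf, scenario) * env.vpd / env.Patm * MOL_TO_MMOL
    )
    return supply - demand


def solve_steady_state(
    psi_soil: float,
    env: Environment,
    scenario: PlantScenario,
    psi_min: float = -10.0,
    grid_points: int = 400,
    residual_tol: float = 1e-8,
) -> dict:
    """Solve the supply-demand balance for the operating leaf state.

    Returns ``{"psi_leaf", "gs", "E", "A", "K_leaf", "residual"}``.  When the
    balance has several roots (possible once K_leaf declines), the wettest
    stable state (highest psi_leaf) is returned, located by a downward grid
    scan followed by bracketed root refinement.  If no root exists above
    ``psi_min`` the plant is desiccating: the closed-stomata state at
    psi_min is returned with ``"desiccated": True``.
    """
    if psi_soil > 0:
        raise ValueError(f"psi_soil must be <= 0, got {psi_soil}")
    if env.vpd == 0.0:
        gs = stomatal_response(psi_soil, scenario)
        photo = couple_diffusion(gs, env.air, scenario.photo_params, scenario.pathway)
        return {
            "psi_leaf": psi_soil,
            "gs": gs,
            "E": 0.0,
            "A": photo["A"],
            "K_leaf": kleaf_response(psi_soil, scenario),
            "residual": 0.0,
            "desiccated": False,
        }

    f = lambda pl: _water_balance_residual(pl, psi_soil, env, scenario)
    grid = np.linspace(psi_soil, psi_min, grid_points)
    root = None
    f_prev = f(grid[0])  # = -demand < 0 at psi_leaf = psi_soil
    for x_prev, x in zip(grid[:-1], grid[1:]):
        f_x = f(x)
        if f_prev < 0 <= f_x or f_prev <= 0 < f_x:
            root = brentq(f, x_prev, x, xtol=1e-13, rtol=8.9e-16)
            # Newton polish: the balance can be stiff (large K), so push the
            # residual down to machine level rather than trusting xtol alone
            h = 1e-9
            for _ in range(5):
                fr = f(root)
                if abs(fr) < residual_tol / 10:
                    break
                dfdx = (f(root + h) - f(root - h)) / (2 * h)
                if dfdx == 0:
                    break
                step = fr / dfdx
                if not np.isfinite(step) or abs(step) > 0.1:
                    break
                root -= step
            break
        f_prev = f_x
    if root is None:
        gs = stomatal_response(psi_min, scenario)
        photo = couple_diffusion(gs, env.air, scenario.photo_params, scenario.pathway)
        return {
            "psi_leaf": psi_min,
            "gs": gs,
            "E": gs * env.vpd / env.Patm * MOL_TO_MMOL,
            "A": photo["A"],
            "K_leaf": kleaf_response(psi_min, scenario),
            "residual": float(f(psi_min)),
            "desiccated": True,
        }

    residual = f(root)
    if abs(residual) > residual_tol:
        raise RuntimeError(
            f"steady state residual {residual:.3g} exceeds {residual_tol}"
        )
    gs = stomatal_response(root, scenario)
    photo = couple_diffusion(gs, env.air, scenario.photo_params, scenario.pathway)
    return {
        "psi_leaf": float(root),
        "gs": float(gs),
        "E": float(gs * env.vpd / env.Patm * MOL_TO_MMOL),
        "A": photo["A"],
        "K_leaf": float(kleaf_response(root, scenario)),
        "residual": float(residual),
        "desiccated": False,
    }


def calibrate_conductance(
    scenario: PlantScenario,
    env: Environment,
    soil: SoilState | None = None,
    tolerance: float = 0.01,
    max_scale: float = 1e6,
) -> tuple[PlantScenario, float]:
    """Scale plant conductance so the wet-soil operating psi_leaf hits target.

    K_max and the vulnerability slope are scaled together (preserving P50)
    until solving the balance at field capacity yields
    ``scenario.target_psi_leaf`` within ``tolerance`` MPa.  Returns the
    rescaled scenario and the scale factor.
    """
    soil = soil or SoilState()
    target = scenario.target_psi_leaf
    if target is None:
        raise ValueError("scenario has no target_psi_leaf to calibrate to")
    psi_fc = soil_water_potential(1.0, soil)
    if not target < psi_fc:
        raise CalibrationError(
            f"target {target} must be below field-capacity soil potential {psi_fc}"
        )

    def scaled(s: float) -> PlantScenario:
        return replace(
            scenario, K_max=scenario.K_max * s, vuln_slope=scenario.vuln_slope * s
        )

    def err(log_s: float) -> float:
        state = solve_steady_state(psi_fc, env, scaled(math.exp(log_s)))
        return state["psi_leaf"] - target

    lo, hi = math.log(1e-6), math.log(max_scale)
    # psi_leaf rises monotonically with conductance scale
    if err(hi) < 0:
        raise CalibrationError(
            f"target psi_leaf {target} unattainable below scale cap {max_scale}"
        )
    if err(lo) > 0:
        raise CalibrationError(
            f"target psi_leaf {target} already exceeded at minimal conductance"
        )
    log_s = brentq(err, lo, hi, xtol=1e-10)
    s = math.exp(log_s)
    out = scaled(s)
    check = solve_steady_state(psi_fc, env, out)
    if abs(check["psi_leaf"] - target) > tolerance:
        raise CalibrationError("calibration failed to reach target within tolerance")
    return out, s


@dataclass
class DrydownTrajectory:
    """Ordered per-step records of one simulated dry-down."""

    scenario: PlantScenario
    env: Environment
    records: pd.DataFrame  # step, psi_soil, psi_leaf, gs, E, A, kleaf

    @property
    def wet_A(self) -> float:
        return float(self.records["A"].iloc[0])


def run_dry_down(
    scenario: PlantScenario,
    env: Environment,
    soil: SoilState | None = None,
    dt_s: float = 3600.0,
    stop_psi_soil: float = -4.0,
    gs_stop_fraction: float = 0.01,
    max_steps: int = 20000,
) -> DrydownTrajectory:
    """Step the soil bucket from field capacity to stomatal closure.

    Each step solves the steady-state balance, then removes E * dt from the
    bucket.  Stops when gs falls below ``gs_stop_fraction`` of g_max, the
    soil passes ``stop_psi_soil``, transpiration effectively ceases (guard
    against an infinite zero-VPD run), or ``max_steps`` elapse.
    """
    if dt_s <= 0:
        raise ValueError(f"dt_s must be > 0, got {dt_s}")
    soil = soil or SoilState()
    water = soil.bucket_mol
    rows = []
    for step in range(max_steps):
        theta = water / soil.bucket_mol
        psi_soil = soil_water_potential(theta, soil)
        if psi_soil < stop_psi_soil:
            break
        state = solve_steady_state(psi_soil, env, scenario)
        rows.append(
            {
                "step": step,
                "psi_soil": psi_soil,
                "psi_leaf": state["psi_leaf"],
                "gs": state["gs"],
                "E": state["E"],
                "A": state["A"],
                "kleaf": state["K_leaf"],
            }
        )
        if state["gs"] < gs_stop_fraction * scenario.g_max:
            break
        depletion = state["E"] / MOL_TO_MMOL * dt_s  # mol m-2
        if depletion / soil.bucket_mol < 1e-12:
            break  # zero-VPD (or fully closed) guard: soil will never dry
        water -= depletion
        if water <= 0:
            break
    return DrydownTrajectory(scenario, env, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scenario suite
# ---------------------------------------------------------------------------

def default_scenarios() -> dict[str, PlantScenario]:
    """The four default plant types.

    The C3 reference pairs g_max 0.32 mol m-2 s-1 with K_max 8 mmol m-2 s-1
    MPa-1 (K_leaf:g_s = 25 mmol mol-1 MPa-1); the C4 reference halves g_max
    at equal K_max, giving the twofold higher K_leaf:g_s observed for C4
    grasses.  Stomatal (psi_gs50, c) and hydraulic vulnerability parameters
    are shared between pathways, which show statistically similar P50 and
    turgor loss point; pathway differences enter through g_max and the
    photosynthesis parameters.  Swap types rescale K_max only (the
    vulnerability slope stays at the pathway's mean), so the swapped plant
    carries the other pathway's K_leaf:g_s.
    """
    c3_photo = C3Params()
    c4_photo = C4Params(Vpmax=60.0, Kp=80.0, Vcmax=30.0, Rd=1.0)
    c3 = PlantScenario(
        label="C3", pathway="C3", g_max=0.32, K_max=8.0, photo_params=c3_photo
    )
    c4 = PlantScenario(
        label="C4", pathway="C4", g_max=0.16, K_max=8.0, photo_params=c4_photo
    )
    c3_swap = replace(
        c3,
        label="C3_with_C4_ratio",
        K_max=c3.g_max * c4.kleaf_gs_ratio,
    )
    c4_swap = replace(
        c4,
        label="C4_with_C3_ratio",
        K_max=c4.g_max * c3.kleaf_gs_ratio,
    )
    return {s.label: s for s in (c3, c4, c3_swap, c4_swap)}


def default_environments() -> dict[str, Environment]:
    """The two VPD settings: 0.5 kPa (20degC, RH 78.6%) and 3 kPa (30degC,
    RH 29.5%)."""
    return {
        "VPD0.5": Environment(T_air=20.0, RH=0.786),
        "VPD3.0": Environment(T_air=30.0, RH=0.295),
    }


def _crossing_psi_soil(
    traj: DrydownTrajectory, threshold_fn, grid: np.ndarray
) -> float:
    """First (least negative) grid psi_soil where A drops below a threshold."""
    ps = traj.records["psi_soil"].to_numpy()[::-1]  # ascending for interp
    A = traj.records["A"].to_numpy()[::-1]
    A_on_grid = np.interp(grid, ps, A, left=np.nan, right=np.nan)
    for psi, a in zip(grid[::-1], A_on_grid[::-1]):  # from wet to dry
        if np.isnan(a):
            continue
        if a < threshold_fn(psi):
            return float(psi)
    return float("nan")


def scenario_suite(
    scenarios: dict[str, PlantScenario] | None = None,
    environments: dict[str, Environment] | None = None,
    soil: SoilState | None = None,
    dt_s: float = 3600.0,
    calibrate: bool = False,
) -> dict:
    """Run every plant type at every VPD and summarize drought thresholds.

    Returns ``{"trajectories": {(env, label): DrydownTrajectory},
    "summary": DataFrame}``.  The summary reports, per trajectory, the soil
    water potential at which net assimilation first drops below (i) 90% of
    its own wet-soil value and (ii) the reference C3 plant's assimilation in
    the same environment (NaN if never within the simulated range).
    """
    scenarios = scenarios or default_scenarios()
    environments = environments or default_environments()
    soil = soil or SoilState()

    trajectories: dict[tuple[str, str], DrydownTrajectory] = {}
    for env_name, env in environments.items():
        for label, scn in scenarios.items():
            if calibrate and scn.target_psi_leaf is not None:
                scn, _ = calibrate_conductance(scn, env, soil)
            trajectories[(env_name, label)] = run_dry_down(
                scn, env, soil, dt_s=dt_s
            )

    rows = []
    for env_name in environments:
        ref = trajectories.get((env_name, "C3"))
        for label in scenarios:
            traj = trajectories[(env_name, label)]
            ps = traj.records["psi_soil"].to_numpy()
            grid = np.linspace(ps.min(), ps.max(), 500)
            psi_90 = _crossing_psi_soil(
                traj, lambda _psi, a0=traj.wet_A: 0.9 * a0, grid
            )
            psi_vs_ref = float("nan")
            if ref is not None and label != "C3":
                ref_ps = ref.records["psi_soil"].to_numpy()[::-1]
                ref_A = ref.records["A"].to_numpy()[::-1]
                lo = max(ps.min(), ref_ps.min())
                hi = min(ps.max(), ref_ps.max())
                cgrid = np.linspace(lo, hi, 500)
                ref_interp = np.interp(cgrid, ref_ps, ref_A)
                psi_vs_ref = _crossing_psi_soil(
                    traj,
                    lambda psi, g=cgrid, r=ref_interp: np.interp(psi, g, r),
                    cgrid,
                )
            rows.append(
                {
                    "environment": env_name,
                    "label": label,
                    "vpd_kPa": environments[env_name].vpd,
                    "wet_A": traj.wet_A,
                    "psi_soil_A90": psi_90,
                    "psi_soil_below_C3": psi_vs_ref,
                }
            )
    return {"trajectories": trajectories, "summary": pd.DataFrame(rows)}
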