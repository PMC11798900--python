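"""Anatomy-based leaf xylem hydraulics.

Theoretical conductances of grass leaf vein xylem are computed from measured
conduit geometry.  Each xylem conduit (or protoxylem lacuna) is treated as an
elliptical capillary, its conductivity given by Poiseuille's law modified for
ellipses.  Per-vein-order conductivities are summed over conduits, scaled by
vein density, and normalized by leaf length and a linear-leaf area correction
to yield the whole-leaf xylem conduit conductance K_xc in the same units as
measured leaf hydraulic conductance (mmol m-2 s-1 MPa-1).

Also provided: a cell-wall-volume index of vein construction cost, and bundle
/ mestome sheath perimeter, surface area, projected area, and volume metrics
that correlate with outside-xylem conductance.

Unit regime (fixed throughout the package):
    conduit axes            micrometres (full axis lengths, i.e. diameters)
    vein density Dv         mm vein per mm2 leaf (= 1000 m-1)
    leaf length LL          metres
    conductivity k_t        mmol m s-1 MPa-1
    conductance K_xc        mmol m-2 s-1 MPa-1
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "ConduitGeometry",
    "SheathGeometry",
    "VeinOrderAnatomy",
    "LeafAnatomy",
    "InvalidGeometryError",
    "AnatomySchemaError",
    "AbsentTissueError",
    "conduit_conductivity",
    "vein_order_conductivity",
    "leaf_xylem_conductance",
    "construction_cost",
    "sheath_perimeter",
    "sheath_area_volume",
    "anatomy_from_frame",
    "hydraulics_table",
]

UM_TO_M = 1e-6
DV_TO_PER_M = 1e3  # mm mm-2  ->  m m-2 (= m-1)

CONDUIT_TYPES = ("xylem_I", "xylem_II", "protoxylem_lacuna")
#: conduit types legal in each longitudinal vein order; minor orders (3, 4)
#: carry only narrow type-II conduits.
LEGAL_TYPES = {
    1: frozenset(CONDUIT_TYPES),
    2: frozenset(CONDUIT_TYPES),
    3: frozenset({"xylem_II"}),
    4: frozenset({"xylem_II"}),
}
MAJOR_ORDERS = (1, 2)
MINOR_ORDERS = (3, 4)


class InvalidGeometryError(ValueError):
    """A conduit or leaf geometry value is physically impossible."""


class AnatomySchemaError(ValueError):
    """An anatomy record violates the per-order schema rules."""


class AbsentTissueError(ValueError):
    """The requested sheath tissue is absent from every vein order."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Water viscosity at 25degC (MPa s) and liquid-water molar density.

    ``molar_volume`` converts a volumetric conductivity (m4 MPa-1 s-1) to the
    molar units the field reports: 1 m3 of liquid water = 5.556e7 mmol.
    """

    water_viscosity: float = 8.9e-10
    molar_volume: float = 5.556e7

    def __post_init__(self) -> None:
        if self.water_viscosity <= 0 or self.molar_volume <= 0:
            raise InvalidGeometryError("physical constants must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class ConduitGeometry:
    """An elliptical conduit lumen: full major/minor axes in micrometres."""

    major_axis_um: float
    minor_axis_um: float
    conduit_type: Literal["xylem_I", "xylem_II", "protoxylem_lacuna"] = "xylem_II"

    def __post_init__(self) -> None:
        a, b = self.major_axis_um, self.minor_axis_um
        if not (a > 0 and b > 0) or not (math.isfinite(a) and math.isfinite(b)):
            raise InvalidGeometryError(
                f"conduit axes must be positive and finite, got ({a}, {b})"
            )
        if self.conduit_type not in CONDUIT_TYPES:
            raise AnatomySchemaError(f"unknown conduit type {self.conduit_type!r}")
        if b > a:  # canonicalize: conductivity is symmetric in (a, b)
            object.__setattr__(self, "major_axis_um", b)
            object.__setattr__(self, "minor_axis_um", a)


@dataclass(frozen=True)
class SheathGeometry:
    """Mean sheath cell diameter (um) and cell count, per sheath per order.

    ``None`` marks an absent tissue (e.g. no bundle sheath on 4-degree veins),
    which is distinct from a zero-sized one.
    """

    bs_cell_diam_um: float | None = None
    bs_cell_count: float | None = None
    ms_cell_diam_um: float | None = None
    ms_cell_count: float | None = None

    def __post_init__(self) -> None:
        for d, n, tag in (
            (self.bs_cell_diam_um, self.bs_cell_count, "bundle"),
            (self.ms_cell_diam_um, self.ms_cell_count, "mestome"),
        ):
            if (d is None) != (n is None):
                raise AnatomySchemaError(
                    f"{tag} sheath diameter and count must be given together"
                )
            if d is not None and (d <= 0 or n < 0):
                raise InvalidGeometryError(
                    f"{tag} sheath: diameter must be > 0 and count >= 0"
                )

    def has(self, sheath: str) -> bool:
        d = self.bs_cell_diam_um if sheath == "bs" else self.ms_cell_diam_um
        return d is not None


@dataclass(frozen=True)
class VeinOrderAnatomy:
    """All conduits of one longitudinal vein order plus its vein density."""

    order: int
    conduits: tuple[ConduitGeometry, ...]
    Dv_mm_mm2: float
    sheath: SheathGeometry = field(default_factory=SheathGeometry)

    def __post_init__(self) -> None:
        if self.order not in LEGAL_TYPES:
            raise AnatomySchemaError(f"vein order must be 1-4, got {self.order}")
        if self.Dv_mm_mm2 <= 0:
            raise AnatomySchemaError(f"Dv must be > 0 for order {self.order}")
        legal = LEGAL_TYPES[self.order]
        for c in self.conduits:
            if c.conduit_type not in legal:
                raise AnatomySchemaError(
                    f"conduit type {c.conduit_type!r} not allowed in "
                    f"{self.order}-degree veins"
                )
        n_lac = sum(c.conduit_type == "protoxylem_lacuna" for c in self.conduits)
        if n_lac > 1:
            raise AnatomySchemaError(
                f"order {self.order}: at most one protoxylem lacuna, got {n_lac}"
            )


@dataclass(frozen=True)
class LeafAnatomy:
    """Per-species leaf: 3 (C3, most C4) or 4 (C4 Panicoideae) vein orders."""

    species: str
    pathway: Literal["C3", "C4"]
    vein_orders: tuple[VeinOrderAnatomy, ...]
    leaf_length_m: float
    shape_correction: float = 0.71

    def __post_init__(self) -> None:
        if self.pathway not in ("C3", "C4"):
            raise AnatomySchemaError(f"pathway must be C3 or C4, got {self.pathway!r}")
        if self.leaf_length_m <= 0:
            raise InvalidGeometryError("leaf length must be > 0")
        if not 0 < self.shape_correction <= 1:
            raise InvalidGeometryError("shape correction must be in (0, 1]")
        orders = sorted(vo.order for vo in self.vein_orders)
        if orders not in ([1, 2, 3], [1, 2, 3, 4]):
            raise AnatomySchemaError(
                f"vein order set must be {{1,2,3}} or {{1,2,3,4}}, got {orders}"
            )
        if orders == [1, 2, 3, 4] and self.pathway == "C3":
            raise AnatomySchemaError("a fourth vein order only occurs in C4 leaves")

    def order(self, k: int) -> VeinOrderAnatomy:
        for vo in self.vein_orders:
            if vo.order == k:
                return vo
        raise KeyError(k)


# ---------------------------------------------------------------------------
# conductivities
# ---------------------------------------------------------------------------

def conduit_conductivity(
    geom: ConduitGeometry, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Theoretical conductivity k_t of one elliptical conduit.

    k_t = (pi / 64 mu) * a^3 b^3 / (a^2 + b^2), with a, b the full major and
    minor axes in metres, converted to molar units (mmol m s-1 MPa-1).  For a
    circular conduit (a = b = 2r) this reduces exactly to Hagen-Poiseuille
    pi r^4 / (8 mu).
    """
    a = geom.major_axis_um * UM_TO_M
    b = geom.minor_axis_um * UM_TO_M
    volumetric = (math.pi / (64.0 * constants.water_viscosity)) * (
        a**3 * b**3 / (a**2 + b**2)
    )
    return volumetric * constants.molar_volume


def vein_order_conductivity(
    vo: VeinOrderAnatomy, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Summed k_t of all conduits (all types) of one vein order."""
    return float(sum(conduit_conductivity(c, constants) for c in vo.conduits))


def leaf_xylem_conductance(
    leaf: LeafAnatomy,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ll_convention: Literal["half-squared", "half-then-square"] = "half-squared",
) -> dict:
    """Whole-leaf xylem conduit conductance K_xc and per-order contributions.

    K_xc = (sum_order k_t(order) * Dv(order) / (0.5 * LL^2)) / shape_correction

    with Dv converted from mm mm-2 to m-1 and LL in metres, so K_xc lands in
    mmol m-2 s-1 MPa-1.  ``ll_convention`` selects the length normalization:
    ``"half-squared"`` divides by 0.5*LL^2 (default), ``"half-then-square"``
    by (0.5*LL)^2.

    Returns a dict with ``k_t_whole`` (mmol m s-1 MPa-1), ``K_xc``,
    ``per_order_kt``, ``per_order_contribution`` (each order's share of the
    Dv-weighted sum) and ``major_fraction`` (share of K_xc carried by the
    1- and 2-degree veins).
    """
    if ll_convention == "half-squared":
        denom = 0.5 * leaf.leaf_length_m**2
    elif ll_convention == "half-then-square":
        denom = (0.5 * leaf.leaf_length_m) ** 2
    else:
        raise ValueError(f"unknown ll_convention {ll_convention!r}")

    per_order_kt: dict[int, float] = {}
    weighted: dict[int, float] = {}
    for vo in leaf.vein_orders:
        kt = vein_order_conductivity(vo, constants)
        per_order_kt[vo.order] = kt
        weighted[vo.order] = kt * (vo.Dv_mm_mm2 * DV_TO_PER_M)

    total_weighted = sum(weighted.values())
    K_xc = (total_weighted / denom) / leaf.shape_correction
    major = sum(v for k, v in weighted.items() if k in MAJOR_ORDERS)
    major_fraction = major / total_weighted if total_weighted > 0 else float("nan")
    return {
        "k_t_whole": float(sum(per_order_kt.values())),
        "K_xc": float(K_xc),
        "per_order_kt": per_order_kt,
        "per_order_contribution": {
            k: v / total_weighted for k, v in weighted.items()
        },
        "major_fraction": float(major_fraction),
    }


# ---------------------------------------------------------------------------
# construction cost
# ---------------------------------------------------------------------------

def construction_cost(
    CD_um: float, CN: float, Dv_mm_mm2: float, exponent: float = 1.0
) -> float:
    """Xylem construction-cost index CC = pi * CD^exponent * CN * Dv.

    An index of conduit cell-wall volume per leaf area; wall thickness is
    treated as constant at exponent 1, or as sublinearly increasing with
    conduit diameter for exponent < 1.  Index units (no conversion applied).
    """
    if exponent <= 0:
        raise ValueError(f"exponent must be > 0, got {exponent}")
    if CD_um < 0 or CN < 0 or Dv_mm_mm2 < 0:
        raise InvalidGeometryError("CD, CN and Dv must be non-negative")
    if CN == 0:
        return 0.0
    return math.pi * CD_um**exponent * CN * Dv_mm_mm2


def _mean_conduit_diameter(vo: VeinOrderAnatomy) -> float:
    """Mean of per-conduit mean axis diameters, xylem conduits only."""
    diams = [
        0.5 * (c.major_axis_um + c.minor_axis_um)
        for c in vo.conduits
        if c.conduit_type != "protoxylem_lacuna"
    ]
    return float(np.mean(diams)) if diams else 0.0


def leaf_construction_cost(leaf: LeafAnatomy, exponent: float = 1.0) -> dict:
    """Per-order, major, minor and total construction-cost index for a leaf."""
    per_order = {}
    for vo in leaf.vein_orders:
        cn = sum(1 for c in vo.conduits if c.conduit_type != "protoxylem_lacuna")
        per_order[vo.order] = construction_cost(
            _mean_conduit_diameter(vo), cn, vo.Dv_mm_mm2, exponent
        )
    major = sum(v for k, v in per_order.items() if k in MAJOR_ORDERS)
    minor = sum(v for k, v in per_order.items() if k in MINOR_ORDERS)
    return {
        "per_order": per_order,
        "CC_major": major,
        "CC_minor": minor,
        "CC_total": major + minor,
    }


# ---------------------------------------------------------------------------
# sheath metrics
# ---------------------------------------------------------------------------

def _sheath_dn(sg: SheathGeometry, sheath: str) -> tuple[float, float]:
    if sheath == "bs":
        return sg.bs_cell_diam_um, sg.bs_cell_count
    return sg.ms_cell_diam_um, sg.ms_cell_count


def sheath_perimeter(orders: Sequence[SheathGeometry]) -> dict:
    """Mean outer sheath perimeter P_bs and P_ms over possessing orders.

    Per order the outer perimeter is approximated as (D/2) * pi * N, i.e. N
    half-circumferences of cells of mean diameter D.  The reported value is
    the mean across the vein orders that actually possess the sheath (the
    classical layout: 3 orders for the bundle sheath, up to 4 for the
    mestome sheath).  Units: um.
    """
    out = {}
    for sheath, key in (("bs", "P_bs"), ("ms", "P_ms")):
        vals = [
            (d / 2.0) * math.pi * n
            for sg in orders
            if sg.has(sheath)
            for d, n in [_sheath_dn(sg, sheath)]
        ]
        out[key] = float(np.mean(vals)) if vals else None
    if out["P_bs"] is None and out["P_ms"] is None:
        raise AbsentTissueError("no vein order possesses a bundle or mestome sheath")
    return out


def sheath_area_volume(
    orders: Sequence[SheathGeometry], Dv_mm_mm2: Sequence[float]
) -> dict:
    """Sheath surface area, projected area and volume per leaf area.

    Per order and sheath with mean cell diameter D (um), cell count N and
    vein density Dv:  SA = D*pi*Dv*N (m2 m-2), PA = D*Dv*N (m2 m-2),
    V = (D/2)^2*pi*Dv*N (m3 m-2).  Totals sum over orders; major (1-2 degree)
    and minor (3-4 degree) splits are also reported, assuming ``orders`` is
    given in ascending vein-order position.
    """
    if len(orders) != len(Dv_mm_mm2):
        raise AnatomySchemaError("need one Dv per sheath record")
    out: dict[str, float | None] = {}
    for sheath, prefix in (("bs", "BS"), ("ms", "MS")):
        sa = pa = vol = 0.0
        sa_major = pa_major = vol_major = 0.0
        any_present = False
        for i, (sg, dv) in enumerate(zip(orders, Dv_mm_mm2)):
            if not sg.has(sheath):
                continue
            any_present = True
            d_um, n = _sheath_dn(sg, sheath)
            d = d_um * UM_TO_M
            dv_m = dv * DV_TO_PER_M
            o_sa = d * math.pi * dv_m * n
            o_pa = d * dv_m * n
            o_v = (d / 2.0) ** 2 * math.pi * dv_m * n
            sa += o_sa
            pa += o_pa
            vol += o_v
            if i < 2:  # positions 0,1 = 1- and 2-degree (major) veins
                sa_major += o_sa
                pa_major += o_pa
                vol_major += o_v
        if any_present:
            out[f"{prefix}SA"] = sa
            out[f"{prefix}PA"] = pa
            out[f"{prefix}V"] = vol
            out[f"{prefix}SA_major"] = sa_major
            out[f"{prefix}SA_minor"] = sa - sa_major
        else:
            for suffix in ("SA", "PA", "V", "SA_major", "SA_minor"):
                out[f"{prefix}{suffix}"] = None
    if out["BSSA"] is None and out["MSSA"] is None:
        raise AbsentTissueError("no vein order possesses a bundle or mestome sheath")
    return out


# ---------------------------------------------------------------------------
# table-level interface
# ---------------------------------------------------------------------------

ANATOMY_COLUMNS = [
    "species",
    "pathway",
    "vein_order",
    "conduit_type",
    "major_axis_um",
    "minor_axis_um",
    "conduit_count",
    "Dv_per_mm",
    "bs_cell_diam_um",
    "bs_cell_count",
    "ms_cell_diam_um",
    "ms_cell_count",
    "leaf_length_cm",
]


def anatomy_from_frame(df: pd.DataFrame) -> list[LeafAnatomy]:
    """Build LeafAnatomy objects from a long-format anatomy table.

    One row per (species, vein order, conduit type); conduit_count rows with
    identical geometry are expanded into individual conduits.  Sheath columns
    and Dv are repeated per order; NaN marks absent sheath tissue.
    """
    missing = [c for c in ANATOMY_COLUMNS if c not in df.columns]
    if missing:
        raise AnatomySchemaError(f"anatomy table missing columns: {missing}")
    leaves = []
    for species, sdf in df.groupby("species", sort=True):
        pathway = sdf["pathway"].iloc[0]
        vein_orders = []
        for order, odf in sdf.groupby("vein_order", sort=True):
            conduits = []
            for row in odf.itertuples():
                for _ in range(int(row.conduit_count)):
                    conduits.append(
                        ConduitGeometry(
                            row.major_axis_um, row.minor_axis_um, row.conduit_type
                        )
                    )
            r0 = odf.iloc[0]

            def _opt(v):
                return None if pd.isna(v) else float(v)

            sheath = SheathGeometry(
                bs_cell_diam_um=_opt(r0["bs_cell_diam_um"]),
                bs_cell_count=_opt(r0["bs_cell_count"]),
                ms_cell_diam_um=_opt(r0["ms_cell_diam_um"]),
                ms_cell_count=_opt(r0["ms_cell_count"]),
            )
            vein_orders.append(
                VeinOrderAnatomy(
                    order=int(order),
                    conduits=tuple(conduits),
                    Dv_mm_mm2=float(r0["Dv_per_mm"]),
                    sheath=sheath,
                )
            )
        leaves.append(
            LeafAnatomy(
                species=str(species),
                pathway=pathway,
                vein_orders=tuple(vein_orders),
                leaf_length_m=float(sdf["leaf_length_cm"].iloc[0]) / 100.0,
            )
        )
    return leaves


def hydraulics_table(
    leaves: Sequence[LeafAnatomy],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ll_convention: str = "half-squared",
    cc_exponent: float = 1.0,
) -> pd.DataFrame:
    """Per-species hydraulic and sheath summary table."""
    rows = []
    for leaf in leaves:
        hyd = leaf_xylem_conductance(leaf, constants, ll_convention)
        cc = leaf_construction_cost(leaf, cc_exponent)
        sheaths = [vo.sheath for vo in leaf.vein_orders]
        dvs = [vo.Dv_mm_mm2 for vo in leaf.vein_orders]
        try:
            perim = sheath_perimeter(sheaths)
            sav = sheath_area_volume(sheaths, dvs)
        except AbsentTissueError:
            perim = {"P_bs": None, "P_ms": None}
            sav = {}
        row = {
            "species": leaf.species,
            "pathway": leaf.pathway,
            "k_t_whole": hyd["k_t_whole"],
            "K_xc": hyd["K_xc"],
            "major_fraction": hyd["major_fraction"],
            "CC_major": cc["CC_major"],
            "CC_minor": cc["CC_minor"],
            "CC_total": cc["CC_total"],
            "P_bs": perim["P_bs"],
            "P_ms": perim["P_ms"],
        }
        for k in ("BSSA", "BSPA", "BSV", "MSSA", "MSPA", "MSV"):
            row[k] = sav.get(k)
        for order, kt in hyd["per_order_kt"].items():
            row[f"kt_order{order}"] = kt
        rows.append(row)
    return pd.DataFrame(rows)
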