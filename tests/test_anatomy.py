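"""Conduit, vein-order and whole-leaf xylem conductance computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasshydro.anatomy import (
    AbsentTissueError,
    AnatomySchemaError,
    ConduitGeometry,
    InvalidGeometryError,
    LeafAnatomy,
    PhysicalConstants,
    SheathGeometry,
    VeinOrderAnatomy,
    anatomy_from_frame,
    conduit_conductivity,
    construction_cost,
    leaf_construction_cost,
    leaf_xylem_conductance,
    sheath_area_volume,
    sheath_perimeter,
    vein_order_conductivity,
)

MU = 8.9e-10
MOLAR = 5.556e7


def kt_oracle(a_um: float, b_um: float) -> float:
    """Independent step-by-step evaluation in SI units, conversion last."""
    a = a_um * 1e-6
    b = b_um * 1e-6
    geometric_factor = (a**3 * b**3) / (a**2 + b**2)  # m^4
    volumetric = math.pi / (64.0 * MU) * geometric_factor  # m^4 MPa-1 s-1
    return volumetric * MOLAR  # mmol m s-1 MPa-1


class TestConduitConductivity:
    def test_circle_reduces_to_hagen_poiseuille(self):
        # a = b = 2r must reproduce pi r^4 / (8 mu) exactly
        r = 12.5e-6
        kt = conduit_conductivity(ConduitGeometry(2 * 12.5, 2 * 12.5))
        hp = math.pi * r**4 / (8.0 * MU) * MOLAR
        assert kt == pytest.approx(hp, rel=1e-12)

    def test_axis_symmetry(self):
        g1 = conduit_conductivity(ConduitGeometry(20.0, 10.0))
        g2 = conduit_conductivity(ConduitGeometry(10.0, 20.0))
        assert g1 == g2

    def test_matches_hand_evaluation(self):
        assert conduit_conductivity(ConduitGeometry(20.0, 10.0)) == pytest.approx(
            kt_oracle(20.0, 10.0), rel=1e-12
        )

    @pytest.mark.parametrize("a,b", [(0.0, 5.0), (-1.0, 5.0), (5.0, 0.0)])
    def test_nonpositive_axis_rejected(self, a, b):
        with pytest.raises(InvalidGeometryError):
            ConduitGeometry(a, b)

    def test_custom_viscosity_scales_inversely(self):
        thick = PhysicalConstants(water_viscosity=2 * MU)
        assert conduit_conductivity(
            ConduitGeometry(20, 10), thick
        ) == pytest.approx(kt_oracle(20, 10) / 2)


class TestVeinOrderConductivity:
    def test_single_conduit_equals_conduit_value(self):
        vo = VeinOrderAnatomy(3, (ConduitGeometry(8, 6),), 4.0)
        assert vein_order_conductivity(vo) == pytest.approx(kt_oracle(8, 6))

    def test_additivity_under_duplication(self):
        conduits = (ConduitGeometry(8, 6), ConduitGeometry(5, 4))
        vo = VeinOrderAnatomy(3, conduits, 4.0)
        vo2 = VeinOrderAnatomy(3, conduits + conduits, 4.0)
        assert vein_order_conductivity(vo2) == pytest.approx(
            2 * vein_order_conductivity(vo), rel=1e-12
        )

    def test_mixed_types_sum_componentwise(self):
        # order 2: one lacuna + two type I + three type II
        conduits = (
            ConduitGeometry(30, 30, "protoxylem_lacuna"),
            ConduitGeometry(20, 15, "xylem_I"),
            ConduitGeometry(20, 15, "xylem_I"),
            ConduitGeometry(8, 6, "xylem_II"),
            ConduitGeometry(8, 6, "xylem_II"),
            ConduitGeometry(8, 6, "xylem_II"),
        )
        vo = VeinOrderAnatomy(2, conduits, 0.8)
        expected = (
            kt_oracle(30, 30) + 2 * kt_oracle(20, 15) + 3 * kt_oracle(8, 6)
        )
        assert vein_order_conductivity(vo) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("order", [3, 4])
    @pytest.mark.parametrize("ctype", ["xylem_I", "protoxylem_lacuna"])
    def test_minor_orders_reject_major_conduit_types(self, order, ctype):
        with pytest.raises(AnatomySchemaError):
            VeinOrderAnatomy(order, (ConduitGeometry(10, 8, ctype),), 4.0)


class TestLeafXylemConductance:
    def test_end_to_end_hand_computation(self, fixture_leaf):
        # independent composition: per-conduit oracle -> order sums ->
        # Dv weighting -> length and shape normalization
        kt1 = kt_oracle(30, 30) + 2 * kt_oracle(20, 15) + kt_oracle(8, 6)
        kt2 = kt_oracle(25, 25) + kt_oracle(15, 12) + kt_oracle(6, 5)
        kt3 = 2 * kt_oracle(5, 4)
        weighted = kt1 * 0.1e3 + kt2 * 0.8e3 + kt3 * 4.0e3  # Dv in m-1
        K_xc = (weighted / (0.5 * 0.25**2)) / 0.71
        res = leaf_xylem_conductance(fixture_leaf)
        assert res["K_xc"] == pytest.approx(K_xc, rel=1e-9)
        assert res["k_t_whole"] == pytest.approx(kt1 + kt2 + kt3, rel=1e-9)
        assert res["major_fraction"] == pytest.approx(
            (kt1 * 0.1e3 + kt2 * 0.8e3) / weighted, rel=1e-9
        )

    def test_linear_in_vein_density(self, fixture_leaf):
        doubled = LeafAnatomy(
            species="x",
            pathway="C3",
            vein_orders=tuple(
                VeinOrderAnatomy(vo.order, vo.conduits, 2 * vo.Dv_mm_mm2, vo.sheath)
                for vo in fixture_leaf.vein_orders
            ),
            leaf_length_m=fixture_leaf.leaf_length_m,
        )
        base = leaf_xylem_conductance(fixture_leaf)["K_xc"]
        assert leaf_xylem_conductance(doubled)["K_xc"] == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_leaf_length_inverse_square(self, fixture_leaf):
        longer = LeafAnatomy(
            species="x",
            pathway="C3",
            vein_orders=fixture_leaf.vein_orders,
            leaf_length_m=2 * fixture_leaf.leaf_length_m,
        )
        base = leaf_xylem_conductance(fixture_leaf)["K_xc"]
        assert leaf_xylem_conductance(longer)["K_xc"] == pytest.approx(
            base / 4, rel=1e-12
        )

    def test_length_convention_switch(self, fixture_leaf):
        default = leaf_xylem_conductance(fixture_leaf)["K_xc"]
        alt = leaf_xylem_conductance(fixture_leaf, ll_convention="half-then-square")
        # (0.5 LL)^2 = 0.25 LL^2 halves the denominator relative to 0.5 LL^2
        assert alt["K_xc"] == pytest.approx(2 * default, rel=1e-12)

    def test_conduit_listing_order_invariance(self, fixture_leaf):
        shuffled = LeafAnatomy(
            species="x",
            pathway="C3",
            vein_orders=tuple(
                VeinOrderAnatomy(
                    vo.order, vo.conduits[::-1], vo.Dv_mm_mm2, vo.sheath
                )
                for vo in fixture_leaf.vein_orders
            ),
            leaf_length_m=fixture_leaf.leaf_length_m,
        )
        assert leaf_xylem_conductance(shuffled)["K_xc"] == pytest.approx(
            leaf_xylem_conductance(fixture_leaf)["K_xc"], rel=1e-12
        )

    def test_major_fraction_in_unit_interval(self, fixture_leaf):
        mf = leaf_xylem_conductance(fixture_leaf)["major_fraction"]
        assert 0.0 <= mf <= 1.0

    def test_fourth_order_only_in_c4(self, fixture_leaf):
        orders4 = fixture_leaf.vein_orders + (
            VeinOrderAnatomy(4, (ConduitGeometry(4, 3.5),), 3.0),
        )
        with pytest.raises(AnatomySchemaError):
            LeafAnatomy("x", "C3", orders4, 0.25)
        LeafAnatomy("x", "C4", orders4, 0.25)  # legal for C4


class TestConstructionCost:
    def test_zero_conduits_zero_cost(self):
        assert construction_cost(10.0, 0, 5.0) == 0.0

    def test_direct_product(self):
        assert construction_cost(10.0, 3, 5.0) == pytest.approx(math.pi * 150.0)

    def test_sublinear_exponent_reduces_cost(self):
        assert construction_cost(10.0, 3, 5.0, exponent=0.8) < construction_cost(
            10.0, 3, 5.0, exponent=1.0
        )

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            construction_cost(10.0, 3, 5.0, exponent=0.0)

    def test_leaf_totals_split_major_minor(self, fixture_leaf):
        cc = leaf_construction_cost(fixture_leaf)
        assert cc["CC_total"] == pytest.approx(cc["CC_major"] + cc["CC_minor"])
        assert cc["CC_major"] == pytest.approx(
            cc["per_order"][1] + cc["per_order"][2]
        )


class TestSheathMetrics:
    def test_single_order_half_circumference(self):
        res = sheath_perimeter([SheathGeometry(10.0, 1, None, None)])
        assert res["P_bs"] == pytest.approx(5 * math.pi)
        assert res["P_ms"] is None

    def test_mean_over_identical_orders(self):
        sg = SheathGeometry(10.0, 6, None, None)
        res = sheath_perimeter([sg, sg, sg])
        assert res["P_bs"] == pytest.approx(5 * math.pi * 6)

    def test_mean_of_four_distinct_orders(self):
        orders = [
            SheathGeometry(None, None, d, n)
            for d, n in [(12, 10), (10, 8), (8, 6), (6, 4)]
        ]
        expected = np.mean([(d / 2) * math.pi * n for d, n in
                            [(12, 10), (10, 8), (8, 6), (6, 4)]])
        assert sheath_perimeter(orders)["P_ms"] == pytest.approx(expected)

    def test_absent_everywhere_raises(self):
        with pytest.raises(AbsentTissueError):
            sheath_perimeter([SheathGeometry()])

    def test_area_volume_formula_ratios(self):
        orders = [SheathGeometry(10.0, 6, None, None)]
        res = sheath_area_volume(orders, [4.0])
        assert res["BSPA"] == pytest.approx(res["BSSA"] / math.pi, rel=1e-12)
        # V = (D/2)^2 pi Dv N = SA * D/4 with D in metres
        assert res["BSV"] == pytest.approx(res["BSSA"] * 10e-6 / 4, rel=1e-12)

    def test_area_volume_unit_handling(self):
        # one order, D = 10 um, N = 6, Dv = 4 mm mm-2:
        # SA = 10e-6 m * pi * 4000 m-1 * 6 (dimensionless m2/m2)
        res = sheath_area_volume([SheathGeometry(10.0, 6, None, None)], [4.0])
        assert res["BSSA"] == pytest.approx(10e-6 * math.pi * 4000 * 6, rel=1e-12)
        assert res["BSPA"] == pytest.approx(10e-6 * 4000 * 6, rel=1e-12)
        assert res["BSV"] == pytest.approx(
            (5e-6) ** 2 * math.pi * 4000 * 6, rel=1e-12
        )


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    a=st.floats(1.0, 100.0),
    b=st.floats(1.0, 100.0),
)
def test_conductivity_positive_and_symmetric(a, b):
    k1 = conduit_conductivity(ConduitGeometry(a, b))
    k2 = conduit_conductivity(ConduitGeometry(b, a))
    assert k1 > 0
    assert k1 == k2


def test_anatomy_frame_round_trip(fixture_leaf):
    """Frame parsing reproduces the conductance of the dataclass route."""
    import pandas as pd

    rows = []
    for vo in fixture_leaf.vein_orders:
        seen = {}
        for c in vo.conduits:
            key = (c.conduit_type, c.major_axis_um, c.minor_axis_um)
            seen[key] = seen.get(key, 0) + 1
        for (ctype, a, b), count in seen.items():
            rows.append(
                {
                    "species": "fixture",
                    "pathway": "C3",
                    "vein_order": vo.order,
                    "conduit_type": ctype,
                    "major_axis_um": a,
                    "minor_axis_um": b,
                    "conduit_count": count,
                    "Dv_per_mm": vo.Dv_mm_mm2,
                    "bs_cell_diam_um": vo.sheath.bs_cell_diam_um,
                    "bs_cell_count": vo.sheath.bs_cell_count,
                    "ms_cell_diam_um": vo.sheath.ms_cell_diam_um,
                    "ms_cell_count": vo.sheath.ms_cell_count,
                    "leaf_length_cm": fixture_leaf.leaf_length_m * 100,
                }
            )
    leaves = anatomy_from_frame(pd.DataFrame(rows))
    assert len(leaves) == 1
    assert leaf_xylem_conductance(leaves[0])["K_xc"] == pytest.approx(
        leaf_xylem_conductance(fixture_leaf)["K_xc"], rel=1e-12
    )
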