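"""Synthetic trees, pathway labels, trait tables and vulnerability curves."""

import numpy as np
import pytest

from grasshydro.anatomy import anatomy_from_frame, leaf_xylem_conductance
from grasshydro.partitioning import fit_vulnerability
from grasshydro.pipeline import validate_tables
from grasshydro.phylostats import pgls_fit, simulate_bm, write_newick
from grasshydro.synthetic import (
    PathwayAssignment,
    SyntheticConfig,
    assign_pathways,
    count_c4_origins,
    generate_anatomy,
    generate_dataset,
    generate_vulnerability_curve,
    meta_analysis_config,
    simulate_traits,
    simulate_tree,
)


def oracle_count_clades(tree, labels):
    """Independent maximal-C4-clade count via leaf-set comparison."""
    c4_tips = {t for t, p in labels.items() if p == "C4"}
    clades = []
    for node in tree.preorder_node_iter():
        tipset = {lf.taxon.label for lf in node.leaf_iter()}
        if tipset and tipset <= c4_tips:
            # maximal if no previously found clade contains it
            if not any(tipset <= c for c in clades):
                clades = [c for c in clades if not (c <= tipset)]
                clades.append(tipset)
    # keep only sets not contained in another
    maximal = [c for c in clades if not any(c < o for o in clades)]
    return len(maximal)


class TestTree:
    def test_single_species_has_positive_depth(self):
        tree = simulate_tree(1, 1.0, seed=0)
        leaf = tree.leaf_nodes()[0]
        assert leaf.edge.length > 0

    def test_ultrametric_with_requested_tips(self):
        tree = simulate_tree(27, 1.0, seed=1)
        tree.calc_node_root_distances()
        depths = [lf.root_distance for lf in tree.leaf_node_iter()]
        assert len(depths) == 27
        assert np.ptp(depths) < 1e-9
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert len(set(labels)) == 27

    def test_all_branch_lengths_positive(self):
        tree = simulate_tree(20, 2.0, seed=3)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0

    def test_determinism(self):
        t1 = simulate_tree(15, 1.0, seed=9)
        t2 = simulate_tree(15, 1.0, seed=9)
        assert write_newick(t1) == write_newick(t2)

    @pytest.mark.parametrize("n,rate", [(0, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, n, rate):
        with pytest.raises(ValueError):
            simulate_tree(n, rate, seed=0)


class TestPathways:
    def test_zero_origins_all_c3(self, tree27):
        pa = assign_pathways(tree27, 0, seed=0)
        assert set(pa.labels.values()) == {"C3"}
        assert pa.n_origins_achieved == 0

    def test_single_origin_is_monophyletic(self, tree27):
        pa = assign_pathways(tree27, 1, seed=2)
        assert oracle_count_clades(tree27, pa.labels) == 1

    def test_eleven_origins_on_27_tips(self, tree27):
        pa = assign_pathways(tree27, 11, seed=4)
        assert pa.n_origins_achieved == 11
        assert oracle_count_clades(tree27, pa.labels) == 11
        assert count_c4_origins(tree27, pa.labels) == 11

    def test_internal_count_matches_oracle_across_seeds(self, tree50):
        for seed in range(5):
            pa = assign_pathways(tree50, 7, seed=seed)
            assert count_c4_origins(tree50, pa.labels) == oracle_count_clades(
                tree50, pa.labels
            )

    def test_more_origins_than_tips_rejected(self, tree27):
        with pytest.raises(ValueError):
            assign_pathways(tree27, 28, seed=0)


class TestTraits:
    def test_exact_means_at_zero_noise(self, tree27):
        pa = assign_pathways(tree27, 11, seed=1)
        cfg = SyntheticConfig(bm_sigma=0.0, lognormal_cv=0.0)
        df = simulate_traits(tree27, pa, cfg).set_index("species")
        for sp, pw in pa.labels.items():
            expected = 0.30 * (0.5 if pw == "C4" else 1.0)
            assert df.loc[sp, "gs"] == pytest.approx(expected, rel=1e-12)

    def test_gs_fold_recovered_geometrically_at_large_n(self):
        tree = simulate_tree(200, 1.0, seed=21)
        pa = assign_pathways(tree, 30, seed=21)
        cfg = SyntheticConfig(
            n_species=200, n_c4_origins=30, bm_sigma=0.0, lognormal_cv=0.2,
            pathway_fold_effects={"gs": 0.29}, seed=21,
        )
        df = simulate_traits(tree, pa, cfg)
        gm = df.groupby("pathway")["gs"].apply(lambda s: np.exp(np.log(s).mean()))
        assert gm["C4"] / gm["C3"] == pytest.approx(0.29, rel=0.10)

    def test_bm_signal_detected_by_lambda(self):
        # phylogenetic signal injected by the BM component is recovered
        hits = 0
        for rep in range(50):
            tree = simulate_tree(100, 1.0, seed=300 + rep)
            pa = PathwayAssignment(
                {lf.taxon.label: "C3" for lf in tree.leaf_node_iter()}, 0, 0
            )
            cfg = SyntheticConfig(
                n_species=100, n_c4_origins=0, bm_sigma=0.5, lognormal_cv=0.0,
                seed=300 + rep,
            )
            df = simulate_traits(tree, pa, cfg).set_index("species")
            _, x = simulate_bm(tree, 1.0, rng=900 + rep)
            fit = pgls_fit(np.log(df["gs"]), x[:, 0], tree, lam="ML")
            hits += fit.lam >= 0.8
        assert hits >= 40  # >= 80% of replicates

    def test_unknown_fold_trait_rejected(self):
        with pytest.raises(ValueError, match="no C3 mean"):
            SyntheticConfig(pathway_fold_effects={"not_a_trait": 2.0})

    def test_derived_columns_present(self, tree27):
        pa = assign_pathways(tree27, 11, seed=1)
        df = simulate_traits(tree27, pa, SyntheticConfig())
        assert {"K_leaf_gs_ratio", "WUE_i"} <= set(df.columns)
        assert (df.select_dtypes("number") > 0).all().all()

    def test_meta_config_encodes_reported_contrasts(self, tree27):
        pa = assign_pathways(tree27, 11, seed=1)
        cfg = meta_analysis_config(
            n_species=27, n_c4_origins=11, bm_sigma=0.0, lognormal_cv=0.0
        )
        df = simulate_traits(tree27, pa, cfg)
        by = df.groupby("pathway")[["K_leaf", "gs", "K_leaf_gs_ratio"]].mean()
        assert by.loc["C4", "K_leaf"] / by.loc["C3", "K_leaf"] == pytest.approx(1.4)
        assert by.loc["C4", "gs"] / by.loc["C3", "gs"] == pytest.approx(0.29)
        assert by.loc["C4", "K_leaf_gs_ratio"] / by.loc[
            "C3", "K_leaf_gs_ratio"
        ] == pytest.approx(2.0)


class TestAnatomyGeneration:
    def test_c3_has_three_orders(self):
        df = generate_anatomy("C3", 3, seed=0)
        assert sorted(df["vein_order"].unique()) == [1, 2, 3]

    def test_minor_orders_type_ii_only(self):
        df = generate_anatomy("C4", 4, seed=0)
        minor = df[df["vein_order"] >= 3]
        assert set(minor["conduit_type"]) == {"xylem_II"}

    def test_four_orders_require_c4(self):
        with pytest.raises(ValueError):
            generate_anatomy("C3", 4, seed=0)

    def test_determinism(self):
        a = generate_anatomy("C4", 4, seed=7)
        b = generate_anatomy("C4", 4, seed=7)
        assert a.equals(b)

    def test_passes_schema_validation_and_major_dominance(self):
        for seed in range(5):
            for pw, orders in (("C3", 3), ("C4", 4)):
                df = generate_anatomy(pw, orders, seed=seed)
                assert validate_tables({"anatomy": df}) == []
                leaf = anatomy_from_frame(df)[0]
                assert leaf_xylem_conductance(leaf)["major_fraction"] > 0.9


class TestVulnerabilityGeneration:
    def test_noiseless_line_evaluation(self):
        df = generate_vulnerability_curve(
            10.0, 5.0, noise_sd=0.0, n_points=5, seed=0, psi_min=-2.0
        )
        at_minus1 = df.loc[np.isclose(df["psi_MPa"], -1.0), "kleaf"]
        assert at_minus1.iloc[0] == pytest.approx(5.0)

    def test_noiseless_fit_recovers_p50_exactly(self):
        # psi grid kept above the zero-conductance truncation point
        df = generate_vulnerability_curve(
            10.0, 5.0, noise_sd=0.0, n_points=5, seed=0, psi_min=-2.0
        )
        fit = fit_vulnerability(df["psi_MPa"], df["kleaf"])
        assert fit.P50 == pytest.approx(-1.0, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_vulnerability_curve(10.0, 5.0, n_points=2, seed=0)

    def test_truncation_at_zero(self):
        df = generate_vulnerability_curve(1.0, 5.0, noise_sd=0.0, n_points=8, seed=0)
        assert (df["kleaf"] >= 0).all()


class TestDataset:
    def test_bundle_is_valid_and_deterministic(self):
        d1 = generate_dataset(SyntheticConfig(seed=3))
        d2 = generate_dataset(SyntheticConfig(seed=3))
        assert d1["traits"].equals(d2["traits"])
        assert d1["anatomy"].equals(d2["anatomy"])
        assert write_newick(d1["tree"]) == write_newick(d2["tree"])
        assert (
            validate_tables(
                {"traits": d1["traits"], "anatomy": d1["anatomy"],
                 "vulnerability": d1["vulnerability"]}
            )
            == []
        )
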