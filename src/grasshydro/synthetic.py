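"""Synthetic grass datasets with the structure the analyses assume.

Generates, under a fixed seed:

* an ultrametric pure-birth (Yule) phylogeny;
* C3/C4 pathway labels forming a requested number of independent C4 origins
  (maximal monophyletic C4 clades), echoing the repeated evolution of C4
  photosynthesis across grass lineages;
* positive, ratio-scaled trait tables: each trait is a C3 geometric mean
  times a multiplicative C4 fold effect, a Brownian-motion deviation along
  the tree, and lognormal measurement noise;
* per-species leaf anatomy tables (conduit geometry by vein order, vein
  densities, sheath geometry) with the grass layout: wide type-I conduits
  and a protoxylem lacuna in the 1- and 2-degree veins, narrow type-II
  conduits only in the minor orders, and an optional 4th vein order for C4
  Panicoideae-like leaves;
* linear-decline hydraulic vulnerability curves with Gaussian noise.

The default fold effects encode the common-garden contrast pattern (C4:
half the stomatal conductance at equal K_leaf, hence exactly twice the
K_leaf:g_s; higher A_area and vein density); ``meta_analysis_config`` gives
the literature-compilation pattern (K_leaf 1.4-fold, g_s 71% lower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .anatomy import ANATOMY_COLUMNS
from .phylostats import simulate_bm

__all__ = [
    "SyntheticConfig",
    "PathwayAssignment",
    "simulate_tree",
    "assign_pathways",
    "count_c4_origins",
    "simulate_traits",
    "generate_anatomy",
    "anatomy_table",
    "generate_vulnerability_curve",
    "generate_dataset",
    "common_garden_config",
    "meta_analysis_config",
]

DEFAULT_TRAIT_MEANS_C3 = {
    "gs": 0.30,       # mol m-2 s-1
    "K_leaf": 8.0,    # mmol m-2 s-1 MPa-1
    "A_area": 20.0,   # umol m-2 s-1
    "D_v": 5.0,       # mm mm-2
}

#: C4-relative-to-C3 multiplicative effects, common-garden pattern:
#: K_leaf similar, g_s halved => K_leaf:g_s exactly twofold.
DEFAULT_FOLD_EFFECTS = {
    "gs": 0.5,
    "K_leaf": 1.0,
    "A_area": 1.6,
    "D_v": 1.8,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 27
    n_c4_origins: int = 11
    birth_rate: float = 1.0
    trait_means_c3: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS_C3))
    pathway_fold_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_FOLD_EFFECTS)
    )
    bm_sigma: float = 0.15
    lognormal_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.n_c4_origins <= self.n_species:
            raise ValueError("n_c4_origins must be in [0, n_species]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if any(v <= 0 for v in self.pathway_fold_effects.values()):
            raise ValueError("fold effects must be > 0")
        if self.bm_sigma < 0 or self.lognormal_cv < 0:
            raise ValueError("bm_sigma and lognormal_cv must be >= 0")
        unknown = set(self.pathway_fold_effects) - set(self.trait_means_c3)
        if unknown:
            raise ValueError(
                f"fold effects for traits with no C3 mean: {sorted(unknown)}"
            )


def common_garden_config(**overrides) -> SyntheticConfig:
    """27 species, 11 C4 origins, common-garden contrasts (the default)."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def meta_analysis_config(**overrides) -> SyntheticConfig:
    """Literature-compilation pattern: many species, K_leaf 1.4-fold,
    g_s 0.29-fold (71% lower) and K_leaf:g_s twofold in C4.

    In a literature compilation each trait is covered by a different species
    subset, so the published per-trait contrasts need not be mutually
    consistent row-wise; K_leaf:g_s (reported only for the subset with both
    traits) is therefore simulated as a primary trait with its own twofold
    effect rather than derived from the marginal K_leaf and g_s folds.
    """
    cfg = SyntheticConfig(
        n_species=332,
        n_c4_origins=20,
        trait_means_c3={**DEFAULT_TRAIT_MEANS_C3,
                        "K_leaf_gs_ratio": DEFAULT_TRAIT_MEANS_C3["K_leaf"]
                        / DEFAULT_TRAIT_MEANS_C3["gs"]},
        pathway_fold_effects={"gs": 0.29, "K_leaf": 1.4, "K_leaf_gs_ratio": 2.0,
                              "A_area": 1.6, "D_v": 2.2},
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips.

    Forward simulation: exponential waiting times between speciation events
    at total rate k * birth_rate for k extant lineages, plus a final waiting
    time so every pendant branch has positive length.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0

    if n_species == 1:
        child = root.new_child(edge_length=float(rng.exponential(1.0 / birth_rate)))
        active = [child]
    else:
        active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
        while len(active) < n_species:
            wait = float(rng.exponential(1.0 / (birth_rate * len(active))))
            for node in active:
                node.edge.length += wait
            i = int(rng.integers(len(active)))
            parent = active.pop(i)
            active.append(parent.new_child(edge_length=0.0))
            active.append(parent.new_child(edge_length=0.0))
        final = float(rng.exponential(1.0 / (birth_rate * len(active))))
        for node in active:
            node.edge.length += final

    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"sp{str(i).zfill(width)}")
    return tree


# ---------------------------------------------------------------------------
# pathway assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayAssignment:
    labels: dict  # tip label -> "C3" | "C4"
    n_origins_requested: int
    n_origins_achieved: int


def count_c4_origins(tree: dendropy.Tree, labels: dict) -> int:
    """Number of maximal monophyletic all-C4 clades on the tree."""
    count = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._all_c4 = labels[node.taxon.label] == "C4"
        else:
            node._all_c4 = all(c._all_c4 for c in node.child_nodes())
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if node._all_c4 and (parent is None or not parent._all_c4):
            count += 1
    return count


def assign_pathways(
    tree: dendropy.Tree,
    n_c4_origins: int,
    seed: int | None = None,
    max_attempts: int = 500,
) -> PathwayAssignment:
    """Label tips C3/C4 so the C4 tips form ``n_c4_origins`` maximal clades.

    Candidate edges (clades, including single tips) are sampled without
    replacement; nested or adjacent picks that would merge clades are
    rejected and resampled.  On trees where the requested count is not
    achievable the best achieved count is reported.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if n_c4_origins > len(tips):
        raise ValueError("cannot place more C4 origins than tips")
    if n_c4_origins == 0:
        return PathwayAssignment({t: "C3" for t in tips}, 0, 0)

    # tip set per candidate node (every node below the root defines a clade)
    candidates = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = frozenset([node.taxon.label])
        else:
            node._tipset = frozenset().union(*(c._tipset for c in node.child_nodes()))
        if node.parent_node is not None:
            candidates.append(node._tipset)

    rng = np.random.default_rng(seed)
    all_tips = frozenset(tips)
    best: set | None = None
    best_count = -1
    for _ in range(max_attempts):
        order = rng.permutation(len(candidates))
        chosen: list[frozenset] = []
        covered: set = set()
        for j in order:
            cand = candidates[j]
            if cand & covered:
                continue
            if covered | cand == all_tips:
                continue  # keep at least one C3 tip
            chosen.append(cand)
            covered |= cand
            if len(chosen) == n_c4_origins:
                break
        labels = {t: ("C4" if t in covered else "C3") for t in tips}
        achieved = count_c4_origins(tree, labels)
        if achieved == n_c4_origins:
            return PathwayAssignment(labels, n_c4_origins, achieved)
        if achieved > best_count:
            best_count = achieved
            best = covered
    labels = {t: ("C4" if t in best else "C3") for t in tips}
    return PathwayAssignment(labels, n_c4_origins, best_count)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def simulate_traits(
    tree: dendropy.Tree,
    pathways: PathwayAssignment | dict,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Simulate the species trait table.

    Each trait is  mean_C3 * fold^(is_C4) * exp(BM deviation) * exp(noise)
    with the BM deviation simulated along the tree at rate bm_sigma^2 and
    lognormal noise of coefficient of variation ``lognormal_cv`` (so all
    traits stay positive and contrasts are exact at zero noise).  Derived
    ratio columns K_leaf:g_s and WUE_i (A_area:g_s) are appended.
    """
    labels_map = pathways.labels if isinstance(pathways, PathwayAssignment) else pathways
    rng = np.random.default_rng(config.seed)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(tips) - set(labels_map)
    if missing:
        raise ValueError(f"pathway labels missing for tips: {sorted(missing)[:5]}")
    is_c4 = np.array([labels_map[t] == "C4" for t in tips])

    sigma_ln = (
        math.sqrt(math.log(1.0 + config.lognormal_cv**2))
        if config.lognormal_cv > 0
        else 0.0
    )
    data = {"species": tips, "pathway": np.where(is_c4, "C4", "C3")}
    for trait, mean in config.trait_means_c3.items():
        fold = config.pathway_fold_effects.get(trait, 1.0)
        values = mean * np.where(is_c4, fold, 1.0)
        if config.bm_sigma > 0:
            _, bm = simulate_bm(tree, rate=config.bm_sigma**2, rng=rng)
            values = values * np.exp(bm[:, 0])
        if sigma_ln > 0:
            values = values * np.exp(rng.normal(0.0, sigma_ln, len(tips)))
        data[trait] = values
    df = pd.DataFrame(data)
    if "K_leaf" in df and "gs" in df and "K_leaf_gs_ratio" not in df:
        df["K_leaf_gs_ratio"] = df["K_leaf"] / df["gs"]
    if "A_area" in df and "gs" in df:
        df["WUE_i"] = df["A_area"] / df["gs"]
    return df


# ---------------------------------------------------------------------------
# anatomy generation
# ---------------------------------------------------------------------------

# exemplar per-order geometry: (conduit_type, major um, minor um, count)
_MAJOR_ORDER_TEMPLATE = {
    1: [("protoxylem_lacuna", 40.0, 40.0, 1), ("xylem_I", 25.0, 20.0, 2),
        ("xylem_II", 10.0, 8.0, 4)],
    2: [("protoxylem_lacuna", 30.0, 30.0, 1), ("xylem_I", 20.0, 15.0, 2),
        ("xylem_II", 8.0, 6.0, 4)],
}
_MINOR_ORDER_TEMPLATE = {
    3: [("xylem_II", 5.0, 4.0, 3)],
    4: [("xylem_II", 4.0, 3.5, 2)],
}
# vein density (mm mm-2) per order; minor-vein Dv is higher in C4 leaves
_DV = {"C3": {1: 0.10, 2: 0.8, 3: 4.0}, "C4": {1: 0.10, 2: 0.8, 3: 7.0, 4: 3.0}}
# (bs_diam, bs_count, ms_diam, ms_count) per order; C4 bundle sheath is
# enlarged (Kranz); 4-degree veins carry a mestome sheath only
_SHEATH = {
    "C3": {1: (14.0, 12, 7.0, 10), 2: (12.0, 10, 7.0, 9), 3: (10.0, 8, 6.0, 8)},
    "C4": {1: (18.0, 12, 8.0, 10), 2: (16.0, 10, 8.0, 9), 3: (15.0, 9, 7.0, 8),
           4: (None, None, 7.0, 7)},
}
_LEAF_LENGTH_CM = {"C3": 30.0, "C4": 35.0}


def generate_anatomy(
    pathway: str,
    n_orders: int = 3,
    seed: int | None = None,
    species: str = "synthetic",
    jitter_cv: float = 0.05,
) -> pd.DataFrame:
    """One species' long-format anatomy table (schema of ANATOMY_COLUMNS).

    ``n_orders`` is 3 (C3 and most C4) or 4 (C4 Panicoideae-like, which adds
    small 4-degree veins sheathed by mestome only).  Conduit axes and vein
    densities receive small lognormal jitter around realistic exemplar
    values chosen so major (1- and 2-degree) veins dominate the xylem
    conductance, as they do in real grass leaves.
    """
    if n_orders not in (3, 4):
        raise ValueError("n_orders must be 3 or 4")
    if pathway not in ("C3", "C4"):
        raise ValueError(f"pathway must be C3 or C4, got {pathway!r}")
    if n_orders == 4 and pathway == "C3":
        raise ValueError("a fourth vein order only occurs in C4 leaves")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2)) if jitter_cv > 0 else 0.0
    jit = lambda: float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    rows = []
    orders = [1, 2, 3] + ([4] if n_orders == 4 else [])
    dv_map = dict(_DV[pathway])
    if pathway == "C4" and n_orders == 3:
        dv_map.pop(4, None)
    ll = _LEAF_LENGTH_CM[pathway] * jit()
    for order in orders:
        template = (
            _MAJOR_ORDER_TEMPLATE.get(order) or _MINOR_ORDER_TEMPLATE[order]
        )
        dv = dv_map[order] * (jit() ** 2)
        sheath = _SHEATH[pathway].get(order, (None, None, None, None))
        bs_d, bs_n, ms_d, ms_n = sheath
        for ctype, a, b, count in template:
            scale = jit()
            rows.append(
                {
                    "species": species,
                    "pathway": pathway,
                    "vein_order": order,
                    "conduit_type": ctype,
                    "major_axis_um": a * scale,
                    "minor_axis_um": b * scale,
                    "conduit_count": count,
                    "Dv_per_mm": dv,
                    "bs_cell_diam_um": np.nan if bs_d is None else bs_d * jit(),
                    "bs_cell_count": np.nan if bs_n is None else bs_n,
                    "ms_cell_diam_um": np.nan if ms_d is None else ms_d * jit(),
                    "ms_cell_count": np.nan if ms_n is None else ms_n,
                    "leaf_length_cm": ll,
                }
            )
    return pd.DataFrame(rows, columns=ANATOMY_COLUMNS)


def anatomy_table(
    species_pathways: dict, seed: int | None = None, p_four_orders: float = 0.5
) -> pd.DataFrame:
    """Anatomy tables for many species; C4 species get a 4th vein order with
    probability ``p_four_orders`` (the Panicoideae-like layout)."""
    rng = np.random.default_rng(seed)
    frames = []
    for sp, pw in species_pathways.items():
        n_orders = 4 if (pw == "C4" and rng.random() < p_four_orders) else 3
        frames.append(
            generate_anatomy(
                pw, n_orders, seed=int(rng.integers(2**31)), species=sp
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# vulnerability curves
# ---------------------------------------------------------------------------

def generate_vulnerability_curve(
    K_max: float,
    slope: float,
    noise_sd: float = 0.5,
    n_points: int = 10,
    seed: int | None = None,
    psi_min: float = -2.5,
    species: str = "synthetic",
) -> pd.DataFrame:
    """(psi, K) points on a noisy declining line K = K_max + slope * psi.

    ``slope`` is positive; psi spans [psi_min, 0] MPa on an even grid;
    Gaussian noise of sd ``noise_sd`` is added and K truncated at zero.
    """
    if K_max <= 0 or slope <= 0:
        raise ValueError("K_max and slope must be > 0")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    psi = np.linspace(0.0, psi_min, n_points)
    K = K_max + slope * psi
    if noise_sd > 0:
        K = K + rng.normal(0.0, noise_sd, n_points)
    K = np.maximum(K, 0.0)
    return pd.DataFrame({"species": species, "psi_MPa": psi, "kleaf": K})


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig | None = None) -> dict:
    """Tree + pathways + traits + anatomy + vulnerability, all from one seed.

    Returns ``{"tree", "pathways", "traits", "anatomy", "vulnerability"}``.
    Vulnerability curves take each species' simulated K_leaf as the maximum
    conductance with a slope placing P50 near -1.2 MPa.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(
        config.n_species, config.birth_rate, seed=int(rng.integers(2**31))
    )
    pathways = assign_pathways(
        tree, config.n_c4_origins, seed=int(rng.integers(2**31))
    )
    traits = simulate_traits(tree, pathways, config)
    anatomy = anatomy_table(pathways.labels, seed=int(rng.integers(2**31)))
    vuln_frames = []
    for row in traits.itertuples():
        k_max = 1.2 * row.K_leaf
        vuln_frames.append(
            generate_vulnerability_curve(
                K_max=k_max,
                slope=k_max / 2.4,  # P50 = -K_max / (2 * slope) = -1.2 MPa
                noise_sd=0.05 * k_max,
                n_points=8,
                seed=int(rng.integers(2**31)),
                species=row.species,
            )
        )
    return {
        "tree": tree,
        "pathways": pathways,
        "traits": traits,
        "anatomy": anatomy,
        "vulnerability": pd.concat(vuln_frames, ignore_index=True),
    }
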