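"""Pipeline orchestration: schema validation, stage running, provenance.

Stages (each optional): synthetic data generation -> anatomy-based xylem
conductance -> hydraulic partitioning and contrasts -> soil dry-down
simulation -> phylogenetic statistics.  Every output CSV carries a commented
metadata header (tool version, seed, config hash) and the run writes a
manifest with per-file checksums, so identical configurations reproduce
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import (
    ANATOMY_COLUMNS,
    LEGAL_TYPES,
    anatomy_from_frame,
    hydraulics_table,
)
from .drydown import scenario_suite
from .partitioning import (
    InfeasiblePartitionError,
    fit_vulnerability_table,
    outside_xylem_conductance,
    pathway_fold_differences,
    trait_ratios,
)
from .phylostats import correlation_test, pgls_fit, phylo_anova, prma_fit, write_newick
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("grasshydro")

__all__ = [
    "PipelineConfig",
    "validate_tables",
    "run_pipeline",
    "write_csv",
    "read_csv",
]


# ---------------------------------------------------------------------------
# provenance-carrying CSV I/O
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: Path, meta: dict | None = None) -> None:
    """Write a CSV with a commented metadata header block."""
    path = Path(path)
    lines = [f"# grasshydro {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

TRAIT_REQUIRED = ["species", "pathway"]
TRAIT_POSITIVE = ["gs", "K_leaf", "A_area", "D_v"]
VULN_COLUMNS = ["species", "psi_MPa", "kleaf"]


def _violation(file: str, row, column: str, message: str) -> dict:
    return {"file": str(file), "row": row, "column": column, "message": message}


def validate_traits_frame(df: pd.DataFrame, name: str = "traits") -> list[dict]:
    out = []
    for col in TRAIT_REQUIRED:
        if col not in df.columns:
            out.append(_violation(name, None, col, "required column missing"))
    if "pathway" in df.columns:
        bad = ~df["pathway"].isin(["C3", "C4"])
        for i in df.index[bad]:
            out.append(
                _violation(name, int(i), "pathway", f"unknown pathway {df.loc[i, 'pathway']!r}")
            )
    for col in TRAIT_POSITIVE:
        if col in df.columns:
            bad = df[col].notna() & ~(df[col] > 0)
            for i in df.index[bad]:
                out.append(
                    _violation(name, int(i), col, f"must be positive, got {df.loc[i, col]}")
                )
    return out


def validate_anatomy_frame(df: pd.DataFrame, name: str = "anatomy") -> list[dict]:
    out = []
    missing = [c for c in ANATOMY_COLUMNS if c not in df.columns]
    for col in missing:
        out.append(_violation(name, None, col, "required column missing"))
    if missing:
        return out
    for i, row in df.iterrows():
        order = int(row["vein_order"])
        legal = LEGAL_TYPES.get(order)
        if legal is None:
            out.append(_violation(name, int(i), "vein_order", f"invalid order {order}"))
            continue
        if row["conduit_type"] not in legal:
            out.append(
                _violation(
                    name, int(i), "conduit_type",
                    f"{row['conduit_type']!r} not allowed in {order}-degree veins "
                    "(minor orders carry type II conduits only)",
                )
            )
        for col in ("major_axis_um", "minor_axis_um", "Dv_per_mm", "leaf_length_cm"):
            if not row[col] > 0:
                out.append(_violation(name, int(i), col, f"must be positive, got {row[col]}"))
    return out


def validate_vulnerability_frame(df: pd.DataFrame, name: str = "vulnerability") -> list[dict]:
    out = []
    missing = [c for c in VULN_COLUMNS if c not in df.columns]
    for col in missing:
        out.append(_violation(name, None, col, "required column missing"))
    if missing:
        return out
    bad_psi = df["psi_MPa"] > 0
    for i in df.index[bad_psi]:
        out.append(_violation(name, int(i), "psi_MPa", "water potential must be <= 0"))
    bad_k = ~(df["kleaf"] >= 0)
    for i in df.index[bad_k]:
        out.append(_violation(name, int(i), "kleaf", f"must be >= 0, got {df.loc[i, 'kleaf']}"))
    for sp, n in df.groupby("species").size().items():
        if n < 3:
            out.append(_violation(name, None, "species", f"{sp}: fewer than 3 points"))
    return out


def validate_tables(files: dict) -> list[dict]:
    """Validate input CSVs; keys among {traits, anatomy, vulnerability}.

    Values may be paths or DataFrames.  Returns a list of violations, each
    citing file, row and column; clean inputs yield an empty list.
    """
    validators = {
        "traits": validate_traits_frame,
        "anatomy": validate_anatomy_frame,
        "vulnerability": validate_vulnerability_frame,
    }
    out = []
    for key, value in files.items():
        if key not in validators:
            raise KeyError(f"unknown table kind {key!r}")
        df = value if isinstance(value, pd.DataFrame) else read_csv(Path(value))
        out.extend(validators[key](df, name=key))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 42
    n_species: int = 27
    n_c4_origins: int = 11
    stages: tuple = ("synthetic", "anatomy", "partition", "drydown", "stats")
    ll_convention: str = "half-squared"
    cc_exponent: float = 1.0
    n_sim_anova: int = 1000
    drydown_dt_s: float = 3600.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/logging excluded)."""
        fields = asdict(self)
        fields.pop("out_dir", None)
        fields.pop("log_level", None)
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write a provenance manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    Re-running with an identical config reproduces identical checksums.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": config.config_hash()}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "checksums": {},
    }

    def _record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "completed"
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)

    dataset = None
    if "synthetic" in config.stages:
        logger.info("stage synthetic: %d species", config.n_species)
        syn = SyntheticConfig(
            n_species=config.n_species,
            n_c4_origins=config.n_c4_origins,
            seed=config.seed,
        )
        dataset = generate_dataset(syn)
        traits_p = out / "traits.csv"
        anatomy_p = out / "anatomy.csv"
        vuln_p = out / "vulnerability.csv"
        tree_p = out / "tree.nwk"
        write_csv(dataset["traits"], traits_p, meta)
        write_csv(dataset["anatomy"], anatomy_p, meta)
        write_csv(dataset["vulnerability"], vuln_p, meta)
        tree_p.write_text(write_newick(dataset["tree"]) + "\n")
        problems = validate_tables(
            {"traits": dataset["traits"], "anatomy": dataset["anatomy"],
             "vulnerability": dataset["vulnerability"]}
        )
        if problems:
            raise RuntimeError(f"synthetic stage produced invalid tables: {problems[:3]}")
        _record("synthetic", traits_p, anatomy_p, vuln_p, tree_p)
    else:
        manifest["stages"]["synthetic"] = "skipped"

    hydraulics = None
    if "anatomy" in config.stages:
        if dataset is None:
            raise RuntimeError("anatomy stage requires the synthetic stage (or input files via the CLI)")
        logger.info("stage anatomy")
        leaves = anatomy_from_frame(dataset["anatomy"])
        hydraulics = hydraulics_table(
            leaves, ll_convention=config.ll_convention, cc_exponent=config.cc_exponent
        )
        hyd_p = out / "hydraulics.csv"
        write_csv(hydraulics, hyd_p, meta)
        _record("anatomy", hyd_p)
    else:
        manifest["stages"]["anatomy"] = "skipped"

    if "partition" in config.stages:
        if dataset is None or hydraulics is None:
            raise RuntimeError("partition stage requires synthetic and anatomy stages")
        logger.info("stage partition")
        traits = trait_ratios(dataset["traits"])
        merged = traits.merge(
            hydraulics[["species", "K_xc", "major_fraction"]], on="species"
        )
        k_oxc = []
        for row in merged.itertuples():
            try:
                k_oxc.append(outside_xylem_conductance(row.K_leaf, row.K_xc))
            except InfeasiblePartitionError:
                k_oxc.append(np.nan)
        merged["K_oxc"] = k_oxc
        fits = fit_vulnerability_table(dataset["vulnerability"])
        contrasts = pathway_fold_differences(merged)
        prof_p, fits_p, ctr_p = (
            out / "profiles.csv", out / "vulnerability_fits.csv", out / "contrasts.csv",
        )
        write_csv(merged, prof_p, meta)
        write_csv(fits, fits_p, meta)
        write_csv(contrasts, ctr_p, meta)
        _record("partition", prof_p, fits_p, ctr_p)
    else:
        manifest["stages"]["partition"] = "skipped"

    if "drydown" in config.stages:
        logger.info("stage drydown")
        suite = scenario_suite(dt_s=config.drydown_dt_s)
        traj_paths = []
        for (env_name, label), traj in suite["trajectories"].items():
            p = out / f"drydown_{env_name}_{label}.csv"
            write_csv(traj.records, p, meta)
            traj_paths.append(p)
        summary_p = out / "drydown_summary.csv"
        write_csv(suite["summary"], summary_p, meta)
        _record("drydown", summary_p, *traj_paths)
    else:
        manifest["stages"]["drydown"] = "skipped"

    if "stats" in config.stages:
        if dataset is None:
            raise RuntimeError("stats stage requires the synthetic stage")
        logger.info("stage stats")
        tree = dataset["tree"]
        traits = dataset["traits"].set_index("species")
        rows = []
        rng = np.random.default_rng(config.seed)
        for trait in ("gs", "K_leaf", "A_area", "K_leaf_gs_ratio"):
            res = phylo_anova(
                traits[trait], traits["pathway"], tree,
                n_sim=config.n_sim_anova, seed=int(rng.integers(2**31)),
            )
            rows.append(
                {"analysis": "phylo_anova", "trait": trait, "estimate": res["F_obs"],
                 "p": res["p_phylo"], "lambda": np.nan, "n_sim": res["n_sim"]}
            )
        for y_name, x_name in (("A_area", "gs"), ("A_area", "K_leaf"), ("gs", "K_leaf")):
            fit = pgls_fit(np.log(traits[y_name]), np.log(traits[x_name]), tree)
            rows.append(
                {"analysis": "pgls", "trait": f"log {y_name} ~ log {x_name}",
                 "estimate": fit.coefficients[1], "p": fit.p_values[1],
                 "lambda": fit.lam, "n_sim": np.nan}
            )
            rma = prma_fit(np.log(traits[x_name]), np.log(traits[y_name]), tree)
            rows.append(
                {"analysis": "prma", "trait": f"log {y_name} ~ log {x_name}",
                 "estimate": rma["slope"], "p": np.nan, "lambda": 1.0,
                 "n_sim": np.nan}
            )
            cor = correlation_test(np.log(traits[x_name]), np.log(traits[y_name]))
            rows.append(
                {"analysis": "pearson", "trait": f"log {y_name} ~ log {x_name}",
                 "estimate": cor["r"], "p": cor["p"], "lambda": np.nan,
                 "n_sim": np.nan}
            )
        stats_p = out / "stats.csv"
        write_csv(pd.DataFrame(rows), stats_p, meta)
        _record("stats", stats_p)
    else:
        manifest["stages"]["stats"] = "skipped"

    manifest_p = out / "manifest.json"
    manifest_p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
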