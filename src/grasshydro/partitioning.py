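"""Partitioning of leaf hydraulic conductance and trait contrasts.

Leaf hydraulic conductance K_leaf is modeled as two resistances in series:
the vein xylem conduit pathway (K_xc, from anatomy) and the outside-xylem
pathway (K_oxc, bundle sheath + mesophyll):

    1/K_leaf = 1/K_xc + 1/K_oxc

so K_oxc is obtained by rearrangement.  Also here: linear vulnerability-curve
fits and the P50 statistic (water potential at 50% loss of the fitted maximum
conductance), species-mean aggregation across studies, trait ratios, C4/C3
fold contrasts, and Dixon's Q test for single outliers in small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InfeasiblePartitionError",
    "NoDeclineError",
    "VulnerabilityFit",
    "outside_xylem_conductance",
    "series_conductance",
    "fit_vulnerability",
    "trait_ratios",
    "aggregate_species_means",
    "pathway_fold_differences",
    "dixon_outlier_test",
]


class InfeasiblePartitionError(ValueError):
    """K_xc <= K_leaf: the outside-xylem resistance would be <= 0."""


class NoDeclineError(ValueError):
    """The vulnerability fit has slope <= 0, so P50 is undefined."""


def outside_xylem_conductance(K_leaf: float, K_xc: float) -> float:
    """Outside-xylem conductance K_oxc = (1/K_leaf - 1/K_xc)^-1.

    Requires K_xc > K_leaf > 0: the whole-leaf conductance cannot exceed
    either of its series components.
    """
    if not (K_leaf > 0):
        raise InfeasiblePartitionError(f"K_leaf must be > 0, got {K_leaf}")
    if not (K_xc > K_leaf):
        raise InfeasiblePartitionError(
            f"K_xc ({K_xc}) must exceed K_leaf ({K_leaf}) for a series partition"
        )
    return 1.0 / (1.0 / K_leaf - 1.0 / K_xc)


def series_conductance(K_a: float, K_b: float) -> float:
    """Conductance of two conductances in series: (1/K_a + 1/K_b)^-1."""
    if K_a <= 0 or K_b <= 0:
        raise ValueError("series components must be > 0")
    return 1.0 / (1.0 / K_a + 1.0 / K_b)


# ---------------------------------------------------------------------------
# vulnerability curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VulnerabilityFit:
    """A fitted linear decline K_leaf = K_max + slope * psi (slope > 0)."""

    K_max: float
    slope: float
    P50: float
    r_squared: float
    p_value: float
    method: str = "ols"

    def predict(self, psi):
        return self.K_max + self.slope * np.asarray(psi)


def fit_vulnerability(
    psi, K, method: str = "ols"
) -> VulnerabilityFit:
    """Fit K = K_max + slope*psi and locate P50 = -K_max / (2*slope).

    ``psi`` are leaf water potentials (MPa, <= 0) and ``K`` the conductances
    measured at them.  P50 is the potential at which the fitted line reaches
    half its y-intercept.  ``method`` is ``"ols"`` (default) or ``"sma"``
    (standardized major axis: slope = sign(r) * sd(K)/sd(psi), line through
    the means) for sensitivity analysis.

    Raises NoDeclineError if the fitted slope is not positive (conductance
    not declining with more negative potential).
    """
    psi = np.asarray(psi, dtype=float)
    K = np.asarray(K, dtype=float)
    if psi.size < 3:
        raise ValueError("need at least 3 points for a vulnerability fit")
    if np.ptp(psi) == 0:
        raise ValueError("psi values must not all be identical")

    res = stats.linregress(psi, K)
    if method == "ols":
        slope, intercept = res.slope, res.intercept
    elif method == "sma":
        r = res.rvalue
        sd_ratio = np.std(K, ddof=1) / np.std(psi, ddof=1)
        slope = math.copysign(sd_ratio, r if r != 0 else 1.0)
        intercept = K.mean() - slope * psi.mean()
    else:
        raise ValueError(f"unknown method {method!r}")

    if slope <= 0:
        raise NoDeclineError(
            f"fitted slope {slope:.4g} <= 0: no conductance decline, P50 undefined"
        )
    return VulnerabilityFit(
        K_max=float(intercept),
        slope=float(slope),
        P50=float(-intercept / (2.0 * slope)),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        method=method,
    )


def fit_vulnerability_table(df: pd.DataFrame, method: str = "ols") -> pd.DataFrame:
    """Fit one vulnerability curve per species from a (species, psi_MPa,
    kleaf) long table; species with no decline get NaN P50 and a flag."""
    rows = []
    for species, sdf in df.groupby("species", sort=True):
        try:
            fit = fit_vulnerability(sdf["psi_MPa"], sdf["kleaf"], method)
            rows.append(
                {
                    "species": species,
                    "K_max": fit.K_max,
                    "slope": fit.slope,
                    "P50": fit.P50,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                    "no_decline": False,
                }
            )
        except NoDeclineError:
            rows.append(
                {
                    "species": species,
                    "K_max": np.nan,
                    "slope": np.nan,
                    "P50": np.nan,
                    "r_squared": np.nan,
                    "p_value": np.nan,
                    "no_decline": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait ratios and contrasts
# ---------------------------------------------------------------------------

def trait_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Append hydraulic-supply and water-use-efficiency ratio columns.

    Adds ``K_leaf_gs_ratio`` (mmol mol-1 MPa-1), ``WUE_i`` = A_area:g_s
    (umol mol-1) and ``K_leaf_Aarea_ratio`` where the inputs exist.  Rows
    with non-positive g_s or A_area are flagged (``ratio_flagged``) and get
    NaN ratios rather than being dropped.
    """
    out = table.copy()
    gs = out.get("gs")
    if gs is None:
        raise KeyError("trait table must contain a 'gs' column")
    bad = ~(gs > 0)
    if "A_area" in out:
        bad |= ~(out["A_area"] > 0)
    out["ratio_flagged"] = bad
    with np.errstate(divide="ignore", invalid="ignore"):
        if "K_leaf" in out:
            out["K_leaf_gs_ratio"] = np.where(bad, np.nan, out["K_leaf"] / gs)
        if "A_area" in out:
            out["WUE_i"] = np.where(bad, np.nan, out["A_area"] / gs)
        if "K_leaf" in out and "A_area" in out:
            out["K_leaf_Aarea_ratio"] = np.where(
                bad, np.nan, out["K_leaf"] / out["A_area"]
            )
    return out


def aggregate_species_means(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-study trait records to one row of species means.

    ``records`` is long format with columns (species, study, pathway, trait,
    value).  Each trait is averaged per species across studies, each study
    weighted once.  The K_leaf:g_s ratio is computed from the aggregated
    species means, but only for species for which at least one study reported
    both K_leaf and g_s (otherwise the ratio pairs values measured under
    different conditions).
    """
    required = {"species", "study", "pathway", "trait", "value"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records table missing columns: {sorted(missing)}")
    pathway = records.groupby("species")["pathway"].agg(lambda s: set(s.dropna()))
    conflict = pathway[pathway.apply(len) > 1]
    if len(conflict):
        raise ValueError(
            f"conflicting pathway labels for species: {list(conflict.index)}"
        )

    means = (
        records.groupby(["species", "trait"])["value"].mean().unstack("trait")
    )
    means["pathway"] = pathway.apply(lambda s: next(iter(s)))
    means = means.reset_index()

    if {"K_leaf", "gs"}.issubset(records["trait"].unique()):
        wide = records.pivot_table(
            index=["species", "study"], columns="trait", values="value"
        )
        has_both = (
            wide.get("K_leaf").notna() & wide.get("gs").notna()
        ).groupby("species").any()
        ratio = means.set_index("species").eval("K_leaf / gs")
        ratio[~has_both.reindex(ratio.index, fill_value=False)] = np.nan
        means["K_leaf_gs_ratio"] = ratio.values
    return means


def pathway_fold_differences(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    statistic: str = "arithmetic",
) -> pd.DataFrame:
    """Per-trait C3 vs C4 contrast with C3 fixed at 100%.

    Returns rows (trait, C3_mean, C4_mean, pct_of_C3) where pct_of_C3 =
    100 * C4_mean / C3_mean; means are arithmetic means of species means
    (each species weighted once), or geometric with
    ``statistic="geometric"``.
    """
    if "pathway" not in table:
        raise KeyError("trait table must contain a 'pathway' column")
    groups = dict(list(table.groupby("pathway")))
    for pw in ("C3", "C4"):
        if pw not in groups or len(groups[pw]) == 0:
            raise ValueError(f"pathway {pw} absent: contrast undefined")
    if traits is None:
        traits = [
            c
            for c in table.columns
            if c not in ("species", "pathway", "ratio_flagged")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for trait in traits:
        c3 = groups["C3"][trait].dropna()
        c4 = groups["C4"][trait].dropna()
        if statistic == "arithmetic":
            m3, m4 = c3.mean(), c4.mean()
        elif statistic == "geometric":
            m3 = float(np.exp(np.log(c3).mean()))
            m4 = float(np.exp(np.log(c4).mean()))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.append(
            {
                "trait": trait,
                "C3_mean": m3,
                "C4_mean": m4,
                "pct_of_C3": 100.0 * m4 / m3,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dixon's Q outlier test
# ---------------------------------------------------------------------------

# Two-sided critical values for Dixon's Q10 = gap/range at alpha = 0.05,
# n = 3..30 (Rorabacher 1991, Anal. Chem. 63:139).
_DIXON_Q10_CRIT_05 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


def dixon_outlier_test(values, alpha: float = 0.05) -> dict:
    """Dixon's Q10 test for a single outlier in a small sample (3 <= n <= 30).

    Q = (gap between the extreme value and its nearest neighbour) / range,
    evaluated at whichever end has the larger gap, against the two-sided
    critical value.  Returns ``{"Q", "outlier_index", "critical", "flagged"}``
    with ``outlier_index`` the position in ``values`` (or None).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not 3 <= n <= 30:
        raise ValueError(f"Dixon's test requires 3 <= n <= 30, got n={n}")
    if alpha != 0.05:
        raise ValueError("critical values embedded for alpha=0.05 only")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng = xs[-1] - xs[0]
    if rng == 0:
        raise ValueError("zero range: Dixon's Q undefined for constant data")
    q_low = (xs[1] - xs[0]) / rng
    q_high = (xs[-1] - xs[-2]) / rng
    if q_high >= q_low:
        Q, idx = q_high, int(order[-1])
    else:
        Q, idx = q_low, int(order[0])
    crit = _DIXON_Q10_CRIT_05[n]
    flagged = Q > crit
    return {
        "Q": float(Q),
        "outlier_index": idx if flagged else None,
        "critical": crit,
        "flagged": bool(flagged),
    }
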