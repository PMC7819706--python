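"""Age-trend statistics: phylostratigraphy slopes and their comparisons.

A phylostratigraphy slope is the ordinary least-squares slope of a sequence
property against assigned age, with one datapoint per homology group and
age expressed in billions of years so that slope magnitudes read as
"property units per BY".  Composition slopes are fit per amino acid on
percentage points.  Slope profiles over the 20 amino acids are compared
across lineages, or against external amino-acid properties (hydrophobicity
via 1-RSA, changeability, recruitment order into the genetic code,
metabolic cost), by rank or linear correlation; the standard error of a
Spearman rho comes from the Fisher z-transformation.  Raw, untransformed
property values are regressed by default; Box-Cox and arcsine transforms
are available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .sequence_metrics import STANDARD_AA

__all__ = [
    "SlopeResult",
    "CorrelationResult",
    "phylostrat_slope",
    "aa_slope_profile",
    "correlate_profiles",
    "consensus_recruitment_order",
    "min_age_sweep",
    "welch_t_test",
    "wilcoxon_paired",
    "binomial_sign_test",
    "transform_values",
    "load_aa_properties",
]


@dataclass(frozen=True)
class SlopeResult:
    property_name: str
    subset: str
    slope: float
    se: float
    r_squared: float
    p_value: float
    n: int
    ci95: tuple[float, float]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    rho: float
    p_value: float | None
    n: int
    fisher_se: float | None = None  # SE on the Fisher z scale
    rho_ci: tuple[float, float] | None = None


def phylostrat_slope(
    age_my: Sequence[float],
    values: Sequence[float],
    property_name: str = "value",
    subset: str = "all",
) -> SlopeResult | None:
    """OLS slope of a property on age (converted MY -> BY).

    Datapoints with a missing value are dropped (their count is implicit in
    ``n``); fewer than three remaining points yields ``None``.  Outliers are
    included.
    """
    age = np.asarray(age_my, dtype=float) / 1000.0
    val = np.asarray(values, dtype=float)
    ok = np.isfinite(age) & np.isfinite(val)
    age, val = age[ok], val[ok]
    if age.size < 3 or np.ptp(age) == 0:
        return None
    model = sm.OLS(val, sm.add_constant(age)).fit()
    ci = model.conf_int(alpha=0.05)
    return SlopeResult(
        property_name=property_name,
        subset=subset,
        slope=float(model.params[1]),
        se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(age.size),
        ci95=(float(ci[1][0]), float(ci[1][1])),
    )


def aa_slope_profile(
    datapoints: pd.DataFrame,
    subset: str = "all",
    age_col: str = "age_my",
    aa_cols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-amino-acid composition slopes, in percentage points per BY.

    ``datapoints`` must carry an age column and one composition-fraction
    column per amino acid (default names ``comp_A`` .. ``comp_Y``).  Failed
    fits propagate as missing rows.
    """
    if aa_cols is None:
        aa_cols = {aa: f"comp_{aa}" for aa in STANDARD_AA}
    rows = []
    for aa in STANDARD_AA:
        res = phylostrat_slope(
            datapoints[age_col], datapoints[aa_cols[aa]] * 100.0,
            property_name=f"pct_{aa}", subset=subset,
        )
        rows.append(
            {
                "aa": aa,
                "slope": res.slope if res else np.nan,
                "se": res.se if res else np.nan,
                "p_value": res.p_value if res else np.nan,
                "n": res.n if res else 0,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def _fisher_se(n: int) -> float:
    return math.sqrt(1.06 / (n - 3))


def correlate_profiles(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> CorrelationResult:
    """Correlate two paired profiles (e.g. 20 amino-acid slope vectors).

    Missing entries are dropped pairwise.  Spearman uses average ranks for
    ties and the t-approximation for the p-value; its SE is reported on the
    Fisher z scale, with a back-transformed rho interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    p_out = float(p) if n >= 4 else None
    fisher_se = rho_ci = None
    if n > 3:
        se = _fisher_se(n)
        if abs(rho) < 1.0:
            z = math.atanh(rho)
            rho_ci = (math.tanh(z - se), math.tanh(z + se))
        else:
            rho_ci = (rho, rho)
        fisher_se = se
    return CorrelationResult(
        method=method, rho=float(rho), p_value=p_out, n=int(n),
        fisher_se=fisher_se, rho_ci=rho_ci,
    )


def consensus_recruitment_order(
    criteria_matrix: pd.DataFrame, excluded_criteria: Sequence[str] = ()
) -> pd.Series:
    """Mean rank over ranking criteria (rows = 20 amino acids).

    Reproduces a consensus chronology of amino-acid recruitment into the
    genetic code as the plain mean of the retained criteria's ranks, with
    no subsequent smoothing step.
    """
    unknown = set(excluded_criteria) - set(criteria_matrix.columns)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    kept = [c for c in criteria_matrix.columns if c not in set(excluded_criteria)]
    if not kept:
        raise ValueError("all criteria excluded")
    return criteria_matrix[kept].mean(axis=1)


def min_age_sweep(
    datapoints: pd.DataFrame,
    thresholds_my: Sequence[float],
    property_vector: pd.Series,
    age_col: str = "age_my",
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of the composition-slope profile with an amino-acid
    property, recomputed over pfams at least as old as each threshold.

    Thresholds that leave too few datapoints (or fewer than four amino
    acids with defined slopes) yield missing entries.
    """
    rows = []
    for thr in thresholds_my:
        sub = datapoints[datapoints[age_col] >= thr]
        if len(sub) < 3:
            rows.append({"threshold_my": thr, "rho": np.nan, "p_value": np.nan,
                         "n_pfams": len(sub), "n_aa": 0, "fisher_se": np.nan})
            continue
        profile = aa_slope_profile(sub, subset=f"age>={thr}", age_col=age_col)
        paired = profile["slope"].reindex(property_vector.index)
        ok = paired.notna() & property_vector.notna()
        if ok.sum() < 4:
            rows.append({"threshold_my": thr, "rho": np.nan, "p_value": np.nan,
                         "n_pfams": len(sub), "n_aa": int(ok.sum()),
                         "fisher_se": np.nan})
            continue
        res = correlate_profiles(paired[ok], property_vector[ok], method=method)
        rows.append({"threshold_my": thr, "rho": res.rho, "p_value": res.p_value,
                     "n_pfams": len(sub), "n_aa": res.n, "fisher_se": res.fisher_se})
    return pd.DataFrame(rows)


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Welch's unequal-variance t-test (two-sided)."""
    res = sps.ttest_ind(values_a, values_b, equal_var=False)
    return {"test": "welch_t", "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "n_a": len(values_a), "n_b": len(values_b)}


def wilcoxon_paired(
    values_a: Mapping[str, float], values_b: Mapping[str, float]
) -> dict:
    """Wilcoxon signed-rank test on paired differences, matched by key."""
    if set(values_a) != set(values_b):
        raise ValueError("paired test requires identical key sets")
    keys = sorted(values_a)
    diffs = np.array([values_a[k] - values_b[k] for k in keys])
    if np.all(diffs == 0):
        return {"test": "wilcoxon", "statistic": 0.0, "p_value": 1.0, "n": len(keys)}
    res = sps.wilcoxon(diffs)
    return {"test": "wilcoxon", "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "n": len(keys)}


def binomial_sign_test(n_positive: int, n_total: int) -> dict:
    """One-tailed exact binomial test of P(positive) = 1/2 against 'greater'."""
    res = sps.binomtest(n_positive, n_total, p=0.5, alternative="greater")
    return {"test": "binomial_one_tailed", "p_value": float(res.pvalue),
            "n_positive": n_positive, "n_total": n_total}


def transform_values(values: Sequence[float], kind: str) -> tuple[np.ndarray, dict]:
    """Optional normalizing transforms.

    ``boxcox`` chooses lambda by maximum likelihood (a positive shift is
    applied and recorded when values are not strictly positive); ``arcsine``
    is asin(sqrt(x)) for proportions in [0, 1].
    """
    vals = np.asarray(values, dtype=float)
    if kind == "boxcox":
        shift = 0.0
        if vals.min() <= 0:
            shift = -vals.min() + 1e-6
        out, lam = sps.boxcox(vals + shift)
        return out, {"lambda": float(lam), "shift": shift}
    if kind == "arcsine":
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("arcsine transform requires values in [0, 1]")
        return np.arcsin(np.sqrt(vals)), {}
    raise ValueError(f"unknown transform {kind!r}")


def load_aa_properties() -> pd.DataFrame:
    """Bundled per-amino-acid property table.

    Columns: ``hydrophobicity_1mrsa`` (1 - mean relative solvent
    accessibility), ``changeability`` (relative evolutionary changeability),
    ``recruitment_rank`` (consensus order of recruitment into the genetic
    code, 1 = earliest), ``cost_atp`` (high-energy phosphate bonds per
    molecule, yeast aerobic), and ``essential_animal``.
    """
    with resources.files("phylostrat.data").joinpath("aa_properties.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("aa")
    return df.loc[list(STANDARD_AA)]
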