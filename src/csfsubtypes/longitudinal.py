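"""Longitudinal biomarker slopes per subtype.

Change over time in Aβ42, p-tau, and delayed-memory scores is estimated
with a linear model of marker value on years from baseline with
subject-level random intercepts (repeated CSF samples are correlated
within subjects).  When the variance component is not estimable the
estimator falls back to an ordinary linear model with subject-clustered
robust standard errors, and the estimate is flagged.

Note on direction: the memory score is a delayed-word-recall error count,
so a *positive* slope means worsening performance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "subtype", "time_years", "marker", "value")

#: markers where an increasing value means decline
WORSENS_WHEN_INCREASING = ("ptau", "memory")


@dataclass
class SlopeEstimate:
    subtype: int | None
    marker: str
    beta: float  # marker units per year
    se: float
    p: float
    n_subjects: int
    n_observations: int
    method: str  # "mixed" or "ols_cluster"
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.direction:
            worsening = (self.beta > 0) == (self.marker in WORSENS_WHEN_INCREASING)
            self.direction = "worsening" if worsening else "improving"


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"longitudinal table missing columns {sorted(missing)}")
    if (table["time_years"] < 0).any():
        raise ValueError("visit times must be nonnegative")


def _subset(table: pd.DataFrame, marker: str, subtype: int | None = None) -> pd.DataFrame:
    rows = table[table["marker"] == marker]
    if subtype is not None:
        rows = rows[rows["subtype"] == subtype]
    if rows.empty:
        raise ValueError(f"no rows for marker {marker!r}" + (f", subtype {subtype}" if subtype else ""))
    return rows


def _fit_mixed(rows: pd.DataFrame, formula: str):
    """Random-intercept fit with an OLS cluster-robust fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, rows, groups=rows["subject_id"])
            fit = model.fit(reml=True, method="lbfgs")
            if np.isfinite(fit.bse.iloc[:-1]).all():
                return fit, "mixed"
        except Exception as exc:  # singular/unconverged variance component
            logger.warning("mixed model failed (%s); using clustered OLS", exc)
    ols = smf.ols(formula, rows).fit(
        cov_type="cluster", cov_kwds={"groups": rows["subject_id"]}
    )
    return ols, "ols_cluster"


def fit_subtype_slope(table: pd.DataFrame, marker: str, subtype: int) -> SlopeEstimate:
    """Per-year slope of one marker within one subtype.

    Requires at least 2 subjects with at least 2 visits; returns the Wald
    estimate, SE, and two-sided p for the time effect.
    """
    _check_table(table)
    rows = _subset(table, marker, subtype)
    visits = rows.groupby("subject_id").size()
    if (visits >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 visits to estimate a slope")
    fit, method = _fit_mixed(rows, "value ~ time_years")
    return SlopeEstimate(
        subtype=subtype,
        marker=marker,
        beta=float(fit.params["time_years"]),
        se=float(fit.bse["time_years"]),
        p=float(fit.pvalues["time_years"]),
        n_subjects=rows["subject_id"].nunique(),
        n_observations=len(rows),
        method=method,
    )


def fit_all_slopes(table: pd.DataFrame, markers: list[str] | None = None) -> list[SlopeEstimate]:
    """Slope estimates for every (marker, subtype) combination present."""
    _check_table(table)
    if markers is None:
        markers = sorted(table["marker"].unique())
    out = []
    for marker in markers:
        for subtype in sorted(table.loc[table["marker"] == marker, "subtype"].unique()):
            try:
                out.append(fit_subtype_slope(table, marker, int(subtype)))
            except ValueError as exc:
                logger.warning("skipping %s subtype %s: %s", marker, subtype, exc)
    return out


def compare_slopes(table: pd.DataFrame, marker: str) -> dict:
    """Test whether slopes differ between subtypes (subtype x time
    interaction, joint Wald test)."""
    _check_table(table)
    rows = _subset(table, marker)
    if rows["subtype"].nunique() < 2:
        raise ValueError("slope comparison needs >= 2 subtypes")
    fit, method = _fit_mixed(rows, "value ~ time_years * C(subtype)")
    terms = [name for name in fit.params.index if ":time_years" in name or "time_years:" in name]
    wald = fit.wald_test(" = 0, ".join(terms) + " = 0", scalar=True)
    per_subtype = {}
    base = float(fit.params["time_years"])
    for subtype in sorted(rows["subtype"].unique()):
        key = f"time_years:C(subtype)[T.{subtype}]"
        per_subtype[int(subtype)] = base + (float(fit.params[key]) if key in fit.params else 0.0)
    return {
        "marker": marker,
        "p_interaction": float(wald.pvalue),
        "statistic": float(wald.statistic),
        "slopes": per_subtype,
        "method": method,
    }


def baseline_comparison(table: pd.DataFrame, marker: str, tol: float = 1e-9) -> dict:
    """Compare baseline (time 0) marker values across subtypes with a
    one-way linear model; subjects without a baseline row are dropped."""
    _check_table(table)
    rows = _subset(table, marker)
    baseline = rows[rows["time_years"] <= tol]
    dropped = set(rows["subject_id"]) - set(baseline["subject_id"])
    if dropped:
        logger.warning("%d subject(s) without baseline measurement dropped", len(dropped))
    if baseline["subtype"].nunique() < 2:
        raise ValueError("baseline comparison needs >= 2 subtypes")
    fit = smf.ols("value ~ C(subtype)", baseline).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    return {
        "marker": marker,
        "p": float(anova.loc["C(subtype)", "PR(>F)"]),
        "marginal_means": baseline.groupby("subtype")["value"].mean(),
        "n_dropped": len(dropped),
    }
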