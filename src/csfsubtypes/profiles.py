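"""Subtype characterization.

Covers loading-outlier detection, protein-to-subtype labelling,
subtype-specific protein screens (conjunction of pairwise linear-model
contrasts), the overlap coefficient between protein sets, cell-type
specificity labelling against an expression reference, and post-hoc
comparisons of subject characteristics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NOT_DETECTED = "not detected"
NON_SPECIFIC = "non-specific"


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # subject -> subtype in 1..k
    loadings: pd.DataFrame  # subjects x k, rows sum to 1
    outliers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.outliers) & set(self.labels.index):
            raise ValueError("outliers must be disjoint from labelled subjects")


def detect_loading_outliers(
    loadings: pd.DataFrame,
    threshold: float = 3.5,
    max_fraction: float = 0.2,
) -> list[str]:
    """Flag subjects whose maximum loading is a robust-z outlier.

    The robust z-score is ``0.6745 (x − median) / MAD`` of each subject's
    maximum raw loading; subjects with ``|z| > threshold`` are flagged.
    Flagging more than ``max_fraction`` of subjects raises instead of
    excluding (a sign the rule, not the data, is off).
    """
    x = loadings.max(axis=1).to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        mad = np.mean(np.abs(x - med))  # fallback for half-constant loadings
        if mad == 0:
            return []
    z = 0.6745 * (x - med) / mad
    flagged = [s for s, zi in zip(loadings.index, z) if abs(zi) > threshold]
    if len(flagged) > max_fraction * len(x):
        raise ValueError(
            f"{len(flagged)}/{len(x)} subjects flagged as loading outliers; "
            "refusing to exclude without an explicit override"
        )
    return flagged


def label_proteins(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Label each protein by the subtype with the highest mean abundance.

    Exact ties leave the protein unlabelled (NaN) and are logged.
    """
    labels = labels.loc[matrix.index]
    group_means = matrix.groupby(labels).mean()  # subtype x proteins
    if (group_means.count(axis=0) == 0).any():
        raise ValueError("every subtype needs at least one subject")
    best = group_means.idxmax(axis=0).astype(float)
    sorted_means = np.sort(group_means.to_numpy(), axis=0)
    tied = np.isclose(sorted_means[-1], sorted_means[-2])
    if tied.any():
        tied_proteins = group_means.columns[tied]
        logger.warning("%d protein(s) tied across subtypes; left unlabelled", len(tied_proteins))
        best[tied_proteins] = np.nan
    best.name = "subtype"
    return best


def _pairwise_contrasts(matrix: pd.DataFrame, labels: pd.Series) -> dict:
    """Pooled-variance linear-model contrasts of subtype means, per protein.

    Equivalent to `t_test` contrasts on a one-way OLS fit: effect
    ``mean_s − mean_t``, SE from the pooled residual mean square with
    ``N − k`` degrees of freedom, two-sided p.
    """
    labels = labels.loc[matrix.index]
    subtypes = sorted(labels.unique())
    X = matrix.to_numpy(dtype=float)
    N, k = X.shape[0], len(subtypes)
    masks = {s: (labels == s).to_numpy() for s in subtypes}
    ns = {s: masks[s].sum() for s in subtypes}
    means = {s: X[masks[s]].mean(axis=0) for s in subtypes}
    sse = np.zeros(X.shape[1])
    for s in subtypes:
        sse += ((X[masks[s]] - means[s]) ** 2).sum(axis=0)
    df = N - k
    mse = sse / df
    out = {}
    for s in subtypes:
        for t in subtypes:
            if s == t:
                continue
            effect = means[s] - means[t]
            se = np.sqrt(mse * (1.0 / ns[s] + 1.0 / ns[t]))
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
            pval = 2.0 * stats.t.sf(np.abs(tval), df)
            out[(s, t)] = (effect, pval)
    return out


def subtype_specific_proteins(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
    min_group: int = 3,
) -> dict[int, dict[str, list[str]]]:
    """Proteins significantly higher (or lower) in one subtype than in each
    other subtype.

    For every subtype ``s`` and protein, two-sided pooled-variance contrasts
    of ``s`` against each other subtype are computed; the protein is
    ``s``-specific-increased iff every contrast has positive effect and
    ``p < alpha`` (conjunction rule, uncorrected by default;
    ``correction="bh"`` applies Benjamini–Hochberg per contrast family).
    Returns ``{subtype: {"increased": [...], "decreased": [...]}}``.
    """
    labels = labels.loc[matrix.index]
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes")
    counts = labels.value_counts()
    usable = [s for s in subtypes if counts[s] >= min_group]
    skipped = set(subtypes) - set(usable)
    if skipped:
        warnings.warn(f"subtypes {sorted(skipped)} have < {min_group} subjects; skipped", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("fewer than 2 subtypes with enough subjects")

    sub = matrix.loc[labels.isin(usable)]
    contrasts = _pairwise_contrasts(sub, labels.loc[sub.index])
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        contrasts = {
            key: (eff, multipletests(p, method="fdr_bh")[1]) for key, (eff, p) in contrasts.items()
        }
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    proteins = matrix.columns
    result: dict[int, dict[str, list[str]]] = {}
    for s in usable:
        others = [t for t in usable if t != s]
        up = np.ones(len(proteins), dtype=bool)
        down = np.ones(len(proteins), dtype=bool)
        for t in others:
            eff, p = contrasts[(s, t)]
            up &= (eff > 0) & (p < alpha)
            down &= (eff < 0) & (p < alpha)
        result[int(s)] = {
            "increased": list(proteins[up]),
            "decreased": list(proteins[down]),
        }
    return result


def overlap_coefficient(set_a, set_b) -> float:
    """``|A ∩ B| / min(|A|, |B|)``; 1 whenever one set contains the other."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def celltype_specificity(
    row,
    detection_threshold: float = 0.2,
    dominance_threshold: float = 0.5,
) -> str:
    """Classify one reference row as a specific cell type, non-specific, or
    not detected.

    Rules, in order: every level below ``detection_threshold`` (raw scale)
    -> "not detected"; any cell type above ``dominance_threshold`` of the
    row total -> that cell type; otherwise "non-specific".
    """
    values = pd.Series(row, dtype=float)
    if (values < 0).any():
        raise ValueError("expression levels must be nonnegative")
    if (values < detection_threshold).all():
        return NOT_DETECTED
    shares = values / values.sum()
    if (shares > dominance_threshold).any():
        return str(shares.idxmax())
    return NON_SPECIFIC


def celltype_composition(
    proteins: list[str],
    reference: pd.DataFrame,
    detection_threshold: float = 0.2,
    dominance_threshold: float = 0.5,
) -> pd.Series:
    """Specificity-label counts over a protein set (missing proteins skipped)."""
    present = [p for p in proteins if p in reference.index]
    labels = [
        celltype_specificity(reference.loc[p], detection_threshold, dominance_threshold)
        for p in present
    ]
    return pd.Series(labels, index=present, name="celltype").value_counts()


def compare_characteristics(
    labels: pd.Series,
    covariates: pd.DataFrame,
    control_ids: list[str] | None = None,
    unstandardized: tuple[str, ...] = ("age",),
    chi2_correction: bool = False,
) -> dict[str, dict]:
    """Post-hoc subtype comparisons of subject characteristics.

    Continuous covariates are compared with a one-way linear model
    (overall F test, estimated marginal means per subtype, pairwise
    pooled-variance contrasts); discrete covariates with a chi-square test
    on the subtype x level contingency table.  Continuous covariates other
    than those named in ``unstandardized`` are first standardized to the
    control group when ``control_ids`` is given.  Constant covariates are
    skipped with a note.
    """
    covariates = covariates.loc[labels.index]
    report: dict[str, dict] = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.nunique(dropna=True) <= 1:
            report[name] = {"kind": "skipped", "reason": "constant covariate"}
            continue
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 5:
            values = col.astype(float)
            if control_ids is not None and name not in unstandardized:
                ctrl = values.loc[[s for s in control_ids if s in values.index]]
                if ctrl.std(ddof=1) > 0:
                    values = (values - ctrl.mean()) / ctrl.std(ddof=1)
            report[name] = _continuous_comparison(values, labels)
        else:
            table = pd.crosstab(labels, col)
            chi2, p, dof, _ = stats.chi2_contingency(table, correction=chi2_correction)
            report[name] = {
                "kind": "chi2",
                "statistic": float(chi2),
                "p": float(p),
                "dof": int(dof),
                "table": table,
            }
    return report


def _continuous_comparison(values: pd.Series, labels: pd.Series) -> dict:
    frame = pd.DataFrame({"value": values, "subtype": labels}).dropna()
    contrasts = _pairwise_contrasts(frame[["value"]], frame["subtype"])
    groups = [g["value"].to_numpy() for _, g in frame.groupby("subtype")]
    fstat, pval = stats.f_oneway(*groups)
    emmeans = frame.groupby("subtype")["value"].mean()
    pairs = {
        f"{s}-{t}": {"effect": float(eff[0]), "p": float(p[0])}
        for (s, t), (eff, p) in contrasts.items()
        if s < t
    }
    return {
        "kind": "glm",
        "statistic": float(fstat),
        "p": float(pval),
        "marginal_means": emmeans,
        "contrasts": pairs,
    }
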