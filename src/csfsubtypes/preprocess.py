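"""Harmonization of fragment- and platform-level measurements.

The harmonization chain mirrors the measurement structure of targeted CSF
proteomics: values are standardized to a control group, correlated MRM
fragments are rolled up into per-protein scores, proteins measured on more
than one platform are reconciled, incompletely observed proteins are
dropped, the matrix is restricted to a protein panel, and finally shifted
to be nonnegative for factorization.

Every function appends structured records to a provenance log (a list of
dicts, one JSON-serializable event each) so that each input fragment and
protein can be accounted for as retained, dropped, or excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Provenance = list[dict]


@dataclass(frozen=True)
class PreprocessConfig:
    correlation_threshold: float = 0.5
    anticorrelation_exclusion_threshold: float = -0.5
    panel: list[str] | None = None  # None = keep all
    nonneg_shift_mode: str = "global_min_shift"
    preferred_platform: str = "MRM"

    def validate(self) -> None:
        if not -1.0 <= self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must lie in [-1, 1]")
        if not -1.0 <= self.anticorrelation_exclusion_threshold <= 1.0:
            raise ValueError("anticorrelation_exclusion_threshold must lie in [-1, 1]")
        if self.nonneg_shift_mode not in ("global_min_shift", "per_protein_min_shift"):
            raise ValueError(f"unknown nonneg_shift_mode {self.nonneg_shift_mode!r}")


def control_reference(matrix: pd.DataFrame, control_ids: list[str]) -> pd.DataFrame:
    """Per-column mean and SD over the designated control subjects."""
    missing = [s for s in control_ids if s not in matrix.index]
    if missing:
        raise KeyError(f"control subjects absent from matrix: {missing[:5]}")
    ctrl = matrix.loc[control_ids]
    return pd.DataFrame({"mean": ctrl.mean(axis=0), "sd": ctrl.std(axis=0, ddof=1)})


def znormalize(
    matrix: pd.DataFrame,
    control_ref: pd.DataFrame,
    provenance: Provenance | None = None,
) -> pd.DataFrame:
    """Standardize each column to the control-group mean and SD.

    Columns whose control SD is zero (or not finite) cannot be standardized
    and are dropped with a warning.
    """
    missing = matrix.columns.difference(control_ref.index)
    if len(missing):
        raise KeyError(f"proteins missing from control reference: {list(missing[:5])}")
    ref = control_ref.loc[matrix.columns]
    bad = ~np.isfinite(ref["sd"]) | (ref["sd"] <= 0)
    if bad.any():
        dropped = list(ref.index[bad])
        warnings.warn(f"dropping {len(dropped)} column(s) with zero control SD", stacklevel=2)
        if provenance is not None:
            for col in dropped:
                provenance.append({"stage": "znormalize", "column": col, "action": "dropped_zero_sd"})
        matrix = matrix.drop(columns=dropped)
        ref = ref.loc[matrix.columns]
    return (matrix - ref["mean"]) / ref["sd"]


def _mean_pairwise_r(corr: pd.DataFrame) -> pd.Series:
    # constant vectors yield NaN correlations; count those as r = 0
    corr = corr.fillna(0.0)
    k = corr.shape[0]
    diag = pd.Series(np.diag(corr), index=corr.index)
    return (corr.sum(axis=1) - diag) / (k - 1)


def merge_fragments(
    fragments: pd.DataFrame,
    config: PreprocessConfig | None = None,
    provenance: Provenance | None = None,
) -> pd.DataFrame:
    """Roll standardized fragments up into per-protein scores.

    For each (protein, platform) group, fragments are retained greedily: the
    fragment with the lowest mean pairwise Pearson correlation to the others
    is removed until every retained fragment's mean pairwise r exceeds
    ``correlation_threshold`` (strictly; ties at the threshold are dropped).
    The protein score is the elementwise mean of the retained fragment
    z-scores.  Single-fragment proteins pass through unchanged.

    Parameters
    ----------
    fragments
        Long table with columns ``fragment_id, protein_id, platform,
        subject_id, value`` holding standardized values.

    Returns
    -------
    Long table with columns ``protein_id, platform, subject_id, value``.
    """
    config = config or PreprocessConfig()
    config.validate()
    required = {"fragment_id", "protein_id", "platform", "subject_id", "value"}
    if not required.issubset(fragments.columns):
        raise ValueError(f"fragment table must have columns {sorted(required)}")
    if fragments.duplicated(["fragment_id", "subject_id"]).any():
        raise ValueError("(fragment, subject) pairs must be unique")

    out_frames = []
    for (protein, platform), group in fragments.groupby(["protein_id", "platform"], sort=True):
        wide = group.pivot(index="subject_id", columns="fragment_id", values="value")
        retained = list(wide.columns)
        dropped: list[str] = []
        while len(retained) > 1:
            mean_r = _mean_pairwise_r(wide[retained].corr())
            if (mean_r > config.correlation_threshold).all():
                break
            worst = mean_r.idxmin()
            retained.remove(worst)
            dropped.append(worst)
        if provenance is not None:
            provenance.append(
                {
                    "stage": "merge_fragments",
                    "protein": protein,
                    "platform": platform,
                    "retained": retained,
                    "dropped": dropped,
                }
            )
        if not retained:  # unreachable with greedy removal, kept as a guard
            logger.warning("protein %s (%s): no fragments retained; omitted", protein, platform)
            continue
        score = wide[retained].mean(axis=1)
        out_frames.append(
            pd.DataFrame(
                {
                    "protein_id": protein,
                    "platform": platform,
                    "subject_id": score.index,
                    "value": score.to_numpy(),
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(columns=["protein_id", "platform", "subject_id", "value"])
    return pd.concat(out_frames, ignore_index=True)


def merge_platforms(
    scores: pd.DataFrame,
    config: PreprocessConfig | None = None,
    provenance: Provenance | None = None,
) -> pd.DataFrame:
    """Reconcile proteins measured on multiple platforms into one matrix.

    For a protein on two platforms with cross-platform Pearson ``r``:
    ``r > correlation_threshold`` averages the standardized vectors;
    ``r <= anticorrelation_exclusion_threshold`` excludes the protein
    entirely; anything in between keeps only the preferred (MRM) platform,
    or excludes the protein when no preferred-platform measurement exists.
    With more than two platforms the rule is applied to the mean pairwise r.

    Returns a subjects x proteins wide matrix.
    """
    config = config or PreprocessConfig()
    config.validate()
    columns = {}
    for protein, group in scores.groupby("protein_id", sort=True):
        wide = group.pivot(index="subject_id", columns="platform", values="value")
        platforms = list(wide.columns)
        if len(platforms) == 1:
            columns[protein] = wide.iloc[:, 0]
            continue
        r = float(_mean_pairwise_r(wide.corr()).mean())
        if r > config.correlation_threshold:
            columns[protein] = wide.mean(axis=1)
            action = "averaged"
        elif r <= config.anticorrelation_exclusion_threshold:
            action = "excluded_anticorrelated"
        elif config.preferred_platform in platforms:
            columns[protein] = wide[config.preferred_platform]
            action = f"kept_{config.preferred_platform}"
        else:
            action = "excluded_no_preferred_platform"
            logger.warning("protein %s: platforms uncorrelated and no %s measurement; excluded",
                           protein, config.preferred_platform)
        if provenance is not None:
            provenance.append(
                {
                    "stage": "merge_platforms",
                    "protein": protein,
                    "platforms": platforms,
                    "r": r,
                    "action": action,
                }
            )
    return pd.DataFrame(columns)


def filter_and_select(
    matrix: pd.DataFrame,
    config: PreprocessConfig | None = None,
    provenance: Provenance | None = None,
) -> pd.DataFrame:
    """Keep only fully observed proteins that are on the configured panel."""
    config = config or PreprocessConfig()
    config.validate()
    incomplete = matrix.columns[matrix.isna().any(axis=0)]
    kept = matrix.drop(columns=incomplete)
    off_panel: list[str] = []
    if config.panel is not None:
        panel = [p for p in config.panel if p in kept.columns]
        off_panel = [p for p in kept.columns if p not in set(config.panel)]
        kept = kept[panel]
    if provenance is not None:
        provenance.append(
            {
                "stage": "filter_and_select",
                "dropped_incomplete": list(incomplete),
                "dropped_off_panel": off_panel,
                "n_retained": kept.shape[1],
            }
        )
    if kept.shape[1] == 0:
        raise ValueError("no proteins survive completeness and panel filters")
    return kept


def nonneg_shift(
    matrix: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, float | pd.Series]:
    """Shift a standardized matrix to be nonnegative.

    ``global_min_shift`` subtracts the single global minimum from every
    entry (preserving all between-protein contrasts);
    ``per_protein_min_shift`` shifts each column by its own minimum.  The
    shift is returned so the transform can be inverted.
    """
    config = config or PreprocessConfig()
    config.validate()
    if config.nonneg_shift_mode == "global_min_shift":
        shift = float(min(matrix.min().min(), 0.0))
        return matrix - shift, shift
    shift = matrix.min(axis=0).clip(upper=0.0)
    return matrix - shift, shift


def harmonize(
    fragments: pd.DataFrame,
    control_ids: list[str],
    config: PreprocessConfig | None = None,
    provenance: Provenance | None = None,
) -> tuple[pd.DataFrame, float | pd.Series]:
    """Full chain: standardize fragments, roll up, reconcile platforms,
    filter, and shift nonnegative.  Returns (matrix, shift)."""
    config = config or PreprocessConfig()
    config.validate()
    wide = fragments.pivot(index="subject_id", columns="fragment_id", values="value")
    ref = control_reference(wide, control_ids)
    z = znormalize(wide, ref, provenance)
    z_long = (
        z.reset_index()
        .melt(id_vars="subject_id", var_name="fragment_id", value_name="value")
        .merge(
            fragments[["fragment_id", "protein_id", "platform"]].drop_duplicates(),
            on="fragment_id",
        )
    )
    scores = merge_fragments(z_long, config, provenance)
    merged = merge_platforms(scores, config, provenance)
    filtered = filter_and_select(merged, config, provenance)
    return nonneg_shift(filtered, config)
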