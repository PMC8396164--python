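"""Synthetic cohort generation.

Produces cohorts with the statistical structure the downstream analysis
assumes: ``k`` latent nonnegative subtype profiles mixed into protein
abundances with Gaussian noise, a designated control subsample providing
reference statistics, correlated fragment panels per protein with optional
cross-platform duplicates, a five-cell-type expression reference, and
per-subtype linear time trends in Aβ42 / p-tau / delayed-memory scores with
subject-level random intercepts.

Every generator is deterministic under a fixed seed; independent
sub-streams are spawned per component so that, e.g., the longitudinal table
does not change when the fragment panel configuration does.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKERS = ("abeta42", "ptau", "memory")

CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "microglia", "endothelial")

#: reference-level categories used by the cell-type generator and recovered
#: by :func:`csfsubtypes.profiles.celltype_specificity`
CATEGORY_DOMINANT = "dominant"
CATEGORY_UNDETECTED = "not detected"
CATEGORY_MIXED = "non-specific"


@dataclass(frozen=True)
class LongitudinalConfig:
    """Generating model for repeated biomarker measures.

    ``slopes`` maps each marker to a per-subtype tuple of yearly slopes
    (marker units per year).  Baseline means/SDs default to the cohort
    characteristics table (Aβ42 247.5 ± 29.2 pg/mL, p-tau 20.3 ± 9.4 pg/mL);
    the memory baseline is an arbitrary score scale.  Visit counts and
    follow-up spans default to 3.2 ± 1.2 visits over 3 ± 1.9 years.
    """

    slopes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "abeta42": (-4.4, -3.7, -5.6),
            "ptau": (2.6, 3.1, 1.29),
            "memory": (0.06, 0.15, 0.20),
        }
    )
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"abeta42": 247.5, "ptau": 20.3, "memory": 3.0}
    )
    baseline_sd: dict[str, float] = field(
        default_factory=lambda: {"abeta42": 29.2, "ptau": 9.4, "memory": 1.8}
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"abeta42": 10.0, "ptau": 3.0, "memory": 1.0}
    )
    intercept_sd: dict[str, float] = field(
        default_factory=lambda: {"abeta42": 25.0, "ptau": 8.0, "memory": 1.5}
    )
    visits_mean: float = 3.2
    visits_sd: float = 1.2
    span_mean: float = 3.0
    span_sd: float = 1.9
    min_visits: int = 2
    min_span: float = 0.3

    def validate(self, k_subtypes: int) -> None:
        if self.min_visits < 2:
            raise ValueError("at least 2 visits are required for slope identifiability")
        if self.min_span <= 0:
            raise ValueError("follow-up span must be positive")
        for marker, per_subtype in self.slopes.items():
            if len(per_subtype) < k_subtypes:
                raise ValueError(
                    f"marker {marker!r} needs a slope for each of {k_subtypes} subtypes"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the latent-subtype abundance generator.

    ``profile_effect`` is the mean abundance shift of a subtype's signature
    proteins in that subtype's subjects, expressed in units of the
    per-protein noise scale (the nominal control SD at ``noise_sd = 1``).
    ``mixing_concentration`` controls loading sharpness: loadings are drawn
    from a symmetric Dirichlet with parameter ``1 / mixing_concentration``,
    so large values approach hard one-subtype membership.
    """

    n_subjects: int = 120
    n_proteins: int = 200
    k_subtypes: int = 3
    mixing_concentration: float = 8.0
    profile_effect: float = 2.0
    noise_sd: float = 1.0
    frac_signature: float = 0.25
    n_fragments_per_protein: int = 3
    fragment_noise_sd: float = 0.5
    platform_duplicate_frac: float = 0.1
    control_frac: float = 0.2
    longitudinal: LongitudinalConfig = field(default_factory=LongitudinalConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_proteins", "k_subtypes", "n_fragments_per_protein"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        if self.k_subtypes > self.n_subjects:
            raise ValueError("k_subtypes cannot exceed n_subjects")
        for name in ("frac_signature", "platform_duplicate_frac", "control_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_signature * self.k_subtypes > 1.0 + 1e-12:
            raise ValueError("frac_signature * k_subtypes must not exceed 1")
        for name in ("mixing_concentration", "profile_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.fragment_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        self.longitudinal.validate(self.k_subtypes)


@dataclass
class SyntheticCohort:
    """Container for one generated cohort plus its ground truth."""

    protein_matrix: pd.DataFrame  # subjects x proteins, raw abundances
    control_ids: list[str]
    control_stats: pd.DataFrame  # protein -> mean, sd over control subsample
    fragment_table: pd.DataFrame  # fragment_id, protein_id, platform, subject_id, value
    celltype_reference: pd.DataFrame
    celltype_truth: pd.Series
    longitudinal_table: pd.DataFrame  # subject_id, subtype, time_years, marker, value
    true_labels: pd.Series  # subject -> subtype in 1..k
    loadings: pd.DataFrame  # subjects x k, rows sum to 1
    signature: dict[int, list[str]]
    protein_scale: pd.Series  # per-protein noise scale (nominal control SD)
    config: CohortConfig


def _draw_loadings(rng: np.random.Generator, n: int, k: int, concentration: float) -> np.ndarray:
    if math.isinf(concentration):
        out = np.zeros((n, k))
        out[np.arange(n), rng.integers(0, k, size=n)] = 1.0
        return out
    alpha = np.full(k, 1.0 / concentration)
    return rng.dirichlet(alpha, size=n)


def generate_celltype_reference(
    n_proteins: int,
    seed: int,
    *,
    protein_ids: list[str] | None = None,
    fraction_dominant: float = 0.5,
    fraction_undetected: float = 0.2,
    detection_threshold: float = 0.2,
    dominance_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build a per-protein expression reference across the 5 brain cell types.

    A ``fraction_dominant`` share of proteins is constructed with one cell
    type exceeding ``dominance_threshold`` of the row total, a
    ``fraction_undetected`` share with all values below
    ``detection_threshold``, and the remainder mixed (detected but with no
    dominant producer).  Returns the reference table and the ground-truth
    category per protein (the dominant rows carry their cell-type name).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if fraction_dominant + fraction_undetected > 1.0 + 1e-12:
        raise ValueError("category fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    n_dom = int(round(fraction_dominant * n_proteins))
    n_und = int(round(fraction_undetected * n_proteins))
    n_und = min(n_und, n_proteins - n_dom)
    categories = (
        [CATEGORY_DOMINANT] * n_dom
        + [CATEGORY_UNDETECTED] * n_und
        + [CATEGORY_MIXED] * (n_proteins - n_dom - n_und)
    )
    rng.shuffle(categories)

    rows = np.empty((n_proteins, len(CELL_TYPES)))
    truth = []
    for i, cat in enumerate(categories):
        if cat == CATEGORY_DOMINANT:
            ct = int(rng.integers(0, len(CELL_TYPES)))
            row = rng.uniform(0.0, 0.1, size=len(CELL_TYPES))
            row[ct] = rng.uniform(1.0, 3.0)
            truth.append(CELL_TYPES[ct])
        elif cat == CATEGORY_UNDETECTED:
            row = rng.uniform(0.0, detection_threshold * 0.95, size=len(CELL_TYPES))
            truth.append(CATEGORY_UNDETECTED)
        else:
            # two comparable producers; rejection-sample the rule directly
            while True:
                row = rng.uniform(0.05, 0.15, size=len(CELL_TYPES))
                leaders = rng.choice(len(CELL_TYPES), size=2, replace=False)
                row[leaders] = rng.uniform(0.8, 1.6, size=2)
                if row.max() >= detection_threshold and row.max() <= dominance_threshold * row.sum():
                    break
            truth.append(CATEGORY_MIXED)
        rows[i] = row
    table = pd.DataFrame(rows, index=protein_ids, columns=list(CELL_TYPES))
    table.index.name = "protein_id"
    return table, pd.Series(truth, index=protein_ids, name="category")


def generate_longitudinal_table(
    config: LongitudinalConfig,
    labels: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate repeated marker measures for labelled subjects.

    Each subject gets ``max(min_visits, round(N(visits_mean, visits_sd)))``
    visits, the first at time 0 and the rest uniform over a follow-up span
    drawn from ``N(span_mean, span_sd)`` (floored at ``min_span`` years).
    Values follow ``baseline + random intercept + slope * t + noise``.
    """
    records = []
    for subject, subtype in labels.items():
        n_visits = max(config.min_visits, int(round(rng.normal(config.visits_mean, config.visits_sd))))
        span = max(config.min_span, rng.normal(config.span_mean, config.span_sd))
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.0, span, size=n_visits - 1))])
        for marker in config.slopes:
            slope = config.slopes[marker][int(subtype) - 1]
            intercept = config.baseline_mean[marker] + rng.normal(0.0, config.baseline_sd[marker])
            intercept += rng.normal(0.0, config.intercept_sd[marker])
            noise = rng.normal(0.0, config.residual_sd[marker], size=n_visits)
            for t, e in zip(times, noise):
                records.append((subject, int(subtype), float(t), marker, intercept + slope * t + e))
    return pd.DataFrame(
        records, columns=["subject_id", "subtype", "time_years", "marker", "value"]
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    The abundance of protein *j* in subject *i* is

    ``b_j + s_j * (profile_effect * 1[label_i owns j] + noise_sd * eps)``

    with a positive log-normal baseline ``b_j`` and a per-protein scale
    ``s_j`` (the nominal control SD at unit noise).  Subject labels are the
    argmax of symmetric-Dirichlet loadings; a subtype's signature proteins
    are elevated in exactly its hard-labelled subjects so the configured
    effect size is exact by construction.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (s_load, s_abund, s_ctrl, s_frag, s_cell, s_long) = [
        np.random.default_rng(s) for s in root.spawn(6)
    ]

    n, p, k = config.n_subjects, config.n_proteins, config.k_subtypes
    subjects = [f"S{i:04d}" for i in range(n)]
    proteins = [f"P{j:04d}" for j in range(p)]

    loadings = _draw_loadings(s_load, n, k, config.mixing_concentration)
    labels = loadings.argmax(axis=1) + 1  # 1-based subtypes

    baseline = s_abund.lognormal(mean=3.0, sigma=0.25, size=p)
    scale = s_abund.uniform(0.5, 1.5, size=p)

    # disjoint signature blocks
    order = s_abund.permutation(p)
    n_sig = int(round(config.frac_signature * p))
    signature: dict[int, list[str]] = {}
    owner = np.zeros(p, dtype=int)  # 0 = unassigned
    for subtype in range(1, k + 1):
        block = order[(subtype - 1) * n_sig : subtype * n_sig]
        owner[block] = subtype
        signature[subtype] = [proteins[j] for j in sorted(block)]

    elevation = (labels[:, None] == owner[None, :]) & (owner[None, :] > 0)
    values = (
        baseline[None, :]
        + scale[None, :]
        * (config.profile_effect * elevation + config.noise_sd * s_abund.standard_normal((n, p)))
    )
    matrix = pd.DataFrame(values, index=subjects, columns=proteins)
    matrix.index.name = "subject_id"

    n_ctrl = max(2, int(round(config.control_frac * n)))
    control_ids = sorted(s_ctrl.choice(subjects, size=n_ctrl, replace=False))
    ctrl = matrix.loc[control_ids]
    control_stats = pd.DataFrame({"mean": ctrl.mean(axis=0), "sd": ctrl.std(axis=0, ddof=1)})
    control_stats.index.name = "protein_id"

    # fragment panel: every protein measured by MRM fragments; a fraction of
    # proteins additionally measured on the RBM platform
    frag_records = []
    f = config.n_fragments_per_protein
    for j, prot in enumerate(proteins):
        truth = matrix[prot].to_numpy()
        frag_noise = s_frag.standard_normal((f, n)) * scale[j] * config.fragment_noise_sd
        for a in range(f):
            frag_id = f"{prot}_frag{a}"
            for i, subj in enumerate(subjects):
                frag_records.append((frag_id, prot, "MRM", subj, truth[i] + frag_noise[a, i]))
    n_dup = int(round(config.platform_duplicate_frac * p))
    dup_idx = s_frag.choice(p, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    for j in dup_idx:
        prot = proteins[j]
        truth = matrix[prot].to_numpy()
        noise = s_frag.standard_normal(n) * scale[j] * config.fragment_noise_sd
        for i, subj in enumerate(subjects):
            frag_records.append((f"{prot}_rbm", prot, "RBM", subj, truth[i] + noise[i]))
    fragment_table = pd.DataFrame(
        frag_records, columns=["fragment_id", "protein_id", "platform", "subject_id", "value"]
    )

    celltype_reference, celltype_truth = generate_celltype_reference(
        p, int(s_cell.integers(0, 2**31 - 1)), protein_ids=proteins
    )

    true_labels = pd.Series(labels, index=subjects, name="subtype")
    longitudinal_table = generate_longitudinal_table(config.longitudinal, true_labels, s_long)

    return SyntheticCohort(
        protein_matrix=matrix,
        control_ids=control_ids,
        control_stats=control_stats,
        fragment_table=fragment_table,
        celltype_reference=celltype_reference,
        celltype_truth=celltype_truth,
        longitudinal_table=longitudinal_table,
        true_labels=true_labels,
        loadings=pd.DataFrame(
            loadings, index=subjects, columns=[f"subtype{s}" for s in range(1, k + 1)]
        ),
        signature=signature,
        protein_scale=pd.Series(scale, index=proteins, name="scale"),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write all cohort tables as TSV plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.protein_matrix.to_csv(outdir / "protein_matrix.tsv", sep="\t")
    cohort.control_stats.to_csv(outdir / "control_stats.tsv", sep="\t")
    cohort.fragment_table.to_csv(outdir / "fragment_table.tsv", sep="\t", index=False)
    cohort.celltype_reference.to_csv(outdir / "celltype_reference.tsv", sep="\t")
    cohort.longitudinal_table.to_csv(outdir / "longitudinal_table.tsv", sep="\t", index=False)
    (outdir / "controls.txt").write_text("\n".join(cohort.control_ids) + "\n")
    sidecar = {
        "true_labels": cohort.true_labels.to_dict(),
        "signature": cohort.signature,
        "celltype_truth": cohort.celltype_truth.to_dict(),
        "config": _config_to_dict(cohort.config),
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))


def _config_to_dict(config: CohortConfig) -> dict:
    out = dataclasses.asdict(config)
    out["longitudinal"] = {
        key: (dict(val) if isinstance(val, dict) else val)
        for key, val in dataclasses.asdict(config.longitudinal).items()
    }
    return out
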