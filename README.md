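# csfsubtypes

Subtype discovery for CSF proteomic cohorts: multi-platform harmonization,
nonsmooth non-negative matrix factorization (nsNMF) with consensus
clustering and stability-based rank selection, subtype characterization
(specific protein sets, overlap coefficients, cell-type specificity), and
longitudinal biomarker slope estimation — all driven by a synthetic-cohort
generator so the full pipeline is testable without access to subject-level
data.

## What's inside

| Module | Purpose |
| --- | --- |
| `csfsubtypes.synthetic` | Synthetic cohorts: latent-subtype abundance matrices, control reference statistics, correlated MRM fragment panels with cross-platform duplicates, a 5-cell-type expression reference, and per-subtype longitudinal trends with subject-level random intercepts. |
| `csfsubtypes.preprocess` | Control-group z-normalization, fragment roll-up (mean pairwise r > 0.5 retention), cross-platform reconciliation (average / keep-MRM / exclude on anticorrelation), 100 %-completeness and panel filters, nonnegative shift. |
| `csfsubtypes.nsnmf` | nsNMF (`V ≈ W S H`, `S = (1−θ)I + (θ/k)J`) with monotone multiplicative updates, 50-restart consensus matrices, cophenetic coefficient, silhouette width, rank selection (cophenetic plateau + 2-fold fit gain over permuted data + silhouette ≥ 0.5), and NNLS-based subject prediction. |
| `csfsubtypes.profiles` | Loading-outlier detection (robust z on max loading), protein labelling by subtype mean, conjunction screens for subtype-specific proteins, overlap coefficient, cell-type specificity rules, post-hoc GLM / χ² comparisons. |
| `csfsubtypes.longitudinal` | Per-subtype per-year biomarker slopes via random-intercept mixed models (clustered-OLS fallback), subtype × time interaction tests, baseline comparisons. |
| `csfsubtypes.pipeline` / `csfsubtypes.cli` | YAML-configured end-to-end orchestration with seeded reproducibility, stage markers with `--resume`, JSON + Markdown run reports. |

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (consensus
stability endpoints, rank/label recovery, slope parameter recovery,
brute-force oracles); the remaining files are per-module unit and property
tests.

## CLI

```bash
# generate a synthetic cohort
csfsubtypes simulate --out cohort/ --seed 1

# harmonize fragments into a nonnegative protein matrix
csfsubtypes preprocess --fragments cohort/fragment_table.tsv \
    --controls cohort/controls.txt --out matrix.tsv

# rank selection + consensus clustering
csfsubtypes cluster --matrix matrix.tsv --ranks 2:5 --runs 50 --seed 1 --out model/

# subtype-specific proteins and cell-type composition
csfsubtypes characterize --matrix matrix.tsv --labels model/labels.tsv \
    --celltypes cohort/celltype_reference.tsv --out report/

# longitudinal slopes under the estimated labels
csfsubtypes longitudinal --table cohort/longitudinal_table.tsv \
    --labels model/labels.tsv --out slopes/

# or the whole chain from one YAML config
csfsubtypes run --config config.yaml --out run/ --seed 1
csfsubtypes run --config config.yaml --out run/ --seed 1 --resume
```

A config file may override any nested option and unknown keys are rejected
up front, e.g.:

```yaml
seed: 1
cohort:
  n_subjects: 120
  k_subtypes: 3
  profile_effect: 2.0
nsnmf:
  theta: 0.5
  n_runs: 50
```

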