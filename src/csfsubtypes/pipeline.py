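"""End-to-end pipeline orchestration.

``run_pipeline`` drives the full chain — simulate (or load) -> preprocess
-> rank selection -> consensus clustering -> loading-outlier recheck ->
subtype characterization -> longitudinal slopes — from a single validated
config with one global seed.  Per-stage child seeds are spawned from the
global seed with ``numpy.random.SeedSequence(seed).spawn`` in a fixed
documented order (simulate, clustering), so stages are independently
reproducible.  Each stage persists its outputs together with a marker file
holding the config hash; ``resume=True`` skips stages whose marker matches
the current config bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import longitudinal as longi
from . import nsnmf, preprocess, profiles
from . import synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "rank_selection", "cluster", "characterize", "longitudinal")


@dataclass(frozen=True)
class CharacterizationConfig:
    alpha: float = 0.05
    correction: str | None = None
    outlier_threshold: float = 3.5
    detection_threshold: float = 0.2
    dominance_threshold: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    nsnmf: nsnmf.NsnmfConfig = field(default_factory=nsnmf.NsnmfConfig)
    characterization: CharacterizationConfig = field(default_factory=CharacterizationConfig)
    markers: tuple[str, ...] = synthetic.MARKERS
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        self.preprocess.validate()
        self.nsnmf.validate()


def _from_dict(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        if isinstance(value, dict) and key in _NESTED:
            value = _from_dict(_NESTED[key], value)
        kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "cohort": synthetic.CohortConfig,
    "preprocess": preprocess.PreprocessConfig,
    "nsnmf": nsnmf.NsnmfConfig,
    "characterization": CharacterizationConfig,
    "longitudinal": synthetic.LongitudinalConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    config = _from_dict(PipelineConfig, data)
    config.validate()
    return config


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_model(model: nsnmf.FactorModel, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "W.tsv", model.W, delimiter="\t")
    np.savetxt(outdir / "H.tsv", model.H, delimiter="\t")
    np.savetxt(outdir / "S.tsv", model.S, delimiter="\t")
    meta = {
        "theta": model.theta,
        "rank": model.rank,
        "rss": model.rss,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "seed": model.seed,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(outdir: Path) -> nsnmf.FactorModel:
    meta = json.loads((outdir / "model.json").read_text())
    return nsnmf.FactorModel(
        W=np.atleast_2d(np.loadtxt(outdir / "W.tsv", delimiter="\t")),
        H=np.atleast_2d(np.loadtxt(outdir / "H.tsv", delimiter="\t")),
        S=np.atleast_2d(np.loadtxt(outdir / "S.tsv", delimiter="\t")),
        rss_trace=np.array([meta["rss"]]),
        **{k: meta[k] for k in ("theta", "rank", "rss", "n_iter", "converged", "seed")},
    )


class _StageRunner:
    """Runs stages in order, persisting outputs and honouring ``--resume``."""

    def __init__(self, outdir: Path, cfg_hash: str, resume: bool):
        self.outdir = outdir
        self.hash = cfg_hash
        self.resume = resume

    def marker(self, stage: str) -> Path:
        return self.outdir / f"{stage}.done.json"

    def is_done(self, stage: str) -> bool:
        path = self.marker(stage)
        if not (self.resume and path.exists()):
            return False
        return json.loads(path.read_text()).get("config_hash") == self.hash

    def mark(self, stage: str, **extra) -> None:
        payload = {"config_hash": self.hash, "stage": stage, **extra}
        self.marker(stage).write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, outdir: str | Path, resume: bool = False) -> dict:
    """Execute every stage and return the run report (also written to
    ``report.json`` / ``report.md``).  A stage failure raises with the
    stage name; outputs of completed stages remain on disk."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    runner = _StageRunner(outdir, chash, resume)
    seeds = np.random.SeedSequence(config.seed).spawn(2)  # simulate, clustering
    report: dict = {"config_hash": chash, "seed": config.seed}

    try:
        cohort = _stage_simulate(config, outdir, runner, seeds[0])
        matrix = _stage_preprocess(config, cohort, outdir, runner)
        report["n_subjects"], report["n_proteins"] = matrix.shape

        cluster_seed = int(seeds[1].generate_state(1)[0])
        selection = _stage_rank_selection(config, matrix, outdir, runner, cluster_seed)
        report["rank_selection"] = {
            str(k): {
                "cophenetic": selection.summaries[k].cophenetic,
                "silhouette": selection.summaries[k].silhouette,
                "criteria": selection.criteria[k],
            }
            for k in selection.summaries
        }
        if selection.selected is None:
            report["selected_rank"] = None
            report["status"] = "no rank satisfied the selection criteria"
            _write_report(report, outdir)
            return report
        rank = selection.selected
        report["selected_rank"] = rank

        assignment, summary = _stage_cluster(config, matrix, rank, outdir, runner, cluster_seed)
        report["cophenetic"] = summary.cophenetic
        report["silhouette"] = summary.silhouette
        report["outliers_excluded"] = assignment.outliers
        report["subtype_counts"] = {
            str(s): int((assignment.labels == s).sum()) for s in sorted(assignment.labels.unique())
        }

        characterization = _stage_characterize(config, matrix, assignment, cohort, outdir, runner)
        report["characterization"] = characterization

        report["longitudinal"] = _stage_longitudinal(config, cohort, assignment, outdir, runner)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    _write_report(report, outdir)
    return report


def _stage_simulate(config, outdir, runner, seed_seq) -> synthetic.SyntheticCohort:
    stage_dir = outdir / "cohort"
    cohort_config = replace(config.cohort, seed=int(seed_seq.generate_state(1)[0]))
    cohort = synthetic.generate_cohort(cohort_config)
    if not runner.is_done("simulate"):
        synthetic.write_cohort(cohort, stage_dir)
        runner.mark("simulate", seed=cohort_config.seed)
    return cohort


def _stage_preprocess(config, cohort, outdir, runner) -> pd.DataFrame:
    path = outdir / "matrix.tsv"
    if runner.is_done("preprocess") and path.exists():
        return pd.read_csv(path, sep="\t", index_col=0)
    provenance: preprocess.Provenance = []
    matrix, shift = preprocess.harmonize(
        cohort.fragment_table, cohort.control_ids, config.preprocess, provenance
    )
    matrix.to_csv(path, sep="\t")
    with open(outdir / "provenance.jsonl", "w") as fh:
        for event in provenance:
            fh.write(json.dumps(event) + "\n")
    runner.mark("preprocess", shift=shift if np.isscalar(shift) else "per_protein")
    return matrix


def _stage_rank_selection(config, matrix, outdir, runner, seed) -> nsnmf.RankSelection:
    nconfig = replace(config.nsnmf, seed=seed)
    selection = nsnmf.select_rank(matrix.T, nconfig)
    payload = {
        "selected": selection.selected,
        "criteria": {str(k): v for k, v in selection.criteria.items()},
        "real_rss": {str(k): v for k, v in selection.real_rss.items()},
        "perm_rss": {str(k): v for k, v in selection.perm_rss.items()},
        "cophenetic": {str(k): s.cophenetic for k, s in selection.summaries.items()},
        "silhouette": {str(k): s.silhouette for k, s in selection.summaries.items()},
    }
    (outdir / "rank_selection.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    runner.mark("rank_selection")
    return selection


def _cluster_once(matrix, rank, nconfig):
    summary = nsnmf.run_consensus(matrix.T, rank, nconfig)
    labels, loadings = nsnmf.predict_subtypes(summary.best_model)
    labels = pd.Series(labels, index=matrix.index, name="subtype")
    loadings = pd.DataFrame(
        loadings.T, index=matrix.index, columns=[f"subtype{s}" for s in range(1, rank + 1)]
    )
    return summary, labels, loadings


def _stage_cluster(config, matrix, rank, outdir, runner, seed):
    nconfig = replace(config.nsnmf, seed=seed)
    summary, labels, loadings = _cluster_once(matrix, rank, nconfig)
    raw_loadings = pd.DataFrame(
        summary.best_model.H.T, index=matrix.index,
        columns=[f"subtype{s}" for s in range(1, rank + 1)],
    )
    outliers = profiles.detect_loading_outliers(
        raw_loadings, config.characterization.outlier_threshold
    )
    if outliers:
        logger.info("re-clustering without %d loading outlier(s)", len(outliers))
        kept = matrix.drop(index=outliers)
        summary, labels, loadings = _cluster_once(kept, rank, nconfig)
    assignment = profiles.SubtypeAssignment(labels=labels, loadings=loadings, outliers=outliers)
    model_dir = outdir / "model"
    save_model(summary.best_model, model_dir)
    labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t")
    loadings.to_csv(outdir / "loadings.tsv", sep="\t")
    np.savetxt(outdir / "consensus.tsv", summary.consensus, delimiter="\t")
    runner.mark("cluster", cophenetic=summary.cophenetic, silhouette=summary.silhouette)
    return assignment, summary


def _stage_characterize(config, matrix, assignment, cohort, outdir, runner) -> dict:
    cc = config.characterization
    kept = matrix.loc[assignment.labels.index]
    protein_labels = profiles.label_proteins(kept, assignment.labels)
    specific = profiles.subtype_specific_proteins(
        kept, assignment.labels, alpha=cc.alpha, correction=cc.correction
    )
    out: dict = {"specific_protein_counts": {}, "celltype_composition": {}, "overlap": {}}
    for subtype, sets in specific.items():
        out["specific_protein_counts"][str(subtype)] = {
            d: len(ps) for d, ps in sets.items()
        }
        comp = profiles.celltype_composition(
            sets["increased"], cohort.celltype_reference,
            cc.detection_threshold, cc.dominance_threshold,
        )
        out["celltype_composition"][str(subtype)] = {str(k): int(v) for k, v in comp.items()}
    # overlap of each subtype's specific-increased set with the generating
    # signature sets (stands in for external reference difference profiles)
    for subtype, sets in specific.items():
        if not sets["increased"]:
            continue
        for true_subtype, sig in cohort.signature.items():
            out["overlap"][f"{subtype}_vs_signature{true_subtype}"] = profiles.overlap_coefficient(
                sets["increased"], sig
            )
    pd.DataFrame(
        {"protein_id": protein_labels.index, "subtype": protein_labels.to_numpy()}
    ).to_csv(outdir / "protein_labels.tsv", sep="\t", index=False)
    (outdir / "characterization.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    runner.mark("characterize")
    return out


def _stage_longitudinal(config, cohort, assignment, outdir, runner) -> dict:
    table = cohort.longitudinal_table.copy()
    # analyse under the *estimated* subtype labels
    table = table[table["subject_id"].isin(assignment.labels.index)]
    table["subtype"] = assignment.labels.loc[table["subject_id"]].to_numpy()
    out: dict = {"slopes": [], "interaction": {}, "baseline": {}}
    for marker in config.markers:
        for est in longi.fit_all_slopes(table, [marker]):
            out["slopes"].append(dataclasses.asdict(est))
        try:
            comp = longi.compare_slopes(table, marker)
            out["interaction"][marker] = {
                "p": comp["p_interaction"], "method": comp["method"],
            }
        except ValueError as exc:
            out["interaction"][marker] = {"error": str(exc)}
        base = longi.baseline_comparison(table, marker)
        out["baseline"][marker] = {"p": base["p"]}
    pd.DataFrame(out["slopes"]).to_csv(outdir / "slopes.tsv", sep="\t", index=False)
    runner.mark("longitudinal")
    return out


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    lines = ["# Subtype discovery run report", ""]
    lines.append(f"- config hash: `{report['config_hash']}`  |  seed: {report['seed']}")
    if report.get("selected_rank") is None:
        lines.append(f"- **{report.get('status', 'selection failed')}**")
    else:
        lines.append(f"- selected rank: **{report['selected_rank']}**")
        lines.append(f"- cophenetic: {report['cophenetic']:.3f}; silhouette: {report['silhouette']:.3f}")
        counts = ", ".join(f"subtype {k}: {v}" for k, v in sorted(report["subtype_counts"].items()))
        lines.append(f"- subjects per subtype: {counts}")
        if report.get("outliers_excluded"):
            lines.append(f"- loading outliers excluded: {len(report['outliers_excluded'])}")
        lines.append("")
        lines.append("## Longitudinal slopes")
        for est in report.get("longitudinal", {}).get("slopes", []):
            lines.append(
                f"- {est['marker']} subtype {est['subtype']}: "
                f"β = {est['beta']:.2f} ± {est['se']:.2f} per year "
                f"(p = {est['p']:.3g}, {est['direction']})"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
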