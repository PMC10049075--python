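"""End-to-end orchestration: simulate/ingest -> filter -> normalize ->
merge -> classify / embed / screen -> report.

Each stage writes plain JSON/TSV artifacts into the run directory and the
manifest records their SHA-256 digests, the configuration hash and the
master seed, so a re-run with the same configuration reproduces identical
digests for every deterministic stage.

Positive and negative ion modes are processed as parallel, independent
analyses (a metabolite may ionise in only one polarity); the report joins
them side by side.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import loocv_classify, repeated_subsample_cv
from .diff_abundance import diff_abundance_screen, pvalue_histogram_diagnostic
from .dimred import add_group_ellipses, pca_embedding, plsda_embedding
from .feature_io import (
    ConfigurationError,
    FeatureTable,
    PipelineConfig,
    SampleMetadata,
    StandardSet,
    read_feature_table,
    read_standards,
    write_feature_table,
    write_sample_metadata,
    write_standards,
)
from .normalization import compute_metrics, fit_standard_pcs, normalize_pc_regression
from .qc_filter import filter_with_report, log_transform, merge_batches, z_transform
from .synthetic_data import SimulationConfig, simulate_cohort

TASKS = ("um-vs-control", "subclass", "driver", "bap1-vs-eif1ax", "metastasis")


@dataclass
class RunManifest:
    """Lineage record of one pipeline run."""

    config_hash: str
    master_seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    timestamp: float = 0.0

    def add_stage(self, name: str, outputs: list[Path], info: dict | None = None) -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": [
                    {"path": p.name, "sha256": _sha256(p)} for p in outputs
                ],
                "info": info or {},
            }
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def without_timestamp(self) -> dict:
        d = self.to_dict()
        d.pop("timestamp", None)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def task_labels(
    meta: SampleMetadata, task: str, sample_ids: list[str]
) -> tuple[list[str], np.ndarray, str | None]:
    """Samples, labels and positive class for one classification task."""
    df = meta.frame
    study = [s for s in sample_ids if df.loc[s, "role"] == "study"]
    if task == "um-vs-control":
        ids = study
        labels = df.loc[ids, "group"].to_numpy()
        pos = "UM"
    elif task == "subclass":
        ids = study
        labels = df.loc[ids, "subclass"].to_numpy()
        pos = None
    elif task == "driver":
        ids = [s for s in study if df.loc[s, "primary_driver"] in ("GNAQ", "GNA11")]
        labels = df.loc[ids, "primary_driver"].to_numpy()
        pos = "GNA11"
    elif task == "bap1-vs-eif1ax":
        ids = [s for s in study if df.loc[s, "subclass"] in ("BAP1", "EIF1AX")]
        labels = df.loc[ids, "subclass"].to_numpy()
        pos = "BAP1"
    elif task == "metastasis":
        ids = [
            s
            for s in study
            if df.loc[s, "group"] == "UM" and df.loc[s, "metastasis"] in ("yes", "no")
        ]
        labels = df.loc[ids, "metastasis"].to_numpy()
        pos = "yes"
    else:
        raise ConfigurationError(f"unknown task {task!r}; choose from {TASKS}")
    if len(set(labels.tolist())) < 2:
        raise ConfigurationError(f"task {task!r} has fewer than 2 classes here")
    return ids, labels, pos


def prepare_mode(
    table: FeatureTable,
    meta: SampleMetadata,
    standards: StandardSet,
    cfg: PipelineConfig,
) -> dict:
    """Filter, normalize per batch, merge and z-transform one mode's table.

    Returns the intermediate products and normalization diagnostics
    (before/after) in a dict keyed by stage name.
    """
    standards.check_in_table(table)
    batches = meta.column("batch", table.sample_ids)
    per_batch_norm: list[FeatureTable] = []
    per_batch_raw: list[FeatureTable] = []
    reports = {}
    for batch in ("discovery", "replication"):
        ids = [s for s, b in zip(table.sample_ids, batches) if b == batch]
        if not ids:
            continue
        sub = log_transform(table.select_samples(ids))
        filtered, report = filter_with_report(
            sub, cfg.pooled_percentile, cfg.min_samples_above, standards
        )
        model = fit_standard_pcs(filtered, standards)
        normalized, model = normalize_pc_regression(
            filtered, model, cfg.nonzero_frac, cfg.z_outlier
        )
        per_batch_raw.append(filtered)
        per_batch_norm.append(normalized)
        reports[batch] = {
            "filter": dataclasses.asdict(report),
            "n_normalized": len(model.coefficients),
            "pc_explained_variance": model.explained_variance.tolist(),
        }
    if len(per_batch_norm) == 2:
        merged_norm = merge_batches(per_batch_norm[0], per_batch_norm[1])
        merged_raw = merge_batches(per_batch_raw[0], per_batch_raw[1])
    else:
        merged_norm = per_batch_norm[0]
        merged_raw = per_batch_raw[0]
    metrics_before = compute_metrics(merged_raw, meta, seed=cfg.master_seed)
    metrics_after = compute_metrics(merged_norm, meta, seed=cfg.master_seed)
    return {
        "filtered": merged_raw,
        "normalized": merged_norm,
        "z": z_transform(merged_norm),
        "reports": reports,
        "metrics_before": metrics_before.to_dict(),
        "metrics_after": metrics_after.to_dict(),
    }


def run_pipeline(
    out_dir: str | Path,
    pipe_cfg: PipelineConfig,
    sim_cfg: SimulationConfig | None = None,
    inputs: dict | None = None,
    tasks: tuple[str, ...] = ("um-vs-control",),
    repeats: bool = False,
    embed: bool = True,
    diffabund: bool = True,
) -> RunManifest:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Either ``sim_cfg`` (simulate a cohort) or ``inputs`` (a dict with
    ``positive``, ``negative``, ``metadata``, ``standards`` file paths)
    must be given. Inputs are validated before any computation starts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (sim_cfg is None) == (inputs is None):
        raise ConfigurationError("give exactly one of sim_cfg or inputs")
    if inputs is not None:
        for key in ("positive", "negative", "metadata", "standards"):
            if key not in inputs:
                raise ConfigurationError(f"inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigurationError(f"input file not found: {inputs[key]}")

    cfg_payload = {
        "pipeline": pipe_cfg.to_dict(),
        "simulation": dataclasses.asdict(sim_cfg) if sim_cfg else None,
        "inputs": {k: str(v) for k, v in inputs.items()} if inputs else None,
        "tasks": list(tasks),
    }
    config_hash = hashlib.sha256(
        json.dumps(cfg_payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        master_seed=pipe_cfg.master_seed,
        version=__version__,
        timestamp=time.time(),
    )
    _dump_json(cfg_payload, out / "config.json")
    manifest.add_stage("config", [out / "config.json"])

    # -- ingest / simulate ----------------------------------------------
    if sim_cfg is not None:
        pos, neg, meta, standards = simulate_cohort(sim_cfg)
        paths = {
            "positive": out / "features_positive.tsv",
            "negative": out / "features_negative.tsv",
            "metadata": out / "metadata.tsv",
            "standards": out / "standards.json",
        }
        write_feature_table(pos, meta, paths["positive"])
        write_feature_table(neg, meta, paths["negative"])
        write_sample_metadata(meta, paths["metadata"])
        write_standards(standards, paths["standards"])
        manifest.add_stage("simulate", list(paths.values()))
    else:
        pos, meta = read_feature_table(inputs["positive"], inputs["metadata"])
        neg, _ = read_feature_table(inputs["negative"], inputs["metadata"])
        standards = read_standards(inputs["standards"])

    results_for_report: dict = {"modes": {}}
    for mode, table in (("positive", pos), ("negative", neg)):
        prep = prepare_mode(table, meta, standards, pipe_cfg)
        ztab = prep["z"]
        norm_path = out / f"normalized_{mode}.tsv"
        write_feature_table(
            prep["normalized"], meta.subset(prep["normalized"].sample_ids), norm_path
        )
        qc_path = _dump_json(
            {
                "filter_reports": prep["reports"],
                "metrics_before": prep["metrics_before"],
                "metrics_after": prep["metrics_after"],
            },
            out / f"normalization_{mode}.json",
        )
        manifest.add_stage(f"normalize:{mode}", [norm_path, qc_path])
        mode_summary = {
            "normalization": {
                "before": prep["metrics_before"],
                "after": prep["metrics_after"],
            },
            "tasks": {},
        }

        for task in tasks:
            ids, labels, positive = task_labels(meta, task, ztab.sample_ids)
            X = ztab.select_samples(ids).abundances.T
            result = loocv_classify(
                X, labels, pipe_cfg, sample_ids=ids, positive_class=positive
            )
            res_path = _dump_json(result.to_dict(), out / f"cv_{task}_{mode}.json")
            stage_outputs = [res_path]
            task_summary = {
                "accuracy": result.accuracy,
                "per_class": result.per_class,
                "auc_mean": result.auc_mean,
                "auc_sd": result.auc_sd,
            }
            if result.roc is not None:
                roc_path = out / f"roc_{task}_{mode}.tsv"
                pd.DataFrame(result.roc, columns=["fpr", "tpr"]).to_csv(
                    roc_path, sep="\t", index=False, float_format="%.12g"
                )
                stage_outputs.append(roc_path)
            if repeats:
                summary = repeated_subsample_cv(
                    X, labels, pipe_cfg, sample_ids=ids, positive_class=positive
                )
                rep_payload = {
                    "auc_range": summary.auc_range,
                    "f1_ranges": summary.f1_ranges,
                    "per_repeat": [
                        {
                            "accuracy": r.accuracy,
                            "auc_mean": r.auc_mean,
                            "per_class": r.per_class,
                        }
                        for r in summary.per_repeat
                    ],
                }
                rep_path = _dump_json(rep_payload, out / f"repeats_{task}_{mode}.json")
                stage_outputs.append(rep_path)
                task_summary["repeats"] = rep_payload
            manifest.add_stage(f"classify:{task}:{mode}", stage_outputs)
            mode_summary["tasks"][task] = task_summary

        if embed:
            emb_outputs = []
            study = [s for s in ztab.sample_ids if meta.frame.loc[s, "role"] == "study"]
            zsub = ztab.select_samples(study)
            glabels = meta.column("subclass", study)
            for method, fn in (("pca", pca_embedding), ("plsda", None)):
                if method == "pca":
                    emb = pca_embedding(zsub, k=2)
                else:
                    emb = plsda_embedding(zsub, glabels, k=2)
                emb = add_group_ellipses(emb, glabels)
                coord_path = out / f"embedding_{method}_{mode}.tsv"
                pd.DataFrame(
                    emb.coordinates,
                    index=pd.Index(emb.sample_ids, name="sample_id"),
                    columns=[f"dim{k+1}" for k in range(emb.coordinates.shape[1])],
                ).to_csv(coord_path, sep="\t", float_format="%.12g")
                ell_path = _dump_json(
                    {
                        g: {
                            "center": e.center.tolist(),
                            "covariance": e.covariance.tolist(),
                            "radii": e.radii.tolist(),
                            "level": e.confidence_level,
                        }
                        for g, e in (emb.group_ellipses or {}).items()
                    },
                    out / f"ellipses_{method}_{mode}.json",
                )
                emb_outputs += [coord_path, ell_path]
            manifest.add_stage(f"embed:{mode}", emb_outputs)

        if diffabund:
            screen = diff_abundance_screen(ztab, meta, alpha=pipe_cfg.fdr_alpha)
            da_path = out / f"diffabund_{mode}.tsv"
            screen.frame.to_csv(da_path, sep="\t", float_format="%.12g")
            counts, stat, p_unif = pvalue_histogram_diagnostic(
                screen.frame["p_t"].to_numpy()
            )
            diag_path = _dump_json(
                {
                    "histogram": counts.tolist(),
                    "uniformity_stat": stat,
                    "uniformity_p": p_unif,
                    "n_joint_significant": int(screen.frame["joint_flag"].sum()),
                },
                out / f"pvalue_diagnostic_{mode}.json",
            )
            manifest.add_stage(f"diffabund:{mode}", [da_path, diag_path])
            mode_summary["diffabund"] = {
                "n_joint_significant": int(screen.frame["joint_flag"].sum()),
                "uniformity_p": p_unif,
            }

        results_for_report["modes"][mode] = mode_summary

    _dump_json(results_for_report, out / "summary.json")
    manifest.add_stage("summary", [out / "summary.json"])
    _dump_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def render_report(out_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run."""
    out = Path(out_dir)
    summary_path = out / "summary.json"
    manifest_path = out / "manifest.json"
    if not summary_path.exists() or not manifest_path.exists():
        missing = [p.name for p in (summary_path, manifest_path) if not p.exists()]
        return "# Incomplete run\n\nMissing artifacts: " + ", ".join(missing) + "\n"
    summary = json.loads(summary_path.read_text())
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# Analysis report",
        "",
        f"- master seed: {manifest['master_seed']}",
        f"- config hash: {manifest['config_hash'][:16]}…",
        f"- package version: {manifest['version']}",
        "",
    ]
    for mode, ms in summary["modes"].items():
        lines.append(f"## {mode.capitalize()} ion mode")
        lines.append("")
        norm = ms.get("normalization", {})
        for when in ("before", "after"):
            m = norm.get(when, {})
            lines.append(
                f"- normalization metrics ({when}): "
                + ", ".join(
                    f"{k}={_fmt(v)}" for k, v in m.items()
                )
            )
        lines.append("")
        for task, ts in ms.get("tasks", {}).items():
            lines.append(f"### Task: {task}")
            lines.append("")
            lines.append("| class | precision | recall | F1 | support |")
            lines.append("|---|---|---|---|---|")
            for c, pc in ts["per_class"].items():
                lines.append(
                    f"| {c} | {pc['precision']:.3f} | {pc['recall']:.3f} "
                    f"| {pc['f1']:.3f} | {pc['support']} |"
                )
            lines.append("")
            lines.append(f"- accuracy: {ts['accuracy']:.3f}")
            if ts.get("auc_mean") is not None:
                lines.append(
                    f"- bootstrap AUC: {ts['auc_mean']:.3f} ± {ts['auc_sd']:.3f}"
                )
            if "repeats" in ts:
                rng = ts["repeats"].get("auc_range")
                if rng:
                    lines.append(
                        f"- ten-repeat AUC range: {rng[0]:.3f} – {rng[1]:.3f}"
                    )
                lines.append("")
                lines.append("| repeat | accuracy | AUC |")
                lines.append("|---|---|---|")
                for k, r in enumerate(ts["repeats"]["per_repeat"]):
                    auc = r["auc_mean"]
                    lines.append(
                        f"| {k+1} | {r['accuracy']:.3f} | "
                        + (f"{auc:.3f}" if auc is not None else "–")
                        + " |"
                    )
            lines.append("")
        if "diffabund" in ms:
            da = ms["diffabund"]
            lines.append(
                f"- jointly significant features (t-test and LTD correlation, "
                f"FDR-adjusted): {da['n_joint_significant']}"
            )
            lines.append(
                f"- p-value right-tail uniformity p: {da['uniformity_p']:.3f}"
            )
            lines.append("")
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if v is None:
        return "absent"
    if isinstance(v, float):
        return f"{v:.3f}"
    return str(v)
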