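"""End-to-end pipeline: simulate -> preprocess -> deconvolve -> train ->
evaluate, driven by a single validated JSON config, with a run manifest
recording every artifact, seed and checksum so reruns can be audited.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .deconv import comparison_report, compare_groups, deconvolve
from .nn.model import ModelConfig
from .signalprep import build_feature_table, fit_pca, project, standardize
from .synthcohort import (
    CHANNELS,
    CohortSpec,
    read_cohort,
    write_cohort,
    generate_cohort,
    VOC_RETENTION_SPAN,
)
from .traineval import (
    SplitSpec,
    TrainConfig,
    cross_validate,
    evaluate_predictions,
    train,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_data_dir"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cohort: CohortSpec = CohortSpec(n_asthmatic=20, n_control=25, age_group="adult")
    plateau_fraction: float = Field(default=0.5, gt=0, lt=1)
    variance_target: float = Field(default=0.95, gt=0, le=1)
    n_deconv_components: int = Field(default=3, ge=1)
    model: ModelConfig = ModelConfig()
    training: TrainConfig = TrainConfig()
    split: SplitSpec = SplitSpec()
    cv_folds: int = Field(default=5, ge=2)
    out_dir: str = "breathdx_run"
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_mean_voc(records) -> dict[str, tuple[int, np.ndarray]]:
    by_subject: dict[str, list] = {}
    labels: dict[str, int] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec.channels["voc_total"])
        labels[rec.subject_id] = rec.label
    return {
        sid: (labels[sid], np.mean(np.vstack(traces), axis=0))
        for sid, traces in by_subject.items()
    }


def deconvolve_cohort(records, n_components: int = 3, seed: int = 0):
    """Average the triplicate voc_total traces per subject, deconvolve each,
    and compare the asthmatic and control groups."""
    results = {"asthmatic": [], "control": []}
    for sid, (label, trace) in sorted(_subject_mean_voc(records).items()):
        t = np.linspace(0.0, VOC_RETENTION_SPAN, len(trace))
        res = deconvolve(trace, n_components, t=t, seed=seed, restarts=2)
        results["asthmatic" if label == 1 else "control"].append(res)
    comparison = compare_groups(results)
    return results, comparison


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    On a stage failure the manifest records the completed stages and the
    failing one, then the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.cohort.seed,
        "stages": {},
        "status": "running",
    }

    def record_stage(name: str, artifacts: dict[str, Path]) -> None:
        manifest["stages"][name] = {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()
        }

    stage = "simulate"
    try:
        records = generate_cohort(config.cohort)
        cohort_dir = out / "cohort"
        write_cohort(records, cohort_dir, spec=config.cohort)
        record_stage(stage, {
            "waveforms": cohort_dir / "waveforms.csv",
            "sidecar": cohort_dir / "cohort.json",
        })

        stage = "preprocess"
        features = build_feature_table(records, config.plateau_fraction)
        features_path = out / "features.csv"
        features.to_csv(features_path, float_format="%.17g")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Z, mean, sd, const = standardize(
                features.drop(columns="label").to_numpy(), return_stats=True
            )
        pca = fit_pca(Z, variance_target=config.variance_target)
        pca_path = out / "pca_model.json"
        pca_path.write_text(
            json.dumps(
                {
                    "loadings": pca.loadings.tolist(),
                    "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                    "mean": pca.mean.tolist(),
                    "feature_means": mean.tolist(),
                    "feature_sds": sd.tolist(),
                    "n_components_kept": pca.n_components_kept,
                },
                indent=1,
            )
        )
        record_stage(stage, {"features": features_path, "pca_model": pca_path})

        stage = "deconvolve"
        _results, comparison = deconvolve_cohort(
            records, config.n_deconv_components, seed=config.cohort.seed
        )
        report_path = out / "deconvolution_report.csv"
        comparison_report(comparison).to_csv(report_path, index=False, float_format="%.10g")
        pct_path = out / "deconvolution_percent_differences.csv"
        comparison.percent_differences.to_csv(pct_path, float_format="%.10g")
        record_stage(stage, {"report": report_path, "percent_differences": pct_path})

        stage = "cross_validate"
        cv_reports = cross_validate(
            records,
            k=config.cv_folds,
            model_config=config.model,
            train_config=config.training,
            seed=config.split.seed,
        )
        cv_path = out / "cv_reports.json"
        cv_path.write_text(json.dumps([r.to_dict() for r in cv_reports], indent=1))
        record_stage(stage, {"cv_reports": cv_path})

        stage = "train_evaluate"
        from .traineval import split_dataset

        train_ids, val_ids, test_ids = split_dataset(records, config.split)
        y = features["label"].to_numpy()
        X = features.drop(columns="label").to_numpy()
        subjects = features.index.to_numpy()
        pool = np.isin(subjects, np.concatenate([train_ids, val_ids]))
        test_mask = np.isin(subjects, test_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Z_tr, mean, sd, const = standardize(X[pool], return_stats=True)
        pca = fit_pca(Z_tr, variance_target=config.variance_target)
        S_tr = project(pca, Z_tr, weight_by_variance=True)
        Z_te = (X[test_mask] - mean) / sd
        Z_te[:, const] = 0.0
        S_te = project(pca, Z_te, weight_by_variance=True)
        model, history = train(config.model, (S_tr, y[pool]), None, config.training)
        weights_dir = out / "model"
        model.save(weights_dir)
        history_path = out / "training_history.csv"
        history.to_csv(history_path, index=False)
        report = evaluate_predictions(y[test_mask], model.predict_proba(S_te))
        report_path2 = out / "eval_report.json"
        report_path2.write_text(json.dumps(report.to_dict(), indent=1))
        record_stage(
            stage,
            {
                "weights": weights_dir / "weights.npz",
                "model_config": weights_dir / "model_config.json",
                "history": history_path,
                "eval_report": report_path2,
            },
        )
        manifest["status"] = "complete"
    except Exception as err:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_data_dir(path: str | Path) -> dict:
    """Schema/completeness check of a cohort directory.

    Verifies the CSV/JSON pair is readable, every record carries the 13
    canonical channels of equal length, labels are present and binary, and
    all values are finite.  Returns {'violations': [...], 'n_records': int}.
    """
    src = Path(path)
    violations: list[dict] = []
    if not src.exists():
        raise FileNotFoundError(src)
    for required in ("waveforms.csv", "cohort.json"):
        if not (src / required).exists():
            violations.append({"file": required, "problem": "missing"})
    if violations:
        return {"violations": violations, "n_records": 0}
    try:
        table = pd.read_csv(src / "waveforms.csv")
        sidecar = json.loads((src / "cohort.json").read_text())
    except Exception as err:
        return {
            "violations": [{"file": str(src), "problem": f"unreadable: {err}"}],
            "n_records": 0,
        }
    subjects_meta = sidecar.get("subjects", {})
    n_records = 0
    for (sid, rep), group in table.groupby(["subject_id", "replicate"]):
        n_records += 1
        chans = set(group["channel"].unique())
        missing = set(CHANNELS) - chans
        extra = chans - set(CHANNELS)
        if missing:
            violations.append(
                {"subject": sid, "replicate": int(rep), "problem": f"missing channels {sorted(missing)}"}
            )
        if extra:
            violations.append(
                {"subject": sid, "replicate": int(rep), "problem": f"unknown channels {sorted(extra)}"}
            )
        lengths = group.groupby("channel").size()
        if lengths.nunique() > 1:
            violations.append(
                {"subject": sid, "replicate": int(rep), "problem": "channel lengths differ"}
            )
        bad = group[~np.isfinite(group["value"])]
        for _, row in bad.iterrows():
            violations.append(
                {
                    "subject": sid,
                    "replicate": int(rep),
                    "channel": row["channel"],
                    "index": int(group.index.get_loc(row.name)),
                    "problem": "non-finite value",
                }
            )
        if str(sid) not in subjects_meta:
            violations.append({"subject": sid, "problem": "no label in sidecar"})
        elif subjects_meta[str(sid)].get("label") not in (0, 1):
            violations.append({"subject": sid, "problem": "label not binary"})
    return {"violations": violations, "n_records": n_records}
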