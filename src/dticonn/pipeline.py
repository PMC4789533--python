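"""End-to-end orchestration: per-subject image processing and cohort statistics.

The subject-level chain is tensor fit -> FACT tracking -> fiber-count
matrix.  The cohort-level chain is permutation group test -> Spearman
screening of the surviving edges against the clinical score -> leave-one-out
linear SVM on the edges significant in both screens.  Statistics stages
accept pre-built matrices (one CSV per subject), so cohort-scale analyses
never require rerunning tractography per subject.

Feature selection for the classifier is performed once on the full cohort
by default, mirroring a screen-then-classify protocol; because that
protocol is optimistically biased, a ``per_fold`` variant that repeats both
screens inside every training fold is provided and flagged in the report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .classify import FeatureTable, loocv_linear_svm
from .connectome import (
    ConnectivityMatrix,
    Parcellation,
    build_connectivity_matrix,
    default_region_table,
)
from .stats import (
    CohortStack,
    correlate_edges_with_scores,
    permutation_group_test,
)
from .tensor import fit_tensor_loglinear
from .tracking import TrackingParams, track_fact

__all__ = ["PipelineConfig", "RunReport", "load_config", "run_pipeline", "process_subject"]


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``load_config`` for the YAML form)."""

    out_dir: str
    seed: int = 0
    cohort_spec: "object | None" = None  # synthetic CohortSpec
    cohort_dir: str | None = None  # pre-built matrices + subjects.csv
    subjects: list[dict] = field(default_factory=list)  # per-subject image paths
    tracking: TrackingParams = field(default_factory=TrackingParams)
    min_fibers: int = 5
    n_permutations: int = 10_000
    alpha_group: float = 0.05
    alpha_corr: float = 0.001
    svm_c: float = 1.0
    positive_class: str | None = None
    feature_selection: str = "pooled"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for name in ("alpha_group", "alpha_corr"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_fibers < 0:
            raise ValueError("min_fibers must be >= 0")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.feature_selection not in ("pooled", "per_fold"):
            raise ValueError("feature_selection must be 'pooled' or 'per_fold'")
        if self.cohort_spec is None and self.cohort_dir is None and not self.subjects:
            raise ValueError("config needs a cohort spec, a cohort directory, or subjects")


@dataclass
class RunReport:
    """Per-stage record of a pipeline run."""

    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def add_stage(self, name: str, input_hash: str, seconds: float, **info) -> None:
        self.stages.append(
            {"stage": name, "input_sha256": input_hash, "wall_seconds": round(seconds, 4), **info}
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
            "outputs": self.outputs,
        }


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Parse a YAML config.  Validation errors surface before any compute."""
    from .synthetic import CohortSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_spec = None
    if "cohort" in raw and raw["cohort"] is not None:
        c = dict(raw["cohort"])
        for key in ("effect_edges", "score_edges"):
            if key in c:
                c[key] = tuple(tuple(e) for e in c[key])
        cohort_spec = CohortSpec(**c)
    tracking = TrackingParams(**raw.get("tracking", {}))
    return PipelineConfig(
        out_dir=raw.get("out_dir", "."),
        seed=int(raw.get("seed", 0)),
        cohort_spec=cohort_spec,
        cohort_dir=raw.get("cohort_dir"),
        subjects=raw.get("subjects", []),
        tracking=tracking,
        min_fibers=int(raw.get("min_fibers", 5)),
        n_permutations=int(raw.get("n_permutations", 10_000)),
        alpha_group=float(raw.get("alpha_group", 0.05)),
        alpha_corr=float(raw.get("alpha_corr", 0.001)),
        svm_c=float(raw.get("svm_c", 1.0)),
        positive_class=raw.get("positive_class"),
        feature_selection=raw.get("feature_selection", "pooled"),
    )


def process_subject(
    dwi_path,
    bvals_path,
    bvecs_path,
    labels_path,
    region_table_path,
    mask_path,
    tracking: TrackingParams | None = None,
    min_fibers: int = 5,
) -> ConnectivityMatrix:
    """Subject-level chain: tensor fit, FACT tracking, fiber-count matrix."""
    volume = dio.load_dwi(dwi_path, bvals_path, bvecs_path)
    mask, _ = dio.load_nifti(mask_path)
    mask = mask > 0.5
    labels, _ = dio.load_nifti(labels_path)
    table = dio.load_region_table(region_table_path)
    parcellation = Parcellation(labels=np.rint(labels).astype(int), region_table=table)
    field_ = fit_tensor_loglinear(volume, mask)
    streamlines = track_fact(field_, mask, tracking or TrackingParams())
    return build_connectivity_matrix(streamlines, parcellation, min_fibers=min_fibers)


def _edge_names(stack: CohortStack) -> list[str]:
    if stack.region_names is not None:
        return stack.region_names
    if stack.n_regions == len(default_region_table()):
        return default_region_table()["name"].tolist()
    return [f"r{k}" for k in range(stack.n_regions)]


def _select_features(stack, n_permutations, alpha_group, alpha_corr, seed):
    """Both screens; returns (edges significant in both, perm result, corr result)."""
    perm = permutation_group_test(
        stack, n_permutations=n_permutations, alpha=alpha_group, seed=seed
    )
    if not perm.significant_edges:
        return [], perm, None
    corr = correlate_edges_with_scores(stack, perm.significant_edges, alpha=alpha_corr)
    return corr.significant_edges, perm, corr


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and write all intermediates.

    Any stage error aborts with the stage name attached.  With a fixed seed
    and config, reruns produce byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage = "setup"
    try:
        # ---- stage: build or load the cohort --------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        stack = None
        if config.subjects:
            matrices, ids, groups_col, scores = [], [], [], []
            for entry in config.subjects:
                sid = entry.get("id", f"sub-{len(ids) + 1:03d}")
                cm = process_subject(
                    entry["dwi"],
                    entry["bvals"],
                    entry["bvecs"],
                    entry["labels"],
                    entry["region_table"],
                    entry["mask"],
                    tracking=config.tracking,
                    min_fibers=config.min_fibers,
                )
                dio.write_matrix_csv(cm, out / f"{sid}.csv")
                matrices.append(cm.weights)
                ids.append(sid)
                groups_col.append(entry.get("group", "A"))
                scores.append(entry.get("score", 0))
            group_names = list(dict.fromkeys(groups_col))
            counts_ok = (
                len(group_names) == 2
                and min(groups_col.count(g) for g in group_names) >= 2
            )
            if counts_ok:
                stack = CohortStack(
                    matrices=np.asarray(matrices),
                    group_labels=np.asarray(groups_col),
                    scores=np.asarray(scores),
                    subject_ids=ids,
                    groups=(group_names[0], group_names[1]),
                )
            else:
                report.warnings.append(
                    "subject matrices written, but too few subjects per group "
                    "for cohort statistics"
                )
        elif config.cohort_spec is not None:
            from .synthetic import make_cohort

            stack, truth = make_cohort(config.cohort_spec)
            stack.region_names = _edge_names(stack)
            dio.write_cohort(stack, out / "cohort")
            dio.write_ground_truth(truth, out / "cohort" / "ground_truth.json")
            report.outputs["cohort_dir"] = str(out / "cohort")
        else:
            stack = dio.load_cohort(config.cohort_dir)
        report.add_stage(
            stage,
            _hash(stack.matrices) if stack is not None else "n/a",
            time.perf_counter() - t0,
            n_subjects=0 if stack is None else stack.n_subjects,
        )
        if stack is None:
            return report

        names = _edge_names(stack)

        # ---- stage: permutation group test ---------------------------------
        stage = "group-test"
        t0 = time.perf_counter()
        perm = permutation_group_test(
            stack,
            n_permutations=config.n_permutations,
            alpha=config.alpha_group,
            seed=config.seed,
        )
        ga, gb = stack.groups
        perm_df = pd.DataFrame(
            {
                "region_i": [e[0] for e in perm.edges],
                "region_j": [e[1] for e in perm.edges],
                "edge": [f"{names[i]}|{names[j]}" for i, j in perm.edges],
                f"mean_{ga}": perm.group_means[0],
                f"sd_{ga}": perm.group_sds[0],
                f"mean_{gb}": perm.group_means[1],
                f"sd_{gb}": perm.group_sds[1],
                "observed_stat": perm.observed_stat,
                "p_uncorrected": perm.p_uncorrected,
                "p_corrected": perm.p_corrected,
                "significant": [e in perm.significant_edges for e in perm.edges],
            }
        )
        perm_df.to_csv(out / "group_test.csv", index=False)
        report.outputs["group_test"] = str(out / "group_test.csv")
        report.add_stage(
            stage,
            _hash(stack.matrices, stack.group_labels),
            time.perf_counter() - t0,
            n_permutations=perm.n_permutations,
            n_edges_tested=len(perm.edges),
            n_significant=len(perm.significant_edges),
        )
        if not perm.significant_edges:
            report.warnings.append("no group-significant edges; stopping after group test")
            _write_report(report, out)
            return report

        # ---- stage: correlation screening ----------------------------------
        stage = "correlate"
        t0 = time.perf_counter()
        corr = correlate_edges_with_scores(
            stack, perm.significant_edges, alpha=config.alpha_corr
        )
        corr_df = pd.DataFrame(
            {
                "region_i": [e[0] for e in corr.edges],
                "region_j": [e[1] for e in corr.edges],
                "edge": [f"{names[i]}|{names[j]}" for i, j in corr.edges],
                "rho": corr.rho,
                "p_raw": corr.p_raw,
                "p_corrected": corr.p_corrected,
                "significant": corr.rejected,
            }
        )
        corr_df.to_csv(out / "correlation.csv", index=False)
        report.outputs["correlation"] = str(out / "correlation.csv")
        report.add_stage(
            stage,
            _hash(stack.matrices, stack.scores),
            time.perf_counter() - t0,
            n_edges_tested=len(corr.edges),
            n_significant=len(corr.significant_edges),
            n_excluded=len(corr.excluded_edges),
        )
        feature_edges = corr.significant_edges
        if not feature_edges:
            report.warnings.append("no score-correlated edges; stopping before classification")
            _write_report(report, out)
            return report

        # ---- stage: classification -----------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        positive = config.positive_class or stack.groups[0]
        if config.feature_selection == "per_fold":
            clf_report = _per_fold_loocv(stack, config, positive)
        else:
            features = FeatureTable(
                features=np.column_stack(
                    [stack.matrices[:, i, j] for i, j in feature_edges]
                ).astype(float),
                labels=stack.group_labels,
                positive_class=positive,
                feature_names=[f"{names[i]}|{names[j]}" for i, j in feature_edges],
                subject_ids=stack.subject_ids,
            )
            clf_report = loocv_linear_svm(features, regularization=config.svm_c)
        clf_report.settings["feature_selection"] = config.feature_selection
        clf_report.settings["feature_edges"] = [list(e) for e in feature_edges]
        pd.DataFrame(
            {
                "subject_id": stack.subject_ids,
                "truth": clf_report.truth,
                "prediction": clf_report.predictions,
            }
        ).to_csv(out / "loocv_predictions.csv", index=False)
        clf_json = {
            "positive_class": clf_report.positive_class,
            "sensitivity": clf_report.sensitivity,
            "specificity": clf_report.specificity,
            "accuracy": clf_report.accuracy,
            "confusion": {
                "tp": clf_report.tp,
                "fn": clf_report.fn,
                "tn": clf_report.tn,
                "fp": clf_report.fp,
            },
            "settings": clf_report.settings,
        }
        with open(out / "classification.json", "w") as fh:
            json.dump(clf_json, fh, indent=2)
        report.outputs["classification"] = str(out / "classification.json")
        report.add_stage(
            stage,
            _hash(stack.matrices),
            time.perf_counter() - t0,
            n_folds=clf_report.n_folds,
            accuracy=clf_report.accuracy,
        )
        _write_report(report, out)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _per_fold_loocv(stack: CohortStack, config: PipelineConfig, positive: str):
    """LOOCV repeating both screens inside every training fold (unbiased)."""
    from .classify import ClassifierReport, _confusion_counts, confusion_metrics
    from sklearn.svm import SVC

    n = stack.n_subjects
    predictions = np.empty(n, dtype=stack.group_labels.dtype)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = CohortStack(
            matrices=stack.matrices[keep],
            group_labels=stack.group_labels[keep],
            scores=stack.scores[keep],
            subject_ids=[s for k, s in enumerate(stack.subject_ids) if keep[k]],
            groups=stack.groups,
            region_names=stack.region_names,
        )
        edges, _, _ = _select_features(
            sub, config.n_permutations, config.alpha_group, config.alpha_corr, config.seed
        )
        if not edges:  # fall back to the strongest uncorrected edge
            perm = permutation_group_test(
                sub, n_permutations=config.n_permutations,
                alpha=config.alpha_group, seed=config.seed,
            )
            edges = [perm.edges[int(np.argmax(np.abs(perm.observed_stat)))]]
        Xtr = np.column_stack([sub.matrices[:, a, b] for a, b in edges]).astype(float)
        Xte = np.array([[stack.matrices[i, a, b] for a, b in edges]], dtype=float)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = SVC(kernel="linear", C=config.svm_c)
        clf.fit((Xtr - mu) / sd, sub.group_labels)
        predictions[i] = clf.predict((Xte - mu) / sd)[0]
    tp, fn, tn, fp = _confusion_counts(predictions, stack.group_labels, positive)
    sens, spec, acc = confusion_metrics(predictions, stack.group_labels, positive)
    return ClassifierReport(
        predictions=predictions,
        truth=stack.group_labels.copy(),
        positive_class=positive,
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        settings={"kernel": "linear", "regularization": config.svm_c,
                  "cv": "leave-one-out", "standardization": "per training fold"},
    )


def _write_report(report: RunReport, out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    report.outputs["run_report"] = str(out / "run_report.json")
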