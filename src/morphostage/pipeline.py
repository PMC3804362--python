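"""Leave-one-out evaluation of the full morphological staging pipeline.

For every fold one subject is held out; everything else — reference
choice, rigid normalization, correspondence, shape-model fitting, mode
selection, classifier and regressor training — is recomputed from the
remaining subjects, and the held-out subject is only ever projected onto
the fold's trained models.  Three analysis approaches are compared:

* ``previous``   — liver model only, modes selected by AVCR prefix;
* ``comparison`` — liver model only, combined (AVCR x correlation) selection;
* ``proposed``   — liver, spleen and joint models, combined selection,
  one mode per model (three features in total).

Per-subject normalization (rigid ICP + TPS-RPM reordering against a given
reference) depends only on the subject/reference pair, so it is cached
across folds and approaches without information leakage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .register import apply_transform, register_rigid
from .selection import LabelVector, ModeSelection, select_by_avcr, select_modes
from .ssm import ShapeModelResults, StatisticalShapeModel
from .staging import StageRegression, classify_nn
from .tpsrpm import AnnealingSchedule, match_tps_rpm, reorder_by_correspondence

log = logging.getLogger(__name__)

VARIANTS = ("liver", "spleen", "joint")
APPROACHES = ("previous", "comparison", "proposed")


@dataclass
class PipelineConfig:
    """All tunables of the evaluation pipeline."""

    avcr_threshold: float = 0.90
    corr_top_k: int = 4
    final_count: int = 1
    svr_C: float = 10.0
    svr_epsilon: float = 0.1
    svr_gamma: float | None = None
    standardize_features: bool = True
    centered_correlation: bool = False
    correspondence: str = "tpsrpm"  # "tpsrpm" | "index" (trust input vertex order)
    # schedule tuned for organ pairs that are already rigidly registered:
    # displacements are a small fraction of the organ scale, so annealing
    # can start well below the fully-fuzzy regime
    schedule: AnnealingSchedule = field(default_factory=lambda: AnnealingSchedule(
        t_init=0.05, decay=0.88, sinkhorn_iterations=5, n_control=100))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


class NormalizationCache:
    """Registered + corresponded vertex arrays, keyed by (subject, reference, organ).

    A cache entry is a (V, 3) array of the subject's organ vertices after
    rigid alignment to the reference subject and reordering into the
    reference vertex ordering.  Entries depend only on the two subjects
    involved, never on cohort composition.
    """

    def __init__(self, surfaces: dict[str, dict[str, "Surface"]], config: PipelineConfig):
        self.surfaces = surfaces
        self.config = config
        self._store: dict[tuple[str, str, str], np.ndarray] = {}

    def vertices(self, sid: str, ref_id: str, organ: str) -> np.ndarray:
        key = (sid, ref_id, organ)
        if key in self._store:
            return self._store[key]
        subject = self.surfaces[sid][organ]
        if sid == ref_id:
            out = subject.vertices.copy()
        else:
            reference = self.surfaces[ref_id][organ]
            transform = register_rigid(subject, reference)
            moved = apply_transform(subject, transform)
            if self.config.correspondence == "tpsrpm":
                corr, _ = match_tps_rpm(moved, reference, self.config.schedule)
                moved = reorder_by_correspondence(moved, corr)
            out = moved.vertices
        self._store[key] = out
        return out


@dataclass
class EvaluationReport:
    """Leave-one-out results for one analysis approach."""

    approach: str
    per_class_accuracy: dict[str, float]
    per_subject: list[dict]
    per_stage_score_stats: dict[int, dict[str, float]]
    selected_modes: list[dict]
    config_hash: str = ""
    seed: int | None = None
    n_folds: int = 0
    skipped_folds: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        d["per_stage_score_stats"] = {int(k): v for k, v in d["per_stage_score_stats"].items()}
        return cls(**d)

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_subject)

    def summary(self) -> str:
        lines = [f"Leave-one-out evaluation — approach: {self.approach}",
                 f"folds: {self.n_folds} (skipped: {len(self.skipped_folds)}); "
                 f"config {self.config_hash}"]
        for cls_name, acc in self.per_class_accuracy.items():
            lines.append(f"  {cls_name} classification accuracy: {acc:.1%}")
        if self.per_stage_score_stats:
            lines.append("  SVR stage scores (mean +- sd):")
            for stage in sorted(self.per_stage_score_stats):
                s = self.per_stage_score_stats[stage]
                lines.append(f"    stage {stage}: {s['mean']:.3f} +- {np.sqrt(s['var']):.3f}"
                             f"  (n={int(s['n'])})")
        return "\n".join(lines)


def _labels_frame(cohort: Sequence, labels: pd.DataFrame | None) -> pd.DataFrame:
    if labels is not None:
        return labels.set_index("subject_id") if "subject_id" in labels.columns else labels
    from .synthetic import cohort_to_label_table

    return cohort_to_label_table(list(cohort)).set_index("subject_id")


def _fold_variant_features(cache: NormalizationCache, train_ids: list[str], test_id: str,
                           ref_id: str, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Training shape matrix and held-out shape vector for one model variant."""

    def vec(sid: str) -> np.ndarray:
        if variant == "joint":
            return np.concatenate([cache.vertices(sid, ref_id, "liver").ravel(),
                                   cache.vertices(sid, ref_id, "spleen").ravel()])
        return cache.vertices(sid, ref_id, variant).ravel()

    train = np.stack([vec(sid) for sid in train_ids])
    return train, vec(test_id)


def fit_fold(cache: NormalizationCache, train_ids: list[str], test_id: str,
             labels: pd.DataFrame, config: PipelineConfig, approach: str) -> dict:
    """Train one fold and project the held-out subject.

    Returns the fold artifacts: trained models, mode selections, the
    training feature matrix and the held-out feature vector.  Everything
    is computed from ``train_ids`` only; ``test_id`` enters through
    projection alone.
    """
    train_ids = sorted(train_ids)
    ref_id = train_ids[0]
    binary = labels.loc[train_ids, "binary_label"].to_numpy(dtype=float)
    variants = VARIANTS if approach == "proposed" else ("liver",)
    models: dict[str, ShapeModelResults] = {}
    selections: dict[str, ModeSelection | None] = {}
    train_cols, test_cols = [], []
    for variant in variants:
        train_mat, test_vec = _fold_variant_features(cache, train_ids, test_id, ref_id, variant)
        model = StatisticalShapeModel(train_mat, layout=variant, subject_ids=train_ids,
                                      reference_id=ref_id).fit()
        coeffs = model.coefficient_matrix(train_mat)
        test_coeffs = model.project(test_vec).values
        if approach == "previous":
            modes = select_by_avcr(model, threshold=config.avcr_threshold)
            selections[variant] = None
            idx = [m - 1 for m in modes]
        else:
            sel = select_modes(model, coeffs, LabelVector(binary, train_ids),
                               avcr_threshold=config.avcr_threshold,
                               corr_top_k=config.corr_top_k,
                               final_count=config.final_count,
                               centered=config.centered_correlation)
            selections[variant] = sel
            idx = [m - 1 for m in sel.selected]
        train_cols.append(coeffs[:, idx])
        test_cols.append(test_coeffs[idx])
        models[variant] = model
    return {
        "ref_id": ref_id,
        "models": models,
        "selections": selections,
        "train_features": np.hstack(train_cols),
        "test_feature": np.concatenate(test_cols),
        "train_ids": train_ids,
        "selected": {v: (tuple(s.selected) if s else "avcr-prefix")
                     for v, s in selections.items()},
    }


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def evaluate(cohort: Sequence, config: PipelineConfig | None = None,
             labels: pd.DataFrame | None = None,
             approaches: Sequence[str] = APPROACHES,
             seed: int | None = None) -> dict[str, EvaluationReport]:
    """Leave-one-out evaluation of one or more approaches on a cohort.

    ``cohort`` items need ``subject_id``, ``liver`` and ``spleen``
    attributes; ``labels`` defaults to the synthetic cohort's label table.
    """
    config = config or PipelineConfig()
    labels = _labels_frame(cohort, labels)
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if labels["binary_label"].nunique() < 2:
        raise ValueError("cohort must contain both classes")
    surfaces = {s.subject_id: {"liver": s.liver, "spleen": s.spleen} for s in cohort}
    ids = sorted(surfaces)
    cache = NormalizationCache(surfaces, config)

    results: dict[str, dict] = {a: {"rows": [], "selected": [], "skipped": []}
                                for a in approaches}
    for fold_i, test_id in enumerate(ids):
        tic = time.perf_counter()
        train_ids = [s for s in ids if s != test_id]
        if labels.loc[train_ids, "binary_label"].nunique() < 2:
            log.warning("fold %s skipped: single-class training set", test_id)
            for a in approaches:
                results[a]["skipped"].append(test_id)
            continue
        stage_truth = labels.loc[test_id, "stage_label"]
        stage_truth = None if pd.isna(stage_truth) else int(stage_truth)
        for approach in approaches:
            fold = fit_fold(cache, train_ids, test_id, labels, config, approach)
            train_f, test_f = fold["train_features"], fold["test_feature"]
            if config.standardize_features:
                train_nn, test_nn = _standardize(train_f, test_f)
            else:
                train_nn, test_nn = train_f, test_f
            nn_label = classify_nn(train_nn, labels.loc[fold["train_ids"],
                                                        "binary_label"].to_numpy(), test_nn)
            svr_score = None
            staged = labels.loc[fold["train_ids"], "stage_label"]
            staged_ids = staged.index[staged.notna()].tolist()
            if stage_truth is not None and len(staged_ids) >= 2:
                keep = [fold["train_ids"].index(s) for s in staged_ids]
                reg = StageRegression(train_f[keep], staged.loc[staged_ids].astype(float),
                                      C=config.svr_C, epsilon=config.svr_epsilon,
                                      gamma=config.svr_gamma,
                                      standardize=config.standardize_features).fit()
                svr_score = float(reg.predict_score(test_f[None, :])[0])
            results[approach]["rows"].append({
                "subject_id": test_id,
                "binary_truth": int(labels.loc[test_id, "binary_label"]),
                "nn_label": int(nn_label),
                "stage_truth": stage_truth,
                "svr_score": svr_score,
            })
            results[approach]["selected"].append({"fold": test_id, **fold["selected"]})
        log.info("fold %d/%d (%s) done in %.1fs", fold_i + 1, len(ids), test_id,
                 time.perf_counter() - tic)

    reports = {}
    for approach in approaches:
        rows = results[approach]["rows"]
        df = pd.DataFrame(rows)
        acc = {}
        for cls_name, cls_val in (("normal", 0), ("abnormal", 1)):
            sub = df[df.binary_truth == cls_val]
            acc[cls_name] = float((sub.nn_label == cls_val).mean()) if len(sub) else float("nan")
        stats: dict[int, dict[str, float]] = {}
        scored = df[df.svr_score.notna() & df.stage_truth.notna()]
        for stage, grp in scored.groupby("stage_truth"):
            stats[int(stage)] = {"mean": float(grp.svr_score.mean()),
                                 "var": float(grp.svr_score.var(ddof=0)),
                                 "n": float(len(grp))}
        reports[approach] = EvaluationReport(
            approach=approach, per_class_accuracy=acc, per_subject=rows,
            per_stage_score_stats=stats, selected_modes=results[approach]["selected"],
            config_hash=config.config_hash(), seed=seed, n_folds=len(rows),
            skipped_folds=results[approach]["skipped"])
    return reports


def run_loo(cohort: Sequence, config: PipelineConfig | None = None,
            labels: pd.DataFrame | None = None, approach: str = "proposed",
            seed: int | None = None) -> EvaluationReport:
    """Leave-one-out evaluation of a single approach (default: proposed)."""
    return evaluate(cohort, config, labels, approaches=(approach,), seed=seed)[approach]


def compare_methods(cohort: Sequence, config: PipelineConfig | None = None,
                    labels: pd.DataFrame | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Run all three approaches under identical conditions.

    Returns a tidy accuracy table and the full per-approach reports.
    """
    reports = evaluate(cohort, config, labels, approaches=APPROACHES, seed=seed)
    table = pd.DataFrame([
        {"approach": a,
         "normal_accuracy": r.per_class_accuracy["normal"],
         "abnormal_accuracy": r.per_class_accuracy["abnormal"]}
        for a, r in reports.items()])
    return table, reports
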