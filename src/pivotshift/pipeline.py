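"""End-to-end glue: recordings -> QC -> features -> models -> report.

These functions are the programmatic counterpart of the command-line
stages, shared by the CLI, the example scripts and the evaluation
harness.  Feature tables are plain DataFrames (``test_id`` + registered
feature columns + any label columns present in the manifest), so each
stage can also be driven from files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    GRADABLE_CLASSES,
    ClassifierModel,
    TrainConfig,
    fit_class_model,
    fit_grade_model,
    gradable_mask,
)
from .evaluate import (
    confusion_counts,
    mann_whitney_u,
    multiclass_accuracy,
    paper_metrics,
    roc_auc,
)
from .features import ALL_FEATURES, CLASS_FEATURES, GRADE_FEATURES, extract_all_features
from .io_formats import GyroRecording
from .preprocessing import QCConfig, run_qc
from .simulate import LabeledDataset

__all__ = [
    "feature_table",
    "train_models",
    "predict_labels",
    "evaluation_report",
    "stratified_holdout",
]


def stratified_holdout(
    table: pd.DataFrame, test_size: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a labeled feature table stratified on (class, grade) jointly.

    With rare cells (a few tests of one grade within one class) a split
    stratified on class alone can leave a grade entirely out of some
    class's training rows, making that grade unpredictable for the
    per-class model.  Joint stratification keeps every populated cell
    represented; cells with a single row fall back to class-only strata.
    """
    from sklearn.model_selection import train_test_split

    key = table["class_label"].astype(int).astype(str) + "/" + table[
        "ikdc_grade"
    ].astype(int).astype(str)
    # collapse strata that are too small to split: cell -> class -> pooled
    for coarser in (table["class_label"].astype(int).astype(str), pd.Series("_", index=table.index)):
        singles = key.map(key.value_counts()) < 2
        if not singles.any():
            break
        key = key.where(~singles, coarser)
    singles = key.map(key.value_counts()) < 2
    if singles.any():  # a lone leftover row joins the largest stratum
        key = key.where(~singles, key.value_counts().idxmax())
    return train_test_split(table, test_size=test_size, random_state=seed, stratify=key)


def feature_table(
    dataset: LabeledDataset,
    qc: QCConfig | None | bool = None,
) -> tuple[pd.DataFrame, list]:
    """Compute the full feature row for every QC-passing recording.

    Returns ``(table, failures)`` where ``failures`` is the list of
    QC reports for excluded tests.  Pass ``qc=False`` to skip screening
    (e.g. when non-standard executions must stay in for class training).
    """
    rows, failures = [], []
    manifest = dataset.manifest.table.set_index("test_id")
    for rec in dataset.recordings:
        if qc is not False:
            report = run_qc(rec, qc if isinstance(qc, QCConfig) else None)
            if not report.passed:
                failures.append(report)
                continue
        fv = extract_all_features(rec)
        row = {"test_id": rec.test_id, **{f: fv[f] for f in ALL_FEATURES}}
        if rec.test_id in manifest.index:
            m = manifest.loc[rec.test_id]
            row["class_label"] = m["class_label"]
            row["ikdc_grade"] = m["ikdc_grade"]
        rows.append(row)
    return pd.DataFrame(rows), failures


def train_models(
    table: pd.DataFrame, cfg: TrainConfig | None = None
) -> tuple[ClassifierModel, dict[int, ClassifierModel]]:
    """Fit the class model and one grade model per gradable class.

    A grade model for class k is fitted only when the table holds rows of
    class k with at least two distinct grades.
    """
    cfg = cfg or TrainConfig()
    y_class = table["class_label"].to_numpy(dtype=int)
    class_model = fit_class_model(table[list(CLASS_FEATURES)].to_numpy(), y_class, cfg)

    grade_models: dict[int, ClassifierModel] = {}
    for k in sorted(GRADABLE_CLASSES):
        sub = table[table["class_label"] == k]
        if len(sub) and sub["ikdc_grade"].nunique() >= 2:
            grade_models[k] = fit_grade_model(
                sub[list(GRADE_FEATURES)].to_numpy(),
                sub["ikdc_grade"].to_numpy(dtype=int),
                k,
                cfg,
            )
    return class_model, grade_models


def predict_labels(
    table: pd.DataFrame,
    class_model: ClassifierModel,
    grade_models: dict[int, ClassifierModel],
    grade_routing: str = "predicted",
) -> pd.DataFrame:
    """Predict maneuver class, then grade via the per-class grade model.

    Tests whose routing class is non-gradable (1 or 8) get ``gradable =
    False`` and no grade.  ``p_injured`` is the predicted probability of
    grade >= 1, the score used for the injury ROC.

    ``grade_routing`` picks which class label selects the grade model:
    ``"predicted"`` (deployment: nothing but the signal is known) or
    ``"true"`` (per-class grade evaluation with known class membership,
    the setting in which the per-class grade confusion matrices are
    defined; requires a ``class_label`` column).
    """
    Xc = table[list(CLASS_FEATURES)].to_numpy()
    pred_class = class_model.predict(Xc)
    if grade_routing == "predicted":
        routing = pred_class
    elif grade_routing == "true":
        routing = table["class_label"].to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown grade_routing {grade_routing!r}")

    pred_grade = np.full(len(table), -1, dtype=int)
    p_injured = np.full(len(table), np.nan)
    Xg = table[list(GRADE_FEATURES)].to_numpy()
    for i, k in enumerate(routing):
        model = grade_models.get(int(k))
        if model is None:
            continue
        proba = model.predict_proba(Xg[i : i + 1])[0]
        pred_grade[i] = model.classes[int(np.argmax(proba))]
        p_injured[i] = proba[np.asarray(model.classes) >= 1].sum()

    out = table[["test_id"]].copy()
    out["pred_class"] = pred_class
    out["gradable"] = gradable_mask(routing)
    out["pred_grade"] = pred_grade
    out.loc[~out["gradable"], "pred_grade"] = pd.NA
    out["p_injured"] = p_injured
    return out


def evaluation_report(
    truth: pd.DataFrame, predictions: pd.DataFrame
) -> dict:
    """Score predictions against true labels.

    Emits per-class confusion counts with the four printed metrics, the
    aggregate row, standard multiclass accuracies, the grade-0-vs-injured
    ROC AUC on the grade-probability score, and a Mann-Whitney comparison
    of the S3 amplitude-driven score between injured and uninjured tests.
    """
    df = truth.merge(predictions, on="test_id")
    y_true = df["class_label"].to_numpy(dtype=int)
    y_pred = df["pred_class"].to_numpy(dtype=int)

    cc = confusion_counts(y_true, y_pred)
    per_class = {
        int(k): {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            **(
                paper_metrics(tp, fp, fn).__dict__
                if tp + fp > 0 and tp + fn > 0
                else {}
            ),
        }
        for k, (tp, fp, fn) in sorted(cc.counts.items())
    }
    tp, fp, fn = cc.total
    report = {
        "class": {
            "per_class": per_class,
            "total": {"tp": tp, "fp": fp, "fn": fn, **paper_metrics(tp, fp, fn).__dict__},
            "accuracy": multiclass_accuracy(y_true, y_pred),
        }
    }

    graded = df[df["gradable"] & df["pred_grade"].notna()]
    if len(graded):
        g_true = graded["ikdc_grade"].to_numpy(dtype=int)
        g_pred = graded["pred_grade"].to_numpy(dtype=int)
        gc = confusion_counts(g_true, g_pred)
        report["grade"] = {
            "per_grade": {int(k): dict(zip(("tp", "fp", "fn"), v)) for k, v in sorted(gc.counts.items())},
            "accuracy": multiclass_accuracy(g_true, g_pred),
        }
        scored = graded[graded["p_injured"].notna()]
        injured = (scored["ikdc_grade"] > 0).to_numpy(dtype=int)
        if len(np.unique(injured)) == 2:
            roc = roc_auc(scored["p_injured"].to_numpy(), injured)
            report["roc"] = {"auc": roc["auc"], "n": int(len(scored))}
            mwu = mann_whitney_u(
                scored.loc[injured == 1, "p_injured"],
                scored.loc[injured == 0, "p_injured"],
                alternative="greater",
            )
            report["mann_whitney_injured_vs_not"] = mwu
    return report
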