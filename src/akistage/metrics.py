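"""Validation statistics against an expert-annotated reference.

Predictions and annotations are aligned on (subject, hour). Hours present
on only one side, and hours where the prediction is undefined (the
reference has no "undefined"), are excluded from the scores and reported
as counts alongside them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score

from .data_model import STAGE_COLUMNS

CATEGORY_LABELS = {
    "uo_stage": "UO",
    "abs_scr_stage": "absolute SCr",
    "rel_scr_stage": "relative SCr",
    "dialysis_stage": "dialysis",
    "overall_stage": "overall",
}


@dataclasses.dataclass
class Alignment:
    n_aligned: int
    n_unmatched: int  # (subject, hour) pairs present on one side only


def align(pred: pd.DataFrame, ref: pd.DataFrame) -> tuple[pd.DataFrame, Alignment]:
    """Inner-join prediction and reference staging tables on (subject, hour)."""
    keys = ["subject_id", "hour_index"]
    merged = pred.merge(ref, on=keys, how="inner", suffixes=("_pred", "_ref"))
    n_unmatched = len(pred) + len(ref) - 2 * len(merged)
    if merged.empty:
        raise ValueError("no aligned (subject, hour) rows between prediction and reference")
    return merged, Alignment(n_aligned=len(merged), n_unmatched=n_unmatched)


def accuracy_by_category(pred: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Per-category, per-stage one-vs-rest accuracy plus category accuracy.

    Returns a tidy frame with columns ``category``, ``stage`` ("all" for
    the category-level multiclass accuracy), ``accuracy``, ``n`` (scored
    hours) and ``n_undefined`` (prediction-undefined hours excluded).
    """
    merged, _ = align(pred, ref)
    rows = []
    for col in STAGE_COLUMNS:
        p = pd.to_numeric(merged[f"{col}_pred"], errors="coerce")
        r = pd.to_numeric(merged[f"{col}_ref"], errors="coerce")
        usable = p.notna() & r.notna()
        n_undefined = int((~usable).sum())
        y_pred = p[usable].to_numpy(dtype=int)
        y_ref = r[usable].to_numpy(dtype=int)
        label = CATEGORY_LABELS[col]
        if len(y_ref) == 0:
            raise ValueError(f"no scorable hours for category {label}")
        rows.append(
            {
                "category": label,
                "stage": "all",
                "accuracy": accuracy_score(y_ref, y_pred),
                "n": len(y_ref),
                "n_undefined": n_undefined,
            }
        )
        for stage in range(4):
            rows.append(
                {
                    "category": label,
                    "stage": str(stage),
                    "accuracy": accuracy_score(y_ref == stage, y_pred == stage),
                    "n": len(y_ref),
                    "n_undefined": n_undefined,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class BinaryDiagnostics:
    sensitivity: float
    specificity: float
    auc: float
    n: int
    degenerate_reference: bool


def binary_aki_diagnostics(pred: pd.DataFrame, ref: pd.DataFrame) -> BinaryDiagnostics:
    """Sensitivity, specificity and ROC-AUC for "any AKI" (overall ≥ 1).

    The ordinal predicted overall stage (0–3) is used as the ROC score; a
    reference with a single class leaves all three statistics NaN and sets
    ``degenerate_reference``.
    """
    merged, _ = align(pred, ref)
    p = pd.to_numeric(merged["overall_stage_pred"], errors="coerce")
    r = pd.to_numeric(merged["overall_stage_ref"], errors="coerce")
    usable = p.notna() & r.notna()
    score = p[usable].to_numpy(dtype=float)
    y_true = (r[usable].to_numpy(dtype=float) >= 1).astype(int)
    y_pred = (score >= 1).astype(int)

    pos = int(y_true.sum())
    neg = int(len(y_true) - pos)
    degenerate = pos == 0 or neg == 0
    sens = float(((y_pred == 1) & (y_true == 1)).sum() / pos) if pos else float("nan")
    spec = float(((y_pred == 0) & (y_true == 0)).sum() / neg) if neg else float("nan")
    auc = float("nan") if degenerate else float(roc_auc_score(y_true, score))
    return BinaryDiagnostics(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n=len(y_true),
        degenerate_reference=degenerate,
    )


def rank_auc(y_true: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney concordance AUC with half credit for ties.

    Independent of trapezoidal ROC integration; used as a cross-check.
    """
    y_true = np.asarray(y_true, dtype=int)
    score = np.asarray(score, dtype=float)
    pos = score[y_true == 1]
    neg = score[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))
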