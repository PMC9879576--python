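"""Threshold-swept balanced-accuracy evaluation.

A sequence is predicted positive when its biting probability is
*strictly above* a threshold t.  The evaluation sweeps t over the grid
0.00, 0.01, ..., 1.00 and records the confusion counts and derived
rates at every point:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* FPR = 1 - specificity
* MMA = (sensitivity + specificity) / 2  (major-mean / balanced accuracy)

``nMMA`` is the MMA at the conventional t = 0.50; ``btMMA`` is the
maximum MMA over the grid (ties broken toward the smallest, i.e. most
sensitive, threshold).  The ROC curve and its AUC are computed on the
same 101-point grid.  Degenerate test sets (a class absent) yield
flagged missing rates rather than silent 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pentail.data_io import CATEGORIES
from pentail.errors import EvaluationError

#: The evaluation threshold grid: 0.00-1.00 in steps of 0.01.
THRESHOLD_GRID = np.round(np.arange(101) / 100.0, 2)


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Rates derived from a confusion; NaN + flag when a denominator is 0."""

    sensitivity: float
    specificity: float
    fpr: float
    mma: float
    flags: tuple[str, ...] = ()


def confusion_at(probs: np.ndarray, labels: np.ndarray, t: float,
                 geq: bool = False) -> Confusion:
    """Confusion counts at threshold t (positive iff prob > t; ``geq`` uses >=)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must be aligned 1-D arrays")
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    pred = probs >= t if geq else probs > t
    pos = labels == 1
    return Confusion(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: Confusion) -> Metrics:
    """Sensitivity, specificity, FPR and MMA from confusion counts."""
    flags = []
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        sens = np.nan
        flags.append("no_positives")
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        spec = np.nan
        flags.append("no_negatives")
    fpr = 1.0 - spec if not np.isnan(spec) else np.nan
    mma = (sens + spec) / 2.0 if not flags else np.nan
    return Metrics(sens, spec, fpr, mma, tuple(flags))


@dataclass
class EvalReport:
    """Threshold-indexed confusion curves plus summary statistics."""

    thresholds: np.ndarray
    curve: pd.DataFrame          # per-threshold counts and rates
    nmma: float
    btmma: float
    best_threshold: float
    auc: float
    category_table: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "nmma": self.nmma,
            "btmma": self.btmma,
            "best_threshold": self.best_threshold,
            "auc": self.auc,
        }
        if self.category_table is not None:
            payload["category_table"] = self.category_table.to_dict(orient="records")
        payload.update(self.extras)
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload


def threshold_sweep(probs: np.ndarray, labels: np.ndarray,
                    geq: bool = False) -> EvalReport:
    """Evaluate the full 101-point threshold grid.

    Raises :class:`EvaluationError` if labels contain a single class
    (rates would be undefined at every threshold).
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("labels contain a single class; MMA undefined")
    rows = []
    for t in THRESHOLD_GRID:
        c = confusion_at(probs, labels, float(t), geq=geq)
        m = metrics(c)
        rows.append(
            {
                "threshold": float(t),
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "fpr": m.fpr,
                "mma": m.mma,
            }
        )
    curve = pd.DataFrame(rows)
    mma = curve["mma"].to_numpy()
    nmma = float(mma[50])  # t = 0.50
    best_i = int(np.argmax(mma))  # argmax returns the smallest maximizing index
    return EvalReport(
        thresholds=THRESHOLD_GRID.copy(),
        curve=curve,
        nmma=nmma,
        btmma=float(mma[best_i]),
        best_threshold=float(THRESHOLD_GRID[best_i]),
        auc=roc_auc_from_curve(curve),
    )


def roc_auc_from_curve(curve: pd.DataFrame) -> float:
    """Trapezoidal AUC over the grid's (FPR, sensitivity) pairs.

    Points are sorted by FPR (then sensitivity); (0,0) and (1,1) are
    appended if the grid does not reach them.
    """
    pts = curve[["fpr", "sensitivity"]].dropna().to_numpy()
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    if len(pts) == 0 or pts[0, 0] > 0 or pts[0, 1] > 0:
        pts = np.vstack([[0.0, 0.0], pts])
    if pts[-1, 0] < 1 or pts[-1, 1] < 1:
        pts = np.vstack([pts, [1.0, 1.0]])
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(report: EvalReport) -> float:
    return roc_auc_from_curve(report.curve)


def category_breakdown(
    probs: np.ndarray,
    labels: np.ndarray,
    categories: np.ndarray,
    t: float,
    geq: bool = False,
) -> pd.DataFrame:
    """Predictions split by behaviour category at threshold t.

    For ``tail_biting`` the table reports sensitivity (share predicted
    biting); for each non-biting category it reports specificity (share
    predicted no-biting).  Categories absent from the data are omitted.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    categories = np.asarray(categories, dtype=object)
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    pred = probs >= t if geq else probs > t
    rows = []
    for cat in CATEGORIES:
        mask = categories == cat
        if not mask.any():
            continue
        n_pred_pos = int(pred[mask].sum())
        n_pred_neg = int((~pred[mask]).sum())
        row = {
            "category": cat,
            "predicted_no_biting": n_pred_neg,
            "predicted_biting": n_pred_pos,
            "sensitivity": np.nan,
            "specificity": np.nan,
        }
        if cat == "tail_biting":
            row["sensitivity"] = n_pred_pos / mask.sum()
        else:
            row["specificity"] = n_pred_neg / mask.sum()
        rows.append(row)
    return pd.DataFrame(rows)


def plot_roc(report: EvalReport, path: str | Path) -> None:
    """Save the ROC curve of a report as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    curve = report.curve.sort_values("fpr")
    ax.plot(curve["fpr"], curve["sensitivity"], marker=".", lw=1)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"AUC = {report.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
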