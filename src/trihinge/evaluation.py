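"""Region-identification metrics, centroid prediction error, gender analysis.

Region identification is scored per vertex with precision, recall and F1 (in
percent). Centroid localization is scored with the prediction error PreE:
the Euclidean distance in mm between predicted and reference 3-hinge
centroids, averaged per hemisphere (lh-/rh-PreE) and over the whole brain
(mean-PreE). The gender analysis computes the point-biserial (Pearson)
correlation between a per-subject identification accuracy and binary gender.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ConfigError, DimensionError

__all__ = [
    "EvalReport",
    "region_metrics",
    "confusion_counts",
    "centroid_pre",
    "aggregate_subjects",
    "gender_correlation",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    lh_pre: float | None
    rh_pre: float | None
    mean_pre: float | None
    aggregation: str
    per_subject: pd.DataFrame = field(default_factory=pd.DataFrame)

    def as_dict(self) -> dict:
        def _clean(v):
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                return None
            return round(float(v), 6)

        return {
            "precision": _clean(self.precision),
            "recall": _clean(self.recall),
            "f1": _clean(self.f1),
            "lh_pre": _clean(self.lh_pre),
            "rh_pre": _clean(self.rh_pre),
            "mean_pre": _clean(self.mean_pre),
            "aggregation": self.aggregation,
        }


def confusion_counts(pred, truth, mask=None) -> tuple[int, int, int]:
    """(TP, FP, FN) over valid vertices."""
    pred = np.asarray(pred).ravel() > 0
    truth = np.asarray(truth).ravel() > 0
    if pred.size != truth.size:
        raise DimensionError("pred and truth must have equal length")
    if mask is not None:
        mask = np.asarray(mask).ravel() > 0
        if mask.size != pred.size:
            raise DimensionError("mask must have the same length as pred")
        pred, truth = pred[mask], truth[mask]
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, fp, fn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f1


def region_metrics(pred, truth, mask=None) -> tuple[float, float, float]:
    """Precision, recall and F1 in percent; undefined ratios report as 0."""
    return _prf(*confusion_counts(pred, truth, mask))


def centroid_pre(pred_centroids, truth_centroids, direction: str = "truth_to_pred") -> float:
    """Mean nearest-neighbor Euclidean distance (mm) between centroid sets.

    The default direction matches each reference centroid to its nearest
    predicted centroid (a missed hinge is penalized by the distance to the
    nearest prediction); ``"symmetric"`` averages both directions. An empty
    prediction yields +inf, reported downstream as missing.
    """
    truth = np.asarray(truth_centroids, dtype=np.float64).reshape(-1, 3)
    if truth.shape[0] == 0:
        raise ConfigError("truth centroid set must be nonempty")
    pred = np.asarray(pred_centroids, dtype=np.float64).reshape(-1, 3)
    if pred.shape[0] == 0:
        return float("inf")
    t2p = cKDTree(pred).query(truth)[0].mean()
    if direction == "truth_to_pred":
        return float(t2p)
    if direction == "symmetric":
        p2t = cKDTree(truth).query(pred)[0].mean()
        return float(0.5 * (t2p + p2t))
    raise ConfigError(f"unknown direction {direction!r}")


def aggregate_subjects(records: list[dict], aggregation: str = "macro") -> EvalReport:
    """Aggregate per-subject confusion counts and PreE values into a report.

    Each record carries ``tp, fp, fn`` and optional ``lh_pre``/``rh_pre`` in
    mm (plus free-form id columns). Macro averages per-subject metrics (F1 is
    the mean of per-subject F1 values); micro pools the confusion counts.
    mean-PreE is the mean over subjects of the per-subject whole-brain PreE
    (hemisphere PreEs averaged; non-finite values are treated as missing).
    """
    if not records:
        raise ConfigError("need at least one subject record")
    if aggregation not in ("macro", "micro"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    df = pd.DataFrame.from_records(records)
    per = df.copy()
    prf = per.apply(lambda r: _prf(int(r.tp), int(r.fp), int(r.fn)), axis=1, result_type="expand")
    per[["precision", "recall", "f1"]] = prf

    def _hemi_mean(row):
        vals = [row.get(k) for k in ("lh_pre", "rh_pre")]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    per["subject_pre"] = per.apply(_hemi_mean, axis=1)

    if aggregation == "micro":
        precision, recall, f1 = _prf(int(df.tp.sum()), int(df.fp.sum()), int(df.fn.sum()))
    else:
        precision = float(per.precision.mean())
        recall = float(per.recall.mean())
        f1 = float(per.f1.mean())

    def _col_mean(col):
        if col not in per:
            return None
        v = per[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else None

    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        lh_pre=_col_mean("lh_pre"),
        rh_pre=_col_mean("rh_pre"),
        mean_pre=_col_mean("subject_pre"),
        aggregation=aggregation,
        per_subject=per,
    )


def gender_correlation(accuracy, gender) -> tuple[float, float]:
    """Point-biserial correlation between per-subject accuracy and gender.

    Returns Pearson's r between the accuracy values and 0/1 gender labels and
    the two-sided p-value from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom.
    """
    acc = np.asarray(accuracy, dtype=np.float64).ravel()
    g = np.asarray(gender).ravel()
    if acc.size != g.size:
        raise DimensionError("accuracy and gender must have equal length")
    if acc.size < 3:
        raise ConfigError("need at least 3 subjects")
    if len(np.unique(g)) != 2:
        raise ConfigError("both genders must be present")
    if np.allclose(acc, acc[0]):
        raise ConfigError("accuracy is constant; correlation undefined")
    g01 = (g == np.max(g)).astype(np.float64)
    r, p = stats.pearsonr(acc, g01)
    return float(r), float(p)
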