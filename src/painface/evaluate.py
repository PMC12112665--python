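"""Evaluation: expression metrics, pain-level accuracy, estimator
comparison, and temporal pain profiles.

"Accuracy" for pain levels is exact agreement of the 0–5 category;
per-class expression metrics are one-vs-rest (precision, recall, F1,
accuracy, ROC-AUC and average precision), macro-averaged over classes
with defined values. A class with zero support yields missing (NaN)
metrics rather than zeros, so macro averages stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import CalibrationTable, ZoneConfig
from .au_zones import compute_zone_intensities, reduce_to_vector
from .emotion import (
    EMOTIONS,
    AUWeightMatrix,
    EmotionWeightTable,
    classify_au_vector,
)
from .errors import InvalidArgumentError
from .ingest import CanonicalLandmarks
from .pain_score import (
    DEFAULT_THRESHOLDS,
    PSPIConfig,
    bin_pain_level,
    pspi_ple,
    weighted_ple,
    zone_max_ple,
)
from .synthetic_faces import SyntheticFrame

__all__ = [
    "confusion",
    "classification_metrics",
    "pain_accuracy",
    "compare_estimators",
    "temporal_profile",
    "ESTIMATORS",
    "plot_confusion",
    "plot_temporal_profile",
]

#: Estimator columns of the accuracy table: PSPI baseline, its weighted
#: variant, the zone-max score, and its weighted variant.
ESTIMATORS = ("PLE", "PLEw", "PLEz", "PLEWz")


def confusion(
    truth: Sequence[str], pred: Sequence[str], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Confusion matrix as a DataFrame: rows = truth, columns = prediction."""
    if len(truth) != len(pred):
        raise InvalidArgumentError(
            f"length mismatch: {len(truth)} truths vs {len(pred)} predictions"
        )
    if labels is None:
        labels = list(EMOTIONS) if set(truth) | set(pred) <= set(EMOTIONS) else sorted(
            set(truth) | set(pred)
        )
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, pred):
        cm[idx[t], idx[p]] += 1
    return pd.DataFrame(cm, index=list(labels), columns=list(labels))


def classification_metrics(
    cm: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    truth: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest metrics per class, plus a macro-average row.

    ``scores`` (per-sample class probability columns) and the matching
    ``truth`` labels are required for AUC and mAP; without them those
    columns are NaN. Undefined ratios (zero support or zero predicted
    positives) are reported as NaN, never coerced to 0, and excluded
    from the macro averages.
    """
    labels = list(cm.index)
    n = int(cm.values.sum())
    rows = {}
    for lab in labels:
        tp = int(cm.loc[lab, lab])
        fn = int(cm.loc[lab].sum()) - tp
        fp = int(cm[lab].sum()) - tp
        tn = n - tp - fn - fp
        precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        accuracy = (tp + tn) / n if n > 0 else np.nan
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = np.nan
        else:
            f1 = 2 * precision * recall / (precision + recall)
        auc = ap = np.nan
        if scores is not None:
            if truth is None:
                raise InvalidArgumentError("truth labels are required with scores")
            y = np.asarray([1 if t == lab else 0 for t in truth])
            s = np.asarray(scores[lab], dtype=float)
            if 0 < y.sum() < len(y):
                auc = float(roc_auc_score(y, s))
                ap = float(average_precision_score(y, s))
        rows[lab] = {
            "precision": precision,
            "recall": recall,
            "accuracy": accuracy,
            "f1": f1,
            "auc": auc,
            "map": ap,
        }
    report = pd.DataFrame(rows).T
    report.loc["macro"] = report.mean(axis=0, skipna=True)
    return report


def pain_accuracy(pred_levels: Sequence[int], true_levels: Sequence[int]) -> float:
    """Percent of exact pain-level matches."""
    if len(pred_levels) != len(true_levels):
        raise InvalidArgumentError("prediction/truth length mismatch")
    if len(true_levels) == 0:
        raise InvalidArgumentError("empty input")
    hits = sum(1 for p, t in zip(pred_levels, true_levels) if int(p) == int(t))
    return 100.0 * hits / len(true_levels)


def compare_estimators(
    frames: list[SyntheticFrame],
    cfg: ZoneConfig,
    cal: CalibrationTable,
    W: AUWeightMatrix,
    table: EmotionWeightTable,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    pspi_cfg: PSPIConfig = PSPIConfig(),
    neutral_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-class exact-level accuracy of the four estimators.

    Columns: PLE (PSPI baseline), PLEw (PSPI × emotion weight), PLEz
    (zone-max score), PLEWz (zone-max × emotion weight). Rows: one per
    emotion class present, plus an ``average`` row (unweighted mean over
    classes, the headline comparison).
    """
    if not frames:
        raise InvalidArgumentError("empty dataset")
    records = []
    for f in frames:
        zi = compute_zone_intensities(f.neutral, f.active, cfg, cal)
        vec = reduce_to_vector(zi, mode="max")
        ps = zone_max_ple(zi)
        label, _dist = classify_au_vector(vec, W, neutral_threshold=neutral_threshold)
        pspi = pspi_ple(
            vec.get("AU4"), vec.get("AU6"), vec.get("AU7"),
            vec.get("AU9"), vec.get("AU10"), vec.get("AU43"),
            pspi_cfg,
        ) if cfg.has_pspi_zones else np.nan
        rec = {"class": f.true_emotion, "true_level": f.true_level}
        if not np.isnan(pspi):
            rec["PLE"] = bin_pain_level(pspi, thresholds)
            rec["PLEw"] = bin_pain_level(weighted_ple(pspi, label, table), thresholds)
        rec["PLEz"] = bin_pain_level(ps, thresholds)
        rec["PLEWz"] = bin_pain_level(weighted_ple(ps, label, table), thresholds)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    out = {}
    present = [c for c in ESTIMATORS if c in df.columns]
    for cls, grp in df.groupby("class", sort=False):
        out[cls] = {
            est: pain_accuracy(grp[est].tolist(), grp["true_level"].tolist())
            for est in present
        }
    tbl = pd.DataFrame(out).T
    tbl = tbl.reindex([e for e in EMOTIONS if e in tbl.index])
    tbl.loc["average"] = tbl.mean(axis=0)
    return tbl


def temporal_profile(
    series: list[tuple[float, CanonicalLandmarks, CanonicalLandmarks]],
    cfg: ZoneConfig,
    cal: CalibrationTable,
    W: AUWeightMatrix,
    table: EmotionWeightTable,
    mode: str = "hard",
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score a time-stamped sequence of frame pairs.

    Returns a DataFrame with columns ``t, emotion, ps, plew, level``
    suitable for plotting the raw versus emotion-weighted trajectories.
    """
    from .pain_score import compute_pain

    times = [t for t, _, _ in series]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InvalidArgumentError("timestamps must be strictly increasing")
    rows = []
    for t, neutral, active in series:
        score = compute_pain(neutral, active, cfg, cal, W, table, mode=mode,
                             thresholds=thresholds)
        rows.append(
            {"t": t, "emotion": score.emotion, "ps": score.ps,
             "plew": score.plew, "level": score.level}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------


def plot_confusion(cm: pd.DataFrame, path: str) -> None:
    """Save a confusion-matrix heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.values, cmap="Blues")
    ax.set_xticks(range(len(cm.columns)), cm.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.index)), cm.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm.values[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_temporal_profile(profile: pd.DataFrame, path: str) -> None:
    """Save raw vs emotion-weighted pain trajectories over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(profile["t"], profile["ps"], label="raw score", lw=1.5)
    ax.plot(profile["t"], profile["plew"], label="weighted score", lw=1.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pain score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
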