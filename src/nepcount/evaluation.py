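"""Scoring: Jaccard index, count metrics, track matching, contrast analyses.

Segmentation accuracy is measured by the Jaccard index J = |X∩Y| / |X∪Y|
between a predicted mask X and a ground-truth mask Y.  Counting accuracy is
measured per video by precision, recall and F-score over true-positive,
false-positive and false-negative track counts, where a split of one animal
into several automatic tracks counts the extras as false positives.  The
module also houses the background-contrast diagnostics: histogram distances
(chi-squared and Euclidean) between grayscale background histograms, and
the Euclidean / Mahalanobis separability of foreground and background RGB
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import ConfigError
from .synthetic import GroundTruth
from .tracking import Track

PAPER_SCALE_PIXELS = 1920 * 1440


@dataclass(frozen=True)
class JaccardScore:
    value: float
    intersection: int
    union: int


def jaccard(pred: np.ndarray, truth: np.ndarray) -> JaccardScore:
    """Jaccard index |X∩Y| / |X∪Y| of two binary masks.

    Two empty masks have no defined similarity under this protocol (there is
    no empty ground truth) and raise an error.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ConfigError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = int(np.logical_and(pred, truth).sum())
    union = int(np.logical_or(pred, truth).sum())
    if union == 0:
        raise ConfigError("Jaccard undefined: both masks empty")
    return JaccardScore(value=inter / union, intersection=inter, union=union)


@dataclass(frozen=True)
class EvalCounts:
    true_positive: int
    false_positive: int
    false_negative: int
    manual_count: int = 0
    automatic_count: int = 0

    def __post_init__(self) -> None:
        if min(self.true_positive, self.false_positive, self.false_negative) < 0:
            raise ConfigError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    fscore: float
    degenerate_precision: bool = False
    degenerate_recall: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
        }


def prf(counts: EvalCounts) -> MetricsReport:
    """Precision, recall and F-score from TP/FP/FN counts.

    0/0 ratios are reported as 0 with a degenerate flag; the F-score is the
    harmonic mean of precision and recall, or 0 when both vanish.
    """
    tp, fp, fn = counts.true_positive, counts.false_positive, counts.false_negative
    deg_p = tp + fp == 0
    deg_r = tp + fn == 0
    precision = 0.0 if deg_p else tp / (tp + fp)
    recall = 0.0 if deg_r else tp / (tp + fn)
    fscore = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(
        precision=precision,
        recall=recall,
        fscore=fscore,
        degenerate_precision=deg_p,
        degenerate_recall=deg_r,
    )


def mean_fscore(reports: list[MetricsReport] | list[float], rounding: int | None = 2) -> float:
    """Unweighted mean of per-video F-scores.

    With ``rounding`` set, each F-score is first rounded to that many
    decimals before averaging — the aggregation convention of summary tables
    that print per-video values at two decimals.  ``rounding=None`` averages
    the raw values.
    """
    if not reports:
        raise ConfigError("cannot average an empty list of reports")
    values = [r.fscore if isinstance(r, MetricsReport) else float(r) for r in reports]
    if rounding is not None:
        values = [round(v, rounding) for v in values]
    return float(np.mean(values))


@dataclass
class TrackMatchResult:
    counts: EvalCounts
    matches: dict[int, list[int]] = field(default_factory=dict)  # gt id -> auto ids


def count_eval(
    gt: GroundTruth,
    auto_tracks: list[Track],
    frame_shape: tuple[int, int],
    gate_px: float = 50.0,
) -> TrackMatchResult:
    """Match automatic tracks to ground-truth trajectories and count errors.

    An automatic track matches a ground-truth trajectory when, over the
    frames both exist, the track centroid lies within the gate for at least
    half of them.  Each matched ground-truth trajectory is one true
    positive; additional automatic tracks on the same trajectory are false
    positives (one animal detected as several); automatic tracks matching
    nothing are false positives; unmatched trajectories are false negatives.
    The 50-px gate is defined at 1920x1440 and scales with the linear frame
    size.
    """
    scale = math.sqrt((frame_shape[0] * frame_shape[1]) / PAPER_SCALE_PIXELS)
    gate = gate_px * scale

    gt_by_frame: dict[int, dict[int, tuple[float, float]]] = {}
    for gid, traj in gt.trajectories.items():
        for f, cx, cy in traj:
            gt_by_frame.setdefault(gid, {})[f] = (cx, cy)

    matches: dict[int, list[int]] = {gid: [] for gid in gt.trajectories}
    unmatched_auto = 0
    for t in auto_tracks:
        best_gid, best_frac = None, 0.0
        for gid, frames in gt_by_frame.items():
            overlap = [(f, x, y) for f, x, y in t.history if f in frames]
            if not overlap:
                continue
            hits = sum(
                1
                for f, x, y in overlap
                if math.hypot(x - frames[f][0], y - frames[f][1]) <= gate
            )
            frac = hits / len(overlap)
            if frac > best_frac:
                best_gid, best_frac = gid, frac
        if best_gid is not None and best_frac >= 0.5:
            matches[best_gid].append(t.id)
        else:
            unmatched_auto += 1

    tp = sum(1 for ids in matches.values() if ids)
    fp = unmatched_auto + sum(max(0, len(ids) - 1) for ids in matches.values())
    fn = sum(1 for ids in matches.values() if not ids)
    counts = EvalCounts(
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        manual_count=gt.total_count,
        automatic_count=len(auto_tracks),
    )
    return TrackMatchResult(counts=counts, matches=matches)


def hist_distance(h1: np.ndarray, h2: np.ndarray, metric: str = "chi_squared") -> float:
    """Distance between two normalized intensity histograms.

    chi-squared uses the symmetric form ½ Σ (h1−h2)²/(h1+h2) over bins with
    mass; euclidean is the plain L2 norm of the difference.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ConfigError(f"histogram bin counts differ: {h1.shape} vs {h2.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(h1 - h2))
    if metric == "chi_squared":
        denom = h1 + h2
        nz = denom > 0
        return float(0.5 * np.sum((h1[nz] - h2[nz]) ** 2 / denom[nz]))
    raise ConfigError(f"unknown histogram metric {metric!r}")


def gray_histogram(gray: np.ndarray, bins: int = 256) -> np.ndarray:
    """Normalized intensity histogram of a unit-scale grayscale image."""
    hist, _ = np.histogram(np.asarray(gray).ravel(), bins=bins, range=(0.0, 1.0))
    return hist / hist.sum()


def fg_bg_separability(
    frame: np.ndarray,
    mask: np.ndarray,
    metric: str = "euclidean",
    ridge: float = 1e-6,
) -> float:
    """Distance between foreground and background mean colors.

    ``euclidean`` is the plain distance between the FG and BG mean RGB
    vectors; ``mahalanobis`` uses the pooled within-class covariance
    (regularized with a small ridge if singular).
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ConfigError("mask must contain both foreground and background pixels")
    fg = frame[mask].reshape(-1, 3)
    bg = frame[~mask].reshape(-1, 3)
    delta = fg.mean(axis=0) - bg.mean(axis=0)
    if metric == "euclidean":
        return float(np.linalg.norm(delta))
    if metric == "mahalanobis":
        n_fg, n_bg = len(fg), len(bg)
        cov_fg = np.cov(fg, rowvar=False) if n_fg > 1 else np.zeros((3, 3))
        cov_bg = np.cov(bg, rowvar=False) if n_bg > 1 else np.zeros((3, 3))
        pooled = ((n_fg - 1) * cov_fg + (n_bg - 1) * cov_bg) / max(1, n_fg + n_bg - 2)
        try:
            inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError:
            inv = np.linalg.inv(pooled + ridge * np.eye(3))
        return float(np.sqrt(delta @ inv @ delta))
    raise ConfigError(f"unknown separability metric {metric!r}")


def crop_centered(
    image: np.ndarray,
    width: int = 2500,
    height: int = 1500,
    center: tuple[int, int] | None = None,
) -> tuple[np.ndarray, bool]:
    """Axis-aligned crop around a center point, clamped to the image.

    Returns the crop and a flag set when the requested window had to be
    clamped at an image border.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    cx, cy = center if center is not None else (w // 2, h // 2)
    x0 = cx - width // 2
    y0 = cy - height // 2
    clamped = x0 < 0 or y0 < 0 or x0 + width > w or y0 + height > h
    x0 = min(max(0, x0), max(0, w - width))
    y0 = min(max(0, y0), max(0, h - height))
    x1 = min(w, x0 + width)
    y1 = min(h, y0 + height)
    return image[y0:y1, x0:x1], clamped
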