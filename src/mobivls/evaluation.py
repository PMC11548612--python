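"""Detection scoring: centroid matching, curves and summary metrics.

A detection is a true positive when its centroid lies within 6 px
(Euclidean) of a ground-truth centroid; each detection and each
ground-truth instance can be matched at most once (greedy nearest-first
assignment). Fully occluded ground-truth instances carry no thermal
signature: they are excluded from the positive set, and a detection at
such a location counts as a false positive.

True negatives are bookkept as 12x12-pixel patches: a frame of W x H
pixels contributes floor(W/12)*floor(H/12) patches and
``tn = patches - tp - fp``. This makes the false-positive rate
denominator proportional to the number of frames.

Curves are produced by sweeping a global threshold over per-frame
saliency maps from one down to zero, extracting connected components at
each threshold and scoring them. The area under the ROC curve is taken
over a restricted linear FPR range (default 0 to 1e-4, where higher
false-alarm rates are impractical for survey work) and expressed as a
percentage of the maximum attainable area. The equal error rate is the
recall at the point of the recall vs (1-precision) curve where recall
and precision coincide.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .detector import saliency_to_detections
from .frames import DetectionRecord, GroundTruthRecord

__all__ = [
    "ConfusionCounts",
    "CurvePoint",
    "MetricsReport",
    "match_frame",
    "confusion_with_tn",
    "patches_per_frame",
    "sweep_thresholds",
    "auroc",
    "eer",
    "summary_metrics",
]

MATCH_RADIUS_PX = 6.0
TN_PATCH_PX = 12


@dataclasses.dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0


@dataclasses.dataclass(frozen=True)
class CurvePoint:
    threshold: float
    tpr: float
    fpr: float
    one_minus_precision: float
    counts: ConfusionCounts | None = None


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    recall: float
    precision: float
    f1: float
    auroc_pct: float
    eer_pct: float
    koala_count: int
    avg_kdet: float
    operating_fpr: float
    operating_threshold: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counts"] = dataclasses.asdict(self.counts)
        return d


def match_frame(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    radius: float = MATCH_RADIUS_PX,
) -> tuple[list[tuple[DetectionRecord, GroundTruthRecord]], ConfusionCounts]:
    """Greedy nearest-first matching of detections to ground truth.

    All records must share one frame id. Candidate pairs within ``radius``
    are assigned in ascending distance order (ties broken by detection
    order after sorting detections by confidence, descending). Returns the
    matched pairs and the confusion counts (tn left at zero).
    """
    frame_ids = {d.frame_id for d in dets} | {g.frame_id for g in gts}
    if len(frame_ids) > 1:
        raise ValueError(f"records span multiple frame ids: {sorted(frame_ids)}")
    positives = [g for g in gts if g.occlusion_state != "full"]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    candidates = []
    for rank, di in enumerate(order):
        d = dets[di]
        for gi, g in enumerate(positives):
            dist = float(np.hypot(d.x - g.x, d.y - g.y))
            if dist <= radius:
                candidates.append((dist, rank, di, gi))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_d: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for _, _, di, gi in candidates:
        if di in used_d or gi in used_g:
            continue
        used_d.add(di)
        used_g.add(gi)
        pairs.append((dets[di], positives[gi]))
    tp = len(pairs)
    return pairs, ConfusionCounts(tp=tp, fp=len(dets) - tp, fn=len(positives) - tp)


def patches_per_frame(width: int, height: int, patch: int = TN_PATCH_PX) -> int:
    """Number of true-negative bookkeeping patches tiling one frame."""
    return (width // patch) * (height // patch)


def confusion_with_tn(
    counts: ConfusionCounts, width: int, height: int, n_frames: int
) -> ConfusionCounts:
    """Fill in the patch-based true-negative count for a dataset."""
    total = n_frames * patches_per_frame(width, height)
    tn = max(total - counts.tp - counts.fp, 0)
    return ConfusionCounts(counts.tp, counts.fp, counts.fn, tn)


def _group_gts(gts: Iterable[GroundTruthRecord]) -> dict[str, list[GroundTruthRecord]]:
    by_frame: dict[str, list[GroundTruthRecord]] = {}
    for g in gts:
        by_frame.setdefault(g.frame_id, []).append(g)
    return by_frame


def _local_peak_values(saliency: np.ndarray) -> np.ndarray:
    """Values of 8-neighbourhood local maxima; each one is a threshold at
    which a new connected component appears during the sweep."""
    peaks = ndimage.maximum_filter(saliency, size=3, mode="constant", cval=-1.0)
    return np.unique(saliency[(saliency == peaks) & (saliency > 0)])


def _score_at_threshold(
    maps: Mapping[str, np.ndarray],
    gts_by_frame: Mapping[str, list[GroundTruthRecord]],
    threshold: float,
    radius: float,
    min_blob_area: int,
) -> ConfusionCounts:
    agg = ConfusionCounts()
    for fid, sal in maps.items():
        dets = saliency_to_detections(sal, threshold, frame_id=fid,
                                      min_blob_area=min_blob_area)
        _, c = match_frame(dets, gts_by_frame.get(fid, []), radius=radius)
        agg = agg + c
    shapes = {m.shape for m in maps.values()}
    h, w = shapes.pop()
    return confusion_with_tn(agg, w, h, n_frames=len(maps))


def sweep_thresholds(
    maps: Mapping[str, np.ndarray],
    gts: Sequence[GroundTruthRecord],
    n_steps: int = 2000,
    radius: float = MATCH_RADIUS_PX,
    min_blob_area: int = 1,
    peak_quantum: float = 1e-4,
) -> list[CurvePoint]:
    """Sweep a global threshold from one to zero over per-frame maps.

    Thresholds are ``n_steps`` uniform values plus the distinct local
    peak values of the maps, so each component-appearance event is
    sampled; peak thresholds are quantised to ``peak_quantum`` (the
    sweep's threshold resolution) to bound the number of points on
    cluttered maps. Points carry the raw counts at each threshold: note
    that with component-based detections the raw TPR/FPR need not be
    strictly monotone (nearby blobs merge as the threshold drops, which
    can turn a false positive into part of a matched component), so the
    monotone upper envelope is taken where required (AUROC).
    """
    if not any(g.occlusion_state != "full" for g in gts):
        raise ValueError("no non-occluded ground truth; recall is undefined")
    if len({m.shape for m in maps.values()}) > 1:
        raise ValueError("all saliency maps must share a shape")
    gts_by_frame = _group_gts(gts)
    thresholds = set(np.linspace(1.0, 0.0, n_steps))
    all_peaks = [_local_peak_values(sal) for sal in maps.values()]
    top = max((p.max() for p in all_peaks if p.size), default=1.0)
    for peaks in all_peaks:
        # sample just below each peak so the peak's component is present;
        # quantisation is relative to the largest peak so sparse maps on
        # an absolute response scale are still finely resolved
        if peak_quantum > 0 and top > 0:
            q = peak_quantum * top
            peaks = np.unique(np.floor(peaks / q) * q)
        else:
            peaks = peaks - 1e-9
        thresholds.update(np.maximum(peaks, 0.0))
    points: list[CurvePoint] = []
    for t in sorted(thresholds, reverse=True):
        c = _score_at_threshold(maps, gts_by_frame, t, radius, min_blob_area)
        points.append(CurvePoint(threshold=float(t), tpr=c.recall, fpr=c.fpr,
                                 one_minus_precision=1.0 - c.precision, counts=c))
    return points


def auroc(curve: Sequence[CurvePoint], fpr_max: float = 1e-4) -> float:
    """Percentage area under the ROC over a restricted linear FPR range.

    Trapezoidal area of TPR over FPR in [0, fpr_max], divided by fpr_max
    and scaled to percent; an ideal detector scores 100. If the curve
    never reaches ``fpr_max`` the last TPR is extended (flagged by a
    warning).
    """
    fpr = np.array([p.fpr for p in curve])
    tpr = np.array([p.tpr for p in curve])
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    tpr = np.maximum.accumulate(tpr)  # monotone upper envelope
    if fpr[0] > 0.0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[tpr[0]], tpr])
    if fpr[-1] < fpr_max:
        warnings.warn("curve does not reach fpr_max; extending last TPR",
                      stacklevel=2)
        fpr = np.concatenate([fpr, [fpr_max]])
        tpr = np.concatenate([tpr, [tpr[-1]]])
    keep = fpr <= fpr_max
    fpr_c = np.concatenate([fpr[keep], [fpr_max]])
    tpr_c = np.concatenate([tpr[keep], [np.interp(fpr_max, fpr, tpr)]])
    area = np.trapezoid(tpr_c, fpr_c)
    return float(area / fpr_max * 100.0)


def eer(curve: Sequence[CurvePoint]) -> float:
    """Equal error rate: recall (percent) where recall equals precision.

    Linear interpolation between sweep points; if the curves never cross,
    the nearest point is reported with a warning.
    """
    recall = np.array([p.tpr for p in curve])
    precision = 1.0 - np.array([p.one_minus_precision for p in curve])
    diff = recall - precision
    exact = np.flatnonzero(diff == 0.0)
    # prefer an exact coincidence with the largest recall
    if exact.size and recall[exact].max() > 0:
        return float(recall[exact].max() * 100.0)
    sign_change = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
    if sign_change.size == 0:
        warnings.warn("recall/precision curves never cross; reporting nearest point",
                      stacklevel=2)
        i = int(np.argmin(np.abs(diff)))
        return float(recall[i] * 100.0)
    i = int(sign_change[0])
    alpha = diff[i] / (diff[i] - diff[i + 1])
    return float((recall[i] + alpha * (recall[i + 1] - recall[i])) * 100.0)


def _operating_point(curve: Sequence[CurvePoint], operating_fpr: float) -> CurvePoint:
    """Largest FPR not exceeding the operating FPR; recall breaks ties
    (component merging can park many thresholds at the same FPR)."""
    eligible = [p for p in curve if p.fpr <= operating_fpr]
    if not eligible:
        return min(curve, key=lambda p: (p.fpr, -p.tpr))
    return max(eligible, key=lambda p: (p.fpr, p.tpr))


def summary_metrics(
    maps: Mapping[str, np.ndarray],
    gts: Sequence[GroundTruthRecord],
    operating_fpr: float = 1e-5,
    n_steps: int = 2000,
    radius: float = MATCH_RADIUS_PX,
    min_blob_area: int = 1,
    curve: Sequence[CurvePoint] | None = None,
) -> MetricsReport:
    """Full report at the sweep threshold whose FPR is the largest not
    exceeding ``operating_fpr``.

    ``koala_count`` is the number of unique animals with at least one true
    positive; ``avg_kdet`` (percent) is the mean over unique animals of
    (frames with a TP for that animal) / (frames where it is present and
    not fully occluded).
    """
    if curve is None:
        curve = sweep_thresholds(maps, gts, n_steps=n_steps, radius=radius,
                                 min_blob_area=min_blob_area)
    point = _operating_point(curve, operating_fpr)
    gts_by_frame = _group_gts(gts)

    present: dict[str, int] = {}
    detected: dict[str, int] = {}
    for fid, sal in maps.items():
        frame_gts = gts_by_frame.get(fid, [])
        for g in frame_gts:
            if g.occlusion_state != "full":
                present[g.koala_id] = present.get(g.koala_id, 0) + 1
        dets = saliency_to_detections(sal, point.threshold, frame_id=fid,
                                      min_blob_area=min_blob_area)
        pairs, _ = match_frame(dets, frame_gts, radius=radius)
        for _, g in pairs:
            detected[g.koala_id] = detected.get(g.koala_id, 0) + 1

    ratios = [detected.get(k, 0) / n for k, n in present.items() if n > 0]
    avg_kdet = 100.0 * float(np.mean(ratios)) if ratios else 0.0
    counts = point.counts if point.counts is not None else ConfusionCounts()
    return MetricsReport(
        recall=counts.recall,
        precision=counts.precision,
        f1=counts.f1,
        auroc_pct=auroc(curve),
        eer_pct=eer(curve),
        koala_count=len(detected),
        avg_kdet=avg_kdet,
        operating_fpr=point.fpr,
        operating_threshold=point.threshold,
        counts=counts,
    )
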