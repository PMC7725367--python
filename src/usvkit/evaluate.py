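"""Detector evaluation: frame-level confusion, ROC/AUC, element matching.

Event detection has no natural "negative event", so false-positive rates
are computed at the frame level: each spectrogram frame is positive iff its
center time falls inside a ground-truth (or detected) element.  The ROC is
swept over the element quality score (9 down to 0): at cutoff q only frames
of elements scoring >= q count as detected.  Element-level error counts use
greedy one-to-one matching by temporal intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Element

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "frame_labels",
    "confusion",
    "roc_from_scores",
    "auc",
    "match_elements",
    "benchmark_detector",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        if pos == 0:
            raise ValueError("TPR undefined: no positive truth frames")
        return self.tp / pos

    @property
    def fpr(self) -> float:
        neg = self.fp + self.tn
        if neg == 0:
            raise ValueError("FPR undefined: no negative truth frames")
        return self.fp / neg


@dataclass(frozen=True)
class RocCurve:
    """(fpr, tpr) operating points with their score cutoffs, anchored at
    (0,0) and (1,1), sorted by fpr then tpr."""

    points: np.ndarray  # (n, 2) columns fpr, tpr
    thresholds: np.ndarray


def frame_labels(
    elements: list[Element], n_frames: int, hop_s: float, t0_s: float = 0.0
) -> np.ndarray:
    """Boolean per frame: positive iff the frame center lies inside any
    element's half-open [start, end)."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    centers = t0_s + np.arange(n_frames) * hop_s
    mask = np.zeros(n_frames, dtype=bool)
    for e in elements:
        mask |= (centers >= e.start_s) & (centers < e.end_s)
    return mask


def confusion(detected: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError("detected and truth frame vectors differ in length")
    return ConfusionCounts(
        tp=int((detected & truth).sum()),
        fp=int((detected & ~truth).sum()),
        fn=int((~detected & truth).sum()),
        tn=int((~detected & ~truth).sum()),
    )


def roc_from_scores(
    elements: list[Element],
    truth: np.ndarray,
    n_frames: int,
    hop_s: float,
    t0_s: float = 0.0,
) -> RocCurve:
    """ROC over quality cutoffs 9..0, frame-level, anchored at (0,0)/(1,1)."""
    truth = np.asarray(truth, dtype=bool)
    if not truth.any() or truth.all():
        raise ValueError("ROC needs both positive and negative truth frames")
    pts = [(0.0, 0.0)]
    thresholds = [np.inf]
    for cutoff in range(9, -1, -1):
        surviving = [e for e in elements if e.quality >= cutoff]
        det = frame_labels(surviving, n_frames, hop_s, t0_s)
        c = confusion(det, truth)
        pts.append((c.fpr, c.tpr))
        thresholds.append(float(cutoff))
    pts.append((1.0, 1.0))
    thresholds.append(-np.inf)
    order = np.lexsort((np.array(pts)[:, 1], np.array(pts)[:, 0]))
    return RocCurve(
        points=np.array(pts)[order], thresholds=np.array(thresholds)[order]
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC over fpr."""
    fpr, tpr = curve.points[:, 0], curve.points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def _iou(a: Element, b: Element) -> float:
    inter = max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))
    union = (a.end_s - a.start_s) + (b.end_s - b.start_s) - inter
    return inter / union if union > 0 else 0.0


def match_elements(
    detected: list[Element], truth: list[Element], iou_min: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one matching by temporal IoU >= iou_min, largest
    overlap first.  Returns (n_tp, n_fp, n_fn)."""
    pairs = []
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            iou = _iou(d, t)
            if iou >= iou_min:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda p: -p[0])
    used_d: set[int] = set()
    used_t: set[int] = set()
    n_tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n_tp += 1
    return n_tp, len(detected) - n_tp, len(truth) - n_tp


def benchmark_detector(
    n_recordings: int = 20,
    n_calls: int = 8,
    snr_range: tuple[float, float] = (20.0, 30.0),
    dur_range_ms: tuple[float, float] = (15.0, 60.0),
    seed: int = 0,
) -> dict:
    """Run the default detector over seeded synthetic recordings and pool
    element-level recall/precision and the frame-level quality-sweep AUC.

    Calls are at least ``dur_range_ms[0]`` long and ``snr_range`` dB above
    the noise floor; one recording per derived seed.
    """
    from .detect import detect_file
    from .spectro import compute_spectrogram
    from .synth import random_recording

    rng = np.random.default_rng(seed)
    tp = fp = fn = 0
    pooled: dict[int, list[int]] = {c: [0, 0, 0, 0] for c in range(10)}
    for _ in range(n_recordings):
        rec_seed = int(rng.integers(0, 2**31 - 1))
        snr = float(rng.uniform(*snr_range))
        w, truth = random_recording(
            n_calls=n_calls, snr_db=snr, dur_range_ms=dur_range_ms, seed=rec_seed
        )
        elements = detect_file(w)
        a, b, c = match_elements(elements, truth)
        tp, fp, fn = tp + a, fp + b, fn + c
        s = compute_spectrogram(w)
        truth_frames = frame_labels(
            truth, s.n_frames, s.hop_s, t0_s=float(s.frame_times_s[0])
        )
        for cutoff in range(10):
            surviving = [e for e in elements if e.quality >= cutoff]
            det = frame_labels(
                surviving, s.n_frames, s.hop_s, t0_s=float(s.frame_times_s[0])
            )
            cc = confusion(det, truth_frames)
            acc = pooled[cutoff]
            acc[0] += cc.tp
            acc[1] += cc.fp
            acc[2] += cc.fn
            acc[3] += cc.tn
    pts = [(0.0, 0.0)]
    for cutoff in range(9, -1, -1):
        t, f, m, n = pooled[cutoff]
        pts.append((f / (f + n), t / (t + m)))
    pts.append((1.0, 1.0))
    arr = np.array(sorted(pts))
    curve = RocCurve(points=arr, thresholds=np.zeros(len(arr)))
    return {
        "recall": tp / (tp + fn),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "auc": auc(curve),
        "n_truth": tp + fn,
        "n_detected": tp + fp,
    }
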