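"""Detection extraction and DR / FA evaluation.

A location fires a detection when the post-inhibition response exceeds
a threshold theta and is a local maximum within a non-maximum-
suppression radius.  Detections are matched per frame to ground-truth
target positions by greedy nearest-first one-to-one assignment within a
5-pixel gate, and summarized by

    DR = true detections / actual targets,
    FA = false detections / number of images,

with DR-FA curves traced by sweeping theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Detection",
    "MatchResult",
    "DRFACurve",
    "extract_detections",
    "match_and_score",
    "dr_fa_curve",
    "dr_at_fa",
    "detections_to_frame",
]


class Detection(NamedTuple):
    frame: int
    x: int
    y: int
    score: float


class MatchResult(NamedTuple):
    """Per-sequence match counts; DR and FA follow directly."""

    true_detections: int
    false_detections: int
    n_actual: int
    n_images: int

    @property
    def dr(self) -> float:
        return self.true_detections / self.n_actual if self.n_actual else 0.0

    @property
    def fa(self) -> float:
        return self.false_detections / self.n_images if self.n_images else 0.0


@dataclass(frozen=True)
class DRFACurve:
    """Operating points swept over descending thresholds."""

    thresholds: np.ndarray
    DR: np.ndarray
    FA: np.ndarray


def _disk_footprint(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    return (xx**2 + yy**2) <= radius**2


def _candidate_peaks(D_w: np.ndarray, nms_radius: int):
    """All strictly positive local maxima within the NMS disk, per frame."""
    foot = _disk_footprint(nms_radius)[None, :, :]
    maxf = ndimage.maximum_filter(D_w, footprint=foot, mode="constant", cval=0.0)
    t, y, x = np.nonzero((D_w > 0) & (D_w >= maxf))
    return t, y, x, D_w[t, y, x]


def _resolve_ties(t, y, x, s, nms_radius: int):
    """Greedy suppression of equal-score peaks within the NMS radius.

    Two candidate peaks inside each other's disk necessarily have equal
    scores (each is a window maximum), so only ties need resolving: the
    smallest row-major index wins.
    """
    order = np.lexsort((x, y, -s, t))  # per frame: score desc, row-major
    keep = []
    r2 = nms_radius**2
    accepted: dict[int, list] = {}
    for i in order:
        acc = accepted.setdefault(int(t[i]), [])
        yi, xi = int(y[i]), int(x[i])
        if any((yi - ya) ** 2 + (xi - xa) ** 2 <= r2 for ya, xa in acc):
            continue
        acc.append((yi, xi))
        keep.append(i)
    keep.sort()
    return keep


def extract_detections(
    D_w: np.ndarray, theta: float, nms_radius: int = 5
) -> list[Detection]:
    """Threshold + non-maximum suppression on a response volume.

    Per frame, voxels greater than theta that are local maxima within
    ``nms_radius`` (Euclidean) survive; among equal-valued peaks within
    the radius the smallest row-major index wins.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    t, y, x, s = _candidate_peaks(np.asarray(D_w, dtype=np.float64), nms_radius)
    sel = s > theta
    t, y, x, s = t[sel], y[sel], x[sel], s[sel]
    keep = _resolve_ties(t, y, x, s, nms_radius)
    return [
        Detection(int(t[i]), int(x[i]), int(y[i]), float(s[i])) for i in keep
    ]


def detections_to_frame(dets: list[Detection]) -> pd.DataFrame:
    return pd.DataFrame(dets, columns=["frame", "x", "y", "score"])


def _truth_points(truth: np.ndarray, frame: int):
    pts = truth[frame]
    ok = ~np.isnan(pts).any(axis=1)
    return pts[ok]


def match_and_score(
    dets: list[Detection],
    truth: np.ndarray,
    dist_threshold: float = 5.0,
    n_images: int | None = None,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within the distance gate.

    ``truth`` has shape (n_frames, n_targets, 2) holding (x, y) centers
    (NaN rows mean no target that frame).  A detection within
    ``dist_threshold`` (Euclidean, default the conventional 5 px) of an
    unmatched truth counts as a true detection; everything else is a
    false detection.  Each truth instance matches at most once.
    """
    truth = np.asarray(truth, dtype=np.float64)
    T = truth.shape[0] if n_images is None else n_images
    by_frame: dict[int, list] = {}
    for i, d in enumerate(dets):
        by_frame.setdefault(d.frame, []).append(i)

    n_true = 0
    n_actual = 0
    for f in range(truth.shape[0]):
        pts = _truth_points(truth, f)
        n_actual += len(pts)
        idxs = by_frame.get(f, [])
        if not len(pts) or not idxs:
            continue
        pairs = []
        for j, i in enumerate(idxs):
            d = dets[i]
            for k, (tx, ty) in enumerate(pts):
                dist = float(np.hypot(d.x - tx, d.y - ty))
                if dist <= dist_threshold:
                    pairs.append((dist, j, k))
        pairs.sort()
        used_d, used_t = set(), set()
        for dist, j, k in pairs:
            if j in used_d or k in used_t:
                continue
            used_d.add(j)
            used_t.add(k)
            n_true += 1
    n_false = len(dets) - n_true
    return MatchResult(n_true, n_false, n_actual, T)


def dr_fa_curve(
    D_w: np.ndarray,
    truth: np.ndarray,
    n_thresholds: int = 25,
    nms_radius: int = 5,
    dist_threshold: float = 5.0,
) -> DRFACurve:
    """Sweep theta over descending quantiles of the positive peak scores."""
    vol = np.asarray(D_w, dtype=np.float64)
    t, y, x, s = _candidate_peaks(vol, nms_radius)
    keep = _resolve_ties(t, y, x, s, nms_radius)
    t, y, x, s = t[keep], y[keep], x[keep], s[keep]
    if s.size == 0:
        thr = np.array([0.0])
    else:
        qs = np.linspace(1.0, 0.0, n_thresholds)
        thr = np.unique(np.quantile(s, qs))[::-1]
        thr = np.concatenate(([s.max() * (1 + 1e-9)], thr * (1 - 1e-12)))
    n_images = vol.shape[0]
    DRs, FAs = [], []
    for theta in thr:
        sel = s > theta
        dets = [
            Detection(int(tf), int(xf), int(yf), float(sf))
            for tf, xf, yf, sf in zip(t[sel], x[sel], y[sel], s[sel])
        ]
        m = match_and_score(dets, truth, dist_threshold, n_images=n_images)
        DRs.append(m.dr)
        FAs.append(m.fa)
    return DRFACurve(
        thresholds=np.asarray(thr), DR=np.asarray(DRs), FA=np.asarray(FAs)
    )


def dr_at_fa(curve: DRFACurve, fa_level: float) -> float:
    """DR linearly interpolated at the requested FA, clamped to the curve."""
    if curve.FA.size == 0:
        raise ValueError("empty curve")
    order = np.argsort(curve.FA, kind="stable")
    fa = curve.FA[order]
    dr = curve.DR[order]
    return float(np.interp(fa_level, fa, dr))
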