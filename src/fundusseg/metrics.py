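"""Evaluation metrics for optic disc / optic cup segmentation.

Confusion-count metrics (F1, precision, recall, specificity, sensitivity,
accuracy), the radial boundary localisation error (BLE) sampled along
equidistant directions from the disc centre, and the vertical cup-to-disc
ratio (CDR).

Label convention: 0 background, 1 optic disc, 2 optic cup.  The cup is
anatomically part of the disc, so the disc's positive class is {1, 2} while
the cup's is {2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "RadialBoundary",
    "confusion_counts",
    "f1_score",
    "precision_recall",
    "rate_metrics",
    "radial_boundary",
    "ble",
    "vertical_cdr",
    "evaluate_masks",
    "summarize_reports",
]

VALID_LABELS = frozenset({0, 1, 2})
_POSITIVE = {"OD": (1, 2), "OC": (2,)}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary decision (positive = structure present)."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class RadialBoundary:
    """Outermost structure radius along each of N equidistant directions."""

    center: tuple
    distances: np.ndarray
    empty: bool = False


def _check_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    bad = set(np.unique(arr)) - VALID_LABELS
    if bad:
        raise ValueError(f"mask contains labels outside {{0,1,2}}: "
                         f"{sorted(bad)}")
    return arr


def _positive(mask: np.ndarray, structure: str) -> np.ndarray:
    if structure not in _POSITIVE:
        raise ValueError(f"structure must be 'OD' or 'OC', got {structure!r}")
    return np.isin(mask, _POSITIVE[structure])


def confusion_counts(pred_mask, gt_mask, structure: str) -> ConfusionCounts:
    """Pixel-wise confusion tallies for one structure (OD or OC)."""
    pred = _check_mask(pred_mask)
    gt = _check_mask(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = _positive(pred, structure)
    g = _positive(gt, structure)
    return ConfusionCounts(TP=int(np.sum(p & g)), FP=int(np.sum(p & ~g)),
                           TN=int(np.sum(~p & ~g)), FN=int(np.sum(~p & g)))


def precision_recall(c: ConfusionCounts) -> tuple:
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    return precision, recall


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2 P R / (P + R); every 0/0 degenerate case returns 0."""
    precision, recall = precision_recall(c)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def rate_metrics(c: ConfusionCounts) -> tuple:
    """(SPC, SEN, ACC): specificity TN/N, sensitivity TP/P and the
    prevalence-weighted accuracy SPC*N/(P+N) + SEN*P/(P+N), which equals
    (TP+TN)/(P+N).  An undefined rate (P=0 or N=0) is reported as NaN."""
    spc = c.TN / c.N if c.N else float("nan")
    sen = c.TP / c.P if c.P else float("nan")
    total = c.P + c.N
    acc = (c.TP + c.TN) / total if total else float("nan")
    return spc, sen, acc


def radial_boundary(mask, structure: str, center, n_dirs: int = 24,
                    step: float = 0.5) -> RadialBoundary:
    """Distance from ``center`` to the outermost positive pixel along each of
    ``n_dirs`` equidistant directions (ray marching with the given step)."""
    arr = _check_mask(mask)
    h, w = arr.shape
    cx, cy = center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"centre {center} outside mask bounds {h}x{w}")
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    pos = _positive(arr, structure)
    if not pos.any():
        return RadialBoundary(center=tuple(center),
                              distances=np.zeros(n_dirs), empty=True)
    t_max = float(np.hypot(h, w))
    ts = np.arange(0.0, t_max + step, step)
    thetas = 2.0 * np.pi * np.arange(n_dirs) / n_dirs
    distances = np.zeros(n_dirs)
    for k, theta in enumerate(thetas):
        # nearest-pixel sampling; exact half-pixel ties resolve downward so
        # a structure edge lying on a pixel boundary is not overshot
        xs = np.ceil(cx + ts * np.cos(theta) - 0.5).astype(int)
        ys = np.ceil(cy + ts * np.sin(theta) - 0.5).astype(int)
        valid = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        hit = np.zeros(ts.shape, dtype=bool)
        hit[valid] = pos[ys[valid], xs[valid]]
        if hit.any():
            distances[k] = ts[np.nonzero(hit)[0][-1]]
    return RadialBoundary(center=tuple(center), distances=distances,
                          empty=False)


def ble(pred_mask, gt_mask, structure: str, center, n_dirs: int = 24,
        printed_radicand: bool = False) -> float:
    """Boundary localisation error in pixels: the mean over ``n_dirs``
    equidistant directions of |d_g - d_0|, where d_g and d_0 are the radial
    boundary distances of ground truth and prediction from the disc centre.

    ``printed_radicand=True`` switches to mean sqrt(d_g^2 - d_0^2) and raises
    on a negative radicand (that form is not a distance and is imaginary
    whenever the prediction overshoots; it exists for comparison only).
    """
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("pred/gt shape mismatch")
    bg = radial_boundary(gt, structure, center, n_dirs)
    bp = radial_boundary(pred, structure, center, n_dirs)
    if bg.empty or bp.empty:
        warnings.warn(f"structure {structure} missing from a mask; BLE "
                      "degenerates to the mean ground-truth radius")
        return float(np.mean(np.abs(bg.distances - bp.distances)))
    if printed_radicand:
        radicand = bg.distances ** 2 - bp.distances ** 2
        if np.any(radicand < 0):
            raise ValueError("negative radicand in the printed-form BLE; "
                             "use the default absolute-difference form")
        return float(np.mean(np.sqrt(radicand)))
    return float(np.mean(np.abs(bg.distances - bp.distances)))


def vertical_cdr(mask) -> float:
    """Vertical cup-to-disc ratio: vertical extent (rows) of cup pixels over
    vertical extent of disc pixels (labels {1, 2}).  Returns 0 when the cup
    is absent and NaN (with a warning) when the disc is absent."""
    arr = _check_mask(mask)
    disc_rows = np.nonzero((arr == 1) | (arr == 2))[0]
    if disc_rows.size == 0:
        warnings.warn("disc absent from mask; CDR undefined")
        return float("nan")
    cup_rows = np.nonzero(arr == 2)[0]
    if cup_rows.size == 0:
        return 0.0
    vcd = cup_rows.max() - cup_rows.min() + 1
    vdd = disc_rows.max() - disc_rows.min() + 1
    return float(vcd / vdd)


def evaluate_masks(pred_mask, gt_mask, center=None, n_dirs: int = 24) -> dict:
    """Full per-image report: F1 / ACC / SPC / SEN / BLE per structure + CDR.

    ``center`` defaults to the ground-truth disc centroid.
    """
    gt = _check_mask(gt_mask)
    if center is None:
        ys, xs = np.nonzero(gt >= 1)
        if ys.size == 0:
            raise ValueError("ground truth contains no disc; supply a centre")
        center = (float(xs.mean()), float(ys.mean()))
    row = {}
    for structure in ("OD", "OC"):
        c = confusion_counts(pred_mask, gt_mask, structure)
        spc, sen, acc = rate_metrics(c)
        row[f"F1_{structure}"] = f1_score(c)
        row[f"ACC_{structure}"] = acc
        row[f"SPC_{structure}"] = spc
        row[f"SEN_{structure}"] = sen
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row[f"BLE_{structure}"] = ble(pred_mask, gt_mask, structure,
                                          center, n_dirs)
    row["CDR_pred"] = vertical_cdr(pred_mask) if (np.asarray(pred_mask) >= 1).any() else float("nan")
    row["CDR_gt"] = vertical_cdr(gt_mask)
    return row


def summarize_reports(rows):
    """Stack per-image rows into a DataFrame and compute the mean/std summary
    (the usual "metric (mean/std)" table convention).  Returns
    ``(per_image, summary)`` where summary has rows "mean" and "std"."""
    frame = pd.DataFrame(list(rows))
    numeric = frame.select_dtypes(include=[np.number])
    summary = pd.DataFrame({col: {"mean": numeric[col].mean(),
                                  "std": numeric[col].std(ddof=0)}
                            for col in numeric.columns})
    return frame, summary
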