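"""Overlap and boundary metrics for binary segmentation.

The soft Dice loss drives training; the (hard) Dice score and the symmetric
Hausdorff distance evaluate predictions, aggregated per patient by stacking
the predicted slices into a 3D volume. Conventions:

* Dice between two empty masks is defined as 1 (and flagged); one empty
  mask gives 0.
* Hausdorff is undefined when either mask is empty and raises
  :class:`UndefinedMetricError` (callers record it, never silently skip).
* Distances are in voxel units unless a physical ``spacing`` is given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given masks (e.g. empty mask)."""


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} grid with optional per-axis physical spacing."""

    grid: np.ndarray
    spacing: tuple | None = None

    def __post_init__(self):
        g = np.asarray(self.grid)
        if not np.isin(g, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        object.__setattr__(self, "grid", g.astype(np.uint8))
        sp = self.spacing
        if sp is None:
            sp = (1.0,) * g.ndim
        sp = tuple(float(s) for s in np.atleast_1d(sp))
        if len(sp) != g.ndim:
            raise ValueError("spacing length must match mask dimensionality")
        object.__setattr__(self, "spacing", sp)


@dataclass
class MetricReport:
    patient_id: str
    dice: float
    hausdorff: float          # NaN when undefined
    slice_count: int
    hausdorff_defined: bool = True
    both_empty: bool = False


def _as_mask(m, spacing=None) -> BinaryMask:
    return m if isinstance(m, BinaryMask) else BinaryMask(m, spacing)


def soft_dice_loss(pred, target, epsilon: float = 1e-6) -> float:
    """1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps), over the batch."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def soft_dice_score(pred, target, epsilon: float = 1e-6) -> float:
    """The complementary overlap score; loss + score == 1 by construction."""
    return 1.0 - soft_dice_loss(pred, target, epsilon)


def soft_dice_loss_grad(pred, target, epsilon: float = 1e-6) -> np.ndarray:
    """d(soft_dice_loss)/d(pred), same shape as ``pred``."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    num = 2.0 * float((p * t).sum()) + epsilon
    den = float(p.sum() + t.sum()) + epsilon
    return (num - 2.0 * t * den) / (den * den)


def dice_score(pred, target) -> float:
    """Hard Dice 2|A n B| / (|A| + |B|); 1 when both masks are empty."""
    a = _as_mask(pred).grid
    b = _as_mask(target).grid
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (sa + sb)


def _directed_distances(src, dst):
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return d


def hausdorff_distance(mask_a, mask_b, percentile: float | None = None,
                       spacing=None) -> float:
    """Symmetric Hausdorff distance between two binary masks.

    ``percentile`` (e.g. 95) replaces the max of each directed distance
    distribution by that percentile; the default is the classical maximum.
    Coordinates are scaled by the masks' physical spacing.
    """
    a = _as_mask(mask_a, spacing)
    b = _as_mask(mask_b, spacing)
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    pa = np.argwhere(a.grid) * np.asarray(a.spacing)
    pb = np.argwhere(b.grid) * np.asarray(b.spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise UndefinedMetricError(
            "Hausdorff distance is undefined for an empty mask")
    dab = _directed_distances(pa, pb)
    dba = _directed_distances(pb, pa)
    if percentile is None:
        return float(max(dab.max(), dba.max()))
    return float(max(np.percentile(dab, percentile),
                     np.percentile(dba, percentile)))


def per_patient_metrics(predictions, volume, threshold: float = 0.5,
                        percentile: float | None = None) -> MetricReport:
    """Binarize per-slice probabilities, stack to 3D, evaluate per patient.

    ``predictions`` is a sequence of 2D probability grids, one per slice of
    ``volume`` (a PatientVolume or any object with patient_id, labels and
    spacing attributes), in acquisition order.
    """
    labels = np.asarray(volume.labels)
    preds = [np.asarray(p) for p in predictions]
    if len(preds) != labels.shape[0]:
        raise ValueError(
            f"{len(preds)} predictions for {labels.shape[0]} slices")
    pred_vol = np.stack([(p >= threshold).astype(np.uint8) for p in preds])
    true_vol = (labels > 0).astype(np.uint8)
    if pred_vol.shape != true_vol.shape:
        raise ValueError(
            f"shape mismatch: {pred_vol.shape} vs {true_vol.shape}")
    spacing = tuple(getattr(volume, "spacing", None) or
                    (1.0,) * true_vol.ndim)
    dice = dice_score(pred_vol, true_vol)
    both_empty = pred_vol.sum() == 0 and true_vol.sum() == 0
    try:
        hd = hausdorff_distance(pred_vol, true_vol, percentile=percentile,
                                spacing=spacing)
        defined = True
    except UndefinedMetricError:
        hd, defined = float("nan"), False
    return MetricReport(patient_id=str(volume.patient_id), dice=dice,
                        hausdorff=hd, slice_count=int(true_vol.shape[0]),
                        hausdorff_defined=defined, both_empty=bool(both_empty))


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id, "dice": r.dice, "hausdorff": r.hausdorff,
        "slice_count": r.slice_count,
        "hausdorff_defined": r.hausdorff_defined,
    } for r in reports])


def write_reports(reports, csv_path, json_path=None):
    """One CSV row per patient plus an optional mean +/- sd JSON summary."""
    frame = reports_to_frame(reports)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        defined = frame[frame.hausdorff_defined]
        summary = {
            "n_patients": int(len(frame)),
            "dice_mean": float(frame.dice.mean()),
            "dice_sd": float(frame.dice.std(ddof=1)) if len(frame) > 1 else 0.0,
            "hausdorff_mean": (float(defined.hausdorff.mean())
                               if len(defined) else None),
            "hausdorff_sd": (float(defined.hausdorff.std(ddof=1))
                             if len(defined) > 1 else None),
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return frame
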