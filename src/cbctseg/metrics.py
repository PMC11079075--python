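"""3-D segmentation evaluation: Dice, mIoU, Hausdorff and average surface
distance, with per-class, per-FDI-tooth and mean +/- std aggregation.

Distance metrics operate on mask *surfaces*: a surface voxel is a mask voxel
with at least one six-connected background neighbour (the grid boundary
counts as background).  Distances are Euclidean between surface-voxel
centers in physical mm, honouring anisotropic spacing.  The Hausdorff
distance is the exact maximum over both directed distances (a 95th-percentile
variant is available but off by default); the average surface distance is
symmetrized by pooling the nearest-surface distances from both directions.

Per-class conventions:

* class absent from both prediction and truth — "vacuous": Dice reported as
  1 but flagged and excluded from aggregates;
* class absent from exactly one side — Dice and IoU 0, distances undefined
  (``None``, flagged);
* mIoU averages over foreground classes only (background excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import CbctError, LabelVolume, STRUCTURE_NAMES

__all__ = [
    "ClassMetrics",
    "MetricReport",
    "dice_score",
    "iou_score",
    "miou",
    "extract_surface",
    "surface_distances",
    "hausdorff_distance",
    "average_surface_distance",
    "fdi_to_position",
    "evaluate_case",
    "aggregate_reports",
    "TOOTH_POSITIONS",
]

#: Tooth position groups, quadrants merged: T1 central incisor ... T8 third molar.
TOOTH_POSITIONS = tuple(f"T{p}" for p in range(1, 9))

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _masks(pred: LabelVolume, gt: LabelVolume, class_id: int):
    pred.require_same_grid(gt)
    return pred.values == class_id, gt.values == class_id


def dice_score(
    pred: LabelVolume, gt: LabelVolume, class_id: int, return_flag: bool = False
):
    """Dice similarity coefficient ``2|A&B| / (|A| + |B|)`` for one class.

    When the class is absent from both volumes the score is vacuously 1;
    ``return_flag=True`` additionally returns that vacuity flag.
    """
    a, b = _masks(pred, gt, class_id)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return (1.0, True) if return_flag else 1.0
    value = 2.0 * int(np.count_nonzero(a & b)) / (na + nb)
    return (value, False) if return_flag else value


def iou_score(pred: LabelVolume, gt: LabelVolume, class_id: int) -> float:
    """Intersection over union for one class (1.0 if absent from both)."""
    a, b = _masks(pred, gt, class_id)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def miou(pred: LabelVolume, gt: LabelVolume, class_list) -> float:
    """Mean IoU over ``class_list`` (background excluded by the caller's list)."""
    classes = list(class_list)
    if not classes:
        raise CbctError("class_list must not be empty")
    return float(np.mean([iou_score(pred, gt, c) for c in classes]))


def extract_surface(mask: np.ndarray) -> np.ndarray:
    """Coordinates ``(n, 3)`` of mask voxels with a six-connected background
    neighbour; the grid boundary counts as background."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise CbctError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(
    pred_mask: np.ndarray, gt_mask: np.ndarray, spacing
) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-surface distance sets (pred->gt, gt->pred) in mm."""
    sp = np.asarray(spacing, float)
    ps = extract_surface(pred_mask) * sp
    gs = extract_surface(gt_mask) * sp
    d_pg, _ = cKDTree(gs).query(ps, k=1)
    d_gp, _ = cKDTree(ps).query(gs, k=1)
    return np.atleast_1d(d_pg), np.atleast_1d(d_gp)


def hausdorff_distance(
    pred_mask: np.ndarray, gt_mask: np.ndarray, spacing, percentile: float | None = None
) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in mm.

    ``percentile`` (e.g. 95) switches to the robust HDp variant; the default
    is the exact maximum.
    """
    if not np.asarray(pred_mask, bool).any():
        raise CbctError("prediction mask is empty")
    if not np.asarray(gt_mask, bool).any():
        raise CbctError("ground-truth mask is empty")
    d_pg, d_gp = surface_distances(pred_mask, gt_mask, spacing)
    if percentile is None:
        return float(max(d_pg.max(), d_gp.max()))
    return float(max(np.percentile(d_pg, percentile), np.percentile(d_gp, percentile)))


def average_surface_distance(pred_mask: np.ndarray, gt_mask: np.ndarray, spacing) -> float:
    """Symmetric ASD: mean of the pooled directed nearest-surface distances, mm."""
    if not np.asarray(pred_mask, bool).any():
        raise CbctError("prediction mask is empty")
    if not np.asarray(gt_mask, bool).any():
        raise CbctError("ground-truth mask is empty")
    d_pg, d_gp = surface_distances(pred_mask, gt_mask, spacing)
    return float(np.concatenate([d_pg, d_gp]).mean())


def fdi_to_position(fdi_code: int) -> str:
    """Map an FDI two-digit tooth code to its position group T1-T8.

    Quadrants are merged: 11, 21, 31, 41 are all T1 (central incisors);
    position 6 is the first molar, so 36 -> T6.
    """
    code = int(fdi_code)
    quadrant, position = divmod(code, 10)
    if quadrant not in (1, 2, 3, 4) or position not in range(1, 9):
        raise CbctError(f"invalid FDI permanent-tooth code: {code}")
    return f"T{position}"


@dataclass(frozen=True)
class ClassMetrics:
    """All four metrics for one class, with a status flag.

    status: "ok" | "vacuous" (absent both sides) | "missing-pred" |
    "missing-gt" (distances undefined in the latter three).
    """

    dice: float
    iou: float
    hd: float | None
    asd: float | None
    status: str = "ok"


@dataclass
class MetricReport:
    """Per-class and per-tooth evaluation of one case."""

    per_class: dict = field(default_factory=dict)  # label/name -> ClassMetrics
    per_tooth: dict = field(default_factory=dict)  # FDI code -> ClassMetrics
    per_position: dict = field(default_factory=dict)  # "T1".."T8" -> mean Dice
    spacing: tuple = (1.0, 1.0, 1.0)

    def to_dict(self) -> dict:
        def enc(cm: ClassMetrics) -> dict:
            return {"dice": cm.dice, "iou": cm.iou, "hd": cm.hd, "asd": cm.asd,
                    "status": cm.status}

        return {
            "per_class": {str(k): enc(v) for k, v in self.per_class.items()},
            "per_tooth": {str(k): enc(v) for k, v in self.per_tooth.items()},
            "per_position": dict(self.per_position),
            "spacing": list(self.spacing),
        }


def _class_metrics(pred: LabelVolume, gt: LabelVolume, a: np.ndarray, b: np.ndarray) -> ClassMetrics:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return ClassMetrics(1.0, 1.0, None, None, "vacuous")
    if na == 0 or nb == 0:
        status = "missing-pred" if na == 0 else "missing-gt"
        return ClassMetrics(0.0, 0.0, None, None, status)
    inter = int(np.count_nonzero(a & b))
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    iou = inter / union
    hd = hausdorff_distance(a, b, pred.spacing)
    asd = average_surface_distance(a, b, pred.spacing)
    return ClassMetrics(dice, iou, hd, asd, "ok")


def evaluate_case(pred: LabelVolume, gt: LabelVolume) -> MetricReport:
    """Evaluate a predicted label volume against ground truth.

    Structural classes (maxillary bone, mandibular bone, sinus, canal) and
    the pooled "teeth" class get all four metrics; every FDI tooth present on
    either side gets its own entry, grouped into positions T1-T8 by mean
    Dice (vacuous teeth excluded).
    """
    pred.require_same_grid(gt)
    report = MetricReport(spacing=tuple(pred.spacing))

    for label, name in STRUCTURE_NAMES.items():
        a, b = pred.values == label, gt.values == label
        report.per_class[name] = _class_metrics(pred, gt, a, b)

    teeth_pred = pred.values >= 11
    teeth_gt = gt.values >= 11
    report.per_class["teeth"] = _class_metrics(pred, gt, teeth_pred, teeth_gt)

    codes = sorted(
        set(int(c) for c in pred.present_labels() if c >= 11)
        | set(int(c) for c in gt.present_labels() if c >= 11)
    )
    for code in codes:
        a, b = pred.values == code, gt.values == code
        report.per_tooth[code] = _class_metrics(pred, gt, a, b)

    for pos in TOOTH_POSITIONS:
        dices = [
            cm.dice
            for code, cm in report.per_tooth.items()
            if fdi_to_position(code) == pos and cm.status != "vacuous"
        ]
        if dices:
            report.per_position[pos] = float(np.mean(dices))
    return report


def aggregate_reports(reports: list[MetricReport]) -> dict[str, pd.DataFrame]:
    """Aggregate case reports into mean +/- std summary tables.

    Returns two DataFrames: ``"classes"`` with columns (Dice/%, mIoU/%,
    HD/mm, ASD/mm) as ``mean +/- std`` strings plus numeric companions, one
    row per class and an unweighted "Average" row; ``"positions"`` with the
    T1-T8 mean Dice.  Vacuous entries are excluded; sample std (ddof 1, 0
    for a single case).
    """
    if not reports:
        raise CbctError("need at least one report to aggregate")

    def mstd(values):
        arr = np.asarray([v for v in values if v is not None], float)
        if arr.size == 0:
            return np.nan, np.nan
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), std

    class_names = sorted(
        {name for r in reports for name in r.per_class},
        key=lambda n: (n != "teeth", n),
    )
    rows = []
    for name in class_names:
        entries = [
            r.per_class[name]
            for r in reports
            if name in r.per_class and r.per_class[name].status != "vacuous"
        ]
        if not entries:
            continue
        dice_m, dice_s = mstd([e.dice * 100 for e in entries])
        iou_m, iou_s = mstd([e.iou * 100 for e in entries])
        hd_m, hd_s = mstd([e.hd for e in entries])
        asd_m, asd_s = mstd([e.asd for e in entries])
        rows.append(
            {
                "class": name,
                "Dice/%": f"{dice_m:.1f} ± {dice_s:.1f}",
                "mIoU/%": f"{iou_m:.1f} ± {iou_s:.1f}",
                "HD/mm": f"{hd_m:.2f} ± {hd_s:.2f}" if np.isfinite(hd_m) else "n/a",
                "ASD/mm": f"{asd_m:.2f} ± {asd_s:.2f}" if np.isfinite(asd_m) else "n/a",
                "dice_mean": dice_m, "dice_std": dice_s,
                "iou_mean": iou_m, "iou_std": iou_s,
                "hd_mean": hd_m, "hd_std": hd_s,
                "asd_mean": asd_m, "asd_std": asd_s,
            }
        )
    classes = pd.DataFrame(rows).set_index("class")
    if len(classes):
        avg = classes[["dice_mean", "iou_mean", "hd_mean", "asd_mean"]].mean()
        classes.loc["Average", ["dice_mean", "iou_mean", "hd_mean", "asd_mean"]] = avg
        classes.loc["Average", "Dice/%"] = f"{avg['dice_mean']:.1f}"
        classes.loc["Average", "mIoU/%"] = f"{avg['iou_mean']:.1f}"
        classes.loc["Average", "HD/mm"] = f"{avg['hd_mean']:.2f}"
        classes.loc["Average", "ASD/mm"] = f"{avg['asd_mean']:.2f}"

    pos_rows = []
    for pos in TOOTH_POSITIONS:
        values = [r.per_position[pos] * 100 for r in reports if pos in r.per_position]
        if values:
            m, s = mstd(values)
            pos_rows.append({"position": pos, "Dice/%": f"{m:.1f} ± {s:.1f}",
                             "dice_mean": m, "dice_std": s})
    positions = pd.DataFrame(pos_rows)
    if len(positions):
        positions = positions.set_index("position")
    return {"classes": classes, "positions": positions}
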