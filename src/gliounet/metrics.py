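"""Region derivation and evaluation metrics for glioma segmentation.

The three nested evaluation regions are derived from the label volume:
enhancing tumor ET = {4}, tumor core TC = {1, 4}, whole tumor WT = {1, 2, 4}.
Per region the overlap statistics are

    Dice(P, T)        = 2|P1 ∩ T1| / (|P1| + |T1|)
    Sensitivity(P, T) = |P1 ∩ T1| / |T1|
    Specificity(P, T) = |P0 ∩ T0| / |T0|

with P the prediction, T the ground truth and the subscripts the positive/
negative voxel sets, plus the 95th-percentile symmetric surface distance
(HD95, in mm). Cohort aggregation reports mean, sample SD, median and the
25th/75th percentiles per region and metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_preprocess import LabelVolume

REGIONS: tuple[str, ...] = ("ET", "TC", "WT")
_REGION_LABELS = {"ET": (4,), "TC": (1, 4), "WT": (1, 2, 4)}
METRICS: tuple[str, ...] = ("dice", "sensitivity", "specificity", "hd95")


@dataclass
class RegionMasks:
    """Binary masks of the three nested evaluation regions."""

    ET: np.ndarray
    TC: np.ndarray
    WT: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def derive_regions(labels: LabelVolume) -> RegionMasks:
    """ET/TC/WT masks from a label volume (ET ⊆ TC ⊆ WT by construction)."""
    d = labels.to_brats().data
    return RegionMasks(
        ET=np.isin(d, _REGION_LABELS["ET"]),
        TC=np.isin(d, _REGION_LABELS["TC"]),
        WT=np.isin(d, _REGION_LABELS["WT"]),
    )


def _check_shapes(p: np.ndarray, t: np.ndarray):
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {t.shape}")


def dice(p1: np.ndarray, t1: np.ndarray) -> float:
    """Dice overlap; NaN (undefined) when both masks are empty."""
    _check_shapes(p1, t1)
    p1 = np.asarray(p1, bool)
    t1 = np.asarray(t1, bool)
    denom = int(p1.sum()) + int(t1.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((p1 & t1).sum()) / denom


def sensitivity(p1: np.ndarray, t1: np.ndarray) -> float:
    """True-positive rate; NaN when the truth mask is empty."""
    _check_shapes(p1, t1)
    p1 = np.asarray(p1, bool)
    t1 = np.asarray(t1, bool)
    nt = int(t1.sum())
    if nt == 0:
        return float("nan")
    return int((p1 & t1).sum()) / nt


def specificity(p1: np.ndarray, t1: np.ndarray) -> float:
    """True-negative rate; NaN when the truth negative set is empty."""
    _check_shapes(p1, t1)
    p0 = ~np.asarray(p1, bool)
    t0 = ~np.asarray(t1, bool)
    nt = int(t0.sum())
    if nt == 0:
        return float("nan")
    return int((p0 & t0).sum()) / nt


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask voxels with a 6-adjacent voxel outside the mask.

    Voxels on the array border count as surface (outside the array is
    outside the mask).
    """
    mask = np.asarray(mask, bool)
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff95(p1: np.ndarray, t1: np.ndarray,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                pooled: bool = False) -> float:
    """95th-percentile surface distance between two masks, in mm.

    Computes directed nearest-surface distances both ways and takes the
    maximum of the two 95th percentiles (the challenge-tooling convention);
    with ``pooled`` the percentile is taken over the pooled distances
    instead. NaN when either mask is empty. Distances honour anisotropic
    voxel spacing.
    """
    _check_shapes(p1, t1)
    if not np.any(p1) or not np.any(t1):
        return float("nan")
    sp = np.asarray(spacing, float)
    ps = surface_voxels(p1) * sp
    ts = surface_voxels(t1) * sp
    d_pt = cKDTree(ts).query(ps)[0]
    d_tp = cKDTree(ps).query(ts)[0]
    if pooled:
        return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))
    return float(max(np.percentile(d_pt, 95), np.percentile(d_tp, 95)))


@dataclass
class MetricsReport:
    """Per-region metric values for one case; NaN marks undefined entries."""

    values: dict[str, dict[str, float]]  # region -> metric -> value
    case_id: str | None = None

    def defined(self, region: str, metric: str) -> bool:
        return not np.isnan(self.values[region][metric])

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        if self.case_id is not None:
            row["case"] = self.case_id
        for region in REGIONS:
            for metric in METRICS:
                row[f"{metric}_{region}"] = self.values[region][metric]
        return row


def evaluate_case(pred: LabelVolume, truth: LabelVolume,
                  spacing: tuple[float, float, float] | None = None,
                  case_id: str | None = None) -> MetricsReport:
    """Dice/sensitivity/specificity/HD95 for ET, TC and WT of one case."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}")
    spacing = spacing or truth.spacing
    pr = derive_regions(pred)
    tr = derive_regions(truth)
    values = {}
    for region in REGIONS:
        p1, t1 = pr[region], tr[region]
        values[region] = {
            "dice": dice(p1, t1),
            "sensitivity": sensitivity(p1, t1),
            "specificity": specificity(p1, t1),
            "hd95": hausdorff95(p1, t1, spacing),
        }
    return MetricsReport(values, case_id)


@dataclass
class CohortSummary:
    """Mean/SD/median/quartiles per region and metric over a cohort."""

    table: pd.DataFrame  # index: (metric, region); columns: the 5 statistics

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path)
        return path


_STATS = ("mean", "sd", "median", "q25", "q75")


def _aggregate(values: np.ndarray) -> dict[str, float]:
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(np.mean(values)),
        "sd": sd,
        "median": float(np.percentile(values, 50)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
    }


def summarize_cohort(reports: list[MetricsReport], policy: str = "zero") -> CohortSummary:
    """Aggregate per-case reports over a cohort.

    ``policy`` controls undefined (NaN) overlap scores, which arise when a
    region is absent in the truth and/or the prediction: ``"zero"`` (the
    challenge convention — such a case scores 0) or ``"exclude"`` (drop the
    case from that cell). Undefined HD95 distances are always excluded:
    there is no meaningful zero distance for an absent surface. Percentiles
    use linear interpolation; SD is the sample (n-1) estimator, 0 for a
    single case.
    """
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    if policy not in ("zero", "exclude"):
        raise ValueError(f"unknown undefined-metric policy {policy!r}")
    rows = []
    for metric in METRICS:
        for region in REGIONS:
            vals = np.array([r.values[region][metric] for r in reports], float)
            nan = np.isnan(vals)
            if metric == "hd95" or policy == "exclude":
                vals = vals[~nan]
            else:
                vals = np.where(nan, 0.0, vals)
            if vals.size == 0:
                stats = {s: float("nan") for s in _STATS}
            else:
                stats = _aggregate(vals)
            rows.append({"metric": metric, "region": region, **stats})
    table = pd.DataFrame(rows).set_index(["metric", "region"])
    return CohortSummary(table)


def write_reports(reports: list[MetricsReport], csv_path: str | Path | None = None,
                  json_path: str | Path | None = None) -> None:
    """Per-case metrics as CSV rows and/or a JSON document."""
    rows = [r.to_row() for r in reports]
    if csv_path is not None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        json_path = Path(json_path)
        json_path.parent.mkdir(parents=True, exist_ok=True)

        def _clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v

        payload = [{k: _clean(v) for k, v in row.items()} for row in rows]
        json_path.write_text(json.dumps(payload, indent=2))
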