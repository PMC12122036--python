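"""Segmentation evaluation metrics.

Per-image confusion-count metrics (IoU, Dice similarity coefficient,
accuracy, recall) and the symmetric average Hausdorff distance between the
foregrounds of two binary masks, aggregated as unweighted per-image mean and
standard deviation.  Both masks empty counts as perfect agreement for the
ratio metrics; the Hausdorff distance is undefined when either foreground is
empty and is reported as ``nan`` with a warning.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

RATIO_METRICS = ("iou", "dsc", "acc", "rec")


def _validate_binary(m, name: str) -> np.ndarray:
    arr = np.asarray(m)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (values 0/1)")
    return arr.astype(bool)


@dataclass
class MetricReport:
    """Per-image metric rows plus mean ± std aggregates."""

    per_image: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        return self._agg(np.nanmean)

    @property
    def std(self) -> dict:
        return self._agg(np.nanstd)

    def _agg(self, fn) -> dict:
        keys = [k for k in self.per_image[0] if k != "identifier"]
        out = {}
        for k in keys:
            vals = np.array([row[k] for row in self.per_image], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[k] = float(fn(vals))
        return out

    def format_summary(self) -> str:
        mean, std = self.mean, self.std
        parts = [f"{k}: {100 * mean[k]:.2f} ± {100 * std[k]:.2f} %"
                 for k in RATIO_METRICS if k in mean]
        if "avg_hausdorff" in mean:
            parts.append(
                f"avg HD: {mean['avg_hausdorff']:.2f} ± {std['avg_hausdorff']:.2f} px")
        return "; ".join(parts)

    def write_csv(self, path) -> None:
        """One row per image plus a mean and a std summary row."""
        keys = list(self.per_image[0].keys())
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            for row in self.per_image:
                w.writerow(row)
            for label, agg in (("mean", self.mean), ("std", self.std)):
                w.writerow({"identifier": label, **{k: agg[k] for k in agg}})


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    p = _validate_binary(pred, "prediction")
    g = _validate_binary(ref, "reference")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return tp, fp, fn, tn


def _ratios(tp: int, fp: int, fn: int, tn: int) -> dict:
    n = tp + fp + fn + tn
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    dsc = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 1.0
    acc = (tp + tn) / n
    rec = tp / (tp + fn) if tp + fn else 1.0
    return {"iou": iou, "dsc": dsc, "acc": acc, "rec": rec}


def average_hausdorff(pred: np.ndarray, ref: np.ndarray) -> float:
    """Symmetric average Hausdorff distance (pixels) between foregrounds.

    (mean over predicted foreground of the Euclidean distance to the nearest
    reference foreground pixel + the same with roles swapped) / 2.
    """
    p = _validate_binary(pred, "prediction")
    g = _validate_binary(ref, "reference")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        warnings.warn("average Hausdorff undefined for an empty foreground; "
                      "reporting nan", RuntimeWarning, stacklevel=2)
        return math.nan
    if p.shape == g.shape and (p == g).all():
        return 0.0
    d_to_g = ndimage.distance_transform_edt(~g)
    d_to_p = ndimage.distance_transform_edt(~p)
    return 0.5 * (float(d_to_g[p].mean()) + float(d_to_p[g].mean()))


def segmentation_metrics(pred_masks, ref_masks, identifiers=None,
                         with_hausdorff: bool = True) -> MetricReport:
    """Per-image IoU/DSC/Acc/Rec (and average HD) over a batch of masks.

    Accepts (B, H, W) or (B, 1, H, W) strictly binary arrays.
    """
    p = np.asarray(pred_masks)
    g = np.asarray(ref_masks)
    if p.ndim == 4:
        p = p[:, 0]
    if g.ndim == 4:
        g = g[:, 0]
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    ids = identifiers or [f"img{i:04d}" for i in range(len(p))]
    report = MetricReport()
    for ident, pi, gi in zip(ids, p, g):
        row = {"identifier": ident, **_ratios(*confusion_counts(pi, gi))}
        if with_hausdorff:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row["avg_hausdorff"] = average_hausdorff(pi, gi)
        report.per_image.append(row)
    return report
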