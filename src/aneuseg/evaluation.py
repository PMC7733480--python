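"""Component-level detection matching and cohort metrics.

A reference aneurysm counts as detected (TP) when at least one predicted
voxel overlaps it; every predicted component is attributed to the reference
component it shares most voxels with, fragments merging into a single TP;
predicted components touching no reference component are false positives.
Cohort metrics follow the usual detection conventions:

    sensitivity = TP / (TP + FN) * 100
    precision   = TP / (TP + FP) * 100
    F1          = 2 * sensitivity * precision / (sensitivity + precision) / 100
    FPs/scan    = FP / number of scans
    DSC(A, B)   = 2|A ∩ B| / (|A| + |B|)

Percentages are rounded half away from zero to integers, DSC/F1/FPs-per-scan
to two decimals, matching the usual clinical-table formatting. Volume-binned
reports restrict reference components (TP/FN) and predicted components (FP)
by their own volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import Volume3D

__all__ = [
    "MatchedPair",
    "DetectionResult",
    "MetricsReport",
    "connected_components",
    "match_detections",
    "merge_results",
    "sensitivity",
    "precision",
    "f1",
    "fps_per_scan",
    "dsc",
    "volume_binned_report",
    "pearson_volume_correlation",
    "round_half_away",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (5 rounds up), unlike banker's rounding."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class MatchedPair:
    ref_id: int
    pred_ids: list[int]
    pair_dsc: float
    ref_volume_mm3: float
    pred_volume_mm3: float
    case_id: str = ""


@dataclass
class DetectionResult:
    """Component-level TP/FP/FN bookkeeping over one or more scans."""

    matched: list[MatchedPair] = field(default_factory=list)
    fn_components: list[tuple[int, float]] = field(default_factory=list)  # (ref id, volume)
    fp_components: list[tuple[int, float]] = field(default_factory=list)  # (pred id, volume)
    n_scans: int = 1

    @property
    def tp(self) -> int:
        return len(self.matched)

    @property
    def fn(self) -> int:
        return len(self.fn_components)

    @property
    def fp(self) -> int:
        return len(self.fp_components)


@dataclass
class MetricsReport:
    stratum: str
    sensitivity_pct: float
    precision_pct: float | None
    f1: float | None
    fps_per_scan: float
    median_dsc: float | None
    pearson_r: float | None
    tp: int
    fp: int
    fn: int
    n_scans: int

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "sensitivity_pct": self.sensitivity_pct,
            "precision_pct": self.precision_pct,
            "f1": self.f1,
            "fps_per_scan": self.fps_per_scan,
            "median_dsc": self.median_dsc,
            "pearson_r": self.pearson_r,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "n_scans": self.n_scans,
        }


def connected_components(
    mask: Volume3D, connectivity: int = 26
) -> list[tuple[int, int, float]]:
    """Label a binary mask; returns (component id, voxel count, volume mm³)."""
    structure = _CONN26 if connectivity == 26 else _CONN6
    labels, n = ndimage.label(mask.values.astype(bool), structure=structure)
    voxel_vol = mask.voxel_volume_mm3
    counts = np.bincount(labels.ravel())
    return [(i, int(counts[i]), float(counts[i]) * voxel_vol) for i in range(1, n + 1)]


def match_detections(
    pred: Volume3D,
    ref: Volume3D,
    connectivity: int = 26,
    min_overlap_fraction: float = 0.0,
    case_id: str = "",
) -> DetectionResult:
    """Match predicted components to reference components on one scan.

    ``min_overlap_fraction`` raises the detection bar: a reference component
    counts as TP only if the overlapping predicted voxels cover more than
    that fraction of it (default: any overlap).
    """
    pred.require_same_grid(ref, "pred/ref masks")
    structure = _CONN26 if connectivity == 26 else _CONN6
    pred_lab, n_pred = ndimage.label(pred.values.astype(bool), structure=structure)
    ref_lab, n_ref = ndimage.label(ref.values.astype(bool), structure=structure)
    voxel_vol = ref.voxel_volume_mm3

    pred_counts = np.bincount(pred_lab.ravel(), minlength=n_pred + 1)
    ref_counts = np.bincount(ref_lab.ravel(), minlength=n_ref + 1)

    # overlap histogram between labelings
    both = (pred_lab > 0) & (ref_lab > 0)
    overlap = np.zeros((n_pred + 1, n_ref + 1), dtype=np.int64)
    if both.any():
        pairs = pred_lab[both].astype(np.int64) * (n_ref + 1) + ref_lab[both]
        hist = np.bincount(pairs, minlength=(n_pred + 1) * (n_ref + 1))
        overlap = hist.reshape(n_pred + 1, n_ref + 1)

    assigned: dict[int, list[int]] = {}
    fp_components: list[tuple[int, float]] = []
    for p in range(1, n_pred + 1):
        row = overlap[p, 1:]
        if row.sum() == 0:
            fp_components.append((p, float(pred_counts[p]) * voxel_vol))
            continue
        target = int(np.argmax(row)) + 1  # reference sharing most voxels
        assigned.setdefault(target, []).append(p)

    matched: list[MatchedPair] = []
    fn_components: list[tuple[int, float]] = []
    for r in range(1, n_ref + 1):
        preds = assigned.get(r, [])
        ref_vox = int(ref_counts[r])
        union_pred_vox = int(sum(pred_counts[p] for p in preds))
        inter = int(overlap[preds, r].sum()) if preds else 0
        detected = bool(preds) and inter > min_overlap_fraction * ref_vox
        if detected:
            pair_dsc = 2.0 * inter / (ref_vox + union_pred_vox)
            matched.append(
                MatchedPair(
                    ref_id=r,
                    pred_ids=preds,
                    pair_dsc=pair_dsc,
                    ref_volume_mm3=ref_vox * voxel_vol,
                    pred_volume_mm3=union_pred_vox * voxel_vol,
                    case_id=case_id,
                )
            )
        else:
            fn_components.append((r, ref_vox * voxel_vol))
            for p in preds:  # fragments below the overlap bar revert to FP
                fp_components.append((p, float(pred_counts[p]) * voxel_vol))
    return DetectionResult(
        matched=matched, fn_components=fn_components, fp_components=fp_components, n_scans=1
    )


def merge_results(results: list[DetectionResult]) -> DetectionResult:
    """Pool per-scan detection results into a cohort-level result."""
    out = DetectionResult(n_scans=sum(r.n_scans for r in results))
    for r in results:
        out.matched.extend(r.matched)
        out.fn_components.extend(r.fn_components)
        out.fp_components.extend(r.fp_components)
    return out


def sensitivity(tp: int, fn: int) -> float:
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no reference components (TP+FN=0)")
    return tp / (tp + fn) * 100.0


def precision(tp: int, fp: int) -> float:
    if tp + fp == 0:
        raise ValueError("precision undefined: no predicted components (TP+FP=0)")
    return tp / (tp + fp) * 100.0


def f1(sens_pct: float, prec_pct: float) -> float:
    """Harmonic mean of unrounded sensitivity and precision percentages, on [0,1]."""
    if sens_pct == 0 and prec_pct == 0:
        return 0.0
    return 2.0 * (sens_pct * prec_pct) / (sens_pct + prec_pct) / 100.0


def fps_per_scan(fp: int, n_scans: int) -> float:
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    return fp / n_scans


def dsc(a: Volume3D, b: Volume3D) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) between binary volumes."""
    a.require_same_grid(b, "DSC operands")
    av, bv = a.values.astype(bool), b.values.astype(bool)
    total = int(av.sum()) + int(bv.sum())
    if total == 0:
        raise ValueError("DSC undefined for two empty masks")
    return 2.0 * int((av & bv).sum()) / total


def pearson_volume_correlation(ref_volumes, pred_volumes) -> float:
    """Pearson r between matched reference and predicted volumes."""
    ref_volumes = np.asarray(ref_volumes, dtype=float)
    pred_volumes = np.asarray(pred_volumes, dtype=float)
    if ref_volumes.shape != pred_volumes.shape or ref_volumes.size < 3:
        raise ValueError("need >= 3 matched volume pairs of equal length")
    if ref_volumes.std() == 0 or pred_volumes.std() == 0:
        raise ValueError("Pearson r undefined for zero-variance volumes")
    return float(stats.pearsonr(ref_volumes, pred_volumes).statistic)


def _report_for(result: DetectionResult, stratum: str) -> MetricsReport:
    tp, fp, fn = result.tp, result.fp, result.fn
    sens = sensitivity(tp, fn)
    prec = precision(tp, fp) if tp + fp > 0 else None
    f1v = f1(sens, prec) if prec is not None else None
    dscs = [m.pair_dsc for m in result.matched]
    med = float(np.median(dscs)) if dscs else None
    r = None
    if len(result.matched) >= 3:
        refs = [m.ref_volume_mm3 for m in result.matched]
        preds = [m.pred_volume_mm3 for m in result.matched]
        if np.std(refs) > 0 and np.std(preds) > 0:
            r = pearson_volume_correlation(refs, preds)
    return MetricsReport(
        stratum=stratum,
        sensitivity_pct=round_half_away(sens),
        precision_pct=round_half_away(prec) if prec is not None else None,
        f1=round_half_away(f1v, 2) if f1v is not None else None,
        fps_per_scan=round_half_away(fps_per_scan(fp, result.n_scans), 2),
        median_dsc=round_half_away(med, 2) if med is not None else None,
        pearson_r=round_half_away(r, 2) if r is not None else None,
        tp=tp,
        fp=fp,
        fn=fn,
        n_scans=result.n_scans,
    )


def volume_binned_report(
    result: DetectionResult, bins: tuple[float, ...] = (30.0, 50.0, 100.0)
) -> list[MetricsReport]:
    """Cohort metrics for the full result and each volume stratum.

    Per stratum, TP/FN are restricted by reference-component volume and FP
    by predicted-component volume; empty strata (no reference components)
    are omitted rather than reported as zero.
    """
    reports = [_report_for(result, "all")]
    for threshold in bins:
        sub = DetectionResult(
            matched=[m for m in result.matched if m.ref_volume_mm3 > threshold],
            fn_components=[c for c in result.fn_components if c[1] > threshold],
            fp_components=[c for c in result.fp_components if c[1] > threshold],
            n_scans=result.n_scans,
        )
        if sub.tp + sub.fn == 0:
            continue
        reports.append(_report_for(sub, f">{threshold:g} mm³"))
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
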