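"""Segmentation evaluation: DSC, precision, recall, ASSD, cohort statistics.

A denotes the manual (reference) segmentation and B the automatic one.

* DSC = 2|A ∩ B| / (|A| + |B|)
* recall = TP/(TP+FN), precision = TP/(TP+FP)
* ASSD = (Σ_{a∈S(A)} min_b d(a,b) + Σ_{b∈S(B)} min_a d(a,b)) / (|S(A)|+|S(B)|)
  where S(·) is the set of surface voxels (foreground voxels with at least
  one face-adjacent background neighbour, 6-connectivity; voxels beyond the
  image border count as background) and d is the Euclidean distance between
  voxel centres in mm.

Cohort means are reported with sample (n-1) standard deviations; methods
are compared with a two-sided paired t-test (p < 0.05 taken as significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .image import Mask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dsc",
    "precision_recall",
    "surface_voxels",
    "assd",
    "evaluate_cohort",
    "paired_compare",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_aligned(a: Mask, b: Mask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def confusion_counts(a: Mask, b: Mask) -> ConfusionCounts:
    """Voxel confusion counts of automatic mask ``b`` against manual truth ``a``."""
    _check_aligned(a, b)
    am = a.data.astype(bool)
    bm = b.data.astype(bool)
    tp = int(np.count_nonzero(am & bm))
    fp = int(np.count_nonzero(~am & bm))
    fn = int(np.count_nonzero(am & ~bm))
    tn = am.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient; 1.0 if both masks empty, 0.0 if exactly one is."""
    _check_aligned(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data.astype(bool) & b.data.astype(bool)))
    return 2.0 * inter / (na + nb)


def precision_recall(a: Mask, b: Mask) -> tuple[float, float]:
    """(precision, recall) of automatic ``b`` against manual ``a``.

    Degenerate conventions: an empty prediction has precision 0.0 (flagged
    undefined in cohort reports) and, with nonempty truth, recall 0.0; an
    empty truth with empty prediction scores 1.0 on both.
    """
    c = confusion_counts(a, b)
    if c.tp + c.fp == 0:
        precision = 1.0 if a.n_foreground == 0 else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 1.0 if b.n_foreground == 0 else 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    return float(precision), float(recall)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: Mask) -> np.ndarray:
    """Indices (n, 3) of foreground voxels with a face-adjacent background neighbour."""
    m = mask.data.astype(bool)
    eroded = ndimage.binary_erosion(m, structure=_FACE_STRUCTURE, border_value=0)
    return np.argwhere(m & ~eroded)


def assd(a: Mask, b: Mask, spacing=None) -> float:
    """Average symmetric surface distance in mm; undefined for empty masks."""
    _check_aligned(a, b)
    if a.n_foreground == 0 or b.n_foreground == 0:
        raise ValueError("ASSD is undefined when either mask is empty")
    sp = np.asarray(spacing if spacing is not None else a.spacing, dtype=float)
    sa = surface_voxels(a) * sp
    sb = surface_voxels(b) * sp
    d_ab, _ = cKDTree(sb).query(sa, k=1)
    d_ba, _ = cKDTree(sa).query(sb, k=1)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


@dataclass
class MetricReport:
    """Per-case metrics with cohort summary (mean ± SD, divisor n-1)."""

    per_case: pd.DataFrame  # columns: case_id, dsc, precision, recall, assd_mm
    comparisons: list = field(default_factory=list)

    _METRICS = ("dsc", "precision", "recall", "assd_mm")

    @property
    def summary(self) -> pd.DataFrame:
        rows = {}
        for m in self._METRICS:
            vals = self.per_case[m].dropna().to_numpy(dtype=float)
            mean = float(vals.mean()) if len(vals) else float("nan")
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows[m] = {"mean": mean, "sd": sd, "n": len(vals)}
        return pd.DataFrame(rows).T

    def metric_values(self, metric: str) -> pd.Series:
        if metric not in self._METRICS:
            raise KeyError(f"unknown metric {metric!r}; choose from {self._METRICS}")
        return self.per_case.set_index("case_id")[metric]

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def evaluate_cohort(cases) -> MetricReport:
    """Evaluate a list of ``(case_id, manual, predicted)`` or
    ``(case_id, manual, predicted, spacing)`` tuples."""
    cases = list(cases)
    if not cases:
        raise ValueError("evaluate_cohort needs at least one case")
    rows = []
    for case in cases:
        case_id, manual, predicted = case[0], case[1], case[2]
        spacing = case[3] if len(case) > 3 else manual.spacing
        p, r = precision_recall(manual, predicted)
        try:
            surf = assd(manual, predicted, spacing)
        except ValueError:
            surf = float("nan")  # undefined, reported missing rather than 0
        rows.append(
            {"case_id": case_id, "dsc": dsc(manual, predicted), "precision": p,
             "recall": r, "assd_mm": surf}
        )
    return MetricReport(per_case=pd.DataFrame(rows))


def paired_compare(report_a: MetricReport, report_b: MetricReport, metric: str = "dsc") -> float:
    """Two-sided paired t-test p-value between two methods on one metric.

    Identical per-case values (zero-variance differences) degenerate the
    test; p = 1.0 is reported by convention.
    """
    va = report_a.metric_values(metric)
    vb = report_b.metric_values(metric)
    if set(va.index) != set(vb.index):
        raise ValueError("reports cover different case ids")
    vb = vb.reindex(va.index)
    pairs = pd.concat([va, vb], axis=1).dropna()
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    diffs = pairs.iloc[:, 0].to_numpy() - pairs.iloc[:, 1].to_numpy()
    if np.allclose(diffs, 0.0):
        return 1.0
    if np.isclose(diffs.std(ddof=1), 0.0):
        return 0.0  # constant nonzero shift: t -> inf
    return float(stats.ttest_rel(pairs.iloc[:, 0], pairs.iloc[:, 1]).pvalue)
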