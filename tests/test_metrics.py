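"""Evaluation metrics against exhaustive brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from gtvseg.image import Mask
from gtvseg.metrics import (
    MetricReport,
    assd,
    confusion_counts,
    dsc,
    evaluate_cohort,
    paired_compare,
    precision_recall,
)

from conftest import random_mask


# -- independent oracles -----------------------------------------------------

def brute_surface(data):
    """Foreground voxels with a face-adjacent background neighbour (6-conn.);
    out-of-bounds counts as background."""
    pts = []
    shape = data.shape
    for idx in np.argwhere(data > 0):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            outside = not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2])
            if outside or data[ni, nj, nk] == 0:
                pts.append((i, j, k))
                break
    return np.asarray(pts, dtype=float)


def brute_assd(a, b, spacing):
    sa = brute_surface(a.data) * spacing
    sb = brute_surface(b.data) * spacing
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    return (sum(d_ab) + sum(d_ba)) / (len(sa) + len(sb))


def brute_counts(a, b):
    tp = fp = fn = tn = 0
    for x, y in zip(a.data.ravel(), b.data.ravel()):
        if x and y:
            tp += 1
        elif y:
            fp += 1
        elif x:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# -- DSC / precision / recall ------------------------------------------------

class TestOverlapMetrics:
    def test_identical_nonempty(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0
        assert precision_recall(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1
        assert dsc(Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1))) == 0.0

    def test_half_overlap_counting_example(self):
        a = np.zeros((4, 4, 1)); a[:2, :2, 0] = 1          # |A| = 4
        b = np.zeros((4, 4, 1)); b[1:3, :2, 0] = 1          # |B| = 4, overlap 2
        assert dsc(Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1))) == pytest.approx(0.5)

    def test_superset_prediction(self):
        a = np.zeros((6, 6, 6)); a[2:4, 2:4, 2:4] = 1       # 8 voxels
        b = np.zeros((6, 6, 6)); b[1:5, 2:4, 2:4] = 1       # 16 voxels, contains a
        p, r = precision_recall(Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1)))
        assert r == 1.0
        assert p == pytest.approx(8 / 16)

    def test_empty_prediction_conventions(self, rng):
        a = random_mask(rng, p=0.5)
        empty = Mask(np.zeros((8, 8, 8)), (1, 1, 1))
        assert dsc(a, empty) == 0.0
        assert dsc(empty, empty) == 1.0
        assert precision_recall(a, empty) == (0.0, 0.0)

    def test_symmetry_and_count_identity(self, rng):
        for _ in range(100):
            a = random_mask(rng, p=rng.uniform(0.1, 0.6))
            b = random_mask(rng, p=rng.uniform(0.1, 0.6))
            assert dsc(a, b) == dsc(b, a)
            c = confusion_counts(a, b)
            if c.tp + c.fp + c.fn:
                assert dsc(a, b) == pytest.approx(2 * c.tp / (2 * c.tp + c.fp + c.fn))

    def test_confusion_counts_against_loop_oracle(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        c = confusion_counts(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_counts(a, b)
        assert c.total == a.data.size

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            dsc(random_mask(rng, (4, 4, 4)), random_mask(rng, (5, 4, 4)))


# -- ASSD ----------------------------------------------------------------------

class TestASSD:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, p=0.4)
        assert assd(m, m) == 0.0

    def test_two_point_masks_known_distance(self):
        a = np.zeros((8, 8, 8)); a[1, 4, 4] = 1
        b = np.zeros((8, 8, 8)); b[4, 4, 4] = 1
        got = assd(Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1)))
        assert got == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8, 8)); a[1, 4, 4] = 1
        b = np.zeros((8, 8, 8)); b[4, 4, 4] = 1
        got = assd(Mask(a, (2, 1, 1)), Mask(b, (2, 1, 1)))
        assert got == pytest.approx(6.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(4, 17, size=3))
            a = random_mask(rng, shape, p=rng.uniform(0.1, 0.5))
            b = random_mask(rng, shape, p=rng.uniform(0.1, 0.5))
            if a.n_foreground == 0 or b.n_foreground == 0:
                continue
            spacing = rng.uniform(0.5, 2.5, size=3)
            assert assd(a, b, spacing) == pytest.approx(
                brute_assd(a, b, spacing), abs=1e-9)

    def test_symmetry_and_translation_invariance(self, rng):
        a = random_mask(rng, (10, 10, 10), p=0.3)
        b = random_mask(rng, (10, 10, 10), p=0.3)
        assert assd(a, b) == assd(b, a)
        shift = lambda m: Mask(np.roll(m.data, (2, 1, 3), axis=(0, 1, 2)), m.spacing)
        # interior-only masks so rolling is a pure translation
        a2 = Mask(np.pad(a.data, 4)[:18, :18, :18], (1, 1, 1))
        b2 = Mask(np.pad(b.data, 4)[:18, :18, :18], (1, 1, 1))
        assert assd(shift(a2), shift(b2)) == pytest.approx(assd(a2, b2), abs=1e-12)

    def test_empty_mask_is_undefined(self, rng):
        with pytest.raises(ValueError, match="undefined"):
            assd(random_mask(rng), Mask(np.zeros((8, 8, 8)), (1, 1, 1)))


# -- cohort aggregation and paired testing ------------------------------------

class TestCohort:
    def test_single_perfect_case(self, rng):
        m = random_mask(rng, p=0.4)
        report = evaluate_cohort([("c0", m, m)])
        assert report.summary.loc["dsc", "mean"] == 1.0
        assert report.summary.loc["dsc", "sd"] == 0.0

    def test_two_case_mean_and_sd(self):
        rows = MetricReport(per_case=__import__("pandas").DataFrame(
            [{"case_id": "a", "dsc": 0.8, "precision": 1, "recall": 1, "assd_mm": 0},
             {"case_id": "b", "dsc": 0.9, "precision": 1, "recall": 1, "assd_mm": 0}]))
        assert rows.summary.loc["dsc", "mean"] == pytest.approx(0.85)
        assert rows.summary.loc["dsc", "sd"] == pytest.approx(0.070710678, abs=1e-6)

    def test_summary_recomputable_from_per_case(self, rng):
        cases = [(f"c{i}", random_mask(rng, p=0.4), random_mask(rng, p=0.4))
                 for i in range(5)]
        report = evaluate_cohort(cases)
        vals = report.per_case["dsc"].to_numpy()
        assert report.summary.loc["dsc", "mean"] == pytest.approx(vals.mean(), abs=1e-9)
        assert report.summary.loc["dsc", "sd"] == pytest.approx(vals.std(ddof=1), abs=1e-9)

    def test_zero_cases_raise(self):
        with pytest.raises(ValueError, match="at least one"):
            evaluate_cohort([])


class TestPairedCompare:
    def _report(self, values):
        import pandas as pd

        return MetricReport(per_case=pd.DataFrame(
            [{"case_id": f"c{i}", "dsc": v, "precision": v, "recall": v, "assd_mm": 1.0}
             for i, v in enumerate(values)]))

    def test_identical_reports_give_p_one(self, rng):
        r = self._report(rng.uniform(0.5, 1.0, size=6))
        assert paired_compare(r, r, "dsc") == 1.0

    def test_matches_scipy_closed_form(self, rng):
        a = rng.uniform(0.6, 0.9, size=10)
        noise = rng.normal(0, 0.02, size=10)
        b = a - 0.05 + noise
        p = paired_compare(self._report(a), self._report(b), "dsc")
        # textbook paired t: t = mean(d) / (sd(d)/sqrt(n))
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_mismatched_case_sets_raise(self, rng):
        r1 = self._report(rng.uniform(size=4))
        r2 = self._report(rng.uniform(size=5))
        with pytest.raises(ValueError, match="case ids"):
            paired_compare(r1, r2, "dsc")
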