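"""Metrics against closed forms and an exhaustive PR-staircase oracle."""

import numpy as np
import pytest

from amsdet import evalx as E
from conftest import seeded


class TestIoU:
    def test_identical_boxes(self):
        assert E.iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert E.iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_reference_value_one_seventh(self):
        assert E.iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_symmetry_and_bounds(self):
        rng = seeded(0)
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4)).take([0, 1, 2, 3])
            a = (a[0], a[2], a[1], a[3])
            b = np.sort(rng.uniform(0, 10, 4))
            b = (b[0], b[2], b[1], b[3])
            va, vb = E.iou(a, b), E.iou(b, a)
            assert va == pytest.approx(vb)
            assert 0.0 <= va <= 1.0

    def test_degenerate_box(self):
        assert E.iou((1, 1, 1, 1), (0, 0, 2, 2)) == 0.0


class TestPrecisionRecall:
    def test_direct_arithmetic(self):
        m = E.MatchResult(np.array([True] * 8 + [False] * 2), 8,
                          np.linspace(1, 0.1, 10))
        p, r = E.precision_recall(m)
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(1.0)

    def test_no_detections_convention(self):
        m = E.MatchResult(np.zeros(0, bool), 5, np.zeros(0))
        p, r = E.precision_recall(m)
        assert (p, r) == (0.0, 0.0)

    def test_hand_counts_on_random_sets(self):
        rng = seeded(1)
        for _ in range(10):
            n = int(rng.integers(1, 12))
            flags = rng.random(n) > 0.5
            n_gt = int(flags.sum() + rng.integers(0, 4))
            m = E.MatchResult(flags, n_gt, np.linspace(1, 0.1, n))
            p, r = E.precision_recall(m)
            tp = flags.sum()
            assert p == pytest.approx(tp / n)
            assert r == pytest.approx(tp / n_gt if n_gt else 0.0)


def staircase_ap_oracle(dets, gts, thr):
    """Exhaustive independent AP: greedy match in confidence order, full PR
    staircase, interpolated envelope sampled at 101 recall points."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    gt_used = [False] * len(gts)
    tps = []
    for i in order:
        img, conf, box = dets[i]
        best, best_v = -1, thr
        for j, (gimg, gbox) in enumerate(gts):
            if gimg != img or gt_used[j]:
                continue
            v = E.iou(box, gbox)
            if v >= best_v:
                best, best_v = j, v
        if best >= 0:
            gt_used[best] = True
            tps.append(1)
        else:
            tps.append(0)
    if not gts:
        return float("nan")
    ps, rs = [], []
    tp = fp = 0
    for f in tps:
        tp += f
        fp += 1 - f
        ps.append(tp / (tp + fp))
        rs.append(tp / len(gts))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        vals = [p for p, rr in zip(ps, rs) if rr >= r]
        total += max(vals) if vals else 0.0
    return total / 101


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        dets = [(0, 0.9, (0, 0, 4, 4))]
        gts = [(0, (0, 0, 4, 4))]
        assert E.average_precision(dets, gts, 0.5) == pytest.approx(1.0)

    def test_non_overlapping_detection(self):
        dets = [(0, 0.9, (10, 10, 12, 12))]
        gts = [(0, (0, 0, 4, 4))]
        assert E.average_precision(dets, gts, 0.5) == 0.0

    def test_hand_listed_staircase(self):
        """3 GT / 4 detections with chosen scores and overlaps equals the
        staircase oracle."""
        gts = [(0, (0, 0, 10, 10)), (0, (20, 0, 30, 10)), (1, (0, 0, 10, 10))]
        dets = [
            (0, 0.95, (0, 0, 10, 10)),     # TP
            (0, 0.90, (0, 0, 10, 10)),     # duplicate -> FP
            (0, 0.85, (20, 1, 30, 11)),    # TP (IoU ~ 0.8)
            (1, 0.80, (50, 50, 60, 60)),   # FP, misses image-1 gt
        ]
        got = E.average_precision(dets, gts, 0.5)
        want = staircase_ap_oracle(dets, gts, 0.5)
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("i", range(50))
    def test_random_toy_sets_match_oracle(self, i):
        rng = seeded(2000 + i)
        n_gt = int(rng.integers(0, 10))
        n_det = int(rng.integers(0, 10))
        gts, dets = [], []
        for _ in range(n_gt):
            x, y = rng.uniform(0, 20, 2)
            w, h = rng.uniform(2, 8, 2)
            gts.append((int(rng.integers(0, 2)), (x, y, x + w, y + h)))
        for _ in range(n_det):
            x, y = rng.uniform(0, 20, 2)
            w, h = rng.uniform(2, 8, 2)
            dets.append((int(rng.integers(0, 2)), float(rng.random()),
                         (x, y, x + w, y + h)))
        for thr in (0.3, 0.5, 0.75):
            got = E.average_precision(dets, gts, thr)
            want = staircase_ap_oracle(dets, gts, thr)
            if np.isnan(want):
                assert np.isnan(got) or got == 0.0
            else:
                assert got == pytest.approx(want, abs=1e-5)

    def test_permutation_invariance(self):
        rng = seeded(3)
        gts = [(0, (i * 10, 0, i * 10 + 5, 5)) for i in range(5)]
        dets = [(0, float(rng.random()), (i * 10 + 1, 0, i * 10 + 6, 5))
                for i in range(5)]
        base = E.average_precision(dets, gts, 0.5)
        for _ in range(5):
            rng.shuffle(dets)
            assert E.average_precision(list(dets), gts, 0.5) == pytest.approx(base)

    def test_monotone_in_threshold(self):
        rng = seeded(4)
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 28, 30))]
        dets = [(0, 0.9, (1, 1, 10, 11)), (0, 0.7, (21, 20, 30, 30))]
        aps = [E.average_precision(dets, gts, t) for t in E.IOU_THRESHOLDS]
        assert all(b <= a + 1e-9 for a, b in zip(aps, aps[1:]))


class TestMapSuite:
    def test_perfect_detections(self):
        gts, dets = [], []
        for img in range(3):
            for k in range(2):
                box = (10 * k, 0, 10 * k + 8, 8)
                gts.append((img, k, box))
                dets.append((img, k, 0.9, box))
        rep = E.map_suite(dets, gts, 13)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)

    def test_iou_point_six_gives_three_tenths(self):
        """Detections at IoU exactly 0.6 pass thresholds 0.50/0.55/0.60 only,
        so mAP50:95 = 3/10."""
        gts, dets = [], []
        for img in range(4):
            gts.append((img, 0, (0, 0, 10, 10)))
            dets.append((img, 0, 0.9, (0, 2.5, 10, 12.5)))  # IoU = 7.5/12.5
        rep = E.map_suite(dets, gts, 1)
        assert E.iou((0, 0, 10, 10), (0, 2.5, 10, 12.5)) == pytest.approx(0.6)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(0.3)

    def test_undetected_class_halves_map(self):
        gts = [(0, 0, (0, 0, 10, 10)), (0, 1, (20, 20, 30, 30))]
        dets = [(0, 0, 0.9, (0, 0, 10, 10))]
        rep = E.map_suite(dets, gts, 2)
        assert rep.map50 == pytest.approx(0.5)

    def test_map5095_never_exceeds_map50(self):
        rng = seeded(5)
        for i in range(10):
            gts, dets = [], []
            for _ in range(int(rng.integers(1, 8))):
                x, y = rng.uniform(0, 20, 2)
                gts.append((0, int(rng.integers(0, 3)), (x, y, x + 5, y + 5)))
            for _ in range(int(rng.integers(0, 8))):
                x, y = rng.uniform(0, 20, 2)
                dets.append((0, int(rng.integers(0, 3)), float(rng.random()),
                             (x, y, x + 5, y + 5)))
            rep = E.map_suite(dets, gts, 3)
            assert rep.map50_95 <= rep.map50 + 1e-9

    def test_unknown_class_rejected(self):
        from amsdet.errors import InputError
        with pytest.raises(InputError):
            E.map_suite([(0, 7, 0.9, (0, 0, 1, 1))], [], 3)


def brute_force_confusion(dets, gts, nc, iou_thr, conf_thr):
    m = np.zeros((nc + 1, nc + 1), int)
    imgs = {d[0] for d in dets} | {g[0] for g in gts}
    for img in imgs:
        dd = sorted([d for d in dets if d[0] == img and d[2] >= conf_thr],
                    key=lambda d: -d[2])
        gg = [g for g in gts if g[0] == img]
        taken = set()
        matched = set()
        for di, d in enumerate(dd):
            cands = [(E.iou(d[3], g[2]), j) for j, g in enumerate(gg) if j not in taken]
            cands = [c for c in cands if c[0] >= iou_thr]
            if cands:
                _, j = max(cands)
                taken.add(j)
                matched.add(di)
                m[gg[j][1], d[1]] += 1
        for j, g in enumerate(gg):
            if j not in taken:
                m[g[1], nc] += 1
        for di, d in enumerate(dd):
            if di not in matched:
                m[nc, d[1]] += 1
    return m


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        gts = [(0, c, (c * 10, 0, c * 10 + 8, 8)) for c in range(3)]
        dets = [(0, c, 0.9, (c * 10, 0, c * 10 + 8, 8)) for c in range(3)]
        m = E.confusion_matrix(dets, gts, 3)
        assert np.all(m[:3, :3] == np.eye(3, dtype=int))
        assert m[3].sum() == 0 and m[:, 3].sum() == 0

    def test_single_misclassification(self):
        gts = [(0, 0, (0, 0, 10, 10))]
        dets = [(0, 1, 0.9, (0, 0, 10, 10))]
        m = E.confusion_matrix(dets, gts, 2)
        want = np.zeros((3, 3), int)
        want[0, 1] = 1
        np.testing.assert_array_equal(m, want)

    def test_row_sums_equal_gt_totals(self):
        rng = seeded(6)
        gts = [(int(rng.integers(0, 3)), int(rng.integers(0, 3)),
                tuple(np.sort(rng.uniform(0, 20, 2)).tolist() * 2)) for _ in range(10)]
        gts = [(i, c, (x, y, x + 5, y + 5)) for (i, c, (x, y, _, _)) in gts]
        dets = []
        m = E.confusion_matrix(dets, gts, 3)
        for c in range(3):
            assert m[c].sum() == sum(1 for _, gc, _ in gts if gc == c)

    @pytest.mark.parametrize("i", range(10))
    def test_matches_brute_force(self, i):
        rng = seeded(3000 + i)
        gts, dets = [], []
        for _ in range(int(rng.integers(0, 8))):
            x, y = rng.uniform(0, 30, 2)
            gts.append((int(rng.integers(0, 2)), int(rng.integers(0, 3)),
                        (x, y, x + rng.uniform(3, 8), y + rng.uniform(3, 8))))
        for _ in range(int(rng.integers(0, 8))):
            x, y = rng.uniform(0, 30, 2)
            dets.append((int(rng.integers(0, 2)), int(rng.integers(0, 3)),
                         float(rng.random()),
                         (x, y, x + rng.uniform(3, 8), y + rng.uniform(3, 8))))
        got = E.confusion_matrix(dets, gts, 3, 0.45, 0.25)
        want = brute_force_confusion(dets, gts, 3, 0.45, 0.25)
        np.testing.assert_array_equal(got, want)

    def test_normalised_rows(self):
        m = np.array([[2, 2], [0, 0]])
        n = E.normalize_confusion(m)
        np.testing.assert_allclose(n[0], [0.5, 0.5])
        np.testing.assert_allclose(n[1], [0, 0])
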