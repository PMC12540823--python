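"""Metric suite vs brute-force per-pixel and all-pairs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mambaseg.metrics import (
    ConfusionCounts,
    SurfaceSet,
    confusion_counts,
    evaluate_pair,
    metric_table,
    miou,
    overlap_metrics,
    surface_distances,
    surface_extract,
)


def _rand_mask(rng, shape=(8, 8), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)


class TestConfusion:
    def test_equal_and_complement(self, rng):
        m = _rand_mask(rng)
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0 and c.tp == int(m.sum())
        cc = confusion_counts(1 - m, m)
        assert cc.tp == cc.tn == 0

    def test_against_per_pixel_loop(self, rng):
        pred, gt = _rand_mask(rng), _rand_mask(rng)
        c = confusion_counts(pred, gt)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                p, g = pred[i, j], gt[i, j]
                tp += p and g
                fp += p and not g
                fn += (not p) and g
                tn += (not p) and (not g)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 64


class TestOverlap:
    def test_hand_values(self):
        recall, precision, f1, dsc = overlap_metrics(ConfusionCounts(3, 1, 2, 10))
        assert recall == pytest.approx(0.6)
        assert precision == pytest.approx(0.75)
        assert dsc == pytest.approx(6 / 9)
        assert f1 == pytest.approx(dsc)
        r2, p2, _, _ = overlap_metrics(ConfusionCounts(8, 0, 2, 0))
        assert (r2, p2) == (pytest.approx(0.8), 1.0)

    def test_perfect_prediction(self):
        assert overlap_metrics(ConfusionCounts(5, 0, 0, 5)) == (1.0, 1.0, 1.0, 1.0)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_dsc_equals_f1_and_range(self, tp, fp, fn):
        recall, precision, f1, dsc = overlap_metrics(ConfusionCounts(tp, fp, fn, 5))
        assert abs(dsc - f1) < 1e-12
        for v in (recall, precision, f1, dsc):
            assert 0.0 <= v <= 1.0


class TestMiou:
    def test_identity_and_disjoint(self, rng):
        m = _rand_mask(rng)
        assert miou(m, m) == 1.0
        pred = np.zeros((4, 4), int)
        pred[0, 0] = 1
        gt = np.zeros((4, 4), int)
        gt[3, 3] = 1
        # fg IoU 0; bg IoU 14/16
        assert miou(pred, gt) == pytest.approx((0 + 14 / 16) / 2)

    def test_against_brute_force_tally(self, rng):
        pred, gt = _rand_mask(rng), _rand_mask(rng)
        ious = []
        for cls in (0, 1):
            inter = sum((pred[i, j] == cls) and (gt[i, j] == cls)
                        for i in range(8) for j in range(8))
            union = sum((pred[i, j] == cls) or (gt[i, j] == cls)
                        for i in range(8) for j in range(8))
            if union:
                ious.append(inter / union)
        assert miou(pred, gt) == pytest.approx(np.mean(ious))

    def test_labels_out_of_range(self):
        with pytest.raises(ValueError):
            miou(np.array([[2]]), np.array([[0]]), k=1)


class TestSurfaces:
    def test_single_pixel_and_square_perimeter(self):
        m = np.zeros((5, 5), int)
        m[2, 2] = 1
        assert len(surface_extract(m)) == 1
        sq = np.zeros((6, 6), int)
        sq[1:5, 1:5] = 1
        pts = surface_extract(sq)
        assert len(pts) == 12  # 4x4 square: all but the 2x2 interior
        assert len(surface_extract(np.zeros((4, 4), int))) == 0

    def test_hand_distances(self):
        a = SurfaceSet(np.array([[0.0, 0.0]]), (1, 1))
        b = SurfaceSet(np.array([[3.0, 4.0]]), (1, 1))
        assert surface_distances(a, b) == (5.0, 5.0, 5.0, 5.0)
        a = SurfaceSet(np.array([[0.0, 0.0], [1.0, 0.0]]), (1, 1))
        b = SurfaceSet(np.array([[0.0, 0.0], [0.0, 3.0]]), (1, 1))
        asd_ab, asd_ba, assd, hd = surface_distances(a, b)
        assert (asd_ab, asd_ba, assd, hd) == (0.5, 1.5, 1.0, 3.0)

    def test_against_all_pairs_oracle(self, rng):
        am, bm = _rand_mask(rng, (10, 10)), _rand_mask(rng, (10, 10))
        sa, sb = surface_extract(am), surface_extract(bm)
        asd_ab, asd_ba, assd, hd = surface_distances(sa, sb)
        d = np.sqrt(((sa.points[:, None] - sb.points[None]) ** 2).sum(-1))
        assert asd_ab == pytest.approx(d.min(axis=1).mean())
        assert asd_ba == pytest.approx(d.min(axis=0).mean())
        assert assd == pytest.approx(0.5 * (d.min(1).mean() + d.min(0).mean()))
        assert hd == pytest.approx(max(d.min(1).max(), d.min(0).max()))

    def test_symmetry_and_ordering(self, rng):
        am, bm = _rand_mask(rng, (12, 12)), _rand_mask(rng, (12, 12))
        sa, sb = surface_extract(am), surface_extract(bm)
        _, _, assd1, hd1 = surface_distances(sa, sb)
        _, _, assd2, hd2 = surface_distances(sb, sa)
        assert assd1 == pytest.approx(assd2)
        assert hd1 == pytest.approx(hd2)
        assert hd1 >= assd1 >= 0

    def test_distances_scale_with_spacing(self, rng):
        am, bm = _rand_mask(rng), _rand_mask(rng)
        r1 = evaluate_pair(am, bm, spacing=(1.0, 1.0))
        r2 = evaluate_pair(am, bm, spacing=(2.0, 2.0))
        assert r2.assd_mm == pytest.approx(2 * r1.assd_mm)
        assert r2.hd_mm == pytest.approx(2 * r1.hd_mm)


class TestEvaluatePair:
    def test_perfect(self, rng):
        m = _rand_mask(rng)
        r = evaluate_pair(m, m)
        assert (r.dsc, r.precision, r.recall, r.f1, r.miou) == (1, 1, 1, 1, 1)
        assert r.assd_mm == 0.0 and r.hd_mm == 0.0

    def test_both_empty_convention(self):
        r = evaluate_pair(np.zeros((4, 4)), np.zeros((4, 4)))
        assert r.dsc == 1.0 and r.assd_mm == 0.0

    def test_one_empty_is_inf_with_warning(self, rng):
        r = evaluate_pair(np.zeros((6, 6)), _rand_mask(rng, (6, 6), p=0.6))
        assert r.dsc == 0.0
        assert np.isinf(r.assd_mm) and np.isinf(r.hd_mm)
        assert r.surface_warning

    def test_composition_matches_individual_oracles(self, rng):
        pred, gt = _rand_mask(rng, (9, 9)), _rand_mask(rng, (9, 9))
        r = evaluate_pair(pred, gt, spacing=(1.0, 1.0))
        c = confusion_counts(pred, gt)
        recall, precision, f1, dsc = overlap_metrics(c)
        assert (r.recall, r.precision, r.f1, r.dsc) == (recall, precision, f1, dsc)
        assert r.miou == pytest.approx(miou(pred, gt))
        _, _, assd, hd = surface_distances(surface_extract(pred), surface_extract(gt))
        assert (r.assd_mm, r.hd_mm) == (assd, hd)


def test_metric_table_has_summary_rows(rng):
    reports = {f"c{i}": evaluate_pair(_rand_mask(rng), _rand_mask(rng)) for i in range(3)}
    df = metric_table(reports)
    assert list(df.index[-2:]) == ["mean", "sd"]
    assert "dsc" in df.columns
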