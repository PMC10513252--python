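"""Evaluation metrics: nucleotide confusion (against a boolean-mask oracle),
PR sweeps, parity R^2, interpolated AP, distances and track plots."""

import numpy as np
import pytest

from retrodetect import evaluate as ev
from retrodetect.labels import DomainAnnotation
from retrodetect.postprocess import Interval
from retrodetect.simulate import COPIA, GYPSY


def dom(start, end, prob=1.0, source="w", dtype="GAG", lineage="TAT"):
    return DomainAnnotation(source, start, end - start, dtype, lineage, prob)


def oracle_nms(domains, iou_threshold):
    """Independent greedy NMS reimplementation (same tie-breaks)."""
    pool = sorted(domains, key=lambda d: (-d.presence_prob, d.start, -d.length))
    kept = []
    while pool:
        best = pool.pop(0)
        kept.append(best)
        rest = []
        for d in pool:
            inter = min(best.end, d.end) - max(best.start, d.start)
            if inter > 0:
                union = (best.end - best.start) + (d.end - d.start) - inter
                if inter / union > iou_threshold:
                    continue
            rest.append(d)
        pool = rest
    return sorted(kept, key=lambda d: d.start)


def mask_confusion(pred, truth, total_len):
    """Independent nucleotide-confusion oracle via boolean coverage masks."""
    pm = np.zeros(total_len, dtype=bool)
    tm = np.zeros(total_len, dtype=bool)
    for iv in pred:
        pm[iv.start : iv.end] = True
    for iv in truth:
        tm[iv.start : iv.end] = True
    return (
        int((pm & tm).sum()),
        int((pm & ~tm).sum()),
        int((~pm & tm).sum()),
        int((~pm & ~tm).sum()),
    )


class TestNucleotideConfusion:
    def test_half_overlap_example(self):
        cc = ev.nucleotide_confusion([Interval(0, 100)], [Interval(50, 150)], 1_000)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (50, 50, 50, 850)
        assert cc.precision == cc.recall == 0.5

    def test_identical_sets(self):
        cc = ev.nucleotide_confusion([Interval(10, 60)], [Interval(10, 60)], 100)
        assert cc.fp == cc.fn == 0 and cc.tp == 50

    def test_empty_predictions(self):
        cc = ev.nucleotide_confusion([], [Interval(0, 100)], 1_000)
        assert (cc.tp, cc.fp, cc.fn) == (0, 0, 100)
        assert cc.precision is None  # undefined, not zero

    def test_double_covered_bases_count_once(self):
        cc = ev.nucleotide_confusion(
            [Interval(0, 100), Interval(50, 150)], [Interval(0, 150)], 200
        )
        assert cc.tp == 150 and cc.fp == 0

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError):
            ev.nucleotide_confusion([Interval(0, 200)], [], 100)

    def test_matches_mask_oracle_and_conservation(self, rng):
        """Sweep-line counts equal brute-force mask counts; tp+fp and tp+fn
        equal the covered lengths of the merged inputs."""
        for _ in range(50):
            total = 2_000
            def rand_ivs():
                n = int(rng.integers(0, 8))
                out = []
                for s in rng.integers(0, total - 100, n):
                    out.append(Interval(int(s), int(s) + int(rng.integers(1, 100))))
                return out
            pred, truth = rand_ivs(), rand_ivs()
            cc = ev.nucleotide_confusion(pred, truth, total)
            assert (cc.tp, cc.fp, cc.fn, cc.tn) == mask_confusion(pred, truth, total)
            assert cc.tp + cc.fp == sum(iv.length for iv in ev.merge_intervals(pred))
            assert cc.tp + cc.fn == sum(iv.length for iv in ev.merge_intervals(truth))
            assert cc.tp + cc.fp + cc.fn + cc.tn == total


class TestPRCurve:
    def _raw(self, rng, n=30, total=5_000):
        return [
            dom(int(s), int(s) + int(rng.integers(50, 300)),
                float(np.round(rng.random(), 3)))
            for s in rng.integers(0, total - 300, n)
        ]

    def test_recall_non_increasing_in_threshold(self, rng):
        truth = [Interval(100, 400), Interval(1_000, 1_300), Interval(3_000, 3_200)]
        for _ in range(10):
            raw = self._raw(rng)
            curve = ev.pr_curve(raw, truth, 5_000, list(np.linspace(0, 1, 21)))
            recalls = [p.recall for p in curve.points if p.recall is not None]
            assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_keep_none_recall_zero(self):
        truth = [Interval(0, 100)]
        curve = ev.pr_curve([dom(0, 100, 0.5)], truth, 1_000, [0.0, 0.99])
        assert curve.points[-1].recall == 0.0
        assert curve.points[-1].precision is None

    def test_perfect_detector_best_threshold(self):
        """With exact calls at probability 0.9, every threshold below 0.9
        gives product 1; the argmax tie-break picks the lowest."""
        truth = [Interval(100, 400)]
        curve = ev.pr_curve([dom(100, 400, 0.9)], truth, 1_000, [0.1, 0.5, 0.95])
        assert curve.best_threshold == 0.1

    def test_best_threshold_matches_exhaustive_search(self, rng):
        """Argmax of precision x recall equals an independent brute-force
        sweep built on the mask-confusion oracle."""
        truth = [Interval(200, 500), Interval(1_500, 1_900), Interval(3_200, 3_600)]
        thresholds = list(np.linspace(0, 1, 21))
        for _ in range(5):
            raw = self._raw(rng)
            curve = ev.pr_curve(raw, truth, 5_000, thresholds)
            best, best_prod = None, -1.0
            for thr in thresholds:
                kept = oracle_nms([d for d in raw if d.presence_prob > thr], 0.1)
                tp, fp, fn, _ = mask_confusion(
                    [Interval(d.start, d.end) for d in kept], truth, 5_000
                )
                if tp + fp == 0 or tp + fn == 0:
                    continue
                prod = (tp / (tp + fp)) * (tp / (tp + fn))
                if prod > best_prod:
                    best_prod, best = prod, thr
            assert curve.best_threshold == best


class TestParity:
    def test_identical_lists_perfect_r2(self):
        doms = [dom(100, 400), dom(1_000, 1_200), dom(2_000, 2_500)]
        par = ev.parity(doms, doms)
        assert par.r_squared == 1.0
        assert par.fp_starts == () and par.fn_starts == ()

    def test_unmatched_prediction_is_fp(self):
        par = ev.parity([dom(100, 400), dom(3_000, 3_100)], [dom(120, 420)])
        assert par.fp_starts == (3_000,)

    def test_unmatched_truth_is_fn(self):
        par = ev.parity([dom(100, 400)], [dom(120, 420), dom(2_000, 2_300)])
        assert par.fn_starts == (2_000,)

    def test_r2_closed_form(self):
        """Three matched pairs with +-10 bp start errors: R^2 must equal the
        hand-computed 1 - SSres/SStot."""
        truth = [dom(100, 150), dom(200, 250), dom(300, 350)]
        pred = [dom(110, 160), dom(190, 240), dom(310, 360)]
        par = ev.parity(pred, truth)
        assert len(par.pairs) == 3
        ss_res = 3 * 10**2
        ss_tot = 2 * 100**2
        assert par.r_squared == pytest.approx(1 - ss_res / ss_tot)

    def test_r2_decreases_with_noise(self, rng):
        truth = [dom(int(s), int(s) + 100) for s in range(500, 5_000, 500)]
        noisy = [dom(int(d.start + rng.integers(-40, 41)), d.start + 100 + 40) for d in truth]
        par = ev.parity(noisy, truth)
        assert par.r_squared is not None and par.r_squared < 1.0


class TestCocoMap:
    def test_all_correct_single_class(self):
        truth = [dom(0, 100), dom(500, 600)]
        preds = [dom(0, 100, 0.9), dom(500, 600, 0.8)]
        res = ev.coco_map(preds, truth, "type")
        assert res.per_class["GAG"] == pytest.approx(1.0)
        assert res.mean_ap == pytest.approx(1.0)

    def test_class_without_predictions_scores_zero(self):
        truth = [dom(0, 100, dtype="GAG"), dom(500, 600, dtype="RT")]
        preds = [dom(0, 100, 0.9, dtype="GAG")]
        res = ev.coco_map(preds, truth, "type")
        assert res.per_class["RT"] == 0.0
        assert res.mean_ap == pytest.approx((1.0 + 0.0) / 2)

    def test_hand_computed_five_prediction_instance(self):
        """Fixed instance tabulated by hand: flags (TP,FP,TP,FP,TP) over 3
        truths give 101-point AP = (34*1 + 33*(2/3) + 34*0.6)/101."""
        truth = [dom(0, 100), dom(200, 300), dom(400, 500)]
        preds = [
            dom(0, 100, 0.9),      # IoU 1.0 -> TP
            dom(600, 700, 0.8),    # no overlap -> FP
            dom(210, 310, 0.7),    # IoU 90/110 -> TP
            dom(150, 250, 0.6),    # IoU 50/150 < 0.5 -> FP
            dom(400, 500, 0.5),    # IoU 1.0 -> TP
        ]
        res = ev.coco_map(preds, truth, "type")
        expected = (34 * 1.0 + 33 * (2 / 3) + 34 * 0.6) / 101
        assert res.per_class["GAG"] == pytest.approx(expected)

    def test_class_contribution_fractions(self):
        truth = [dom(0, 100, dtype="GAG"), dom(300, 400, dtype="GAG"),
                 dom(600, 700, dtype="RT")]
        res = ev.coco_map([], truth, "type")
        assert res.class_contribution == {"GAG": 2 / 3, "RT": 1 / 3}

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ev.coco_map([], [dom(0, 10, dtype="GAG", lineage="NOPE")], "lineage")

    def test_matches_brute_force_on_random_instances(self, rng):
        """AP equals an independent recomputation (fresh cumulative P/R
        tabulation + 101-point interpolation) on random small instances."""
        for _ in range(30):
            nt, np_ = int(rng.integers(1, 6)), int(rng.integers(0, 10))
            truth = [dom(int(s), int(s) + 100) for s in rng.integers(0, 2_000, nt)]
            preds = [dom(int(s), int(s) + int(rng.integers(50, 150)),
                         float(np.round(rng.random(), 3)))
                     for s in rng.integers(0, 2_000, np_)]
            res = ev.coco_map(preds, truth, "type")
            # brute force
            order = sorted(preds, key=lambda d: (-d.presence_prob, d.start))
            taken = [False] * len(truth)
            flags = []
            for p in order:
                best, bi = None, 0.5
                for j, t in enumerate(truth):
                    if taken[j]:
                        continue
                    inter = min(p.end, t.end) - max(p.start, t.start)
                    if inter <= 0:
                        continue
                    iou = inter / ((p.end - p.start) + (t.end - t.start) - inter)
                    if iou >= bi:
                        best, bi = j, iou
                if best is None:
                    flags.append(False)
                else:
                    taken[best] = True
                    flags.append(True)
            tp = np.cumsum(flags) if flags else np.array([])
            ap = 0.0
            for r in np.linspace(0, 1, 101):
                best_p = 0.0
                for k in range(len(flags)):
                    rec = tp[k] / len(truth)
                    prec = tp[k] / (k + 1)
                    if rec >= r and prec > best_p:
                        best_p = prec
                ap += best_p / 101
            assert res.per_class["GAG"] == pytest.approx(ap)


class TestDetectionF1:
    def test_perfect_predictions(self):
        truth = [dom(0, 100), dom(500, 600)]
        cc = ev.detection_f1(truth, truth)
        assert (cc.tp, cc.fp, cc.fn) == (2, 0, 0) and cc.f1 == 1.0

    def test_classification_ignored(self):
        truth = [dom(0, 100, dtype="GAG")]
        pred = [dom(0, 100, dtype="RT")]
        assert ev.detection_f1(pred, truth).tp == 1


class TestDomainDistances:
    def test_copia_fixture_distances_exact(self):
        domains = [
            dom(1_000, 1_400, dtype="GAG"), dom(1_900, 2_300, dtype="AP"),
            dom(2_500, 2_800, dtype="INT"), dom(3_100, 3_450, dtype="RT"),
            dom(3_450, 3_600, dtype="RH"), dom(3_900, 4_100, dtype="ENV"),
        ]
        ltrs = (Interval(0, 500), Interval(4_800, 5_300))
        table = ev.domain_distances([(COPIA, domains, ltrs)])
        d = table.distances[COPIA]
        assert d["5'-LTR-GAG"] == (500,)
        assert d["GAG-AP"] == (500,)
        assert d["AP-INT"] == (200,)
        assert d["INT-RT"] == (300,)
        assert d["RT-RH"] == (0,)       # adjacent domains -> distance 0
        assert d["RH-NEXT"] == (300,)   # RH to the following ENV
        assert d["PRE-LTR-3'"] == (700,)
        assert table.n_skipped == 0

    def test_gypsy_pair_labels(self):
        domains = [
            dom(100, 200, dtype="GAG"), dom(300, 400, dtype="AP"),
            dom(600, 700, dtype="RT"), dom(800, 900, dtype="RH"),
            dom(1_000, 1_100, dtype="INT"),
        ]
        table = ev.domain_distances([(GYPSY, domains, None)])
        d = table.distances[GYPSY]
        assert d["AP-RT"] == (200,) and d["RH-INT"] == (100,)
        # no LTR coordinates -> PRE-LTR-3' omitted; no domain after INT
        assert d["PRE-LTR-3'"] == () and d["INT-NEXT"] == ()

    def test_out_of_order_element_skipped(self):
        domains = [dom(100, 200, dtype="RT"), dom(300, 400, dtype="GAG")]
        table = ev.domain_distances([(COPIA, domains, None)])
        assert table.n_skipped == 1

    def test_means(self):
        t1 = [dom(0, 100, dtype="GAG"), dom(200, 300, dtype="AP")]
        t2 = [dom(0, 100, dtype="GAG"), dom(400, 500, dtype="AP")]
        table = ev.domain_distances([(COPIA, t1, None), (COPIA, t2, None)])
        assert table.means()[COPIA]["GAG-AP"] == pytest.approx(200.0)


class TestPlotTracks:
    def test_empty_canvas(self, tmp_path):
        fig = ev.plot_tracks([], [], 50_000, tmp_path / "t.png")
        assert (tmp_path / "t.png").exists()

    def test_segments_drawn_and_colors_distinct(self, tmp_path):
        assert len(set(ev.TYPE_COLORS.values())) == 6
        ev.plot_tracks([dom(100, 400)], [dom(120, 420)], 5_000, tmp_path / "t.png")
        assert (tmp_path / "t.png").stat().st_size > 0
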