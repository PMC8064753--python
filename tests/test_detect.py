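"""Detection-pipeline tests: preprocessing contracts, ground-truth
recovery, size filtering, F1 scoring, and threshold calibration."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import granulekit as gk
from granulekit.detect import (
    GRANULE_PARAMS,
    DetectionParams,
    GranuleSet,
    _empty_particles,
    detect_particles,
    preprocess,
)
from granulekit.image import ImageField

from conftest import match_to_truth


def make_granule_set(rects, shape=(64, 64), resize_factor=2):
    """Hand-built GranuleSet from (row0, col0, height, width) rectangles."""
    mask = np.zeros(shape, dtype=np.int64)
    rows = []
    for i, (r0, c0, h, w) in enumerate(rects, start=1):
        mask[r0 : r0 + h, c0 : c0 + w] = i
        rows.append(
            (
                i,
                h * w,
                r0 + (h - 1) / 2,
                c0 + (w - 1) / 2,
                r0 + (h - 1) / 2,
                c0 + (w - 1) / 2,
                np.nan,
                r0,
                c0,
                r0 + h,
                c0 + w,
            )
        )
    particles = pd.DataFrame(
        rows,
        columns=[
            "id",
            "area_px",
            "centroid_row",
            "centroid_col",
            "wcentroid_row",
            "wcentroid_col",
            "max_raw_intensity",
            "bbox_min_row",
            "bbox_min_col",
            "bbox_max_row",
            "bbox_max_col",
        ],
    )
    return GranuleSet(label_mask=mask, particles=particles, resize_factor=resize_factor)


class TestPreprocess:
    def test_shape_contract(self):
        fld = ImageField(np.random.default_rng(0).uniform(0, 100, (64, 64)))
        det = preprocess(fld)
        assert det.shape == (128, 128)
        assert det.data.max() == pytest.approx(65535.0)
        assert det.data.min() == pytest.approx(0.0)

    def test_constant_image_degenerates_to_zero(self):
        fld = ImageField(np.full((32, 32), 7.0))
        with pytest.warns(UserWarning, match="constant image"):
            det = preprocess(fld)
        assert not det.data.any()
        assert detect_particles(det).n_particles == 0

    def test_argmax_maps_back_to_granule_center(self):
        spec = gk.random_scene(1, seed=2, amplitude_range=(300.0, 300.0))
        fld, gt = gk.generate_field(spec, seed=2)
        det = preprocess(fld)
        r, c = np.unravel_index(np.argmax(det.data), det.shape)
        true = gt.granules[0].center
        assert abs(r / 2 - true[0]) <= 1 and abs(c / 2 - true[1]) <= 1


class TestDetectParticles:
    def test_blank_field_yields_zero_particles(self):
        fld = ImageField(np.zeros((64, 64)))
        with pytest.warns(UserWarning, match="constant image"):
            gset = detect_particles(preprocess(fld))
        assert gset.n_particles == 0

    def test_equal_granules_recovered_at_default_threshold(self, equal_amp_field):
        fld, gt = equal_amp_field
        gset = detect_particles(preprocess(fld))
        assert gset.n_particles == len(gt.granules)
        true = np.array([g.center for g in gt.granules])
        for c in gset.raw_centroids():
            # within 1 detection px = 0.5 raw px of some true center
            assert np.hypot(true[:, 0] - c[0], true[:, 1] - c[1]).min() <= 0.5

    @pytest.mark.parametrize("thresholds", [(0.6234, 0.8), (0.3, 0.5), (0.2, 0.9)])
    def test_count_monotone_in_threshold(self, equal_amp_field, thresholds):
        fld, _ = equal_amp_field
        det = preprocess(fld)
        lo, hi = thresholds
        n_lo = detect_particles(det, replace(GRANULE_PARAMS, relative_threshold=lo)).n_particles
        n_hi = detect_particles(det, replace(GRANULE_PARAMS, relative_threshold=hi)).n_particles
        assert n_hi <= n_lo

    def test_count_monotone_in_min_size(self, equal_amp_field):
        fld, _ = equal_amp_field
        det = preprocess(fld)
        counts = [
            detect_particles(det, replace(GRANULE_PARAMS, min_size=m)).n_particles
            for m in (1, 4, 10, 30)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        spec = gk.synthgen.SceneSpec(
            field_shape=(128, 128),
            cells=[gk.CellRing((64.0, 64.0), 18.0, 45.0)],
        )
        spec.granules = [
            gk.GranuleTruth(center=(64.0, 94.0), amplitude=300.0),
            gk.GranuleTruth(center=(40.0, 64.0), amplitude=300.0),
        ]
        fld, _ = gk.generate_field(spec, seed=0)
        shifted = ImageField(np.roll(fld.data, (3, 5), axis=(0, 1)))
        a = gk.detect_and_measure(fld).raw_centroids()
        b = gk.detect_and_measure(shifted).raw_centroids()
        assert len(a) == len(b) == 2
        a = a[np.lexsort(a.T)]
        b = b[np.lexsort(b.T)]
        np.testing.assert_allclose(b - a, [[3, 5], [3, 5]], atol=0.01)


class TestFilterBySize:
    def test_thirteen_pixel_exclusion(self):
        gset = make_granule_set([(2, 2, 2, 2), (10, 10, 3, 4), (20, 20, 1, 13), (30, 30, 5, 8)])
        kept = gk.filter_by_size(gset, 13)
        assert sorted(kept.particles["area_px"]) == [13, 40]
        assert kept.particles["id"].tolist() == [1, 2]  # labels re-compacted
        assert set(np.unique(kept.label_mask)) == {0, 1, 2}

    def test_exclusion_one_is_identity(self):
        gset = make_granule_set([(2, 2, 2, 2), (30, 30, 5, 8)])
        kept = gk.filter_by_size(gset, 1)
        assert kept.n_particles == 2
        np.testing.assert_array_equal(kept.label_mask, gset.label_mask)

    def test_exclusion_above_max_empties(self):
        gset = make_granule_set([(2, 2, 2, 2), (30, 30, 5, 8)])
        kept = gk.filter_by_size(gset, 41)
        assert kept.n_particles == 0
        assert not kept.label_mask.any()


class TestMeasureMaxOnRaw:
    def test_uniform_raw_gives_uniform_max(self):
        gset = make_granule_set([(2, 2, 4, 4), (20, 20, 4, 4)])
        raw = ImageField(np.full((32, 32), 123.0))
        out = gk.measure_max_on_raw(gset, raw)
        assert out.particles["max_raw_intensity"].tolist() == [123.0, 123.0]

    def test_noise_free_peak_recovered(self):
        spec = gk.random_scene(1, seed=2, amplitude_range=(300.0, 300.0))
        fld, _ = gk.generate_field(spec, seed=2)
        gset = gk.detect_and_measure(fld)
        assert gset.particles["max_raw_intensity"].iloc[0] == pytest.approx(500.0)

    def test_rank_order_matches_true_amplitudes(self):
        spec = gk.random_scene(20, seed=13, amplitude_range=(150.0, 450.0))
        fld, gt = gk.generate_field(spec, seed=13)
        params = replace(GRANULE_PARAMS, relative_threshold=0.25)
        gset = gk.detect_and_measure(fld, params)
        assert gset.n_particles == 20
        pairs = match_to_truth(gset.raw_centroids(), [g.center for g in gt.granules])
        assert len(pairs) == 20
        measured = gset.particles["max_raw_intensity"].to_numpy()[[i for i, _ in pairs]]
        true_amp = np.array([gt.granules[j].amplitude for _, j in pairs])
        assert np.array_equal(np.argsort(measured), np.argsort(true_amp))

    def test_grid_mismatch_rejected(self):
        gset = make_granule_set([(2, 2, 4, 4)])
        with pytest.raises(ValueError, match="grid mismatch"):
            gk.measure_max_on_raw(gset, ImageField(np.zeros((16, 16))))


class TestF1:
    def test_perfect_detection(self):
        gset = make_granule_set([(r, r, 2, 2) for r in range(2, 42, 5)])
        ann = [((r + 0.5) / 2, (r + 0.5) / 2) for r in range(2, 42, 5)]
        score = gk.f1_against_annotations(gset, ann)
        assert score == (1.0, 1.0, 1.0, 8, 0, 0)

    def test_zero_particles_zero_f1(self):
        gset = GranuleSet(np.zeros((32, 32), np.int64), _empty_particles())
        score = gk.f1_against_annotations(gset, [(3.0, 3.0)])
        assert score.f1 == 0.0 and score.fn == 1

    def test_hand_enumerated_confusion(self):
        # 8 particles, 10 annotations, 6 matched -> P=0.75, R=0.6, F1=2/3
        gset = make_granule_set([(r, r, 2, 2) for r in range(2, 42, 5)])
        ann = [((r + 0.5) / 2, (r + 0.5) / 2) for r in range(2, 32, 5)]  # 6 inside
        ann += [(30.0, 2.0), (2.0, 30.0), (28.0, 5.0), (5.0, 28.0)]  # 4 in background
        score = gk.f1_against_annotations(gset, ann)
        assert score.tp == 6 and score.fp == 2 and score.fn == 4
        assert score.precision == pytest.approx(0.75)
        assert score.recall == pytest.approx(0.6)
        assert score.f1 == pytest.approx(2 / 3)

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_par = int(rng.integers(0, 12))
            rects = []
            taken = set()
            while len(rects) < n_par:
                r0, c0 = rng.integers(0, 56, 2)
                cells = {(r0 + dr, c0 + dc) for dr in range(4) for dc in range(4)}
                if not cells & taken:
                    rects.append((int(r0), int(c0), 3, 3))
                    taken |= {(r, c) for r in range(r0 - 1, r0 + 4) for c in range(c0 - 1, c0 + 4)}
            gset = make_granule_set(rects)
            ann = rng.uniform(0, 29, size=(int(rng.integers(0, 15)), 2))
            score = gk.f1_against_annotations(gset, ann)

            # independent oracle: recompute confusion counts naively
            footprints = {
                int(pid): set(map(tuple, gset.particle_raw_coords(int(pid))))
                for pid in gset.particles["id"]
            }
            cands = []
            cents = {int(pid): cen for pid, cen in zip(gset.particles["id"], gset.raw_centroids())}
            for ai, (r, c) in enumerate(ann):
                px = (int(round(r)), int(round(c)))
                for pid, fp in footprints.items():
                    if px in fp:
                        cands.append((np.hypot(r - cents[pid][0], c - cents[pid][1]), ai, pid))
            cands.sort()
            used_a, used_p = set(), set()
            tp = 0
            for _, ai, pid in cands:
                if ai in used_a or pid in used_p:
                    continue
                used_a.add(ai)
                used_p.add(pid)
                tp += 1
            assert (score.tp, score.fp, score.fn) == (tp, n_par - tp, len(ann) - tp)


class TestCalibration:
    def test_singleton_grid(self, equal_amp_field):
        fld, gt = equal_amp_field
        ann = [[g.center for g in gt.granules]]
        res = gk.calibrate_threshold([fld], ann, [0.6234])
        assert res.best_threshold == 0.6234

    def test_grid_order_invariance(self, equal_amp_field):
        fld, gt = equal_amp_field
        ann = [[g.center for g in gt.granules]]
        grid = [0.2, 0.4, 0.6, 0.8]
        a = gk.calibrate_threshold([fld], ann, grid)
        b = gk.calibrate_threshold([fld], ann, grid[::-1])
        assert a.best_threshold == b.best_threshold
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_matches_brute_force_argmax(self):
        fields, anns = [], []
        for s in range(3):
            spec = gk.random_scene(12, seed=60 + s)
            fld, gt = gk.generate_field(spec, seed=60 + s)
            fields.append(fld)
            anns.append([g.center for g in gt.granules])
        grid = np.round(np.arange(0.1, 0.91, 0.1), 3).tolist()
        res = gk.calibrate_threshold(fields, anns, grid)

        # brute force through the public per-field pipeline
        means = []
        for thr in grid:
            p = replace(GRANULE_PARAMS, relative_threshold=thr)
            scores = [
                gk.f1_against_annotations(detect_particles(preprocess(f, p), p), a).f1
                for f, a in zip(fields, anns)
            ]
            means.append(np.mean(scores))
        best = max(t for t, s in zip(grid, means) if s == max(means))
        assert res.best_threshold == best
        np.testing.assert_allclose(res.table["mean_f1"], means)

    def test_all_zero_returns_largest_with_warning(self):
        blank = ImageField(np.full((32, 32), 5.0))
        with pytest.warns(UserWarning):
            res = gk.calibrate_threshold([blank], [[(5.0, 5.0)]], [0.3, 0.7])
        assert res.best_threshold == 0.7

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            gk.calibrate_threshold([], [], [])
        with pytest.raises(ValueError):
            gk.calibrate_threshold([], [], [1.5])


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(relative_threshold=0.0)
    with pytest.raises(ValueError):
        DetectionParams(min_size=0)
    with pytest.raises(ValueError):
        DetectionParams(size_exclusion=2, min_size=4)
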