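import numpy as np
import pytest

from plateworm.detector import (
    Detection,
    DetectionResult,
    detect,
    match_detections,
    merge_detections,
    overlay,
)
from plateworm.errors import ConfigurationError
from plateworm.metrics import ConfusionCounts
from plateworm.synthetic import SceneConfig, WormAnnotation, render_scene
from plateworm.windows import tile

BLANK_CFG = SceneConfig(image_height=504, image_width=504, n_worms=0,
                        n_scratches=0, n_glyphs=0, n_tape_corners=0, seed=5)
# a 1008-px plate bearing 13 well-separated worms and no distractors
PLATE13_CFG = SceneConfig(image_height=1008, image_width=1008, n_worms=13,
                          n_scratches=0, n_glyphs=0, n_tape_corners=0, seed=4)


@pytest.fixture(scope="module")
def plate13():
    return render_scene(PLATE13_CFG)


class TestDetect:
    def test_blank_plate_yields_no_detections(self, full_model):
        image, _ = render_scene(BLANK_CFG)
        result = detect(image, full_model)
        assert len(result) == 0

    def test_most_worms_found_at_half_overlap(self, full_model, plate13):
        """At the default 50% overlap some worms fall between window
        centers and are missed — the known windowing limitation — but the
        clear majority must be framed."""
        image, annotations = plate13
        counts = match_detections(detect(image, full_model), annotations)
        assert counts.tp >= 8
        assert counts.fp <= 4

    def test_all_worms_covered_at_dense_overlap(self, full_model, plate13):
        """At 75% overlap every window offset is within the training jitter
        of some worm-bearing window, so every worm is framed."""
        image, annotations = plate13
        counts = match_detections(detect(image, full_model, overlap=0.75), annotations)
        assert counts.fn == 0
        assert counts.tp == len(annotations) == 13

    def test_two_runs_identical(self, full_model, plate13):
        image, _ = plate13
        r1 = detect(image, full_model)
        r2 = detect(image, full_model)
        assert r1.detections == r2.detections

    def test_detections_subset_of_tiling(self, full_model, plate13):
        image, _ = plate13
        result = detect(image, full_model)
        grid = tile(1008, 1008, 168, 0.5)
        tiling = {(r, c, r + 168, c + 168) for r, c in grid.offsets}
        assert {d.window for d in result.detections} <= tiling
        windows = [d.window for d in result.detections]
        assert windows == sorted(windows)  # row-major order

    def test_shared_offsets_agree_across_overlaps(self, full_model, plate13):
        """Window offsets present in both the 0%- and 50%-overlap tilings
        get identical decision values — the descriptor depends only on the
        pixels under the window."""
        image, _ = plate13
        r_half = detect(image, full_model, overlap=0.5)
        r_none = detect(image, full_model, overlap=0.0)
        half = {d.window: d.decision_value for d in r_half.detections}
        none = {d.window: d.decision_value for d in r_none.detections}
        shared = set(half) & set(none)
        for w in shared:
            assert half[w] == none[w]
        # and any 0%-tiling positive window must appear positively at 50%
        offsets_half = {(r, c) for r, c in tile(1008, 1008, 168, 0.5).offsets}
        for w in none:
            assert (w[0], w[1]) in offsets_half and w in half

    def test_fingerprint_mismatch_refused(self, full_model, plate13):
        image, _ = plate13
        with pytest.raises(ConfigurationError):
            detect(image, full_model, preprocess_on=False)

    def test_image_smaller_than_window_refused(self, full_model):
        with pytest.raises(ValueError):
            detect(np.zeros((100, 100), dtype=np.uint8), full_model)

    def test_durations_recorded_nonnegative(self, full_model):
        image, _ = render_scene(BLANK_CFG)
        result = detect(image, full_model)
        assert set(result.durations) == {"model_load", "hog", "classify"}
        assert all(v >= 0 for v in result.durations.values())


def _result(windows, shape=(504, 504)):
    return DetectionResult(
        detections=[Detection(window=w, decision_value=1.0) for w in windows],
        config={"image_height": shape[0], "image_width": shape[1],
                "window_size": 168, "overlap_fraction": 0.5},
    )


class TestOverlay:
    def test_empty_result_copies_image(self, rng):
        image = rng.integers(0, 256, size=(504, 504), dtype=np.uint8)
        out = overlay(image, _result([]))
        assert out.shape == (504, 504, 3)
        assert np.array_equal(out[..., 0], image)
        assert np.array_equal(out[..., 1], image)

    def test_source_untouched(self, rng):
        image = rng.integers(0, 256, size=(504, 504), dtype=np.uint8)
        before = image.copy()
        overlay(image, _result([(0, 0, 168, 168)]))
        assert np.array_equal(image, before)

    def test_frames_roundtrip_to_window_coordinates(self):
        image = np.full((504, 504), 200, dtype=np.uint8)
        windows = [(0, 0, 168, 168), (336, 0, 504, 168), (168, 336, 336, 504)]
        out = overlay(image, _result(windows), thickness=2)
        green = (out[..., 1] == 255) & (out[..., 0] == 0) & (out[..., 2] == 0)
        # every perimeter is drawn, nothing else is: the recolored pixel
        # count equals the union of the disjoint 2-px frame bands
        band = 168 * 168 - (168 - 4) * (168 - 4)
        assert int(green.sum()) == len(windows) * band
        for r0, c0, r1, c1 in windows:
            assert green[r0, c0] and green[r1 - 1, c1 - 1]
            assert green[r0 : r0 + 2, c0:c1].all()
            assert not green[r0 + 2 : r1 - 2, c0 + 2 : c1 - 2].any()


class TestMatchDetections:
    def test_empty_scene_empty_result(self):
        counts = match_detections(_result([]), [])
        grid = tile(504, 504, 168, 0.5)
        assert counts == ConfusionCounts(tp=0, fn=0, fp=0, tn=len(grid))

    def test_five_covered_worms_no_spurious_windows(self):
        anns = [
            WormAnnotation(
                centerline=np.array([[r + 20.0, 30.0], [r + 20.0, 60.0]]),
                bounding_box=(r + 10, 20, r + 30, 70),
            )
            for r in range(0, 420, 84)
        ]
        windows = [(r, 0, r + 168, 168) for r in range(0, 420, 84)]
        counts = match_detections(_result(windows), anns)
        assert counts.tp == 5 and counts.fn == 0 and counts.fp == 0

    def test_counts_match_bruteforce_all_pairs(self, full_model, plate13):
        image, annotations = plate13
        result = detect(image, full_model)
        counts = match_detections(result, annotations)

        # independent all-pairs recomputation
        def hit(a, b):
            return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]

        boxes = [a.bounding_box for a in annotations]
        pos = [d.window for d in result.detections]
        tp = sum(any(hit(w, b) for w in pos) for b in boxes)
        fp = sum(not any(hit(w, b) for b in boxes) for w in pos)
        grid = tile(1008, 1008, 168, 0.5)
        neg = [(r, c, r + 168, c + 168) for r, c in grid.offsets
               if (r, c, r + 168, c + 168) not in set(pos)]
        tn = sum(not any(hit(w, b) for b in boxes) for w in neg)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (tp, len(boxes) - tp, fp, tn)


def test_merge_detections_unions_overlapping_windows():
    result = _result([(0, 0, 168, 168), (84, 0, 252, 168), (336, 336, 504, 504)])
    merged = merge_detections(result)
    assert merged == [(0, 0, 252, 168), (336, 336, 504, 504)]
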