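"""Crop proposals, statistics, polygon ROIs, export, dataset layout."""

import csv
import os

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from colonyseg.fixtures import make_training_set
from colonyseg.workflow import (
    export_results,
    load_frames,
    load_training_set,
    polygon_rois,
    propose_crops,
    save_training_set,
    shape_stats,
)


def rects_disjoint(a, b):
    ax, ay, asz = a
    bx, by, bsz = b
    return ax + asz <= bx or bx + bsz <= ax or ay + asz <= by or by + bsz <= ay


class TestProposeCrops:
    def test_large_image_yields_three_disjoint_proposals(self):
        img = np.zeros((2048, 2048), np.uint16)
        props = propose_crops(img, 320, seed=0)
        assert len(props) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert rects_disjoint(props[i].rect, props[j].rect)

    def test_exact_fit_yields_single_full_cover(self):
        props = propose_crops(np.zeros((320, 320)), 320, seed=1)
        assert len(props) == 1
        assert props[0].rect == (0, 0, 320)

    def test_intermediate_width_yields_two(self):
        # 700 px fits two 320-px bands
        props = propose_crops(np.zeros((700, 700)), 320, seed=2)
        assert len(props) == 2
        assert rects_disjoint(props[0].rect, props[1].rect)

    def test_too_large_crop_rejected(self):
        with pytest.raises(ValueError):
            propose_crops(np.zeros((200, 200)), 320, seed=0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_proposals_always_in_bounds_and_disjoint(self, seed):
        img = np.zeros((900, 1100))
        props = propose_crops(img, 256, seed=seed)
        assert len(props) == 3
        for p in props:
            x0, y0, size = p.rect
            assert 0 <= x0 and x0 + size <= 1100
            assert 0 <= y0 and y0 + size <= 900
        for i in range(len(props)):
            for j in range(i + 1, len(props)):
                assert rects_disjoint(props[i].rect, props[j].rect)


class TestShapeStats:
    def test_empty_mask_all_zero(self):
        st_ = shape_stats(np.zeros((16, 16), np.uint16))
        assert st_.cell_count == 0
        assert st_.mean_area == st_.total_area == 0.0
        assert st_.mean_minor_axis == st_.mean_major_axis == 0.0

    def test_rectangle_moments(self):
        """10x4 rectangle: axes from the ellipse with identical normalized
        second central moments; verified against the direct moment formula
        axis = 4 * sqrt(second central moment)."""
        m = np.zeros((20, 20), np.uint16)
        m[5:9, 4:14] = 1  # height 4, width 10
        st_ = shape_stats(m)
        assert st_.cell_count == 1
        assert st_.total_area == 40
        cols = np.arange(4, 14)
        var_x = np.mean((cols - cols.mean()) ** 2)  # discrete central moment
        rows = np.arange(5, 9)
        var_y = np.mean((rows - rows.mean()) ** 2)
        assert st_.mean_major_axis == pytest.approx(4 * np.sqrt(var_x), rel=1e-6)
        assert st_.mean_minor_axis == pytest.approx(4 * np.sqrt(var_y), rel=1e-6)
        assert st_.mean_major_axis > st_.mean_minor_axis

    def test_two_identical_instances(self):
        m = np.zeros((20, 20), np.uint16)
        m[2:6, 2:6] = 1
        m[10:14, 10:14] = 2
        st_ = shape_stats(m)
        assert st_.cell_count == 2
        assert st_.mean_area == 16.0
        assert st_.total_area == 32.0


class TestPolygonRois:
    def test_empty_mask_no_polygons(self):
        assert polygon_rois(np.zeros((8, 8), np.uint16)) == []

    def test_square_polygon_is_closed_with_correct_area(self):
        m = np.zeros((10, 10), np.uint16)
        m[4:7, 4:7] = 1
        polys = polygon_rois(m)
        assert len(polys) == 1
        poly = polys[0]
        assert np.allclose(poly[0], poly[-1])  # closed
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))  # shoelace
        assert abs(area - 9) <= 1.0

    def test_one_polygon_per_instance(self, colony30):
        assert len(polygon_rois(colony30.mask)) == colony30.mask.max()


class TestExport:
    def test_five_artifacts_per_frame(self, small_colony, tmp_path):
        files = export_results([small_colony.image], [small_colony.mask], str(tmp_path))
        tifs = [f for f in files if f.endswith(".tif")]
        csvs = [f for f in files if f.endswith(".csv")]
        assert len(tifs) == 4 and len(csvs) == 1
        with open(csvs[0]) as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == ["frame", "cell_count", "mean_area", "mean_minor_axis", "mean_major_axis", "total_area"]
        assert len(rows) == 2
        assert int(rows[1][1]) == small_colony.mask.max()

    def test_mask_round_trip_is_bit_identical(self, small_colony, tmp_path):
        export_results([small_colony.image], [small_colony.mask], str(tmp_path), stem="rt")
        back = tifffile.imread(tmp_path / "rt_0000_mask.tif")
        assert back.dtype == np.uint16
        assert np.array_equal(back, small_colony.mask)

    def test_outlines_match_neighborhood_recomputation(self, small_colony, tmp_path):
        export_results([small_colony.image], [small_colony.mask], str(tmp_path), stem="ol")
        outlines = tifffile.imread(tmp_path / "ol_0000_outlines.tif") > 0
        mask = small_colony.mask
        h, w = mask.shape
        ref = np.zeros_like(outlines)
        for yy in range(h):
            for xx in range(w):
                if mask[yy, xx] == 0:
                    continue
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        y2, x2 = yy + dy, xx + dx
                        if 0 <= y2 < h and 0 <= x2 < w and mask[y2, x2] != mask[yy, xx]:
                            ref[yy, xx] = True
        assert np.array_equal(outlines, ref)


@pytest.fixture(scope="module")
def model():
    from colonyseg.network import build_model

    return build_model("distance", budget=3_000_000, seed=0)


class TestInference:
    def test_none_params_equal_defaults_for_unevaluated_model(self, model, small_colony):
        from colonyseg.postprocess import PostParams
        from colonyseg.workflow import infer

        a = infer([small_colony.image], model, None)[0]
        b = infer([small_colony.image], model, PostParams())[0]
        assert np.array_equal(a, b)

    def test_infer_pads_non_divisible_frames(self, model):
        from colonyseg.workflow import infer

        img = np.random.default_rng(0).integers(0, 65535, (100, 100)).astype(np.uint16)
        mask = infer([img], model)[0]
        assert mask.shape == (100, 100)

    def test_prelabel_contract(self, model, small_colony):
        from colonyseg.workflow import infer, prelabel

        off = prelabel(small_colony.image, model, include_prediction=False)
        assert off.prelabel is None
        on1 = prelabel(small_colony.image, model)
        on2 = prelabel(small_colony.image, model)
        assert np.array_equal(on1.prelabel, on2.prelabel)
        assert np.array_equal(on1.prelabel, infer([small_colony.image], model)[0])


def test_end_to_end_determinism(tmp_path):
    """simulate -> split -> train (seeded) -> infer -> export twice with one
    seed produces byte-identical analysis CSVs."""
    from colonyseg.fixtures import ColonyParams, generate_colony
    from colonyseg.training import TrainConfig, train_models
    from colonyseg.workflow import infer

    held = generate_colony(ColonyParams(image_height=128, image_width=128, n_cells=8, seed=50))
    outputs = []
    for run in ("a", "b"):
        tset = make_training_set(8, 128, seed=4)
        cfg = TrainConfig(n_models=1, seed=4, param_budget=3_000_000, epochs_max=1)
        spec = train_models(tset, cfg)[0]
        mask = infer([held.image], spec)[0]
        out = tmp_path / run
        export_results([held.image], [mask], str(out), stem="det")
        outputs.append((out / "det_analysis.csv").read_bytes())
    assert outputs[0] == outputs[1]


class TestDatasetLayout:
    def test_save_load_round_trip_preserves_subsets(self, tmp_path):
        tset = make_training_set(13, 128, seed=1)
        save_training_set(tset, str(tmp_path / "proj"), "ds1")
        loaded = load_training_set(str(tmp_path / "proj"), "ds1")
        assert loaded.crop_size == 128
        for subset in ("train", "val", "test"):
            orig = tset.subset(subset)
            back = loaded.subset(subset)
            assert len(orig) == len(back)
        orig_imgs = sorted(c.image.tobytes() for c in tset.crops)
        back_imgs = sorted(c.image.tobytes() for c in loaded.crops)
        assert orig_imgs == back_imgs

    def test_multipage_tiff_explodes_to_frames(self, tmp_path):
        stack = np.stack([np.full((32, 32), i, np.uint16) for i in range(4)])
        path = str(tmp_path / "stack.tif")
        tifffile.imwrite(path, stack, photometric="minisblack")
        frames = load_frames(path)
        assert len(frames) == 4
        assert all(f.shape == (32, 32) for f in frames)
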