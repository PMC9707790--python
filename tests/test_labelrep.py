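"""Label representations: boundary classes and distance maps."""

import numpy as np
import pytest

from colonyseg.labelrep import (
    boundary_representation,
    cell_distance,
    default_cutoff_radius,
    make_targets,
    neighbor_distance,
)


def brute_force_boundary(mask):
    """Reference: per-pixel 8-neighborhood scan."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if mask[y, x] == 0:
                continue
            out[y, x] = 1
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] != mask[y, x]:
                        out[y, x] = 2
    return out


def test_boundary_empty_mask():
    assert (boundary_representation(np.zeros((6, 6), int)) == 0).all()


def test_boundary_single_square_counts():
    m = np.zeros((10, 10), int)
    m[3:7, 3:7] = 1
    b = boundary_representation(m)
    assert (b == 2).sum() == 12
    assert (b == 1).sum() == 4


def test_boundary_touching_squares_separated(two_squares):
    b = boundary_representation(two_squares)
    # every pixel on both sides of the shared edge is boundary
    assert (b[3:7, 4] == 2).all()
    assert (b[3:7, 5] == 2).all()


def test_boundary_matches_brute_force(colony30):
    crop = colony30.mask[90:140, 90:140]
    assert np.array_equal(boundary_representation(crop), brute_force_boundary(crop))


def test_boundary_invariant_to_relabeling(two_squares):
    permuted = np.where(two_squares == 1, 7, np.where(two_squares == 2, 3, 0))
    assert np.array_equal(
        boundary_representation(two_squares), boundary_representation(permuted)
    )


def test_cell_distance_3x3_square():
    m = np.zeros((9, 9), int)
    m[3:6, 3:6] = 1
    cd = cell_distance(m)
    assert cd[4, 4] == pytest.approx(1.0)
    assert cd[3, 3] == pytest.approx(0.5)
    assert cd[m == 0].max() == 0.0


def test_cell_distance_max_is_one_per_instance(colony30):
    cd = cell_distance(colony30.mask)
    for k in range(1, colony30.mask.max() + 1):
        assert cd[colony30.mask == k].max() == pytest.approx(1.0)


def test_cell_distance_empty():
    assert (cell_distance(np.zeros((5, 5), int)) == 0).all()


def test_neighbor_distance_isolated_instance_is_zero():
    m = np.zeros((12, 12), int)
    m[4:8, 4:8] = 1
    assert (neighbor_distance(m, cutoff_radius=10) == 0).all()


def test_neighbor_distance_two_bars_matches_brute_force():
    """Bars on rows 2 and 4 are 2 px apart center-to-center, so with a
    cutoff of 5 and no sharpening every facing pixel reads 1 - 2/5 = 0.6."""
    m = np.zeros((7, 9), int)
    m[2, 2:7] = 1
    m[4, 2:7] = 2
    nd = neighbor_distance(m, cutoff_radius=5, gamma=1.0)
    # brute force pairwise distances
    ys, xs = np.nonzero(m)
    for y, x in zip(ys, xs):
        others = [(yy, xx) for yy, xx in zip(ys, xs) if m[yy, xx] != m[y, x]]
        d = min(np.hypot(y - yy, x - xx) for yy, xx in others)
        assert nd[y, x] == pytest.approx(max(0.0, 1 - d / 5), abs=1e-6)
    assert nd[2, 4] == pytest.approx(0.6)


def test_neighbor_distance_rises_toward_contact(two_squares):
    nd = neighbor_distance(two_squares, cutoff_radius=6, gamma=1.0)
    row = nd[4, 1:5]  # instance-1 pixels approaching the contact
    assert (np.diff(row) > 0).all()


@pytest.mark.parametrize("transform", [np.flipud, np.fliplr, np.rot90])
def test_distance_maps_equivariant_to_flips_and_rotations(colony30, transform):
    mask = colony30.mask[64:128, 64:192]
    t_mask = transform(mask).copy()
    assert np.allclose(transform(cell_distance(mask)), cell_distance(t_mask))
    assert np.allclose(
        transform(neighbor_distance(mask, 6.0)), neighbor_distance(t_mask, 6.0)
    )


def test_make_targets_boundary_empty_is_background_onehot():
    t = make_targets(np.zeros((8, 8), int), "boundary")
    assert t.shape == (3, 8, 8)
    assert (t[0] == 1).all() and (t[1] == 0).all() and (t[2] == 0).all()


def test_make_targets_distance_shapes_and_support(colony30):
    t = make_targets(colony30.mask, "distance")
    assert t.shape == (2,) + colony30.mask.shape
    assert t.dtype == np.float32
    bg = colony30.mask == 0
    assert (t[0][bg] == 0).all() and (t[1][bg] == 0).all()


def test_make_targets_rejects_unknown_method():
    with pytest.raises(ValueError):
        make_targets(np.zeros((4, 4), int), "flowfield")


def test_target_cache_round_trip(tmp_path, colony30):
    from colonyseg.labelrep import read_targets, write_targets

    t = make_targets(colony30.mask, "distance")
    path = str(tmp_path / "targets.tif")
    write_targets(t, path)
    assert np.array_equal(read_targets(path), t)


def test_default_cutoff_tracks_cell_width():
    m = np.zeros((40, 40), int)
    m[5:25, 5:10] = 1  # 5-px wide bar
    m[5:25, 20:25] = 2
    cut = default_cutoff_radius(m)
    assert 3.0 < cut < 8.0
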