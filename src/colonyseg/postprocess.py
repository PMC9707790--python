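"""Instance recovery from raw network predictions.

Both methods use a seeded watershed: markers are extracted from the
prediction, then grown over an elevation map restricted to a foreground
mask, so touching cells are split along the ridge between their seeds.

* distance method: foreground = cell-distance above ``th_cell``; seeds =
  connected components of (cell distance minus the neighbor distance) above
  ``th_seed``.  Subtracting the neighbor prediction carves the seed map
  apart exactly where two cells meet.
* boundary method: hard argmax classes; seeds = interior components;
  watershed on the boundary-class probability floods interiors back over
  their own boundary band.

8-connectivity is used throughout; output labels are renumbered 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

__all__ = ["PostParams", "distance_postprocess", "boundary_postprocess"]

_STRUCT8 = ndi.generate_binary_structure(2, 2)

#: weight of the neighbor-distance subtraction when forming the seed map
NEIGHBOR_ALPHA = 1.0


@dataclass(frozen=True)
class PostParams:
    """Post-processing thresholds for the distance method.

    ``th_cell`` adjusts the cell size (foreground threshold on the cell
    distance); ``th_seed`` adjusts the seed extraction.  Defaults are the
    values used when a model has not been evaluated yet.
    """

    th_cell: float = 0.09
    th_seed: float = 0.45
    min_seed_area: int = 4
    min_cell_area: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.th_cell < 1.0) or not (0.0 < self.th_seed < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.th_seed <= self.th_cell:
            raise ValueError("th_seed must exceed th_cell (seeds are a subset of the mask)")


def _relabel(mask: np.ndarray) -> np.ndarray:
    """Renumber labels to consecutive 1..K (uint16)."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros(mask.shape, np.uint16)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


def distance_postprocess(
    cell_pred: np.ndarray, neigh_pred: np.ndarray, p: PostParams | None = None
) -> np.ndarray:
    """Recover instances from cell/neighbor distance predictions."""
    if p is None:
        p = PostParams()
    cell_pred = np.asarray(cell_pred, np.float32)
    neigh_pred = np.asarray(neigh_pred, np.float32)
    if cell_pred.shape != neigh_pred.shape:
        raise ValueError("prediction maps must share shape")
    mask = cell_pred > p.th_cell
    seed_map = cell_pred - NEIGHBOR_ALPHA * np.clip(neigh_pred, 0.0, 1.0)
    seeds, n_seeds = ndi.label(seed_map > p.th_seed, structure=_STRUCT8)
    if n_seeds:
        areas = np.bincount(seeds.ravel())
        small = np.flatnonzero(areas < p.min_seed_area)
        seeds[np.isin(seeds, small[small > 0])] = 0
    out = watershed(-cell_pred, markers=seeds, mask=mask, connectivity=2)
    # components of the foreground that received no seed become instances
    # on their own when large enough
    comp, n_comp = ndi.label(mask, structure=_STRUCT8)
    next_label = out.max() + 1
    for k in range(1, n_comp + 1):
        sel = comp == k
        if (out[sel] > 0).any():
            continue
        if sel.sum() >= p.min_cell_area:
            out[sel] = next_label
            next_label += 1
    return _relabel(out)


def boundary_postprocess(class_probs: np.ndarray) -> np.ndarray:
    """Recover instances from 3-class (background/interior/boundary)
    probability maps of shape (3, H, W)."""
    class_probs = np.asarray(class_probs, np.float32)
    if class_probs.ndim != 3 or class_probs.shape[0] != 3:
        raise ValueError("expected class probabilities of shape (3, H, W)")
    sums = class_probs.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("class probabilities must sum to 1 per pixel")
    classes = class_probs.argmax(axis=0)
    interior = classes == 1
    foreground = classes > 0
    seeds, n_seeds = ndi.label(interior, structure=_STRUCT8)
    if n_seeds:
        areas = np.bincount(seeds.ravel())
        small = np.flatnonzero(areas < PostParams().min_seed_area)
        seeds[np.isin(seeds, small[small > 0])] = 0
    out = watershed(class_probs[2], markers=seeds, mask=foreground, connectivity=2)
    return _relabel(out)
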