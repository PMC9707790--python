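"""User-facing workflow: crop proposals, pre-labeling, dataset layout,
inference, statistics and result export.

The on-disk layout mirrors a project -> dataset hierarchy::

    project/dataset/{train,val,test}/image_NNN.tif + mask_NNN.tif

Result export writes, per frame, exactly five artifacts: the original image
(.tif), the intensity-coded instance mask (.tif), a cell-outlines image
(.tif), the original image overlaid with the outlines in red (.tif), and a
row of per-frame shape statistics appended to an analysis .csv.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.measure import find_contours, regionprops

from .labelrep import boundary_representation
from .network import ModelSpec, percentile_normalize
from .postprocess import PostParams, boundary_postprocess, distance_postprocess
from .training import ALLOWED_CROP_SIZES, Crop, TrainingSet

__all__ = [
    "CropProposal",
    "ShapeStats",
    "propose_crops",
    "prelabel",
    "predict_raw",
    "infer",
    "shape_stats",
    "polygon_rois",
    "write_polygon_rois",
    "export_results",
    "save_training_set",
    "load_training_set",
    "load_frames",
]


@dataclass
class CropProposal:
    source_image_id: str
    frame: int
    rect: tuple[int, int, int]  # (x0, y0, size), 0-based, half-open
    region_index: int
    selected: bool = False
    prelabel: np.ndarray | None = None


@dataclass
class ShapeStats:
    frame: int
    cell_count: int
    mean_area: float
    mean_minor_axis: float
    mean_major_axis: float
    total_area: float


def propose_crops(
    image: np.ndarray, crop_size: int, seed: int, source_image_id: str = "", frame: int = 0
) -> list[CropProposal]:
    """Up to three random crop proposals from non-overlapping image regions.

    The image is split into ``k = min(3, width // crop_size)`` vertical bands
    of equal width; one crop is placed per band at a uniform random in-band
    x and uniform random y, so proposals are pairwise disjoint by
    construction.
    """
    if crop_size not in ALLOWED_CROP_SIZES:
        raise ValueError(f"crop_size must be one of {ALLOWED_CROP_SIZES}")
    h, w = image.shape[:2]
    if crop_size > min(h, w):
        raise ValueError("crop_size larger than image")
    rng = np.random.default_rng(seed)
    k = min(3, w // crop_size)
    band_w = w // k
    proposals = []
    for b in range(k):
        x0 = int(rng.integers(b * band_w, b * band_w + band_w - crop_size + 1))
        y0 = int(rng.integers(0, h - crop_size + 1))
        proposals.append(
            CropProposal(
                source_image_id=source_image_id,
                frame=frame,
                rect=(x0, y0, crop_size),
                region_index=b,
            )
        )
    return proposals


def prelabel(
    crop_image: np.ndarray,
    model: ModelSpec,
    params: PostParams | None = None,
    include_prediction: bool = True,
    source_image_id: str = "",
    frame: int = 0,
) -> CropProposal:
    """Attach a model prediction to a crop so annotators correct it instead
    of labeling from scratch; with ``include_prediction=False`` the crop is
    returned unlabeled."""
    if model.net is None:
        raise ValueError("model is not trained/built")
    size = crop_image.shape[0]
    mask = infer([crop_image], model, params)[0] if include_prediction else None
    return CropProposal(
        source_image_id=source_image_id,
        frame=frame,
        rect=(0, 0, size),
        region_index=0,
        selected=True,
        prelabel=mask,
    )


def predict_raw(image: np.ndarray, model: ModelSpec):
    """Normalize, reflection-pad to the network's divisibility requirement,
    predict, and crop back.  Returns raw maps (method-dependent)."""
    from .network import forward as net_forward

    if model.net is None:
        raise ValueError("model is not trained/built")
    img = percentile_normalize(image)
    h, w = img.shape
    div = 2 ** (model.depth - 1)
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    out = net_forward(model, img[None])
    if model.method == "boundary":
        return out[0][:, :h, :w]
    return out[0][0, :h, :w], out[1][0, :h, :w]


def infer(
    images: list[np.ndarray], model: ModelSpec, params: PostParams | None = None
) -> list[np.ndarray]:
    """Predict and post-process a list of frames, preserving order.

    ``params=None`` uses the model's evaluated thresholds if present, else
    the defaults (the behavior for a not-yet-evaluated model)."""
    if params is None and model.best_params:
        params = PostParams(**model.best_params)
    masks = []
    for image in images:
        raw = predict_raw(image, model)
        if model.method == "boundary":
            masks.append(boundary_postprocess(raw))
        else:
            masks.append(distance_postprocess(raw[0], raw[1], params or PostParams()))
    return masks


def shape_stats(mask: np.ndarray, frame: int = 0) -> ShapeStats:
    """Per-frame cell statistics: count, mean area, mean minor/major ellipse
    axis lengths, total area (all in pixel units)."""
    props = regionprops(np.asarray(mask).astype(np.int64))
    if not props:
        return ShapeStats(frame, 0, 0.0, 0.0, 0.0, 0.0)
    areas = [p.area for p in props]
    return ShapeStats(
        frame=frame,
        cell_count=len(props),
        mean_area=float(np.mean(areas)),
        mean_minor_axis=float(np.mean([p.axis_minor_length for p in props])),
        mean_major_axis=float(np.mean([p.axis_major_length for p in props])),
        total_area=float(np.sum(areas)),
    )


def polygon_rois(mask: np.ndarray) -> list[np.ndarray]:
    """One closed sub-pixel outer contour per instance (marching squares at
    level 0.5), vertices as (x, y) float pairs in 0-based pixel coordinates."""
    mask = np.asarray(mask)
    polys = []
    for k in np.unique(mask):
        if k == 0:
            continue
        binary = np.pad((mask == k).astype(float), 1)
        contours = find_contours(binary, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) - 1.0  # undo the pad
        poly = np.stack([contour[:, 1], contour[:, 0]], axis=1)  # (x, y)
        polys.append(poly)
    return polys


def write_polygon_rois(polys: list[np.ndarray], path: str) -> None:
    data = [{"points": p.tolist()} for p in polys]
    with open(path, "w") as fh:
        json.dump(data, fh)


_CSV_HEADER = ["frame", "cell_count", "mean_area", "mean_minor_axis", "mean_major_axis", "total_area"]


def export_results(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    out_dir: str,
    stem: str = "result",
) -> list[str]:
    """Write the five export artifacts per frame.

    Per frame ``i``: ``<stem>_NNNN.tif`` (original), ``..._mask.tif``
    (16-bit labels), ``..._outlines.tif``, ``..._overlay.tif`` (8-bit RGB,
    red outlines), plus one statistics row per frame appended to
    ``<stem>_analysis.csv``."""
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, f"{stem}_analysis.csv")
    new_csv = not os.path.exists(csv_path)
    written = []
    with open(csv_path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new_csv:
            writer.writerow(_CSV_HEADER)
        for i, (image, mask) in enumerate(zip(images, masks)):
            base = os.path.join(out_dir, f"{stem}_{i:04d}")
            image = np.asarray(image)
            mask16 = np.asarray(mask).astype(np.uint16)
            outlines = (boundary_representation(mask16) == 2).astype(np.uint8) * 255
            img8 = (percentile_normalize(image) * 255).astype(np.uint8)
            overlay = np.stack([img8] * 3, axis=-1)
            overlay[outlines > 0] = (255, 0, 0)
            tifffile.imwrite(base + ".tif", image)
            tifffile.imwrite(base + "_mask.tif", mask16)
            tifffile.imwrite(base + "_outlines.tif", outlines)
            tifffile.imwrite(base + "_overlay.tif", overlay)
            st = shape_stats(mask16, frame=i)
            writer.writerow(
                [
                    st.frame,
                    st.cell_count,
                    f"{st.mean_area:.3f}",
                    f"{st.mean_minor_axis:.3f}",
                    f"{st.mean_major_axis:.3f}",
                    f"{st.total_area:.3f}",
                ]
            )
            written += [base + ".tif", base + "_mask.tif", base + "_outlines.tif", base + "_overlay.tif"]
    written.append(csv_path)
    return written


# ---------------------------------------------------------------------------
# dataset directory layout
# ---------------------------------------------------------------------------


def save_training_set(tset: TrainingSet, project_dir: str, dataset: str) -> str:
    """Write crops to ``project/dataset/<subset>/image_NNN.tif`` pairs."""
    root = os.path.join(project_dir, dataset)
    counters = {s: 0 for s in ("train", "val", "test")}
    for crop in tset.crops:
        sub = os.path.join(root, crop.subset)
        os.makedirs(sub, exist_ok=True)
        i = counters[crop.subset]
        tifffile.imwrite(os.path.join(sub, f"image_{i:03d}.tif"), np.asarray(crop.image).astype(np.uint16))
        tifffile.imwrite(os.path.join(sub, f"mask_{i:03d}.tif"), np.asarray(crop.mask).astype(np.uint16))
        counters[crop.subset] += 1
    with open(os.path.join(root, "dataset.json"), "w") as fh:
        json.dump({"crop_size": tset.crop_size, "counts": counters}, fh)
    return root


def load_training_set(project_dir: str, dataset: str) -> TrainingSet:
    root = os.path.join(project_dir, dataset)
    with open(os.path.join(root, "dataset.json")) as fh:
        meta = json.load(fh)
    crops = []
    for subset in ("train", "val", "test"):
        sub = os.path.join(root, subset)
        if not os.path.isdir(sub):
            continue
        names = sorted(f for f in os.listdir(sub) if f.startswith("image_"))
        for name in names:
            image = tifffile.imread(os.path.join(sub, name))
            mask = tifffile.imread(os.path.join(sub, name.replace("image_", "mask_")))
            crops.append(Crop(image=image, mask=mask, subset=subset, name=name))
    return TrainingSet(crops=crops, crop_size=meta["crop_size"])


def load_frames(path: str) -> list[np.ndarray]:
    """Read a TIFF as a list of 2-D frames (multi-page files are exploded)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        return [data]
    return [data[i] for i in range(data.shape[0])]
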