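"""Segmentation scoring with AJI+, threshold grid search, model ranking.

AJI+ (aggregated Jaccard index with one-to-one matching) compares a
predicted instance mask against ground truth: predicted and true objects
are matched one-to-one so that the total IoU of the matching is maximal
(optimal assignment; zero-IoU pairs are never matched), then

    AJI+ = sum_matched |G ∩ P| /
           (sum_matched |G ∪ P| + sum_unmatched |G| + sum_unmatched |P|).

The one-to-one matching prevents the over-penalization of the original AJI,
where one predicted object could be charged against several true objects.
Scores range from 0 to 1, with 1 indicating perfect segmentation.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import ModelSpec
from .postprocess import PostParams, distance_postprocess, boundary_postprocess

__all__ = [
    "EvalRecord",
    "aji_plus",
    "default_grid",
    "evaluate_model",
    "select_best",
    "write_eval_csv",
]

#: grid searched on the internal test split for the distance method
DEFAULT_TH_CELL = (0.05, 0.07, 0.09, 0.11, 0.13)
DEFAULT_TH_SEED = (0.35, 0.40, 0.45, 0.50, 0.55, 0.60)


@dataclass
class EvalRecord:
    model_id: str
    method: str
    best_params: PostParams | None
    aji_mean: float
    aji_std: float
    per_image: list[tuple[str, float]] = field(default_factory=list)


def aji_plus(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index with optimal one-to-one matching."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks must share shape")
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    pr_ids = np.unique(pred)
    pr_ids = pr_ids[pr_ids > 0]
    if gt_ids.size == 0 and pr_ids.size == 0:
        return 1.0
    if gt_ids.size == 0 or pr_ids.size == 0:
        return 0.0
    # pairwise intersection table via joint histogram over overlap pixels
    both = (gt > 0) & (pred > 0)
    inter = np.zeros((gt_ids.size, pr_ids.size), np.int64)
    if both.any():
        gi = np.searchsorted(gt_ids, gt[both])
        pi = np.searchsorted(pr_ids, pred[both])
        np.add.at(inter, (gi, pi), 1)
    gt_areas = np.array([(gt == k).sum() for k in gt_ids], np.int64)
    pr_areas = np.array([(pred == k).sum() for k in pr_ids], np.int64)
    union = gt_areas[:, None] + pr_areas[None, :] - inter
    iou = np.where(union > 0, inter / union, 0.0)
    rows, cols = linear_sum_assignment(-iou)
    matched = iou[rows, cols] > 0
    rows, cols = rows[matched], cols[matched]
    num = inter[rows, cols].sum()
    den = union[rows, cols].sum()
    den += gt_areas.sum() - gt_areas[rows].sum()
    den += pr_areas.sum() - pr_areas[cols].sum()
    return float(num / den) if den > 0 else 0.0


def default_grid() -> list[PostParams]:
    """The (th_cell, th_seed) grid, ordered so earlier entries win ties."""
    return [
        PostParams(th_cell=tc, th_seed=ts)
        for tc, ts in product(DEFAULT_TH_CELL, DEFAULT_TH_SEED)
    ]


def evaluate_model(
    model: ModelSpec,
    test_crops: list[tuple[np.ndarray, np.ndarray]],
    grid: list[PostParams] | None = None,
    csv_path: str | None = None,
) -> EvalRecord:
    """Score a model on the internal test split.

    ``test_crops`` is a list of (image, ground-truth mask) pairs.  For
    distance models the post-processing grid is swept and the pair with the
    highest mean AJI+ wins (ties: earlier grid entry, i.e. lower th_cell then
    lower th_seed).  Boundary models have no grid.  Appends one CSV row when
    ``csv_path`` is given.
    """
    if not test_crops:
        raise ValueError("need at least one test crop with ground truth")
    from .workflow import predict_raw  # late import to avoid a cycle

    # the network runs once per image; only the (cheap) post-processing is
    # repeated across the threshold grid
    raws = [predict_raw(img, model) for img, _ in test_crops]

    if model.method == "distance":
        candidates = grid if grid is not None else default_grid()
    else:
        candidates = [None]

    best: tuple[float, float, PostParams | None, list[float]] | None = None
    for params in candidates:
        scores = []
        for raw, (_, mask) in zip(raws, test_crops):
            if model.method == "distance":
                pred = distance_postprocess(raw[0], raw[1], params)
            else:
                pred = boundary_postprocess(raw)
            scores.append(aji_plus(mask, pred))
        mean = float(np.mean(scores))
        std = float(np.std(scores))  # population std, for CSV comparability
        if best is None or mean > best[0]:
            best = (mean, std, params, scores)
    mean, std, params, scores = best
    record = EvalRecord(
        model_id=model.model_id,
        method=model.method,
        best_params=params,
        aji_mean=mean,
        aji_std=std,
        per_image=[(f"test_{i:03d}", s) for i, s in enumerate(scores)],
    )
    if params is not None:
        model.best_params = {
            "th_cell": params.th_cell,
            "th_seed": params.th_seed,
            "min_seed_area": params.min_seed_area,
            "min_cell_area": params.min_cell_area,
        }
    if csv_path is not None:
        write_eval_csv([record], csv_path, append=True)
    return record


def select_best(records: list[EvalRecord]) -> EvalRecord:
    """Pick the model for inference: highest mean AJI+, ties broken by lower
    std, then lexicographic model id."""
    if not records:
        raise ValueError("no evaluation records")
    return min(records, key=lambda r: (-r.aji_mean, r.aji_std, r.model_id))


def write_eval_csv(records: list[EvalRecord], path: str, append: bool = False) -> None:
    header = ["model_id", "method", "th_cell", "th_seed", "aji_mean", "aji_std", "n_test_images"]
    exists = os.path.exists(path)
    mode = "a" if append else "w"
    with open(path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if not (append and exists):
            writer.writerow(header)
        for r in records:
            writer.writerow(
                [
                    r.model_id,
                    r.method,
                    r.best_params.th_cell if r.best_params else "",
                    r.best_params.th_seed if r.best_params else "",
                    f"{r.aji_mean:.4f}",
                    f"{r.aji_std:.4f}",
                    len(r.per_image),
                ]
            )
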