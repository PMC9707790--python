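"""Synthetic microcolony image generator.

Emulates time-lapse microscopy of dense microbial microcolonies so that the
whole segmentation workflow (label generation, training, post-processing,
evaluation, export) can be exercised with exact instance ground truth and no
microscope.

Cells are spherocylinders (a rectangle capped by two semicircles) whose
midline may be bent into a circular arc; they are rasterized at 4x
supersampling and placed by rejection sampling against an occupancy mask so
that instances may touch but never overlap.  Two render modes are provided:

* ``phase``  -- dark rods with a bright halo on a mid-gray textured
  background (phase-contrast look),
* ``fluor``  -- bright, roundish nucleus-like blobs on a dark background
  (fluorescence look).
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "ColonyParams",
    "SyntheticSample",
    "PlacementError",
    "generate_colony",
    "generate_timelapse",
    "write_samples",
]

_SUPERSAMPLE = 4
_PLACE_ATTEMPTS = 120
_TOUCH_FRACTION = 0.5  # fraction of colony placements allowed to touch


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} requested cells "
            f"without overlap; reduce n_cells or enlarge the image"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class ColonyParams:
    """Parameters of one synthetic colony image.

    ``noise_sigma`` is the additive Gaussian noise level as a fraction of the
    dynamic range; ``psf_sigma`` the Gaussian blur emulating the point-spread
    function, in pixels.  ``curvature`` in [0, 1] scales how strongly rod
    midlines bend.
    """

    image_height: int = 256
    image_width: int = 256
    n_cells: int = 30
    cell_length_range: tuple[float, float] = (12.0, 22.0)
    cell_width_range: tuple[float, float] = (5.0, 8.0)
    curvature: float = 0.25
    packing: str = "colony"
    modality: str = "phase"
    psf_sigma: float = 1.0
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for lo, hi in (self.cell_length_range, self.cell_width_range):
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError("length/width ranges must be positive with min <= max")
        if self.packing not in ("sparse", "colony"):
            raise ValueError("packing must be 'sparse' or 'colony'")
        if self.modality not in ("phase", "fluor"):
            raise ValueError("modality must be 'phase' or 'fluor'")


@dataclass
class SyntheticSample:
    """A rendered image with its instance ground truth."""

    image: np.ndarray  # uint16, (H, W)
    mask: np.ndarray  # uint16 label image, 0 = background
    params: ColonyParams


# ---------------------------------------------------------------------------
# cell geometry and rasterization
# ---------------------------------------------------------------------------


@dataclass
class _Rod:
    cy: float
    cx: float
    angle: float  # orientation of the chord, radians
    length: float  # midline arc length, px
    width: float  # diameter, px
    bend: float  # total bend angle of the midline arc, radians (0 = straight)
    shade: float  # per-cell intensity jitter in [-1, 1]


def _rasterize(rod: _Rod, shape: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a rod into a local boolean patch.

    Returns ``(patch, (y0, x0))`` with the patch placed at that offset in the
    full image; the patch is clipped to the image bounds.
    """
    half = rod.length / 2.0 + rod.width / 2.0 + 2.0
    y0 = max(0, int(math.floor(rod.cy - half)))
    x0 = max(0, int(math.floor(rod.cx - half)))
    y1 = min(shape[0], int(math.ceil(rod.cy + half)) + 1)
    x1 = min(shape[1], int(math.ceil(rod.cx + half)) + 1)
    if y1 <= y0 or x1 <= x0:
        return np.zeros((0, 0), bool), (y0, x0)
    s = _SUPERSAMPLE
    yy = (np.arange(y0 * s, y1 * s) + 0.5) / s
    xx = (np.arange(x0 * s, x1 * s) + 0.5) / s
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    # rotate into the rod frame: u along the chord, v across
    dy = gy - rod.cy
    dx = gx - rod.cx
    ca, sa = math.cos(rod.angle), math.sin(rod.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca

    if abs(rod.bend) < 1e-3:
        uc = np.clip(u, -rod.length / 2.0, rod.length / 2.0)
        dist = np.hypot(u - uc, v)
    else:
        # midline = circular arc of radius R through the origin, tangent to u
        r = rod.length / abs(rod.bend)
        sign = 1.0 if rod.bend > 0 else -1.0
        # arc center sits at (0, sign * R) in the rod frame
        pu, pv = u, v - sign * r
        rho = np.hypot(pu, pv)
        theta = np.arctan2(pu, -sign * pv)  # 0 at the rod center
        half_ang = abs(rod.bend) / 2.0
        inside = np.abs(theta) <= half_ang
        # distance to the nearest arc endpoint for points beyond the span
        d_end = np.full_like(u, np.inf)
        for s_end in (-half_ang, half_ang):
            eu = r * math.sin(s_end)
            ev = sign * (r - r * math.cos(s_end))
            d_end = np.minimum(d_end, np.hypot(u - eu, v - ev))
        dist = np.where(inside, np.abs(rho - r), d_end)
    fine = dist <= rod.width / 2.0
    h, w = y1 - y0, x1 - x0
    patch = fine.reshape(h, s, w, s).mean(axis=(1, 3)) >= 0.5
    return patch, (y0, x0)


def _sample_geometry(p: ColonyParams, rng: np.random.Generator) -> _Rod:
    width = rng.uniform(*p.cell_width_range)
    if p.modality == "fluor":
        # nucleus-like roundish blobs: short, straight
        length = width * rng.uniform(1.0, 1.6)
        bend = 0.0
    else:
        length = rng.uniform(*p.cell_length_range)
        bend = p.curvature * rng.uniform(-1.2, 1.2)
    return _Rod(
        cy=0.0,
        cx=0.0,
        angle=rng.uniform(0.0, math.pi),
        length=length,
        width=width,
        bend=bend,
        shade=rng.uniform(-1.0, 1.0),
    )


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _try_place(
    rod: _Rod,
    occ: np.ndarray,
    occ_dil: np.ndarray,
    cy: float,
    cx: float,
    direction: tuple[float, float] | None,
    need_gap: bool,
) -> _Rod | None:
    """Place ``rod`` at (cy, cx), optionally pushing it along ``direction``
    until it clears the occupancy mask.  Returns the placed rod or None."""
    shape = occ.shape
    max_push = int(math.hypot(*shape))
    uy, ux = direction if direction is not None else (0.0, 0.0)
    steps = max_push if direction is not None else 1
    for s in range(steps):
        ty = cy + s * uy
        tx = cx + s * ux
        half = rod.length / 2.0 + rod.width / 2.0 + 2.0
        if not (half <= ty <= shape[0] - half and half <= tx <= shape[1] - half):
            return None
        cand = dataclasses.replace(rod, cy=ty, cx=tx)
        patch, (y0, x0) = _rasterize(cand, shape)
        if patch.size == 0 or not patch.any():
            return None
        sl = (slice(y0, y0 + patch.shape[0]), slice(x0, x0 + patch.shape[1]))
        blocker = occ_dil if need_gap else occ
        if not (patch & blocker[sl]).any():
            return cand
        if direction is None:
            return None
    return None


def _place_cells(p: ColonyParams, rng: np.random.Generator) -> list[_Rod]:
    shape = (p.image_height, p.image_width)
    occ = np.zeros(shape, bool)
    occ_dil = np.zeros(shape, bool)
    struct = ndi.generate_binary_structure(2, 2)
    rods: list[_Rod] = []
    center = (
        shape[0] / 2.0 + rng.uniform(-0.05, 0.05) * shape[0],
        shape[1] / 2.0 + rng.uniform(-0.05, 0.05) * shape[1],
    )
    for k in range(p.n_cells):
        placed = None
        for _ in range(_PLACE_ATTEMPTS):
            rod = _sample_geometry(p, rng)
            if p.packing == "sparse":
                margin = rod.length / 2.0 + rod.width / 2.0 + 3.0
                cy = rng.uniform(margin, shape[0] - margin)
                cx = rng.uniform(margin, shape[1] - margin)
                placed = _try_place(rod, occ, occ_dil, cy, cx, None, need_gap=True)
            else:
                ang = rng.uniform(0.0, 2.0 * math.pi)
                direction = (math.sin(ang), math.cos(ang))
                need_gap = not rods or rng.random() >= _TOUCH_FRACTION
                placed = _try_place(rod, occ, occ_dil, center[0], center[1], direction, need_gap)
            if placed is not None:
                break
        if placed is None:
            raise PlacementError(p.n_cells, k)
        patch, (y0, x0) = _rasterize(placed, shape)
        sl = (slice(y0, y0 + patch.shape[0]), slice(x0, x0 + patch.shape[1]))
        occ[sl] |= patch
        occ_dil = ndi.binary_dilation(occ, struct)
        rods.append(placed)
    return rods


def _paint_mask(rods: list[_Rod], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, np.uint16)
    for i, rod in enumerate(rods, start=1):
        patch, (y0, x0) = _rasterize(rod, shape)
        sl = (slice(y0, y0 + patch.shape[0]), slice(x0, x0 + patch.shape[1]))
        region = mask[sl]
        region[patch & (region == 0)] = i
    return mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _texture(shape: tuple[int, int], rng: np.random.Generator, scale: float, amp: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    tex = ndi.gaussian_filter(noise, scale)
    peak = np.abs(tex).max()
    if peak > 0:
        tex = tex / peak
    return amp * tex


def _render(mask: np.ndarray, rods: list[_Rod], p: ColonyParams, rng: np.random.Generator) -> np.ndarray:
    shape = mask.shape
    fg = mask > 0
    if p.modality == "phase":
        img = 0.52 + _texture(shape, rng, 6.0, 0.06)
        halo = ndi.binary_dilation(fg, ndi.generate_binary_structure(2, 2), iterations=2) & ~fg
        img[halo] = 0.78
        for i, rod in enumerate(rods, start=1):
            img[mask == i] = 0.27 + 0.05 * rod.shade
    else:
        img = 0.06 + _texture(shape, rng, 6.0, 0.02)
        for i, rod in enumerate(rods, start=1):
            img[mask == i] = 0.72 + 0.12 * rod.shade
    if p.psf_sigma > 0:
        img = ndi.gaussian_filter(img, p.psf_sigma)
    img = img + p.noise_sigma * rng.standard_normal(shape)
    return (np.clip(img, 0.0, 1.0) * 65535.0).round().astype(np.uint16)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_colony(params: ColonyParams) -> SyntheticSample:
    """Generate one synthetic colony image with exact instance ground truth.

    Deterministic given ``params.seed``.  Raises :class:`PlacementError` when
    the requested number of cells cannot be placed without overlap.
    """
    rng = np.random.default_rng(params.seed)
    place_rng, render_rng = rng.spawn(2)
    rods = _place_cells(params, place_rng)
    mask = _paint_mask(rods, (params.image_height, params.image_width))
    image = _render(mask, rods, params, render_rng)
    return SyntheticSample(image=image, mask=mask, params=params)


def generate_timelapse(
    params: ColonyParams, n_frames: int, growth_rate: float
) -> list[SyntheticSample]:
    """Simulate a growing colony: per frame, cells elongate by ``growth_rate``
    (fractional) and divide in two once longer than a division threshold.

    Elongation or division steps that would create an overlap are skipped, so
    masks stay overlap-free and the cell count is non-decreasing.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    place_rng, render_rng, growth_rng = rng.spawn(3)
    rods = _place_cells(params, place_rng)
    shape = (params.image_height, params.image_width)
    div_length = 1.6 * params.cell_length_range[1]

    frames: list[SyntheticSample] = []
    for frame in range(n_frames):
        mask = _paint_mask(rods, shape)
        image = _render(mask, rods, params, render_rng.spawn(1)[0])
        frames.append(SyntheticSample(image=image, mask=mask, params=params))
        if frame == n_frames - 1:
            break
        rods = _grow_step(rods, shape, growth_rate, div_length, growth_rng)
    return frames


def _grow_step(
    rods: list[_Rod],
    shape: tuple[int, int],
    growth_rate: float,
    div_length: float,
    rng: np.random.Generator,
) -> list[_Rod]:
    occ = _paint_mask(rods, shape) > 0
    out: list[_Rod] = list(rods)
    for idx, rod in enumerate(rods):
        patch, (y0, x0) = _rasterize(rod, shape)
        sl = (slice(y0, y0 + patch.shape[0]), slice(x0, x0 + patch.shape[1]))
        others = occ.copy()
        others[sl] &= ~patch
        if rod.length >= div_length:
            children = _divide(rod, rng)
            ok = True
            occupied = others
            placed = []
            for child in children:
                cp, (cy0, cx0) = _rasterize(child, shape)
                csl = (slice(cy0, cy0 + cp.shape[0]), slice(cx0, cx0 + cp.shape[1]))
                if cp.size == 0 or (cp & occupied[csl]).any():
                    ok = False
                    break
                occupied = occupied.copy()
                occupied[csl] |= cp
                placed.append(child)
            if ok:
                out[idx] = placed[0]
                out.append(placed[1])
                occ = occupied
                continue
        if growth_rate <= 0:
            continue
        new_len = rod.length * (1.0 + growth_rate)
        shift = (new_len - rod.length) / 2.0
        ca, sa = math.cos(rod.angle), math.sin(rod.angle)
        # try symmetric elongation first, then growing toward either free end
        for dy, dx in ((0.0, 0.0), (shift * sa, shift * ca), (-shift * sa, -shift * ca)):
            grown = dataclasses.replace(
                rod, length=new_len, cy=rod.cy + dy, cx=rod.cx + dx
            )
            gp, (gy0, gx0) = _rasterize(grown, shape)
            gsl = (slice(gy0, gy0 + gp.shape[0]), slice(gx0, gx0 + gp.shape[1]))
            in_bounds = (
                gy0 > 0
                and gx0 > 0
                and gy0 + gp.shape[0] < shape[0]
                and gx0 + gp.shape[1] < shape[1]
            )
            if in_bounds and gp.any() and not (gp & others[gsl]).any():
                out[idx] = grown
                occ = others
                occ[gsl] |= gp
                break
        # all directions blocked: keep the old geometry
    return out


def _divide(rod: _Rod, rng: np.random.Generator) -> list[_Rod]:
    """Split a rod into two straight daughters along its chord."""
    # the footprint of a rod spans length + width along its axis (caps add
    # width/2 at each end); size daughters so both fit inside the parent span
    gap = 1.0
    child_len = max((rod.length - rod.width - gap) / 2.0, rod.width * 0.5)
    off = child_len / 2.0 + rod.width / 2.0 + gap / 2.0
    ca, sa = math.cos(rod.angle), math.sin(rod.angle)
    kids = []
    for s in (-1.0, 1.0):
        kids.append(
            _Rod(
                cy=rod.cy + s * off * sa,
                cx=rod.cx + s * off * ca,
                angle=rod.angle + rng.uniform(-0.05, 0.05),
                length=child_len,
                width=rod.width,
                bend=0.0,
                shade=np.clip(rod.shade + rng.uniform(-0.3, 0.3), -1.0, 1.0),
            )
        )
    return kids


def make_training_set(
    n_crops: int,
    crop_size: int = 128,
    seed: int = 0,
    modality: str = "phase",
    cells_range: tuple[int, int] = (8, 20),
):
    """Assemble a ready-to-train synthetic crop set.

    Each crop is an independent colony image of ``crop_size`` pixels with a
    cell count drawn from ``cells_range``; crops are assigned to the
    train/val/test subsets by the automatic largest-deficit rule in
    generation order.
    """
    from .training import Crop, TrainingSet, assign_subset

    rng = np.random.default_rng(seed)
    counts = {"train": 0, "val": 0, "test": 0}
    crops = []
    for i in range(n_crops):
        n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
        sample = generate_colony(
            ColonyParams(
                image_height=crop_size,
                image_width=crop_size,
                n_cells=n_cells,
                modality=modality,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        subset = assign_subset(counts)
        counts[subset] += 1
        crops.append(Crop(image=sample.image, mask=sample.mask, subset=subset))
    return TrainingSet(crops=crops, crop_size=crop_size)


def write_samples(samples: list[SyntheticSample], out_dir: str | os.PathLike) -> list[str]:
    """Write ``image_####.tif`` / ``mask_####.tif`` pairs (16-bit)."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for i, s in enumerate(samples):
        ipath = os.path.join(out_dir, f"image_{i:04d}.tif")
        mpath = os.path.join(out_dir, f"mask_{i:04d}.tif")
        tifffile.imwrite(ipath, s.image.astype(np.uint16))
        tifffile.imwrite(mpath, s.mask.astype(np.uint16))
        written += [ipath, mpath]
    return written
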