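"""ROI perturbation operators.

Four geometric perturbations of a binary segmentation mask, applied
independently to every axial slice and reassembled:

* **erosion / dilation** with a 3x3 cross kernel, driven to an *exact*
  per-slice target area ``round(A0 * (1 + tau))`` — whole morphology passes
  while the next full pass would not overshoot, then a partial pass that
  toggles boundary pixels ranked by Euclidean distance-transform depth;
* **contour randomization** — SLIC superpixels of a target physical area
  are included in the new ROI when their overlap fraction with the original
  ROI is >= nu_hi, excluded when <= nu_lo, and Bernoulli-selected with
  probability equal to the overlap in between;
* **translation** of the whole mask by a fixed fraction of its in-plane
  bounding-box extent (area-preserving; clipping at the grid border is an
  error, never silent).

Small perturbations (|tau| = 0.15, 25 mm^2 superpixels) form the stability
set used for robustness screening; large translations (30% of the bounding
box) form the discrimination set; larger perturbations (|tau| = 0.30,
400 mm^2 superpixels) form the augmentation set that synthesizes new
training samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, distance_transform_edt
from skimage.segmentation import slic

from .volumes import ImageVolume, RoiMask

__all__ = [
    "PerturbationSpec",
    "PerturbedMask",
    "PaddingError",
    "erode_or_dilate_slice",
    "randomize_contour_slice",
    "translate_mask",
    "make_stability_set",
    "make_discrimination_set",
    "make_augmentation_set",
    "STABILITY_TAU",
    "AUGMENT_TAU",
    "STABILITY_SUPERPIXEL_MM2",
    "AUGMENT_SUPERPIXEL_MM2",
]

logger = logging.getLogger(__name__)

# 3x3 cross: a pixel and its two horizontal and two vertical neighbours
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

STABILITY_TAU = 0.15
AUGMENT_TAU = 0.30
STABILITY_SUPERPIXEL_MM2 = 25.0
AUGMENT_SUPERPIXEL_MM2 = 400.0
NU_LO = 0.20
NU_HI = 0.90
TRANSLATION_FRACTION = 0.30

# below kernel scale the 3x3 morphology is meaningless; such slices pass
# through unperturbed
MIN_SLICE_AREA = 9
MIN_TARGET_AREA = 4

SLIC_COMPACTNESS = 0.1  # for images normalized to [0, 1]


class PaddingError(ValueError):
    """A perturbation would cross the grid border."""


@dataclass
class PerturbationSpec:
    """Operator kind plus its parameters."""

    kind: str  # erode | dilate | randomize_contour | translate
    tau: float = 0.0
    superpixel_area_mm2: float = STABILITY_SUPERPIXEL_MM2
    nu_lo: float = NU_LO
    nu_hi: float = NU_HI
    translation_fraction: float = TRANSLATION_FRACTION
    axis: str = "x"
    sign: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("erode", "dilate", "randomize_contour", "translate"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not abs(self.tau) < 1:
            raise ValueError("|tau| must be < 1")
        if not (0 <= self.nu_lo < self.nu_hi <= 1):
            raise ValueError("need 0 <= nu_lo < nu_hi <= 1")
        if self.superpixel_area_mm2 <= 0:
            raise ValueError("superpixel_area_mm2 must be positive")
        if not (0 < self.translation_fraction < 1):
            raise ValueError("translation_fraction must be in (0, 1)")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class PerturbedMask:
    """A perturbed mask plus its provenance and achieved per-slice area ratios."""

    mask: RoiMask
    spec: PerturbationSpec
    parent_patient_id: str = ""
    achieved_area_ratio: dict[int, float] = field(default_factory=dict)


def _rank_pixels(candidates: np.ndarray, depth: np.ndarray) -> list[tuple[int, int]]:
    """Candidate pixels ordered by (distance-transform depth, raster index)."""
    idx = np.argwhere(candidates)
    keys = [(depth[r, c], r, c) for r, c in idx]
    keys.sort()
    return [(r, c) for _, r, c in keys]


def erode_or_dilate_slice(mask2d: np.ndarray, tau: float, seed: int = 0) -> np.ndarray:
    """Erode (tau < 0) or dilate (tau > 0) one slice to an exact pixel count.

    The output area equals ``round(A0 * (1 + tau))``; erosion outputs are
    subsets of the input, dilation outputs supersets. Slices below kernel
    scale (A0 < 9 px or target < 4 px) are returned unchanged with a
    logged warning.
    """
    m = np.asarray(mask2d).astype(bool)
    a0 = int(m.sum())
    if a0 == 0:
        raise ValueError("cannot perturb an empty slice")
    target = int(round(a0 * (1.0 + tau)))
    if a0 < MIN_SLICE_AREA or target < MIN_TARGET_AREA:
        logger.warning(
            "slice area %d px below viable minimum for tau=%.2f; left unperturbed", a0, tau
        )
        return m.copy()
    if tau == 0:
        return m.copy()
    cur = m.copy()
    if tau < 0:
        # whole passes while they do not undershoot the target
        while True:
            nxt = binary_erosion(cur, CROSS)
            if int(nxt.sum()) < target:
                break
            cur = nxt
        need = int(cur.sum()) - target
        if need > 0:
            removable = cur & ~binary_erosion(cur, CROSS)
            # outermost boundary pixels (smallest depth) are removed first,
            # so the innermost survive
            depth = distance_transform_edt(cur)
            for r, c in _rank_pixels(removable, depth)[:need]:
                cur[r, c] = False
    else:
        while True:
            prev = int(cur.sum())
            nxt = binary_dilation(cur, CROSS)
            grown = int(nxt.sum())
            if grown > target:
                break
            if grown == prev:
                raise PaddingError("dilation blocked by the grid border before target area")
            cur = nxt
        need = target - int(cur.sum())
        if need > 0:
            ring = binary_dilation(cur, CROSS) & ~cur
            if not ring.any():
                raise PaddingError("dilation blocked by the grid border before target area")
            # outside pixels nearest to the mask are added first
            depth = distance_transform_edt(~cur)
            for r, c in _rank_pixels(ring, depth)[:need]:
                cur[r, c] = True
    assert int(cur.sum()) == target
    return cur


def randomize_contour_slice(
    image2d: np.ndarray,
    mask2d: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    superpixel_area_mm2: float,
    nu_lo: float = NU_LO,
    nu_hi: float = NU_HI,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomize one slice's ROI contour via intensity-based superpixels.

    The slice is partitioned into ``round(slice_area_mm2 / superpixel_area_mm2)``
    SLIC superpixels; each superpixel's overlap ``nu`` with the original ROI
    region decides inclusion (>= nu_hi), exclusion (<= nu_lo) or a
    Bernoulli(nu) draw in between. Pure function of (inputs, rng state).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = np.asarray(mask2d).astype(bool)
    if not m.any():
        raise ValueError("cannot randomize an empty slice")
    img = np.asarray(image2d, dtype=np.float64)
    ny, nx = m.shape
    slice_area_mm2 = ny * nx * pixel_spacing_mm[0] * pixel_spacing_mm[1]
    n_segments = int(round(slice_area_mm2 / superpixel_area_mm2))
    if n_segments < 4:
        raise ValueError(
            f"superpixel area {superpixel_area_mm2} mm^2 yields only "
            f"{n_segments} superpixels on a {slice_area_mm2:.0f} mm^2 slice"
        )
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    labels = slic(
        norm,
        n_segments=n_segments,
        compactness=SLIC_COMPACTNESS,
        channel_axis=None,
        start_label=1,
        enforce_connectivity=True,
    )
    overlapping = np.unique(labels[m])
    if overlapping.size == 1:
        # a lone superpixel swallowing the whole ROI cannot randomize its
        # contour — only accept it if it genuinely tracks the ROI region
        sp = labels == overlapping[0]
        if int(sp.sum()) > 2 * int(m.sum()):
            raise ValueError(
                "single superpixel covers the ROI; use a smaller superpixel area"
            )
    out = np.zeros_like(m)
    best_label, best_nu = None, -1.0
    for lab in np.unique(labels):
        sp = labels == lab
        nu = float(m[sp].sum()) / float(sp.sum())
        if nu >= nu_hi:
            out |= sp
        elif nu <= nu_lo:
            continue
        else:
            if nu > best_nu:
                best_label, best_nu = lab, nu
            if rng.random() < nu:
                out |= sp
    if not out.any():
        # every borderline draw failed and no superpixel met nu_hi; keep the
        # best-overlapping borderline superpixel so the ROI stays nonempty
        logger.warning("randomized contour came up empty; keeping best superpixel")
        out |= labels == best_label
    return out


def translate_mask(mask: RoiMask, fraction: float, axis: str, sign: int) -> RoiMask:
    """Shift the whole mask in-plane by round(fraction * bbox extent) pixels.

    The pixel count is exactly preserved; a shift that would cross the grid
    border raises :class:`PaddingError` (clipping would change the area).
    """
    if mask.is_empty():
        raise ValueError("cannot translate an empty mask")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    arr_axis = 2 if axis == "x" else 1
    bbox = mask.bounding_box()
    lo, hi = bbox[arr_axis]
    extent = hi - lo + 1
    shift = int(round(fraction * extent)) * int(sign)
    n = mask.shape[arr_axis]
    if lo + shift < 0 or hi + shift > n - 1:
        raise PaddingError(
            f"translation of {shift} px along {axis} leaves the grid "
            f"(bbox [{lo}, {hi}], size {n})"
        )
    out = np.zeros_like(mask.data)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift >= 0:
        src[arr_axis] = slice(0, n - shift)
        dst[arr_axis] = slice(shift, n)
    else:
        src[arr_axis] = slice(-shift, n)
        dst[arr_axis] = slice(0, n + shift)
    out[tuple(dst)] = mask.data[tuple(src)]
    return RoiMask(data=out.astype(np.uint8), spacing=mask.spacing)


def _apply_slicewise_morph(mask: RoiMask, tau: float) -> tuple[RoiMask, dict[int, float]]:
    out = np.zeros_like(mask.data)
    ratios: dict[int, float] = {}
    for z in range(mask.shape[0]):
        sl = mask.data[z]
        a0 = int(sl.sum())
        if a0 == 0:
            continue
        new = erode_or_dilate_slice(sl, tau)
        out[z] = new
        ratios[z] = float(new.sum()) / a0
    return RoiMask(data=out.astype(np.uint8), spacing=mask.spacing), ratios


def _apply_slicewise_randomize(
    image: ImageVolume,
    mask: RoiMask,
    superpixel_area_mm2: float,
    seed: int,
) -> tuple[RoiMask, dict[int, float]]:
    rng = np.random.default_rng(seed)
    out = np.zeros_like(mask.data)
    ratios: dict[int, float] = {}
    spacing_yx = (mask.spacing[1], mask.spacing[2])
    pixel_area = spacing_yx[0] * spacing_yx[1]
    for z in range(mask.shape[0]):
        sl = mask.data[z]
        a0 = int(sl.sum())
        if a0 == 0:
            continue
        if a0 * pixel_area < superpixel_area_mm2:
            # slice smaller than a single superpixel cannot be randomized
            logger.warning(
                "slice %d ROI (%.0f mm^2) below superpixel area %.0f mm^2; left unperturbed",
                z, a0 * pixel_area, superpixel_area_mm2,
            )
            out[z] = sl
            ratios[z] = 1.0
            continue
        try:
            new = randomize_contour_slice(
                image.data[z], sl, spacing_yx, superpixel_area_mm2, rng=rng
            )
        except ValueError as exc:
            logger.warning("slice %d: %s; left unperturbed", z, exc)
            new = sl
        out[z] = new
        ratios[z] = float(new.sum()) / a0
    return RoiMask(data=out.astype(np.uint8), spacing=mask.spacing), ratios


def _entity_set(
    image: ImageVolume, mask: RoiMask, seed: int, tau: float, sp_area: float
) -> dict[str, PerturbedMask]:
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    mask.check_aligned(image)
    out: dict[str, PerturbedMask] = {}
    eroded, r_e = _apply_slicewise_morph(mask, -tau)
    out["erode"] = PerturbedMask(
        mask=eroded, spec=PerturbationSpec(kind="erode", tau=-tau, seed=seed),
        achieved_area_ratio=r_e,
    )
    dilated, r_d = _apply_slicewise_morph(mask, +tau)
    out["dilate"] = PerturbedMask(
        mask=dilated, spec=PerturbationSpec(kind="dilate", tau=+tau, seed=seed),
        achieved_area_ratio=r_d,
    )
    rand, r_r = _apply_slicewise_randomize(image, mask, sp_area, seed)
    out["randomize"] = PerturbedMask(
        mask=rand,
        spec=PerturbationSpec(
            kind="randomize_contour", superpixel_area_mm2=sp_area, seed=seed
        ),
        achieved_area_ratio=r_r,
    )
    return out


def make_stability_set(
    image: ImageVolume, mask: RoiMask, seed: int = 0
) -> dict[str, PerturbedMask]:
    """Small-entity perturbations used to score feature *stability*:
    erosion and dilation at |tau| = 0.15 and contour randomization with
    25 mm^2 superpixels."""
    return _entity_set(image, mask, seed, STABILITY_TAU, STABILITY_SUPERPIXEL_MM2)


def make_augmentation_set(
    image: ImageVolume, mask: RoiMask, seed: int = 0
) -> dict[str, PerturbedMask]:
    """Large-entity perturbations used to synthesize training samples:
    |tau| = 0.30 and 400 mm^2 (4 cm^2) superpixels."""
    return _entity_set(image, mask, seed, AUGMENT_TAU, AUGMENT_SUPERPIXEL_MM2)


def make_discrimination_set(mask: RoiMask) -> dict[str, PerturbedMask]:
    """Four large translations used to score feature *discrimination*:
    +/-30% of the bounding-box extent along x and along y."""
    if mask.is_empty():
        raise ValueError("cannot translate an empty mask")
    out: dict[str, PerturbedMask] = {}
    for axis in ("x", "y"):
        for sign, tag in ((1, "pos"), (-1, "neg")):
            spec = PerturbationSpec(
                kind="translate",
                translation_fraction=TRANSLATION_FRACTION,
                axis=axis,
                sign=sign,
            )
            shifted = translate_mask(mask, TRANSLATION_FRACTION, axis, sign)
            ratios = {
                z: 1.0 for z in range(mask.shape[0]) if mask.data[z].any()
            }
            out[f"translate_{axis}_{tag}"] = PerturbedMask(
                mask=shifted, spec=spec, achieved_area_ratio=ratios
            )
    return out
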