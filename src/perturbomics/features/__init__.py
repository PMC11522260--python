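"""Preprocessing and the 107-feature radiomic registry.

The registry is the standard default set: 14 shape, 18 first-order and 75
texture features (24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM).
Preprocessing is Gaussian denoising (3x3x3 kernel, sigma 0.5 voxels),
z-score standardization for MR-like intensities, and B-spline resampling
to a 2 mm isotropic grid (nearest-neighbour for the mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter

from ..volumes import ImageVolume, RoiMask
from ._firstorder import FIRSTORDER_NAMES, firstorder_features
from ._shape import SHAPE_NAMES, shape_features
from ._texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "ExtractionConfig",
    "ALL_FEATURE_CLASSES",
    "TEXTURE_CLASSES",
    "feature_names",
    "preprocess",
    "extract_features",
    "build_feature_table",
    "META_COLUMNS",
]

ALL_FEATURE_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
TEXTURE_CLASSES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

_CLASS_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

META_COLUMNS = ["patient_id", "variant", "label"]

# registry closure: 14 + 18 + 75
assert len(SHAPE_NAMES) == 14
assert len(FIRSTORDER_NAMES) == 18
assert sum(len(_CLASS_NAMES[c]) for c in TEXTURE_CLASSES) == 75


def feature_names(feature_classes=ALL_FEATURE_CLASSES) -> list[str]:
    """Prefixed feature names in fixed registry order."""
    out: list[str] = []
    for cls in ALL_FEATURE_CLASSES:
        if cls in feature_classes:
            out.extend(f"{cls}_{n}" for n in _CLASS_NAMES[cls])
    return out


@dataclass
class ExtractionConfig:
    """Preprocessing and discretization parameters.

    ``bin_width=None`` resolves per modality: 25 intensity units for
    CT-like images, 0.1 standardized units for MR-like images after
    z-scoring. ``standardize_zscore=None`` resolves to "MR only".
    """

    gaussian_sigma: float = 0.5  # voxels; truncate=2 gives the 3x3x3 kernel
    resample_spacing_mm: float = 2.0
    standardize_zscore: bool | None = None
    bin_width: float | None = None
    feature_classes: tuple[str, ...] = ALL_FEATURE_CLASSES

    def __post_init__(self) -> None:
        if self.resample_spacing_mm <= 0:
            raise ValueError("resample_spacing_mm must be positive")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        unknown = set(self.feature_classes) - set(ALL_FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    def resolve_bin_width(self, modality: str) -> float:
        if self.bin_width is not None:
            return self.bin_width
        return 0.1 if modality == "MR" else 25.0

    def wants_zscore(self, modality: str) -> bool:
        if self.standardize_zscore is None:
            return modality == "MR"
        return self.standardize_zscore


def _resample_to_iso(
    arr: np.ndarray, spacing_zyx, new_spacing: float, interpolator
) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((sx, sy, sz))
    old_size = img.GetSize()  # (x, y, z)
    old_spacing = img.GetSpacing()
    new_size = [
        max(1, int(round(n * s / new_spacing))) for n, s in zip(old_size, old_spacing)
    ]
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        (new_spacing,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return sitk.GetArrayFromImage(out)


def _denoise_standardize(image: ImageVolume, config: ExtractionConfig) -> np.ndarray:
    data = gaussian_filter(image.data, sigma=config.gaussian_sigma, truncate=2.0)
    if config.wants_zscore(image.modality):
        sd = data.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant image")
        data = (data - data.mean()) / sd
    return data


def preprocess(
    image: ImageVolume, mask: RoiMask, config: ExtractionConfig, name: str = "<volume>"
) -> tuple[ImageVolume, RoiMask]:
    """Denoise, (optionally) standardize, and resample an aligned pair."""
    mask.check_aligned(image)
    data = _denoise_standardize(image, config)
    s = config.resample_spacing_mm
    img_rs = _resample_to_iso(data, image.spacing, s, sitk.sitkBSpline)
    msk_rs = _resample_to_iso(
        mask.data.astype(np.uint8), mask.spacing, s, sitk.sitkNearestNeighbor
    )
    new_mask = RoiMask(data=msk_rs, spacing=(s, s, s))
    if new_mask.is_empty():
        raise ValueError(f"{name}: mask is empty after resampling to {s} mm")
    return (
        ImageVolume(data=img_rs, spacing=(s, s, s), modality=image.modality),
        new_mask,
    )


def extract_features(
    image: ImageVolume,
    mask: RoiMask,
    config: ExtractionConfig,
    preprocessed: bool = False,
    name: str = "<volume>",
) -> dict[str, float]:
    """Extract the configured feature classes from one image/mask pair.

    Returns an ordered mapping (registry order). With the default config
    the vector has exactly 107 entries. Set ``preprocessed=True`` when the
    pair already went through :func:`preprocess`.
    """
    if not preprocessed:
        image, mask = preprocess(image, mask, config, name=name)
    mask.check_aligned(image)
    if mask.is_empty():
        raise ValueError(f"{name}: cannot extract features from an empty mask")
    # crop to the bounding box (1-voxel margin) — texture is translation
    # invariant and this keeps the matrix passes cheap
    (z0, z1), (y0, y1), (x0, x1) = mask.bounding_box()
    sl = (
        slice(max(0, z0 - 1), z1 + 2),
        slice(max(0, y0 - 1), y1 + 2),
        slice(max(0, x0 - 1), x1 + 2),
    )
    m = mask.data[sl]
    img = image.data[sl]
    vals = img[m]
    bw = config.resolve_bin_width(image.modality)
    voxvol = float(np.prod(image.spacing))

    out: dict[str, float] = {}
    want = config.feature_classes
    if "shape" in want:
        for k, v in shape_features(m, image.spacing).items():
            out[f"shape_{k}"] = v
    if "firstorder" in want:
        for k, v in firstorder_features(vals, voxvol, bw).items():
            out[f"firstorder_{k}"] = v
    if any(c in want for c in TEXTURE_CLASSES):
        levels = np.zeros(m.shape, dtype=np.int64)
        levels[m] = discretize(vals, bw)
        for cls, fn in (
            ("glcm", glcm_features),
            ("glrlm", glrlm_features),
            ("glszm", glszm_features),
            ("ngtdm", ngtdm_features),
            ("gldm", gldm_features),
        ):
            if cls in want:
                for k, v in fn(levels, m).items():
                    out[f"{cls}_{k}"] = v
    ordered = {n: out[n] for n in feature_names(want)}
    for k, v in ordered.items():
        if not np.isfinite(v):
            raise ValueError(f"{name}: non-finite feature {k} = {v}")
    return ordered


def build_feature_table(
    cohort,
    variants: dict[str, dict] | None,
    config: ExtractionConfig,
) -> pd.DataFrame:
    """One row per (patient, variant) with label and variant tag.

    ``variants`` maps patient_id -> {variant_name -> RoiMask or
    PerturbedMask}; pass None for originals only. The image is denoised and
    resampled once per patient; each variant mask is resampled onto the
    same grid, so feature rows for all variants of a patient share the
    identical intensity field.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for rec in cohort:
        per_patient: list[tuple[str, RoiMask]] = [("original", rec.mask)]
        if variants and rec.patient_id in variants:
            for vname in sorted(variants[rec.patient_id]):
                vmask = variants[rec.patient_id][vname]
                mask_obj = getattr(vmask, "mask", vmask)
                per_patient.append((vname, mask_obj))
        data = _denoise_standardize(rec.image, config)
        s = config.resample_spacing_mm
        img_rs = ImageVolume(
            data=_resample_to_iso(data, rec.image.spacing, s, sitk.sitkBSpline),
            spacing=(s, s, s),
            modality=rec.image.modality,
        )
        for vname, vmask in per_patient:
            key = (rec.patient_id, vname)
            if key in seen:
                raise ValueError(f"duplicate (patient, variant) row {key}")
            seen.add(key)
            msk_rs = RoiMask(
                data=_resample_to_iso(
                    vmask.data.astype(np.uint8), vmask.spacing, s, sitk.sitkNearestNeighbor
                ),
                spacing=(s, s, s),
            )
            if msk_rs.is_empty():
                raise ValueError(
                    f"{rec.patient_id}/{vname}: mask empty after resampling"
                )
            feats = extract_features(
                img_rs, msk_rs, config, preprocessed=True,
                name=f"{rec.patient_id}/{vname}",
            )
            rows.append(
                {"patient_id": rec.patient_id, "variant": vname, "label": rec.label, **feats}
            )
    return pd.DataFrame(rows, columns=META_COLUMNS + feature_names(config.feature_classes))
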