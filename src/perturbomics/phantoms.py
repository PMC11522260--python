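"""Synthetic two-class phantom cohorts.

Each phantom is an ellipsoidal ROI filled with spatially correlated texture
on a homogeneous background, mimicking a segmented soft-tissue structure in
a CT-like volume. The two classes differ in their intra-ROI texture
statistics (mean level and correlation length) by a controllable,
dimensionless effect size; at ``texture_effect=0`` the class-conditional
distributions are identical, which makes null calibration of the downstream
pipeline possible.

The intensity model for a patient of class c is::

    I(v) = [ base + b_p + shift_c + T_c(v) ] * roi(v) + eps(v)

where ``b_p ~ N(0, patient_sd)`` is a per-patient offset, ``shift_c``
equals ``texture_effect * patient_sd`` for class B and 0 for class A,
``T_c`` is Gaussian-filtered white noise (sd ``texture_sd``, in-plane
correlation length differing between classes with the effect size), and
``eps`` is white acquisition noise with sd ``noise_sd``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import ImageVolume, RoiMask

__all__ = [
    "PhantomConfig",
    "PatientRecord",
    "PaddingError",
    "generate_ellipsoid_mask",
    "generate_cohort",
    "write_cohort",
]

# Intensity-model constants (arbitrary CT-like units).
BASE_MEAN = 100.0
TEXTURE_SD = 50.0
PATIENT_SD = 25.0
CORR_LEN_VOX = 1.5  # in-plane correlation length of the texture field, class A

# fraction of the bounding-box extent used by the translation perturbation;
# generation guarantees this much free margin around every ROI
TRANSLATION_FRACTION = 0.30


class PaddingError(ValueError):
    """The grid is too small for the ROI plus its perturbation margin."""


@dataclass
class PhantomConfig:
    """Parameters of a two-class phantom cohort.

    Attributes
    ----------
    n_per_class : int
        Patients per class (>= 2).
    grid_shape : tuple
        Voxels per axis, (nz, ny, nx).
    spacing_mm : tuple
        Voxel spacing in mm, (z, y, x).
    roi_axes_mm : tuple of (lo, hi) pairs
        Sampling ranges of the ellipsoid semi-axes in mm, per axis (z, y, x).
    texture_effect : float
        Dimensionless class separation; 0 means the two classes are drawn
        from the same distribution.
    noise_sd : float
        Standard deviation of additive white intensity noise (>= 0).
    seed : int
        RNG seed; cohorts are bit-reproducible under a fixed seed.
    """

    n_per_class: int = 20
    grid_shape: tuple[int, int, int] = (16, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 1.0, 1.0)
    roi_axes_mm: tuple[tuple[float, float], ...] = ((6.0, 10.0), (10.0, 16.0), (10.0, 16.0))
    texture_effect: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.grid_shape) != 3 or len(self.spacing_mm) != 3:
            raise ValueError("grid_shape and spacing_mm must be length-3")
        for lo, hi in self.roi_axes_mm:
            if not (0 < lo <= hi):
                raise ValueError(f"bad semi-axis range ({lo}, {hi})")
        # largest possible in-plane ROI plus a 30% bounding-box margin on
        # each side must fit; fail fast rather than mid-cohort
        for ax in (1, 2):
            hi_vox = self.roi_axes_mm[ax][1] / self.spacing_mm[ax]
            extent = 2 * hi_vox + 1
            need = extent * (1 + 2 * TRANSLATION_FRACTION) + 4
            if need > self.grid_shape[ax]:
                raise PaddingError(
                    f"grid axis {ax} ({self.grid_shape[ax]} voxels) cannot hold an ROI "
                    f"of extent {extent:.0f} voxels plus a {TRANSLATION_FRACTION:.0%} "
                    "translation margin; enlarge the grid or shrink roi_axes_mm"
                )


@dataclass
class PatientRecord:
    patient_id: str
    label: str
    image: ImageVolume
    mask: RoiMask

    def __post_init__(self) -> None:
        self.mask.check_aligned(self.image)
        if self.mask.is_empty():
            raise ValueError(f"{self.patient_id}: empty mask")


def generate_ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
) -> RoiMask:
    """Voxelize an axis-aligned ellipsoid.

    A voxel belongs to the mask iff its physical center (index * spacing)
    satisfies the ellipsoid inequality
    ``sum(((p_i - c_i)/a_i)^2) <= 1``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    for ax in range(3):
        lo = center_mm[ax] - semi_axes_mm[ax]
        hi = center_mm[ax] + semi_axes_mm[ax]
        if lo < 0 or hi > (grid_shape[ax] - 1) * spacing_mm[ax]:
            raise ValueError(
                f"ellipsoid exceeds grid along axis {ax}: "
                f"[{lo:.1f}, {hi:.1f}] mm outside [0, {(grid_shape[ax]-1)*spacing_mm[ax]:.1f}]"
            )
    coords = [
        np.arange(grid_shape[ax]) * spacing_mm[ax] - center_mm[ax]
        for ax in range(3)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    q = (
        (zz / semi_axes_mm[0]) ** 2
        + (yy / semi_axes_mm[1]) ** 2
        + (xx / semi_axes_mm[2]) ** 2
    )
    return RoiMask(data=(q <= 1.0).astype(np.uint8), spacing=spacing_mm)


def _check_padding(mask: RoiMask) -> None:
    """Every generated ROI must admit +/-30% in-plane translations."""
    (z0, z1), (y0, y1), (x0, x1) = mask.bounding_box()
    ny, nx = mask.shape[1], mask.shape[2]
    for lo, hi, n, name in ((y0, y1, ny, "y"), (x0, x1, nx, "x")):
        shift = int(round(TRANSLATION_FRACTION * (hi - lo + 1)))
        if lo - shift < 0 or hi + shift > n - 1:
            raise PaddingError(
                f"ROI too close to the {name} border for a "
                f"{TRANSLATION_FRACTION:.0%} translation (shift {shift} px)"
            )


def _texture_field(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int],
    corr_len_vox: float,
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit variance."""
    white = rng.standard_normal(grid_shape)
    # smooth in-plane only; slices are thick relative to pixels
    smooth = gaussian_filter(white, sigma=(0, corr_len_vox, corr_len_vox))
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_cohort(config: PhantomConfig) -> list[PatientRecord]:
    """Generate ``2 * n_per_class`` textured phantoms, n_per_class per class.

    A pure function of the config: identical configs yield bit-identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.grid_shape
    sz, sy, sx = config.spacing_mm
    records: list[PatientRecord] = []
    effect = config.texture_effect
    width = len(str(config.n_per_class))
    for label_idx, label in enumerate(config.labels):
        shift = effect * PATIENT_SD if label_idx == 1 else 0.0
        corr = CORR_LEN_VOX * (1.0 + 0.2 * effect) if label_idx == 1 else CORR_LEN_VOX
        for i in range(config.n_per_class):
            semi = tuple(rng.uniform(lo, hi) for lo, hi in config.roi_axes_mm)
            # center near the grid middle, jittered within the safe margin
            center = []
            for ax, (n, sp, a) in enumerate(zip(config.grid_shape, config.spacing_mm, semi)):
                mid = (n - 1) * sp / 2.0
                margin_vox = a / sp
                if ax > 0:
                    margin_vox = margin_vox * (1 + TRANSLATION_FRACTION) + 3
                slack = max(0.0, (n - 1) / 2.0 - margin_vox) * sp
                jitter = rng.uniform(-1, 1) * min(slack, 3.0 * sp)
                center.append(mid + jitter)
            mask = generate_ellipsoid_mask(config.grid_shape, config.spacing_mm, center, semi)
            _check_padding(mask)
            patient_mean = BASE_MEAN + rng.normal(0.0, PATIENT_SD) + shift
            texture = _texture_field(rng, config.grid_shape, corr) * TEXTURE_SD
            intensity = np.where(mask.data, patient_mean + texture, 0.0)
            if config.noise_sd > 0:
                intensity = intensity + rng.normal(0.0, config.noise_sd, config.grid_shape)
            image = ImageVolume(data=intensity, spacing=config.spacing_mm, modality="CT")
            pid = f"{label}{i + 1:0{width}d}"
            records.append(PatientRecord(patient_id=pid, label=label, image=image, mask=mask))
    return records


def write_cohort(records: list[PatientRecord], out_dir: str) -> str:
    """Write NIfTI image/mask pairs plus a CSV manifest; returns manifest path.

    Manifest columns: patient_id, label, image_path, mask_path — the same
    entry point a real cohort would use.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "image_path", "mask_path"])
        for rec in records:
            img_path = os.path.join(out_dir, f"{rec.patient_id}_image.nii.gz")
            msk_path = os.path.join(out_dir, f"{rec.patient_id}_mask.nii.gz")
            rec.image.save(img_path)
            rec.mask.save(msk_path)
            writer.writerow([rec.patient_id, rec.label, img_path, msk_path])
    return manifest_path
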