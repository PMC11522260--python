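"""Cohort manifests, feature-table round-trips, and the run configuration."""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .features import ExtractionConfig, META_COLUMNS
from .phantoms import PatientRecord
from .resampling import ResamplingPlan
from .volumes import load_mask, load_volume

__all__ = [
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "RunConfig",
]

MANIFEST_COLUMNS = ("patient_id", "label", "image_path", "mask_path")


def read_cohort(manifest_path: str, modality: str = "CT") -> list[PatientRecord]:
    """Load a cohort from a CSV manifest of image/mask NIfTI paths.

    Alignment (shape and spacing) of every pair is validated; a mask with
    voxel values outside {0, 1} or a missing file is an error naming the
    offender.
    """
    records = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = [c for c in MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise ValueError(f"manifest missing columns {missing_cols}")
        for row in reader:
            if not row["label"]:
                raise ValueError(f"patient {row['patient_id']!r}: empty label")
            for key in ("image_path", "mask_path"):
                if not os.path.exists(row[key]):
                    raise FileNotFoundError(f"{row['patient_id']}: no such file {row[key]}")
            image = load_volume(row["image_path"], modality=modality)
            mask = load_mask(row["mask_path"])
            try:
                mask.check_aligned(image)
            except ValueError as exc:
                raise ValueError(f"patient {row['patient_id']!r}: {exc}") from exc
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"], label=row["label"], image=image, mask=mask
                )
            )
    return records


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    """CSV dump preserving 12 significant digits and column order."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate columns {dupes}")
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    if len(table) and not np.isfinite(table[feat_cols].to_numpy(dtype=np.float64)).all():
        raise ValueError("refusing to write non-finite feature values")
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicate columns in header")
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """One YAML document resolving every stage's parameters.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.
    """

    manifest: str = ""
    out_dir: str = "runs"
    modality: str = "CT"
    positive_class: str | None = None
    selector: str = "pvalue"
    corr_threshold: float = 0.95
    folds: int = 10
    seed: int = 0
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    resampling: ResamplingPlan = field(default_factory=ResamplingPlan)

    def __post_init__(self) -> None:
        if self.corr_threshold not in (0.90, 0.95):
            raise ValueError("corr_threshold must be 0.90 or 0.95")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extraction" in doc and isinstance(doc["extraction"], dict):
            sub = doc["extraction"]
            bad = set(sub) - set(ExtractionConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown extraction keys: {sorted(bad)}")
            if "feature_classes" in sub:
                sub["feature_classes"] = tuple(sub["feature_classes"])
            doc["extraction"] = ExtractionConfig(**sub)
        if "resampling" in doc and isinstance(doc["resampling"], dict):
            sub = doc["resampling"]
            bad = set(sub) - set(ResamplingPlan.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown resampling keys: {sorted(bad)}")
            doc["resampling"] = ResamplingPlan(**sub)
        return cls(**doc)

    def dump(self, path: str) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def write_json(obj, path: str) -> None:
    class _Enc(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            return super().default(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Enc)
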