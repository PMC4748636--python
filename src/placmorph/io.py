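"""File formats and run configuration.

Images are 8-bit RGB TIFF (PNG optional) with the micron-per-pixel
calibration stored both in the TIFF resolution tags and in a JSON sidecar
(readers differ in tag support); ground truth is a JSON sidecar per field;
cohorts, profiles and test results are plain CSV (comma, UTF-8, '.'
decimal, header mandatory).  Every run directory gets its resolved
:class:`RunConfig` written next to the outputs so any run can be reproduced
from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ConfigError
from .stains import CalibratedImage
from .synthetic.cohort import COHORT_COLUMNS
from .synthetic.field import GroundTruth, NucleusTruth, VesselTruth, VillusTruth

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Resolved knobs of a pipeline run; fully serialisable."""

    seed: int = 0
    alpha: float = 0.05
    sna_k: int = 10
    sna_linkage_um: float = 7.0
    terminal_diameter_um: float = 100.0
    min_lumen_area_um2: float = 20.0
    positivity_rule: str = "otsu"
    level_rule: str = "range"
    mostly_fraction: float = 0.5
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        positive = {
            "sna_linkage_um": self.sna_linkage_um,
            "terminal_diameter_um": self.terminal_diameter_um,
            "min_lumen_area_um2": self.min_lumen_area_um2,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ConfigError(f"RunConfig.{key} must be > 0, got {value}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"RunConfig.alpha must be in (0,1), got {self.alpha}")
        if self.sna_k < 2:
            raise ConfigError(f"RunConfig.sna_k must be >= 2, got {self.sna_k}")
        if self.positivity_rule not in ("otsu", "fixed"):
            raise ConfigError(
                f"RunConfig.positivity_rule must be otsu|fixed, got {self.positivity_rule!r}"
            )
        if self.level_rule not in ("range", "percentile"):
            raise ConfigError(
                f"RunConfig.level_rule must be range|percentile, got {self.level_rule!r}"
            )
        if not 0 < self.mostly_fraction <= 1:
            raise ConfigError(
                f"RunConfig.mostly_fraction must be in (0,1], got {self.mostly_fraction}"
            )

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        version = data.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ConfigError(
                f"config schema version {version!r} != supported {SCHEMA_VERSION}"
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# --------------------------------------------------------------------------
# images


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(img: CalibratedImage, path: str | Path) -> Path:
    """Write an 8-bit RGB TIFF/PNG plus a calibration JSON sidecar."""
    path = Path(path)
    pixels8 = np.clip(
        np.round(img.pixels / img.white_point * 255.0), 0, 255
    ).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        # resolution in pixels per centimetre
        ppcm = 1e4 / img.microns_per_pixel
        tifffile.imwrite(
            path, pixels8, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER"
        )
    elif path.suffix.lower() == ".png":
        Image.fromarray(pixels8).save(path)
    else:
        raise ConfigError(f"unsupported image format: {path.suffix!r}")
    sidecar = {
        "microns_per_pixel": img.microns_per_pixel,
        "stain_kind": img.stain_kind,
        "white_point": 255.0,
        "schema_version": SCHEMA_VERSION,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_image(path: str | Path) -> CalibratedImage:
    """Read an image written by :func:`write_image` (sidecar required)."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigError(f"missing calibration sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError("sidecar schema version mismatch")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return CalibratedImage(
        pixels=pixels.astype(float),
        microns_per_pixel=float(meta["microns_per_pixel"]),
        stain_kind=str(meta["stain_kind"]),
        white_point=float(meta["white_point"]),
    )


# --------------------------------------------------------------------------
# ground truth JSON


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "field_size_um": truth.field_size_um,
        "microns_per_pixel": truth.microns_per_pixel,
        "trophoblast_rim_um": truth.trophoblast_rim_um,
        "villi": [
            {
                "villus_id": v.villus_id,
                "center_um": list(v.center_um),
                "polygon_um": np.asarray(v.polygon_um).tolist(),
                "area_um2": v.area_um2,
                "equivalent_diameter_um": v.equivalent_diameter_um,
                "trophoblast_area_um2": v.trophoblast_area_um2,
                "avascular": v.avascular,
                "vessel_count": v.vessel_count,
            }
            for v in truth.villi
        ],
        "nuclei": [
            {
                "x_um": n.x_um,
                "y_um": n.y_um,
                "compartment": n.compartment,
                "ki67_positive": n.ki67_positive,
                "cd45_positive": n.cd45_positive,
                "sna_id": n.sna_id,
                "villus_id": n.villus_id,
            }
            for n in truth.nuclei
        ],
        "vessels": [
            {
                "villus_id": v.villus_id,
                "x_um": v.x_um,
                "y_um": v.y_um,
                "lumen_radius_um": v.lumen_radius_um,
                "wall_um": v.wall_um,
            }
            for v in truth.vessels
        ],
        "sna_ids": list(truth.sna_ids),
    }


def ground_truth_from_dict(data: dict) -> GroundTruth:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError("ground-truth schema version mismatch")
    villi = [
        VillusTruth(
            villus_id=v["villus_id"],
            center_um=tuple(v["center_um"]),
            polygon_um=np.asarray(v["polygon_um"], dtype=float),
            area_um2=v["area_um2"],
            equivalent_diameter_um=v["equivalent_diameter_um"],
            trophoblast_area_um2=v["trophoblast_area_um2"],
            avascular=v["avascular"],
            vessel_count=v["vessel_count"],
        )
        for v in data["villi"]
    ]
    nuclei = [NucleusTruth(**n) for n in data["nuclei"]]
    vessels = [VesselTruth(**v) for v in data["vessels"]]
    return GroundTruth(
        field_size_um=data["field_size_um"],
        microns_per_pixel=data["microns_per_pixel"],
        trophoblast_rim_um=data["trophoblast_rim_um"],
        villi=villi,
        nuclei=nuclei,
        vessels=vessels,
        sna_ids=list(data["sna_ids"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ground_truth_to_dict(truth)))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return ground_truth_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# tables


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort table missing columns: {missing}")
    path = Path(path)
    df.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort CSV {path} missing columns: {missing}")
    return df
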