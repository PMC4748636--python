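"""Brightfield stain separation and masking.

Brightfield immunohistochemistry obeys Beer-Lambert: the transmitted RGB
intensity is ``I = I0 * exp(-OD)`` where the optical density ``OD`` is a
non-negative linear mixture of per-stain absorbance vectors (haematoxylin,
eosin, DAB).  Colour deconvolution inverts that mixture: convert pixels to
OD space, project onto the stain basis with the pseudo-inverse, clip
negative concentrations.  Everything downstream (tissue masks, positivity
masks, morphometry) operates on the resulting per-stain OD maps, which carry
the physical calibration so areas are always reported in um^2 / mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import CollinearStainsError

# Published absorbance unit vectors (Ruifrok & Johnston convention), rows=stains.
HAEMATOXYLIN = np.array([0.650, 0.704, 0.286])
EOSIN = np.array([0.072, 0.990, 0.105])
DAB = np.array([0.268, 0.570, 0.776])


def _unit(v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=float) / np.linalg.norm(v)


STAIN_KINDS = ("HE", "DAB_Ki67", "DAB_CD31", "DAB_CK7", "DAB_CD45")

#: Default two-stain basis per stain kind: channel 0 is always haematoxylin,
#: channel 1 is eosin (H&E) or DAB (immunostains).
DEFAULT_STAIN_VECTORS: dict[str, np.ndarray] = {
    "HE": np.stack([_unit(HAEMATOXYLIN), _unit(EOSIN)]),
    "DAB_Ki67": np.stack([_unit(HAEMATOXYLIN), _unit(DAB)]),
    "DAB_CD31": np.stack([_unit(HAEMATOXYLIN), _unit(DAB)]),
    "DAB_CK7": np.stack([_unit(HAEMATOXYLIN), _unit(DAB)]),
    "DAB_CD45": np.stack([_unit(HAEMATOXYLIN), _unit(DAB)]),
}

#: Channel names matching the default bases above.
DEFAULT_CHANNEL_NAMES: dict[str, tuple[str, ...]] = {
    "HE": ("haematoxylin", "eosin"),
    "DAB_Ki67": ("haematoxylin", "dab"),
    "DAB_CD31": ("haematoxylin", "dab"),
    "DAB_CK7": ("haematoxylin", "dab"),
    "DAB_CD45": ("haematoxylin", "dab"),
}

OD_MAX = 3.0  # upper OD clip; 8-bit brightfield saturates near I/I0 = exp(-3)


@dataclass(frozen=True)
class CalibratedImage:
    """An RGB brightfield field with physical calibration.

    ``pixels`` is H x W x 3 float in ``[0, white_point]``; ``white_point`` is
    the background (no tissue) intensity.  Quantisation to 8-bit happens only
    on file write, so in-memory round trips are exact.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    stain_kind: str
    white_point: float = 255.0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.white_point <= 0:
            raise ValueError("white_point must be > 0")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainMaps:
    """Per-stain optical-density maps (H x W x C, dimensionless OD units)."""

    od: np.ndarray
    stain_vectors: np.ndarray
    channel_names: tuple[str, ...]
    microns_per_pixel: float
    stain_kind: str

    def channel(self, name: str) -> np.ndarray:
        """Return the OD map for a named stain channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no stain channel {name!r}; have {self.channel_names}"
            ) from None
        return self.od[..., idx]

    @property
    def total_od(self) -> np.ndarray:
        return self.od.sum(axis=-1)

    @property
    def um2_per_px(self) -> float:
        return self.microns_per_pixel**2


def _check_basis(vectors: np.ndarray) -> np.ndarray:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 2 or vectors.shape[1] != 3:
        raise CollinearStainsError("need >= 2 stain vectors of length 3")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise CollinearStainsError("zero-length stain vector")
    unit = vectors / norms[:, None]
    gram = unit @ unit.T
    off = gram[~np.eye(len(unit), dtype=bool)]
    if np.any(np.abs(off) > 1 - 1e-6):
        raise CollinearStainsError("stain vectors are (near-)collinear")
    return unit


def rgb_to_od(pixels: np.ndarray, white_point: float) -> np.ndarray:
    """Per-channel optical density, clipped to ``[0, OD_MAX]``."""
    scaled = np.clip(np.asarray(pixels, dtype=float), 1e-8, None) / white_point
    return np.clip(-np.log(scaled), 0.0, OD_MAX)


def od_to_rgb(od_rgb: np.ndarray, white_point: float) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (Beer-Lambert forward model)."""
    return white_point * np.exp(-np.asarray(od_rgb, dtype=float))


def deconvolve(
    img: CalibratedImage,
    stain_vectors: np.ndarray | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> StainMaps:
    """Unmix an RGB field into per-stain OD concentration maps.

    OD = -log(pixel / white_point) per RGB channel, projected onto the stain
    basis via the Moore-Penrose pseudo-inverse; negative concentrations are
    clipped to zero.  Raises :class:`CollinearStainsError` for an
    ill-conditioned basis.
    """
    if stain_vectors is None:
        if img.stain_kind not in DEFAULT_STAIN_VECTORS:
            raise CollinearStainsError(
                f"no default stain basis for stain kind {img.stain_kind!r}"
            )
        stain_vectors = DEFAULT_STAIN_VECTORS[img.stain_kind]
        if channel_names is None:
            channel_names = DEFAULT_CHANNEL_NAMES[img.stain_kind]
    unit = _check_basis(stain_vectors)
    if channel_names is None:
        channel_names = tuple(f"stain_{i}" for i in range(len(unit)))
    od_rgb = rgb_to_od(img.pixels, img.white_point)
    conc = od_rgb @ np.linalg.pinv(unit)
    conc = np.clip(conc, 0.0, OD_MAX)
    return StainMaps(
        od=conc,
        stain_vectors=unit,
        channel_names=tuple(channel_names),
        microns_per_pixel=img.microns_per_pixel,
        stain_kind=img.stain_kind,
    )


def clean_mask(
    mask: np.ndarray,
    microns_per_pixel: float,
    min_object_um2: float = 60.0,
    max_hole_um2: float = 300.0,
) -> np.ndarray:
    """Remove sub-threshold specks and fill small holes (idempotent)."""
    px_area = microns_per_pixel**2
    out = mask.astype(bool)
    if not out.any():
        return out
    min_px = max(1, int(round(min_object_um2 / px_area)))
    hole_px = max(1, int(round(max_hole_um2 / px_area)))
    out = remove_small_objects(out, max_size=min_px - 1)
    out = remove_small_holes(out, max_size=hole_px - 1)
    return out


def tissue_mask(
    maps: StainMaps,
    min_total_od: float = 0.15,
    min_object_um2: float = 60.0,
    max_hole_um2: float = 300.0,
) -> np.ndarray:
    """Binary villous-tissue mask: summed OD over stains >= ``min_total_od``.

    Small objects below ``min_object_um2`` are discarded and holes (e.g.
    capillary lumens) below ``max_hole_um2`` filled, so the mask area is a
    denominator for per-mm^2 densities.  An empty mask is a valid result.
    """
    if min_total_od < 0:
        raise ValueError("min_total_od must be >= 0")
    raw = maps.total_od >= min_total_od
    return clean_mask(raw, maps.microns_per_pixel, min_object_um2, max_hole_um2)


def positivity_mask(
    maps: StainMaps,
    channel: str = "dab",
    rule: str = "otsu",
    fixed_threshold: float = 0.30,
    tissue: np.ndarray | None = None,
    min_total_od: float = 0.15,
) -> np.ndarray:
    """Stain-positive mask (e.g. DAB-positive) restricted to tissue.

    ``rule`` is ``"otsu"`` (Otsu threshold on the channel's OD values inside
    the tissue mask; the sensible default when no threshold is known) or
    ``"fixed"`` (``od >= fixed_threshold``).  A degenerate channel (constant
    within tissue) makes Otsu fall back to the fixed threshold with a warning.
    """
    od = maps.channel(channel)
    if tissue is None:
        tissue = tissue_mask(maps, min_total_od=min_total_od)
    if rule not in ("otsu", "fixed"):
        raise ValueError(f"unknown positivity rule {rule!r}")
    if rule == "otsu":
        vals = od[tissue]
        if vals.size == 0 or np.ptp(vals) < 1e-9:
            warnings.warn(
                "degenerate stain channel for Otsu; falling back to fixed threshold",
                stacklevel=2,
            )
            thr = fixed_threshold
        else:
            thr = float(threshold_otsu(vals))
            # Otsu on an essentially-negative field splits noise; guard with
            # a floor so an all-negative slide yields an empty mask.
            thr = max(thr, 0.5 * fixed_threshold)
    else:
        thr = fixed_threshold
    return (od >= thr) & tissue


def mask_area_um2(mask: np.ndarray, microns_per_pixel: float) -> float:
    """Physical area of a binary mask in um^2."""
    return float(np.count_nonzero(mask)) * microns_per_pixel**2


def boundary_distance_um(mask: np.ndarray, microns_per_pixel: float) -> np.ndarray:
    """Per-pixel distance (um) to the mask boundary, defined on both sides."""
    inside = ndi.distance_transform_edt(mask)
    outside = ndi.distance_transform_edt(~mask)
    return np.where(mask, inside, outside) * microns_per_pixel
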