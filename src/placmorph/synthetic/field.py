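"""Synthetic multi-villus histology fields with exact ground truth.

A field is a square region of villous tissue: terminal-villus profiles drawn
as smoothed perturbed ellipses, each carrying a syncytiotrophoblast rim,
rim and stromal nuclei, capillary cross-sections, and optionally syncytial
nuclear aggregates (SNAs) protruding from the rim.  Marker identities
(Ki67+, CD45+) are assigned per nucleus; CD31 lives on capillary walls and
CK7 on the trophoblast rim.  Rendering follows Beer-Lambert mixing of
haematoxylin/eosin/DAB absorbance vectors, so the stain-deconvolution
inverse recovers the planted optical densities exactly at zero noise.

Geometry is generated in micron coordinates and rasterised at the requested
calibration; all randomness flows from a single seeded generator, so
identical parameters give byte-identical images and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from ..errors import ConfigError, PackingError, StainKindError
from ..stains import DEFAULT_STAIN_VECTORS, STAIN_KINDS, CalibratedImage

# --------------------------------------------------------------------------
# Rendering constants (optical densities of planted structures).
NUCLEUS_OD = 1.1          # peak haematoxylin OD of a nucleus
NUCLEUS_SIGMA_UM = 1.4    # Gaussian radius of a nucleus footprint
EOSIN_TISSUE_OD = 0.35    # cytoplasm/stroma eosin OD in H&E
IHC_WASH_OD = 0.25        # light haematoxylin counterstain over tissue in IHC
LUMEN_OD = 0.03           # near-clear capillary lumen
VESSEL_WALL_EOSIN_OD = 0.50
DAB_NUCLEUS_OD = 1.0      # DAB OD of a marker-positive nucleus (Ki67/CD45)
DAB_CD31_OD = 0.90        # DAB OD of the capillary endothelial ring
DAB_CK7_OD = 0.80         # DAB OD of the trophoblast rim

# Placement constants (um).
VILLUS_GAP_UM = 8.0           # guaranteed clearance between villus boundaries
SNA_OFFSET_UM = 5.0           # SNA centre offset outward from the rim
SNA_MIN_SEPARATION_UM = 40.0  # between SNA centres
SNA_NUCLEUS_MIN_SEP_UM = 4.8  # within an aggregate
SNA_LINKAGE_UM = 7.0          # single-linkage radius used when counting
SNA_PLANT_LINKAGE_UM = 5.5    # planted clusters connect with margin to spare
NUCLEUS_MIN_SEP_UM = 6.0      # between ordinary nuclei
RIM_NUCLEUS_DEPTH_FRAC = 0.5  # rim nuclei sit mid-rim
VESSEL_WALL_UM = 2.0
SHAPE_MAX_FACTOR = 1.15       # max radial perturbation of the villus outline


@dataclass(frozen=True)
class FieldParams:
    """Parameters of one simulated field.

    Defaults describe a plausible terminal-villus field from a healthy term
    placenta: ~5 % Ki67+ nuclei, ~4 capillaries per villus, ~5 % avascular
    profiles, ~15 SNAs per mm^2 of villous tissue, ~10 leukocytes per 1000
    nuclei.  They are simulation defaults, clearly tunable per condition.
    """

    field_size_um: float = 600.0
    microns_per_pixel: float = 1.0
    n_villi: int = 24
    villus_diameter_um_range: tuple[float, float] = (35.0, 75.0)
    sna_per_mm2: float = 15.0
    ki67_fraction: float = 0.05
    vessels_per_villus_mean: float = 4.0
    avascular_fraction: float = 0.05
    trophoblast_rim_um: float = 6.0
    cd45_per_1000: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    # secondary texture knobs
    rim_nucleus_spacing_um: float = 10.0
    stromal_nuclei_per_um2: float = 0.004
    sna_k: int = 10
    sna_radius_um: float = 12.0

    def __post_init__(self) -> None:
        checks = {
            "field_size_um": self.field_size_um > 0,
            "microns_per_pixel": self.microns_per_pixel > 0,
            "n_villi": self.n_villi >= 0,
            "villus_diameter_um_range": (
                0 < self.villus_diameter_um_range[0] <= self.villus_diameter_um_range[1]
            ),
            "sna_per_mm2": self.sna_per_mm2 >= 0,
            "ki67_fraction": 0 <= self.ki67_fraction <= 1,
            "vessels_per_villus_mean": self.vessels_per_villus_mean >= 0,
            "avascular_fraction": 0 <= self.avascular_fraction <= 1,
            "trophoblast_rim_um": self.trophoblast_rim_um >= 0,
            "cd45_per_1000": 0 <= self.cd45_per_1000 <= 1000,
            "noise_sd": self.noise_sd >= 0,
            "rim_nucleus_spacing_um": self.rim_nucleus_spacing_um > 0,
            "stromal_nuclei_per_um2": self.stromal_nuclei_per_um2 >= 0,
            "sna_k": self.sna_k >= 2,
            "sna_radius_um": self.sna_radius_um > 0,
        }
        for key, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid FieldParams.{key} = {getattr(self, key)!r}")


@dataclass(frozen=True)
class VillusTruth:
    villus_id: int
    center_um: tuple[float, float]        # (x, y)
    polygon_um: np.ndarray                # N x 2 boundary vertices (x, y)
    area_um2: float
    equivalent_diameter_um: float
    trophoblast_area_um2: float
    avascular: bool
    vessel_count: int


@dataclass(frozen=True)
class NucleusTruth:
    x_um: float
    y_um: float
    compartment: str                      # "rim" | "stroma"
    ki67_positive: bool
    cd45_positive: bool
    sna_id: int | None = None
    villus_id: int | None = None


@dataclass(frozen=True)
class VesselTruth:
    villus_id: int
    x_um: float
    y_um: float
    lumen_radius_um: float
    wall_um: float


@dataclass
class GroundTruth:
    """Complete annotation of a simulated field (the recovery oracle)."""

    field_size_um: float
    microns_per_pixel: float
    trophoblast_rim_um: float
    villi: list[VillusTruth]
    nuclei: list[NucleusTruth]
    vessels: list[VesselTruth]
    sna_ids: list[int]
    _masks: dict = field(default_factory=dict, repr=False, compare=False)

    # -- derived tallies ---------------------------------------------------
    @property
    def shape_px(self) -> tuple[int, int]:
        n = int(round(self.field_size_um / self.microns_per_pixel))
        return (n, n)

    @property
    def total_villous_area_um2(self) -> float:
        return float(sum(v.area_um2 for v in self.villi))

    @property
    def total_villous_area_mm2(self) -> float:
        return self.total_villous_area_um2 / 1e6

    @property
    def n_snas(self) -> int:
        return len(self.sna_ids)

    def field_tallies(self) -> dict:
        """Ground-truth per-field tallies matching the measured FieldIndices."""
        nuclei_total = len(self.nuclei)
        return {
            "sna_count": self.n_snas,
            "villous_area_mm2": self.total_villous_area_mm2,
            "ki67_pos": sum(n.ki67_positive for n in self.nuclei),
            "nuclei_total": nuclei_total,
            "vessel_total": sum(v.vessel_count for v in self.villi),
            "n_villi": len(self.villi),
            "n_avascular": sum(v.avascular for v in self.villi),
            "trophoblast_area_mm2": sum(v.trophoblast_area_um2 for v in self.villi)
            / 1e6,
            "cd45_count": sum(n.cd45_positive for n in self.nuclei),
        }

    # -- rasterisation (cached) --------------------------------------------
    def _raster(self, key: str) -> np.ndarray:
        if key not in self._masks:
            self._build_masks()
        return self._masks[key]

    def villus_label_image(self) -> np.ndarray:
        """Integer label image; villus_id i labelled i+1, background 0."""
        return self._raster("labels")

    def villus_union(self) -> np.ndarray:
        return self._raster("union")

    def rim_union(self) -> np.ndarray:
        return self._raster("rim")

    def vessel_ring_union(self) -> np.ndarray:
        return self._raster("ring")

    def vessel_lumen_union(self) -> np.ndarray:
        return self._raster("lumen")

    def _build_masks(self) -> None:
        h, w = self.shape_px
        mpp = self.microns_per_pixel
        labels = np.zeros((h, w), dtype=np.int32)
        rim = np.zeros((h, w), dtype=bool)
        for v in self.villi:
            mask = rasterise_polygon(v.polygon_um, (h, w), mpp)
            labels[mask] = v.villus_id + 1
            rim |= rim_mask_of(mask, self.trophoblast_rim_um, mpp)
        ring = np.zeros((h, w), dtype=bool)
        lumen = np.zeros((h, w), dtype=bool)
        if self.vessels:
            yy, xx = np.mgrid[0:h, 0:w]
            for ves in self.vessels:
                cx, cy = ves.x_um / mpp, ves.y_um / mpp
                r2 = (xx - cx) ** 2 + (yy - cy) ** 2
                r_in = ves.lumen_radius_um / mpp
                r_out = (ves.lumen_radius_um + ves.wall_um) / mpp
                lumen |= r2 <= r_in**2
                ring |= (r2 > r_in**2) & (r2 <= r_out**2)
        self._masks.update(
            labels=labels, union=labels > 0, rim=rim, ring=ring, lumen=lumen
        )


# --------------------------------------------------------------------------
# geometry helpers


def villus_outline(
    r0_um: float, phases: tuple[float, float], n_vertices: int = 128
) -> np.ndarray:
    """Radial outline r(theta) of a perturbed-ellipse villus (um, centred)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = r0_um * (
        1.0
        + 0.10 * np.cos(2 * theta + phases[0])
        + 0.05 * np.cos(3 * theta + phases[1])
    )
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def rasterise_polygon(
    polygon_um: np.ndarray, shape: tuple[int, int], mpp: float
) -> np.ndarray:
    """Boolean mask of a polygon given in (x, y) micron vertices."""
    poly = np.asarray(polygon_um, dtype=float)
    rr, cc = draw_polygon(poly[:, 1] / mpp, poly[:, 0] / mpp, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def rim_mask_of(villus_mask: np.ndarray, rim_um: float, mpp: float) -> np.ndarray:
    """Trophoblast rim: pixels within ``rim_um`` of the villus boundary, inside."""
    if rim_um <= 0 or not villus_mask.any():
        return np.zeros_like(villus_mask)
    depth = ndi.distance_transform_edt(villus_mask) * mpp
    return villus_mask & (depth <= rim_um)


# --------------------------------------------------------------------------
# ground-truth generation


def generate_truth(params: FieldParams) -> GroundTruth:
    """Plant villi, vessels, SNAs and nuclei; return the full annotation.

    Raises :class:`PackingError` if the requested villi cannot be placed
    without overlap within the retry budget (never a silent shortfall).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    mpp = params.microns_per_pixel
    size = params.field_size_um
    h = w = int(round(size / mpp))

    dmin, dmax = params.villus_diameter_um_range
    r0 = rng.uniform(dmin / 2.0, dmax / 2.0, size=params.n_villi)
    r0 = np.sort(r0)[::-1]  # place large villi first: much better packing
    phases = rng.uniform(0, 2 * np.pi, size=(params.n_villi, 2))
    rmax = r0 * SHAPE_MAX_FACTOR
    sna_extent = SNA_OFFSET_UM + params.sna_radius_um + 3.0

    centers: list[tuple[float, float]] = []
    for i in range(params.n_villi):
        margin = rmax[i] + (sna_extent if params.sna_per_mm2 > 0 else 4.0)
        if 2 * margin >= size:
            raise PackingError(
                f"villus of max radius {rmax[i]:.0f} um cannot fit in a "
                f"{size:.0f} um field"
            )
        placed = False
        for _ in range(4000):
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            ok = all(
                math.hypot(cx - px, cy - py) >= rmax[i] + rmax[j] + VILLUS_GAP_UM
                for j, (px, py) in enumerate(centers)
            )
            if ok:
                centers.append((cx, cy))
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place villus {i + 1}/{params.n_villi} after 4000 tries"
            )

    # rasterise each villus once; keep per-villus masks for placement
    villus_masks: list[np.ndarray] = []
    polygons: list[np.ndarray] = []
    areas: list[float] = []
    rim_areas: list[float] = []
    depth_maps: list[np.ndarray] = []
    for i, (cx, cy) in enumerate(centers):
        poly = villus_outline(r0[i], tuple(phases[i])) + np.array([cx, cy])
        mask = rasterise_polygon(poly, (h, w), mpp)
        depth = ndi.distance_transform_edt(mask) * mpp
        polygons.append(poly)
        villus_masks.append(mask)
        depth_maps.append(depth)
        areas.append(float(mask.sum()) * mpp**2)
        rim_areas.append(float((mask & (depth <= params.trophoblast_rim_um)).sum()) * mpp**2)

    total_area_mm2 = sum(areas) / 1e6

    # --- capillaries ------------------------------------------------------
    vessels: list[VesselTruth] = []
    vessel_counts = np.zeros(params.n_villi, dtype=int)
    avascular = np.zeros(params.n_villi, dtype=bool)
    # Draw the avascular uniform and the vessel count unconditionally per
    # villus so that raising avascular_fraction with a fixed seed flips
    # villi monotonically from vascular to avascular.
    u_avasc = rng.uniform(size=params.n_villi)
    for i in range(params.n_villi):
        # zero-truncated Poisson count for vascular villi
        k = int(rng.poisson(params.vessels_per_villus_mean))
        if params.vessels_per_villus_mean > 0:
            while k == 0:
                k = int(rng.poisson(params.vessels_per_villus_mean))
        if u_avasc[i] < params.avascular_fraction or params.vessels_per_villus_mean == 0:
            avascular[i] = True
            continue
        placed_v: list[tuple[float, float, float]] = []
        for _ in range(k):
            lumen_r = rng.uniform(2.5, 4.0)
            need = params.trophoblast_rim_um + lumen_r + VESSEL_WALL_UM + 2.0
            cand = np.argwhere(depth_maps[i] > need)
            if len(cand) == 0:
                break
            ok = False
            for _try in range(60):
                ry, rx = cand[rng.integers(len(cand))]
                vx, vy = (rx + 0.5) * mpp, (ry + 0.5) * mpp
                if all(
                    math.hypot(vx - ox, vy - oy)
                    >= lumen_r + orad + 2 * VESSEL_WALL_UM + 3.0
                    for ox, oy, orad in placed_v
                ):
                    ok = True
                    break
            if not ok:
                break
            placed_v.append((vx, vy, lumen_r))
            vessels.append(VesselTruth(i, vx, vy, lumen_r, VESSEL_WALL_UM))
        vessel_counts[i] = len(placed_v)
        if vessel_counts[i] == 0:
            avascular[i] = True  # packing left no room; truth records reality

    # --- syncytial nuclear aggregates ------------------------------------
    n_snas = int(round(params.sna_per_mm2 * total_area_mm2))
    sna_centers: list[tuple[float, float]] = []
    sna_villus: list[int] = []
    if n_snas > 0 and params.n_villi > 0:
        weights = np.asarray(areas) / sum(areas)
        for _ in range(n_snas):
            for _try in range(600):
                vi = int(rng.choice(params.n_villi, p=weights))
                cx, cy = centers[vi]
                theta = rng.uniform(0, 2 * np.pi)
                r_theta = r0[vi] * (
                    1.0
                    + 0.10 * np.cos(2 * theta + phases[vi][0])
                    + 0.05 * np.cos(3 * theta + phases[vi][1])
                )
                ux, uy = np.cos(theta), np.sin(theta)
                sx = cx + (r_theta + SNA_OFFSET_UM) * ux
                sy = cy + (r_theta + SNA_OFFSET_UM) * uy
                lim = params.sna_radius_um + 3.0
                if not (lim <= sx <= size - lim and lim <= sy <= size - lim):
                    continue
                if any(
                    math.hypot(sx - ox, sy - oy) < SNA_MIN_SEPARATION_UM
                    for ox, oy in sna_centers
                ):
                    continue
                if any(
                    j != vi
                    and math.hypot(sx - centers[j][0], sy - centers[j][1])
                    < rmax[j] + params.sna_radius_um + 6.0
                    for j in range(params.n_villi)
                ):
                    continue
                sna_centers.append((sx, sy))
                sna_villus.append(vi)
                break
            # if no spot found the aggregate is simply not planted;
            # truth records what was placed

    # --- nuclei -----------------------------------------------------------
    nuclei: list[NucleusTruth] = []
    positions: list[tuple[float, float]] = []

    def _far_enough(x: float, y: float, sep: float) -> bool:
        return all(math.hypot(x - px, y - py) >= sep for px, py in positions)

    # SNA nuclei first: grow each aggregate as a connected cluster, every
    # new nucleus within linking range of an existing one, so the counting
    # rule's single-linkage graph is connected by construction (with margin
    # to spare for detection jitter).
    sna_ids: list[int] = []
    for sid, ((sx, sy), vi) in enumerate(zip(sna_centers, sna_villus)):
        pts: list[tuple[float, float]] | None = None
        for _attempt in range(40):
            cand: list[tuple[float, float]] = [(sx, sy)]
            for _ in range(params.sna_k - 1):
                for _try in range(300):
                    px, py = cand[int(rng.integers(len(cand)))]
                    rr = rng.uniform(SNA_NUCLEUS_MIN_SEP_UM, SNA_PLANT_LINKAGE_UM)
                    th = rng.uniform(0, 2 * np.pi)
                    x, y = px + rr * math.cos(th), py + rr * math.sin(th)
                    if math.hypot(x - sx, y - sy) > params.sna_radius_um:
                        continue
                    if all(
                        math.hypot(x - qx, y - qy) >= SNA_NUCLEUS_MIN_SEP_UM
                        for qx, qy in cand
                    ) and _far_enough(x, y, SNA_NUCLEUS_MIN_SEP_UM):
                        cand.append((x, y))
                        break
                else:
                    break
            if len(cand) == params.sna_k:
                pts = cand
                break
        if pts is None:  # pragma: no cover - essentially unreachable
            continue
        sna_ids.append(sid)
        for x, y in pts:
            positions.append((x, y))
            nuclei.append(
                NucleusTruth(x, y, "rim", False, False, sna_id=sid, villus_id=vi)
            )

    # rim nuclei along each villus boundary, mid-rim depth
    for i, poly in enumerate(polygons):
        seg = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1)
        perimeter = float(seg.sum())
        n_rim = int(round(perimeter / params.rim_nucleus_spacing_um))
        if n_rim == 0:
            continue
        arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        offsets = (rng.uniform() + np.arange(n_rim)) / n_rim * perimeter
        cx, cy = centers[i]
        for s in offsets:
            j = int(np.searchsorted(arc, s, side="right") - 1)
            bx, by = poly[j]
            ux, uy = bx - cx, by - cy
            norm = math.hypot(ux, uy)
            depth = RIM_NUCLEUS_DEPTH_FRAC * params.trophoblast_rim_um
            x = cx + (norm - depth) / norm * ux
            y = cy + (norm - depth) / norm * uy
            if any(
                math.hypot(x - ox, y - oy) < params.sna_radius_um + 4.0
                for ox, oy in sna_centers
            ):
                continue  # nuclei near an aggregate are part of the knot
            if not _far_enough(x, y, SNA_NUCLEUS_MIN_SEP_UM):
                continue
            positions.append((x, y))
            nuclei.append(NucleusTruth(x, y, "rim", False, False, villus_id=i))

    # stromal nuclei
    for i in range(params.n_villi):
        stroma_area = max(0.0, areas[i] - rim_areas[i])
        n_st = int(round(params.stromal_nuclei_per_um2 * stroma_area))
        if n_st == 0:
            continue
        interior = depth_maps[i] > params.trophoblast_rim_um + 3.0
        cand = np.argwhere(interior)
        if len(cand) == 0:
            continue
        vset = [v for v in vessels if v.villus_id == i]
        placed = 0
        tries = 0
        while placed < n_st and tries < 80 * n_st:
            tries += 1
            ry, rx = cand[rng.integers(len(cand))]
            x, y = (rx + 0.5) * mpp, (ry + 0.5) * mpp
            if not _far_enough(x, y, NUCLEUS_MIN_SEP_UM):
                continue
            if any(
                math.hypot(x - v.x_um, y - v.y_um)
                < v.lumen_radius_um + v.wall_um + 2.0
                for v in vset
            ):
                continue
            positions.append((x, y))
            nuclei.append(NucleusTruth(x, y, "stroma", False, False, villus_id=i))
            placed += 1

    # marker identities for ordinary (non-SNA) nuclei
    final_nuclei: list[NucleusTruth] = []
    for n in nuclei:
        if n.sna_id is not None:
            final_nuclei.append(n)
            continue
        ki67 = bool(rng.uniform() < params.ki67_fraction)
        cd45 = bool(rng.uniform() < params.cd45_per_1000 / 1000.0)
        final_nuclei.append(
            NucleusTruth(n.x_um, n.y_um, n.compartment, ki67, cd45, villus_id=n.villus_id)
        )

    villi = [
        VillusTruth(
            villus_id=i,
            center_um=centers[i],
            polygon_um=polygons[i],
            area_um2=areas[i],
            equivalent_diameter_um=2.0 * math.sqrt(areas[i] / math.pi),
            trophoblast_area_um2=rim_areas[i],
            avascular=bool(avascular[i]),
            vessel_count=int(vessel_counts[i]),
        )
        for i in range(params.n_villi)
    ]
    return GroundTruth(
        field_size_um=size,
        microns_per_pixel=mpp,
        trophoblast_rim_um=params.trophoblast_rim_um,
        villi=villi,
        nuclei=final_nuclei,
        vessels=vessels,
        sna_ids=sna_ids,
    )


# --------------------------------------------------------------------------
# rendering


def _stamp_gaussians(
    canvas: np.ndarray,
    points_um: np.ndarray,
    amplitude: float,
    sigma_um: float,
    mpp: float,
) -> None:
    """Additively stamp Gaussian bumps at micron positions (in place)."""
    if len(points_um) == 0:
        return
    h, w = canvas.shape
    sigma = sigma_um / mpp
    rad = int(math.ceil(3.5 * sigma))
    ax = np.arange(-rad, rad + 1)
    kernel = amplitude * np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    for x_um, y_um in points_um:
        cx, cy = int(round(x_um / mpp)), int(round(y_um / mpp))
        y0, y1 = max(0, cy - rad), min(h, cy + rad + 1)
        x0, x1 = max(0, cx - rad), min(w, cx + rad + 1)
        canvas[y0:y1, x0:x1] += kernel[
            y0 - (cy - rad) : y1 - (cy - rad), x0 - (cx - rad) : x1 - (cx - rad)
        ]


def planted_od(truth: GroundTruth, stain_kind: str) -> np.ndarray:
    """Per-pixel planted stain concentrations (H x W x 2, OD units).

    Channel 0 is haematoxylin; channel 1 is eosin (H&E) or DAB.  This is
    exactly what colour deconvolution should recover from the rendering at
    zero noise.
    """
    if stain_kind not in STAIN_KINDS:
        raise StainKindError(f"unknown stain kind {stain_kind!r}")
    mpp = truth.microns_per_pixel
    h, w = truth.shape_px
    union = truth.villus_union()
    lumen = truth.vessel_lumen_union()
    ring = truth.vessel_ring_union()

    haem = np.zeros((h, w), dtype=float)
    all_xy = np.array([[n.x_um, n.y_um] for n in truth.nuclei]).reshape(-1, 2)
    _stamp_gaussians(haem, all_xy, NUCLEUS_OD, NUCLEUS_SIGMA_UM, mpp)

    second = np.zeros((h, w), dtype=float)
    if stain_kind == "HE":
        second[union] = EOSIN_TISSUE_OD
        second[ring] = VESSEL_WALL_EOSIN_OD
        second[lumen] = LUMEN_OD
    else:
        haem = haem + IHC_WASH_OD * union
        haem[lumen] = np.minimum(haem[lumen], LUMEN_OD)
        if stain_kind == "DAB_Ki67":
            pos = np.array(
                [[n.x_um, n.y_um] for n in truth.nuclei if n.ki67_positive]
            ).reshape(-1, 2)
            _stamp_gaussians(second, pos, DAB_NUCLEUS_OD, NUCLEUS_SIGMA_UM, mpp)
        elif stain_kind == "DAB_CD45":
            pos = np.array(
                [[n.x_um, n.y_um] for n in truth.nuclei if n.cd45_positive]
            ).reshape(-1, 2)
            _stamp_gaussians(second, pos, DAB_NUCLEUS_OD, NUCLEUS_SIGMA_UM, mpp)
        elif stain_kind == "DAB_CD31":
            second[ring] = DAB_CD31_OD
        elif stain_kind == "DAB_CK7":
            second[truth.rim_union()] = DAB_CK7_OD
    return np.stack([haem, second], axis=-1)


def render_stains(
    truth: GroundTruth,
    stain_kind: str,
    noise_sd: float = 0.0,
    white_point: float = 255.0,
    seed: int | None = None,
) -> CalibratedImage:
    """Render a ground-truth field as an RGB brightfield image.

    Pixels are ``white_point * exp(-OD)`` with OD the planted mixture of the
    default stain vectors (see :func:`planted_od`); marker-positive
    structures appear only in the matching stain kind.  Gaussian sensor
    noise (intensity units) is added after mixing.  Float pixels are
    returned; quantisation to 8 bits happens only on file write.
    """
    conc = planted_od(truth, stain_kind)
    vectors = DEFAULT_STAIN_VECTORS[stain_kind]
    od_rgb = conc[..., 0, None] * vectors[0] + conc[..., 1, None] * vectors[1]
    pixels = white_point * np.exp(-od_rgb)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, white_point)
    return CalibratedImage(
        pixels=pixels,
        microns_per_pixel=truth.microns_per_pixel,
        stain_kind=stain_kind,
        white_point=white_point,
    )


def simulate_field(
    params: FieldParams, stain_kind: str = "HE"
) -> tuple[CalibratedImage, GroundTruth]:
    """Generate one field and render it in the requested stain kind."""
    truth = generate_truth(params)
    img = render_stains(
        truth,
        stain_kind,
        noise_sd=params.noise_sd,
        seed=_render_seed(params.seed, stain_kind),
    )
    return img, truth


def simulate_field_all_stains(
    params: FieldParams,
) -> tuple[dict[str, CalibratedImage], GroundTruth]:
    """One ground truth rendered in every stain kind (serial-section idealisation)."""
    truth = generate_truth(params)
    images = {
        kind: render_stains(
            truth, kind, noise_sd=params.noise_sd, seed=_render_seed(params.seed, kind)
        )
        for kind in STAIN_KINDS
    }
    return images, truth


def simulate_sample(
    params: FieldParams, n_fields: int
) -> tuple[list[dict[str, CalibratedImage]], list[GroundTruth]]:
    """Simulate one placenta: ``n_fields`` independent fields, all stains each.

    Field k reseeds from a child of ``params.seed``, so samples are
    reproducible and fields mutually independent.
    """
    import dataclasses

    bundles, truths = [], []
    for k in range(n_fields):
        child = int(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(1000 + k,))
            .generate_state(1, dtype=np.uint32)[0]
            & 0x7FFFFFFF
        )
        images, truth = simulate_field_all_stains(
            dataclasses.replace(params, seed=child)
        )
        bundles.append(images)
        truths.append(truth)
    return bundles, truths


def pooled_truth_indices(truths: list[GroundTruth]) -> dict[str, float]:
    """Ground-truth six indices pooled over fields (the recovery target)."""
    t = [tr.field_tallies() for tr in truths]
    area = sum(x["villous_area_mm2"] for x in t)
    nuclei = sum(x["nuclei_total"] for x in t)
    villi = sum(x["n_villi"] for x in t)
    return {
        "sna_per_mm2": sum(x["sna_count"] for x in t) / area,
        "proliferative_index": sum(x["ki67_pos"] for x in t) / nuclei,
        "vessels_per_villus": sum(x["vessel_total"] for x in t) / villi,
        "avascular_pct": 100.0 * sum(x["n_avascular"] for x in t) / villi,
        "trophoblast_fraction": sum(x["trophoblast_area_mm2"] for x in t) / area,
        "cd45_per_1000": 1000.0 * sum(x["cd45_count"] for x in t) / nuclei,
    }


def _render_seed(seed: int, stain_kind: str) -> int:
    child = np.random.SeedSequence(
        entropy=seed, spawn_key=(STAIN_KINDS.index(stain_kind),)
    )
    return int(child.generate_state(1, dtype=np.uint32)[0])
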