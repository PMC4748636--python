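"""Measurement operators for the six villous-structure indices.

Per field: villous segmentation, nucleus detection with marker positivity,
SNA cluster counting, per-villus capillary counting and trophoblast-area
measurement.  Per sample: pooled-ratio aggregation over fields

    sna_per_mm2          = sum(SNA counts)     / sum(villous areas, mm^2)
    proliferative_index  = sum(Ki67+ nuclei)   / sum(nuclei)
    vessels_per_villus   = sum(vessel counts)  / sum(villi)
    avascular_pct        = 100 * sum(avascular villi) / sum(villi)
    trophoblast_fraction = sum(CK7+ areas)     / sum(villous areas)
    cd45_per_1000        = 1000 * sum(CD45+ cells) / sum(nuclei)

Pooling tallies (rather than averaging per-field ratios) keeps the
estimates unbiased when fields contain unequal amounts of tissue.  The
random-field sampling protocol (five accepted fields per section, reject
fields not mostly of terminal villi) and observer blinding helpers live
here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import (
    CalibrationMismatchError,
    ConfigError,
    SamplingFailureError,
    StainKindError,
    UndefinedIndexError,
)
from .stains import (
    CalibratedImage,
    StainMaps,
    boundary_distance_um,
    deconvolve,
    mask_area_um2,
    positivity_mask,
    tissue_mask,
)

TERMINAL_DIAMETER_UM = 100.0   # equivalent-diameter rule for a terminal villus
MIN_VILLUS_AREA_UM2 = 300.0    # smaller profiles are debris, not villi
MIN_LUMEN_AREA_UM2 = 20.0      # minimum CD31+ component for a vessel call
SNA_K_DEFAULT = 10             # minimum nuclei for an aggregate call
SNA_LINKAGE_UM = 7.0           # single-linkage radius for nucleus clustering
SNA_PERIMETER_TOL_UM = 14.0    # cluster centroid must sit this close to a rim
NUCLEUS_PEAK_OD = 0.55         # detection threshold on smoothed haematoxylin OD
NUCLEUS_MIN_DISTANCE_UM = 2.5  # non-maximum suppression radius
DAB_POSITIVE_OD = 0.35         # nucleus-level DAB positivity threshold


@dataclass(frozen=True)
class VillusRegion:
    """One segmented villous profile."""

    label: int
    mask: np.ndarray
    area_um2: float
    equivalent_diameter_um: float
    is_terminal: bool
    vessel_count: int | None = None
    avascular: bool | None = None
    trophoblast_area_um2: float | None = None


@dataclass(frozen=True)
class NucleusDetection:
    x_um: float
    y_um: float
    ki67_positive: bool = False
    cd45_positive: bool = False


@dataclass(frozen=True)
class FieldIndices:
    """Raw per-field tallies behind the six indices."""

    sna_count: int
    villous_area_mm2: float
    ki67_pos: int
    nuclei_total: int
    vessel_counts: tuple[int, ...]
    n_villi: int
    n_avascular: int
    trophoblast_area_mm2: float
    cd45_count: int

    def __post_init__(self) -> None:
        if min(
            self.sna_count,
            self.ki67_pos,
            self.nuclei_total,
            self.n_villi,
            self.n_avascular,
            self.cd45_count,
        ) < 0:
            raise ValueError("field tallies must be non-negative")
        if self.ki67_pos > self.nuclei_total:
            raise ValueError("ki67_pos cannot exceed nuclei_total")
        if self.n_avascular > self.n_villi:
            raise ValueError("n_avascular cannot exceed n_villi")
        if self.trophoblast_area_mm2 > self.villous_area_mm2 * 1.05 + 1e-12:
            raise ValueError("trophoblast area cannot exceed villous area")

    @property
    def vessel_total(self) -> int:
        return int(sum(self.vessel_counts))


@dataclass(frozen=True)
class SampleIndices:
    """One placenta's six morphometric indices (pooled over fields)."""

    sna_per_mm2: float
    proliferative_index: float
    vessels_per_villus: float
    avascular_pct: float
    trophoblast_fraction: float
    cd45_per_1000: float
    n_fields: int

    def as_dict(self) -> dict[str, float]:
        return {
            "sna_per_mm2": self.sna_per_mm2,
            "proliferative_index": self.proliferative_index,
            "vessels_per_villus": self.vessels_per_villus,
            "avascular_pct": self.avascular_pct,
            "trophoblast_fraction": self.trophoblast_fraction,
            "cd45_per_1000": self.cd45_per_1000,
        }


# --------------------------------------------------------------------------
# segmentation and detection


def _merge_oversplit(
    labels: np.ndarray, mpp: float, neck_fraction: float
) -> np.ndarray:
    """Merge watershed fragments whose shared boundary is not a neck.

    Two adjacent fragments are rejoined when their contact line is longer
    than ``neck_fraction`` times the smaller fragment's equivalent diameter:
    genuinely touching villi meet along a short neck, whereas a false split
    of a single lobed profile cuts across its whole body.
    """
    labels = labels.copy()
    for _ in range(6):  # chained (3+-way) splits converge in a few passes
        contacts: dict[tuple[int, int], int] = {}
        for axis in (0, 1):
            a = labels.take(range(labels.shape[axis] - 1), axis=axis)
            b = labels.take(range(1, labels.shape[axis]), axis=axis)
            sel = (a != b) & (a > 0) & (b > 0)
            for i, j in zip(a[sel].ravel(), b[sel].ravel()):
                key = (min(i, j), max(i, j))
                contacts[key] = contacts.get(key, 0) + 1
        if not contacts:
            break
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        eq_diam = dict(zip(ids, 2.0 * np.sqrt(counts * mpp**2 / np.pi)))
        parent = {int(i): int(i) for i in ids}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged = False
        for (i, j), n_contact in contacts.items():
            if n_contact * mpp > neck_fraction * min(eq_diam[i], eq_diam[j]):
                ri, rj = find(int(i)), find(int(j))
                if ri != rj:
                    parent[rj] = ri
                    merged = True
        if not merged:
            break
        remap = np.arange(labels.max() + 1)
        for i in ids:
            remap[i] = find(int(i))
        labels = remap[labels]
    return labels


def segment_villi(
    maps: StainMaps,
    tissue: np.ndarray | None = None,
    terminal_diameter_um: float = TERMINAL_DIAMETER_UM,
    min_area_um2: float = MIN_VILLUS_AREA_UM2,
    split_touching: bool = True,
    split_h_um: float = 12.0,
    neck_fraction: float = 0.7,
) -> list[VillusRegion]:
    """Label villous profiles in a field.

    Connected tissue components are labelled; profiles that touch are split
    by a marker-based watershed whose markers are the h-maxima of the
    interior distance transform (depth prominence ``split_h_um``).  A split
    is kept only when the shared boundary between the fragments is narrow
    relative to the fragments (a true neck); wide cuts through a single
    lobed profile are merged back, which leaves solitary profiles intact.
    Terminal villi are those with equivalent diameter below
    ``terminal_diameter_um``.
    """
    mpp = maps.microns_per_pixel
    if tissue is None:
        tissue = tissue_mask(maps)
    if not tissue.any():
        return []
    if split_touching:
        dist = ndi.distance_transform_edt(tissue) * mpp
        markers_mask = h_maxima(dist, split_h_um)
        markers, n_markers = ndi.label(markers_mask)
        if n_markers == 0:
            labels, _ = ndi.label(tissue)
        else:
            labels = watershed(-dist, markers, mask=tissue)
            labels = _merge_oversplit(labels, mpp, neck_fraction)
    else:
        labels, _ = ndi.label(tissue)

    regions: list[VillusRegion] = []
    out_label = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = mask_area_um2(mask, mpp)
        if area < min_area_um2:
            continue
        out_label += 1
        eq_diam = 2.0 * np.sqrt(area / np.pi)
        regions.append(
            VillusRegion(
                label=out_label,
                mask=mask,
                area_um2=area,
                equivalent_diameter_um=eq_diam,
                is_terminal=eq_diam < terminal_diameter_um,
            )
        )
    return regions


def detect_nuclei(
    maps: StainMaps,
    tissue: np.ndarray | None = None,
    smoothing_um: float = 0.8,
    peak_od: float = NUCLEUS_PEAK_OD,
    min_distance_um: float = NUCLEUS_MIN_DISTANCE_UM,
    dab_positive_od: float = DAB_POSITIVE_OD,
) -> list[NucleusDetection]:
    """Blob-detect nuclei on the haematoxylin OD channel.

    Local maxima of the lightly smoothed haematoxylin map above ``peak_od``
    are nuclei; for Ki67/CD45 stain kinds each detection is scored positive
    when the smoothed DAB OD at the nucleus exceeds ``dab_positive_od``.
    """
    mpp = maps.microns_per_pixel
    haem = ndi.gaussian_filter(maps.channel("haematoxylin"), smoothing_um / mpp)
    if tissue is None:
        tissue = tissue_mask(maps)
    coords = peak_local_max(
        haem,
        min_distance=max(1, int(round(min_distance_um / mpp))),
        threshold_abs=peak_od,
        exclude_border=False,
    )
    if len(coords) == 0:
        return []
    keep = tissue[coords[:, 0], coords[:, 1]]
    coords = coords[keep]

    marker = None
    if maps.stain_kind in ("DAB_Ki67", "DAB_CD45") and "dab" in maps.channel_names:
        marker = ndi.gaussian_filter(maps.channel("dab"), smoothing_um / mpp)
    detections = []
    for r, c in coords:
        positive = bool(marker is not None and marker[r, c] >= dab_positive_od)
        detections.append(
            NucleusDetection(
                x_um=(c + 0.5) * mpp,
                y_um=(r + 0.5) * mpp,
                ki67_positive=positive and maps.stain_kind == "DAB_Ki67",
                cd45_positive=positive and maps.stain_kind == "DAB_CD45",
            )
        )
    return detections


def _single_linkage_clusters(points: np.ndarray, linkage_um: float) -> list[np.ndarray]:
    """Union-find single-linkage clustering of 2-D points."""
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(linkage_um):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.asarray(idx) for idx in groups.values()]


def detect_snas(
    maps: StainMaps,
    villi: list[VillusRegion],
    k_min: int = SNA_K_DEFAULT,
    linkage_um: float = SNA_LINKAGE_UM,
    perimeter_tol_um: float = SNA_PERIMETER_TOL_UM,
    nuclei: list[NucleusDetection] | None = None,
) -> int:
    """Count syncytial nuclear aggregates on an H&E field.

    An aggregate is a single-linkage cluster (radius ``linkage_um``) of at
    least ``k_min`` detected nuclei whose centroid lies within
    ``perimeter_tol_um`` of a villous boundary; each cluster counts once.
    """
    if maps.stain_kind != "HE":
        raise StainKindError(
            f"SNA counting requires an H&E field, got {maps.stain_kind!r}"
        )
    if nuclei is None:
        nuclei = detect_nuclei(maps)
    if not nuclei or not villi:
        return 0
    points = np.array([[n.x_um, n.y_um] for n in nuclei])
    union = np.zeros_like(villi[0].mask)
    for v in villi:
        union |= v.mask
    bdist = boundary_distance_um(union, maps.microns_per_pixel)
    h, w = union.shape
    count = 0
    for idx in _single_linkage_clusters(points, linkage_um):
        if len(idx) < k_min:
            continue
        cx, cy = points[idx].mean(axis=0)
        r = min(h - 1, max(0, int(cy / maps.microns_per_pixel)))
        c = min(w - 1, max(0, int(cx / maps.microns_per_pixel)))
        if bdist[r, c] <= perimeter_tol_um:
            count += 1
    return count


def count_vessels(
    villus: VillusRegion,
    maps: StainMaps,
    min_lumen_area_um2: float = MIN_LUMEN_AREA_UM2,
    dab_threshold: float = 0.40,
) -> tuple[int, bool]:
    """Count CD31-positive capillary profiles inside one villus.

    A vessel is a connected CD31-positive component of at least
    ``min_lumen_area_um2`` within the villus mask; the villus is avascular
    iff no such component exists.
    """
    if maps.stain_kind != "DAB_CD31":
        raise StainKindError(
            f"vessel counting requires a CD31 field, got {maps.stain_kind!r}"
        )
    if villus.mask.shape != maps.od.shape[:2]:
        raise CalibrationMismatchError("villus mask does not match image shape")
    dab = maps.channel("dab")
    pos = (dab >= dab_threshold) & villus.mask
    labels, n = ndi.label(pos)
    if n == 0:
        return 0, True
    areas = ndi.sum_labels(
        np.ones_like(labels, dtype=float), labels, index=np.arange(1, n + 1)
    ) * maps.um2_per_px
    count = int(np.count_nonzero(areas >= min_lumen_area_um2))
    return count, count == 0


# --------------------------------------------------------------------------
# per-field and per-sample assembly


def compute_field_indices(
    maps_by_kind: dict[str, StainMaps],
    villi: list[VillusRegion],
    nuclei: list[NucleusDetection],
    sna_count: int,
) -> FieldIndices:
    """Assemble per-field tallies from the per-stain measurements.

    ``villi`` are the CD31-field regions with vessel counts to fill;
    ``nuclei`` are the Ki67-field detections (the denominator used for both
    the proliferative index and the leukocyte rate).  Villous and
    trophoblast areas come from the H&E and CK7 fields respectively.
    """
    mpps = {k: m.microns_per_pixel for k, m in maps_by_kind.items()}
    if len(set(mpps.values())) > 1:
        raise CalibrationMismatchError(f"mixed calibrations: {mpps}")
    for required in ("HE", "DAB_Ki67", "DAB_CD31", "DAB_CK7", "DAB_CD45"):
        if required not in maps_by_kind:
            raise ConfigError(f"missing stain kind {required!r}")

    he = maps_by_kind["HE"]
    villous_area_mm2 = mask_area_um2(tissue_mask(he), he.microns_per_pixel) / 1e6

    cd31 = maps_by_kind["DAB_CD31"]
    counted = [count_vessels(v, cd31) for v in villi]
    vessel_counts = tuple(c for c, _ in counted)
    n_avascular = sum(av for _, av in counted)

    ck7 = maps_by_kind["DAB_CK7"]
    ck7_tissue = tissue_mask(ck7)
    troph = positivity_mask(ck7, channel="dab", tissue=ck7_tissue)
    trophoblast_area_mm2 = mask_area_um2(troph, ck7.microns_per_pixel) / 1e6

    cd45 = maps_by_kind["DAB_CD45"]
    cd45_count = sum(n.cd45_positive for n in detect_nuclei(cd45))

    return FieldIndices(
        sna_count=int(sna_count),
        villous_area_mm2=villous_area_mm2,
        ki67_pos=sum(n.ki67_positive for n in nuclei),
        nuclei_total=len(nuclei),
        vessel_counts=vessel_counts,
        n_villi=len(villi),
        n_avascular=int(n_avascular),
        trophoblast_area_mm2=min(trophoblast_area_mm2, villous_area_mm2),
        cd45_count=int(cd45_count),
    )


def quantify_field(images: dict[str, CalibratedImage]) -> FieldIndices:
    """Measure all per-field tallies from one field's five stain renders."""
    maps = {kind: deconvolve(img) for kind, img in images.items()}
    he_villi = segment_villi(maps["HE"])
    sna_count = detect_snas(maps["HE"], he_villi)
    nuclei = detect_nuclei(maps["DAB_Ki67"])
    cd31_villi = segment_villi(maps["DAB_CD31"])
    return compute_field_indices(maps, cd31_villi, nuclei, sna_count)


def quantify_sample(bundles: list[dict[str, CalibratedImage]]) -> SampleIndices:
    """Measure and pool all fields of one placenta."""
    return aggregate_sample([quantify_field(images) for images in bundles])


def aggregate_sample(fields: list[FieldIndices]) -> SampleIndices:
    """Pool field tallies into one placenta's six indices (pooled ratios)."""
    if not fields:
        raise ConfigError("aggregate_sample needs at least one field")
    area = sum(f.villous_area_mm2 for f in fields)
    nuclei = sum(f.nuclei_total for f in fields)
    villi = sum(f.n_villi for f in fields)
    if area <= 0:
        raise UndefinedIndexError("zero total villous area: densities undefined")
    if nuclei == 0:
        raise UndefinedIndexError("no nuclei detected: per-nucleus indices undefined")
    if villi == 0:
        raise UndefinedIndexError("no villi: per-villus indices undefined")
    return SampleIndices(
        sna_per_mm2=sum(f.sna_count for f in fields) / area,
        proliferative_index=sum(f.ki67_pos for f in fields) / nuclei,
        vessels_per_villus=sum(f.vessel_total for f in fields) / villi,
        avascular_pct=100.0 * sum(f.n_avascular for f in fields) / villi,
        trophoblast_fraction=sum(f.trophoblast_area_mm2 for f in fields) / area,
        cd45_per_1000=1000.0 * sum(f.cd45_count for f in fields) / nuclei,
        n_fields=len(fields),
    )


# --------------------------------------------------------------------------
# acquisition protocol


@dataclass(frozen=True)
class FieldSample:
    section_index: int
    x_um: float
    y_um: float
    image: CalibratedImage


def sample_fields(
    sections: list[CalibratedImage],
    n_per_section: int = 5,
    field_size_um: float = 300.0,
    seed: int = 0,
    mostly_fraction: float = 0.5,
    min_tissue_fraction: float = 0.05,
    max_attempts_per_field: int = 200,
    terminal_diameter_um: float = TERMINAL_DIAMETER_UM,
) -> list[FieldSample]:
    """Draw random accepted fields from each section image.

    Random window positions are drawn per section; a window is rejected
    unless it contains tissue (>= ``min_tissue_fraction`` of its area) and
    is mostly of terminal villi (terminal-villus area >= ``mostly_fraction``
    of its tissue).  Rejected windows are redrawn; exhausting the budget
    raises :class:`SamplingFailureError`.  Deterministic under ``seed``.
    """
    if n_per_section < 1:
        raise ConfigError("n_per_section must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[FieldSample] = []
    for si, section in enumerate(sections):
        mpp = section.microns_per_pixel
        win = int(round(field_size_um / mpp))
        h, w = section.shape
        if win > min(h, w):
            raise ConfigError(
                f"field_size_um {field_size_um} exceeds section {si} extent"
            )
        maps = deconvolve(section)
        tissue = tissue_mask(maps)
        terminal = np.zeros_like(tissue)
        for v in segment_villi(maps, tissue=tissue, terminal_diameter_um=terminal_diameter_um):
            if v.is_terminal:
                terminal |= v.mask
        # summed-area tables make per-window fractions O(1)
        tis_int = np.pad(tissue.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
        ter_int = np.pad(terminal.cumsum(0).cumsum(1), ((1, 0), (1, 0)))

        def boxsum(table: np.ndarray, r0: int, c0: int) -> float:
            r1, c1 = r0 + win, c0 + win
            return float(
                table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]
            )

        accepted = 0
        attempts = 0
        while accepted < n_per_section:
            if attempts >= max_attempts_per_field * n_per_section:
                raise SamplingFailureError(
                    f"section {si}: only {accepted}/{n_per_section} fields accepted "
                    f"after {attempts} attempts"
                )
            attempts += 1
            r0 = int(rng.integers(0, h - win + 1))
            c0 = int(rng.integers(0, w - win + 1))
            tis = boxsum(tis_int, r0, c0)
            if tis < min_tissue_fraction * win * win:
                continue
            if boxsum(ter_int, r0, c0) < mostly_fraction * tis:
                continue
            crop = section.pixels[r0 : r0 + win, c0 : c0 + win].copy()
            out.append(
                FieldSample(
                    section_index=si,
                    x_um=c0 * mpp,
                    y_um=r0 * mpp,
                    image=CalibratedImage(
                        pixels=crop,
                        microns_per_pixel=mpp,
                        stain_kind=section.stain_kind,
                        white_point=section.white_point,
                    ),
                )
            )
            accepted += 1
    return out


def blind_labels(
    cohort: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conceal condition labels behind opaque codes.

    Returns the blinded table (condition column replaced by codes) and the
    key mapping codes back to conditions.  The code assignment is a
    bijection, so merging the key onto the blinded table restores the
    original exactly.
    """
    if "condition" not in cohort.columns or "sample_id" not in cohort.columns:
        raise ConfigError("cohort table needs 'sample_id' and 'condition' columns")
    if cohort["sample_id"].duplicated().any():
        dups = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConfigError(f"duplicate sample ids: {dups}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    conditions = sorted(cohort["condition"].unique())
    codes = [f"G{i + 1:03d}" for i in range(len(conditions))]
    rng.shuffle(conditions)
    mapping = dict(zip(conditions, codes))
    blinded = cohort.copy()
    blinded["condition"] = blinded["condition"].map(mapping)
    key = pd.DataFrame(
        {"code": list(mapping.values()), "condition": list(mapping.keys())}
    ).sort_values("code", ignore_index=True)
    return blinded, key


def unblind_labels(blinded: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`blind_labels` using the key."""
    mapping = dict(zip(key["code"], key["condition"]))
    out = blinded.copy()
    out["condition"] = out["condition"].map(mapping)
    return out
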