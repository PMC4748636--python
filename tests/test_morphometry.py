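"""Measurement operators against the generator's ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from placmorph.errors import (
    CalibrationMismatchError,
    ConfigError,
    SamplingFailureError,
    StainKindError,
    UndefinedIndexError,
)
from placmorph.morphometry import (
    FieldIndices,
    aggregate_sample,
    blind_labels,
    count_vessels,
    detect_nuclei,
    detect_snas,
    quantify_field,
    sample_fields,
    segment_villi,
    unblind_labels,
)
from placmorph.stains import CalibratedImage, deconvolve
from placmorph.synthetic import FieldParams, simulate_field, simulate_field_all_stains
from tests.conftest import SMALL_PARAMS


class TestSegmentVilli:
    def test_planted_villi_recovered_with_areas(self, default_bundle):
        images, truth = default_bundle
        regions = segment_villi(deconvolve(images["HE"]))
        assert len(regions) == len(truth.villi)
        meas = sorted(r.area_um2 for r in regions)
        planted = sorted(v.area_um2 for v in truth.villi)
        for m, p in zip(meas, planted):
            assert m == pytest.approx(p, rel=0.10)

    def test_empty_field_gives_empty_list(self):
        img = CalibratedImage(np.full((64, 64, 3), 255.0), 1.0, "HE")
        assert segment_villi(deconvolve(img)) == []

    def test_region_masks_are_pairwise_disjoint(self, small_bundle):
        images, _ = small_bundle
        regions = segment_villi(deconvolve(images["HE"]))
        total = np.zeros_like(regions[0].mask, dtype=int)
        for r in regions:
            total += r.mask
        assert total.max() <= 1

    def test_terminal_flag_follows_diameter_rule(self):
        img, truth = simulate_field(
            dataclasses.replace(
                SMALL_PARAMS,
                field_size_um=700.0,
                n_villi=4,
                villus_diameter_um_range=(120.0, 160.0),
                sna_per_mm2=0.0,
            ),
            "HE",
        )
        regions = segment_villi(deconvolve(img))
        assert regions and all(not r.is_terminal for r in regions)


class TestDetectNuclei:
    def test_count_close_to_planted(self, default_bundle):
        images, truth = default_bundle
        detections = detect_nuclei(deconvolve(images["DAB_Ki67"]))
        assert len(detections) == pytest.approx(len(truth.nuclei), rel=0.05)

    def test_zero_ki67_fraction_gives_zero_positives(self):
        params = dataclasses.replace(SMALL_PARAMS, ki67_fraction=0.0)
        images, _ = simulate_field_all_stains(params)
        detections = detect_nuclei(deconvolve(images["DAB_Ki67"]))
        assert detections and not any(d.ki67_positive for d in detections)

    def test_ki67_positive_count_matches_truth(self, default_bundle):
        images, truth = default_bundle
        detections = detect_nuclei(deconvolve(images["DAB_Ki67"]))
        planted = sum(n.ki67_positive for n in truth.nuclei)
        assert sum(d.ki67_positive for d in detections) == pytest.approx(
            planted, abs=max(1, 0.1 * planted)
        )

    def test_detections_inside_tissue(self, small_bundle):
        images, truth = small_bundle
        maps = deconvolve(images["HE"])
        from placmorph.stains import tissue_mask

        tissue = tissue_mask(maps)
        for d in detect_nuclei(maps):
            r = int(d.y_um / maps.microns_per_pixel)
            c = int(d.x_um / maps.microns_per_pixel)
            assert tissue[r, c]


class TestDetectSnas:
    def test_planted_aggregates_counted(self, small_bundle):
        images, truth = small_bundle
        maps = deconvolve(images["HE"])
        villi = segment_villi(maps)
        assert detect_snas(maps, villi) == truth.n_snas
        assert truth.n_snas >= 2

    def test_no_aggregates_counts_zero(self):
        params = dataclasses.replace(SMALL_PARAMS, sna_per_mm2=0.0)
        img, _ = simulate_field(params, "HE")
        maps = deconvolve(img)
        assert detect_snas(maps, segment_villi(maps)) == 0

    def test_clusters_below_k_threshold_not_counted(self):
        # aggregates planted with 7 nuclei must not satisfy a K=10 rule
        params = dataclasses.replace(SMALL_PARAMS, sna_k=7)
        img, truth = simulate_field(params, "HE")
        maps = deconvolve(img)
        villi = segment_villi(maps)
        assert truth.n_snas >= 2
        assert detect_snas(maps, villi, k_min=10) == 0
        assert detect_snas(maps, villi, k_min=7) >= truth.n_snas - 1

    def test_requires_he_stain(self, small_bundle):
        images, _ = small_bundle
        maps = deconvolve(images["DAB_Ki67"])
        with pytest.raises(StainKindError):
            detect_snas(maps, [])


class TestCountVessels:
    def test_per_villus_counts_and_flags_match_truth(self, default_bundle):
        images, truth = default_bundle
        maps = deconvolve(images["DAB_CD31"])
        regions = segment_villi(maps)
        # match each region to the planted villus by centroid containment
        labels = truth.villus_label_image()
        total = 0
        for region in regions:
            count, avascular = count_vessels(region, maps)
            ys, xs = np.nonzero(region.mask)
            vid = np.bincount(labels[ys, xs].ravel()).argmax() - 1
            planted = truth.villi[vid]
            assert count == planted.vessel_count
            assert avascular == planted.avascular
            total += count
        assert total == sum(v.vessel_count for v in truth.villi)

    def test_wrong_stain_kind_rejected(self, default_bundle):
        images, _ = default_bundle
        he = deconvolve(images["HE"])
        region = segment_villi(he)[0]
        with pytest.raises(StainKindError):
            count_vessels(region, he)

    def test_mask_shape_mismatch_rejected(self, default_bundle):
        images, _ = default_bundle
        maps = deconvolve(images["DAB_CD31"])
        region = segment_villi(maps)[0]
        bad = dataclasses.replace(region, mask=region.mask[:-10, :-10])
        with pytest.raises(CalibrationMismatchError):
            count_vessels(bad, maps)


class TestAggregation:
    def test_pooled_ratio_arithmetic(self):
        fields = [
            FieldIndices(
                sna_count=2,
                villous_area_mm2=0.5,
                ki67_pos=25,
                nuclei_total=500,
                vessel_counts=(3, 4),
                n_villi=2,
                n_avascular=0,
                trophoblast_area_mm2=0.1,
                cd45_count=2,
            )
        ] * 15
        sample = aggregate_sample(fields)
        assert sample.sna_per_mm2 == pytest.approx(4.0)
        assert sample.proliferative_index == pytest.approx(0.05)
        assert sample.vessels_per_villus == pytest.approx(3.5)
        assert sample.avascular_pct == pytest.approx(0.0)
        assert sample.trophoblast_fraction == pytest.approx(0.2)
        assert sample.cd45_per_1000 == pytest.approx(4.0)
        assert sample.n_fields == 15

    def test_cd45_rate_arithmetic(self):
        field = FieldIndices(
            sna_count=0,
            villous_area_mm2=1.0,
            ki67_pos=0,
            nuclei_total=6000,
            vessel_counts=(1,),
            n_villi=1,
            n_avascular=0,
            trophoblast_area_mm2=0.0,
            cd45_count=30,
        )
        assert aggregate_sample([field]).cd45_per_1000 == pytest.approx(5.0)

    def test_zero_denominators_raise(self):
        empty = FieldIndices(
            sna_count=0,
            villous_area_mm2=0.0,
            ki67_pos=0,
            nuclei_total=0,
            vessel_counts=(),
            n_villi=0,
            n_avascular=0,
            trophoblast_area_mm2=0.0,
            cd45_count=0,
        )
        with pytest.raises(UndefinedIndexError):
            aggregate_sample([empty])

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            FieldIndices(
                sna_count=0,
                villous_area_mm2=1.0,
                ki67_pos=10,
                nuclei_total=5,
                vessel_counts=(),
                n_villi=0,
                n_avascular=0,
                trophoblast_area_mm2=0.0,
                cd45_count=0,
            )
        with pytest.raises(ValueError):
            FieldIndices(
                sna_count=0,
                villous_area_mm2=1.0,
                ki67_pos=0,
                nuclei_total=5,
                vessel_counts=(),
                n_villi=2,
                n_avascular=3,
                trophoblast_area_mm2=0.0,
                cd45_count=0,
            )


@pytest.fixture(scope="module")
def sections():
    out = []
    for s in range(2):
        img, _ = simulate_field(
            FieldParams(
                seed=60 + s,
                field_size_um=700.0,
                n_villi=10,
                villus_diameter_um_range=(35.0, 70.0),
            ),
            "HE",
        )
        out.append(img)
    return out


class TestSampleFields:
    def test_returns_requested_fields(self, sections):
        fields = sample_fields(sections, n_per_section=5, field_size_um=250, seed=1)
        assert len(fields) == 10
        assert {f.section_index for f in fields} == {0, 1}

    def test_deterministic_under_seed(self, sections):
        a = sample_fields(sections, n_per_section=3, field_size_um=250, seed=4)
        b = sample_fields(sections, n_per_section=3, field_size_um=250, seed=4)
        assert [(f.x_um, f.y_um) for f in a] == [(f.x_um, f.y_um) for f in b]

    def test_background_section_fails_explicitly(self):
        bg = CalibratedImage(np.full((400, 400, 3), 255.0), 1.0, "HE")
        with pytest.raises(SamplingFailureError):
            sample_fields([bg], n_per_section=2, field_size_um=200, seed=0)

    def test_non_terminal_section_rejected_by_mostly_rule(self):
        img, _ = simulate_field(
            FieldParams(
                seed=77,
                field_size_um=600.0,
                n_villi=1,
                villus_diameter_um_range=(250.0, 280.0),
                sna_per_mm2=0.0,
            ),
            "HE",
        )
        with pytest.raises(SamplingFailureError):
            sample_fields(
                [img], n_per_section=2, field_size_um=250, seed=0,
                max_attempts_per_field=50,
            )


class TestBlinding:
    @pytest.fixture()
    def cohort(self):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "condition": ["fgr", "control", "fgr", "infection", "control", "fgr"],
                "sna_per_mm2": np.arange(6.0),
            }
        )

    def test_blind_then_unblind_is_identity(self, cohort):
        blinded, key = blind_labels(cohort, seed=9)
        restored = unblind_labels(blinded, key)
        pd.testing.assert_frame_equal(restored, cohort)

    def test_blinded_table_has_no_condition_strings(self, cohort):
        blinded, _ = blind_labels(cohort, seed=9)
        assert not set(blinded["condition"]) & set(cohort["condition"])

    def test_code_assignment_is_bijection(self, cohort):
        _, key = blind_labels(cohort, seed=9)
        assert key["code"].is_unique and key["condition"].is_unique
        assert set(key["condition"]) == set(cohort["condition"])

    def test_duplicate_sample_ids_rejected(self, cohort):
        dup = pd.concat([cohort, cohort.iloc[[0]]], ignore_index=True)
        with pytest.raises(ConfigError):
            blind_labels(dup, seed=0)


def test_avascular_pct_monotone_in_planted_fraction():
    """Raising planted avascular_fraction never lowers measured avascular %."""
    fractions = [0.0, 0.3, 0.7, 1.0]
    measured = []
    for frac in fractions:
        params = dataclasses.replace(
            SMALL_PARAMS, avascular_fraction=frac, sna_per_mm2=0.0
        )
        images, _ = simulate_field_all_stains(params)
        fi = quantify_field(images)
        measured.append(fi.n_avascular / fi.n_villi)
    assert measured == sorted(measured)
    assert measured[-1] == 1.0
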