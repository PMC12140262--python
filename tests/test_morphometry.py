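import numpy as np
import pytest

from peroatlas import morphometry as mm


class TestSynthSection:
    def test_determinism(self):
        a = mm.synth_section(seed=5)
        b = mm.synth_section(seed=5)
        assert np.array_equal(a[0].labels, b[0].labels)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert a[2] == b[2]

    def test_single_class_request(self):
        lab, realized = mm._mosaic_labels((64, 64), 4.0, (1, 0, 0, 0),
                                          np.random.default_rng(0))
        assert (lab == 0).all()
        assert realized[0] == 1.0

    def test_requested_fractions_realized_within_half_percent(self):
        lab, realized = mm._mosaic_labels(
            (512, 512), 6.0, (0.4, 0.3, 0.2, 0.1), np.random.default_rng(1))
        pix = np.bincount(lab.ravel(), minlength=4) / lab.size
        assert np.allclose(pix, realized)
        assert np.max(np.abs(pix - np.array([0.4, 0.3, 0.2, 0.1]))) < 0.005

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            mm._mosaic_labels((64, 64), 4.0, (0.5, 0.2, 0.2, 0.2),
                              np.random.default_rng(0))

    def test_zone_truth_matches_mask(self):
        sec, comp, truth = mm.synth_section(seed=2)
        inside = sec.labels > 0
        for k in (1, 2, 3):
            frac = (sec.labels == k).sum() / inside.sum()
            assert frac == pytest.approx(truth["zone_fractions"][k - 1])
        assert comp.pixel_fractions() == pytest.approx(
            np.asarray(truth["compartment_fractions"]))


class TestZoneAreas:
    def test_uniform_labyrinth_square(self):
        sec = mm.LabeledSection(np.full((100, 100), 3, dtype=np.int32), 10.0)
        za = mm.zone_areas([sec])
        assert za.median_mm2["labyrinth_zone"] == pytest.approx(1.0)
        assert za.relative_fraction == pytest.approx(
            {"decidua": 0.0, "junctional_zone": 0.0, "labyrinth_zone": 1.0})

    def test_median_over_three_sections(self):
        secs = []
        for i, side in enumerate((100, 141, 316)):  # ~1, 2, 10 mm^2 at 10um
            lab = np.full((side, side), 3, dtype=np.int32)
            secs.append(mm.LabeledSection(lab, 10.0, section_id=f"s{i}"))
        za = mm.zone_areas(secs)
        assert za.median_mm2["labyrinth_zone"] == pytest.approx(1.988, abs=0.01)

    def test_matches_brute_force_pixel_counts(self):
        rng = np.random.default_rng(3)
        secs = [mm.synth_section(seed=s)[0] for s in range(3)]
        za = mm.zone_areas(secs)
        for sec in secs:
            for k, name in mm.ZONE_NAMES.items():
                brute = (sec.labels == k).sum() * (10.0 / 1000.0) ** 2
                assert za.per_section_mm2.loc[sec.section_id, name] == \
                    pytest.approx(brute)

    def test_pixel_size_scaling(self):
        lab = (np.random.default_rng(0).random((80, 80)) > 0.5).astype(np.int32) * 3
        a1 = mm.zone_areas([mm.LabeledSection(lab, 5.0)])
        a2 = mm.zone_areas([mm.LabeledSection(lab, 10.0)])
        assert a2.median_mm2["labyrinth_zone"] == pytest.approx(
            4 * a1.median_mm2["labyrinth_zone"])
        assert a1.relative_fraction == pytest.approx(a2.relative_fraction)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mm.zone_areas([])


class TestStereology:
    def test_uniform_mask_gives_unit_fraction(self):
        mask = mm.CompartmentMask(np.full((64, 64), 2, dtype=np.int32), 1.0)
        r = mm.stereology_fractions(mask, 400, seed=0)
        assert r.fractions["tissue"] == 1.0
        assert r.pooled_tissue_fraction == 1.0
        assert sum(r.counts.values()) == 400

    def test_half_plane_estimate(self):
        lab = np.zeros((512, 512), dtype=np.int32)
        lab[:, 256:] = 1
        mask = mm.CompartmentMask(lab, 1.0)
        ests = [mm.stereology_fractions(mask, 400, seed=s).fractions["maternal_blood"]
                for s in range(100)]
        assert abs(np.mean(ests) - 0.5) < 0.01
        assert all(abs(e - 0.5) <= 3 * np.sqrt(0.25 / 400) for e in ests)

    def test_pooled_tissue_matches_planted(self):
        _, comp, truth = mm.synth_section(
            compartment_fractions=(0.45, 0.25, 0.2, 0.1), seed=4)
        pooled = [mm.stereology_fractions(comp, 400, seed=s).pooled_tissue_fraction
                  for s in range(50)]
        planted = truth["compartment_fractions"][2] + truth["compartment_fractions"][3]
        assert np.mean(pooled) == pytest.approx(planted, abs=0.01)

    def test_fixed_grid_reproducible(self):
        _, comp, _ = mm.synth_section(seed=6)
        a = mm.stereology_fractions(comp, 400, grid="fixed")
        b = mm.stereology_fractions(comp, 400, grid="fixed")
        assert a.fractions == b.fractions

    def test_variance_scales_roughly_inverse_n(self):
        _, comp, truth = mm.synth_section(seed=7)
        p = truth["compartment_fractions"][0]
        var = {}
        for n in (100, 400, 1600):
            est = [mm.stereology_fractions(comp, n, seed=s).fractions["maternal_blood"]
                   for s in range(150)]
            var[n] = np.var(est)
        assert var[100] > var[400] > var[1600]
        # systematic grids meet or beat the 1/n binomial rate
        assert 2.5 < var[100] / var[400] < 10
        assert 2.5 < var[400] / var[1600] < 25

    def test_too_many_points_rejected(self):
        mask = mm.CompartmentMask(np.zeros((10, 10), dtype=np.int32), 1.0)
        with pytest.raises(ValueError):
            mm.stereology_fractions(mask, 400)

    def test_pooling_over_replicate_images(self):
        results = [mm.stereology_fractions(mm.synth_section(seed=s)[1], 400,
                                           seed=s) for s in range(6)]
        pooled = mm.pool_stereology(results)
        assert pooled["maternal_blood"] == pytest.approx(
            np.mean([r.fractions["maternal_blood"] for r in results]))


class TestCompartmentTotalArea:
    def test_simple_multiplication(self):
        mask = mm.CompartmentMask(np.zeros((64, 64), dtype=np.int32), 1.0)
        r = mm.stereology_fractions(mask, 400, seed=0)
        areas = mm.compartment_total_area(r, 4.0)
        assert areas["maternal_blood"] == pytest.approx(4.0)

    def test_conservation(self):
        _, comp, _ = mm.synth_section(seed=8)
        r = mm.stereology_fractions(comp, 400, seed=1)
        areas = mm.compartment_total_area(r, 2.5)
        assert sum(areas.values()) == pytest.approx(2.5, abs=1e-12)

    def test_planted_truth_within_three_se(self):
        _, comp, truth = mm.synth_section(seed=9)
        zone = 3.0
        r = mm.stereology_fractions(comp, 400, seed=2)
        est = mm.compartment_total_area(r, zone)["maternal_blood"]
        p = truth["compartment_fractions"][0]
        assert abs(est - p * zone) <= 3 * np.sqrt(p * (1 - p) / 400) * zone

    def test_negative_zone_area_rejected(self):
        mask = mm.CompartmentMask(np.zeros((8, 8), dtype=np.int32), 1.0)
        r = mm.stereology_fractions(mask, 16, seed=0)
        with pytest.raises(ValueError):
            mm.compartment_total_area(r, -1.0)


class TestCellCounting:
    def test_empty_mask(self):
        count, dens = mm.count_cells(np.zeros((50, 50), bool), 1.0)
        assert count == 0 and dens == 0.0

    def test_well_separated_discs(self):
        mask, centers = mm.synth_nuclei(10, shape=(256, 256), radius=8,
                                        radius_jitter=0.0,
                                        min_center_dist=40, seed=0)
        count, _ = mm.count_cells(mask, 1.0)
        assert count == 10

    def test_watershed_splits_touching_pair(self):
        from skimage.draw import disk

        mask = np.zeros((80, 80), bool)
        rr, cc = disk((40, 30), 10)
        mask[rr, cc] = True
        rr, cc = disk((40, 46), 10)
        mask[rr, cc] = True
        count, _ = mm.count_cells(mask, 1.0)
        assert count == 2

    def test_planted_field_counted_within_five_percent(self):
        errs = []
        for seed in range(10):
            mask, _ = mm.synth_nuclei(50, seed=seed)
            count, _ = mm.count_cells(mask, 1.0)
            errs.append(abs(count - 50) / 50)
        assert np.mean(errs) <= 0.05

    def test_translation_invariance_and_additivity(self):
        mask, _ = mm.synth_nuclei(12, shape=(200, 200), radius=7,
                                  min_center_dist=30, seed=1)
        c0, _ = mm.count_cells(mask, 1.0)
        shifted = np.roll(mask, (13, -9), axis=(0, 1))
        c1, _ = mm.count_cells(shifted, 1.0)
        assert c0 == c1
        tiled = np.zeros((200, 400), bool)
        tiled[:, :200] = mask
        tiled[:, 200:] = mask
        c2, _ = mm.count_cells(tiled, 1.0)
        assert c2 == 2 * c0


def test_unbiasedness_of_point_count_estimator():
    # 200 seeded grids: mean within 0.01 of pixel truth per class and
    # empirical SD within 20% of the binomial standard error
    _, comp, truth = mm.synth_section(seed=1)
    p = np.asarray(truth["compartment_fractions"])
    est = np.array([
        [mm.stereology_fractions(comp, 400, seed=s).fractions[n]
         for n in mm.COMPARTMENT_NAMES]
        for s in range(200)
    ])
    assert np.all(np.abs(est.mean(axis=0) - p) < 0.01)
    binom = np.sqrt(p * (1 - p) / 400)
    assert np.all(np.abs(est.std(axis=0) / binom - 1.0) < 0.2)
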