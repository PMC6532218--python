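"""Tissue detection, nuclei segmentation and spatial zoning."""

import numpy as np
import pytest

import oracles
from ihczone.stains import RGBImage
from ihczone.synthetic import CoreSpec, Pattern, render_core
from ihczone.zoning import (
    TERRITORIAL_ZONES,
    EmptyCoreError,
    NucleiLabels,
    TissueMask,
    Zone,
    ZoneParams,
    build_zones,
    detect_tissue,
    nuclei_density,
    segment_nuclei,
)


def _labels_from_mask(mask):
    from scipy import ndimage as ndi

    lab, n = ndi.label(mask)
    cent = ndi.center_of_mass(mask, lab, index=np.arange(1, n + 1)) if n else []
    return NucleiLabels(lab.astype(np.int32), n, np.asarray(cent).reshape(-1, 2))


class TestDetectTissue:
    def test_uniform_white_image_is_empty_core(self):
        img = RGBImage(np.full((32, 32, 3), 255, dtype=np.uint8), 0.5)
        with pytest.raises(EmptyCoreError):
            detect_tissue(img)

    def test_synthetic_disc_recovered(self, mixed_core):
        image, truth = mixed_core
        mask = detect_tissue(image).mask
        inter = (mask & truth.tissue_mask).sum()
        union = (mask | truth.tissue_mask).sum()
        assert inter / union >= 0.95

    def test_area_field_is_pixel_count_times_px_area(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:7, 2:7] = True
        tm = TissueMask(mask, um_per_px=2.0)
        assert tm.tissue_area_mm2 == pytest.approx(25 * (2.0 / 1000) ** 2)


class TestSegmentNuclei:
    def test_zero_hematoxylin_finds_nothing(self):
        tissue = TissueMask(np.ones((32, 32), dtype=bool), 0.5)
        out = segment_nuclei(np.zeros((32, 32)), tissue)
        assert out.n_objects == 0

    def test_well_separated_nuclei_counted_exactly(self):
        spec = CoreSpec(seed=5, n_nuclei=50, noise_sd=0.0,
                        target_positive_fraction=0.0, pattern=Pattern.NONE,
                        min_center_sep_um=14.0)
        image, truth = render_core(spec)
        from ihczone.stains import StainMatrix, rgb_to_od, unmix

        tissue = detect_tissue(image)
        od = unmix(rgb_to_od(image.pixels), StainMatrix.hdab())
        out = segment_nuclei(od.hematoxylin, tissue)
        assert out.n_objects == 50

    def test_default_layout_count_within_5_percent(self, mixed_core):
        image, truth = mixed_core
        from ihczone.stains import StainMatrix, rgb_to_od, unmix

        tissue = detect_tissue(image)
        od = unmix(rgb_to_od(image.pixels), StainMatrix.hdab())
        out = segment_nuclei(od.hematoxylin, tissue)
        assert abs(out.n_objects - truth.n_nuclei) <= 0.05 * truth.n_nuclei

    def test_non_finite_field_rejected(self):
        tissue = TissueMask(np.ones((8, 8), dtype=bool), 0.5)
        field = np.zeros((8, 8))
        field[0, 0] = np.nan
        with pytest.raises(ValueError):
            segment_nuclei(field, tissue)


class TestNucleiDensity:
    def test_arithmetic(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:, :] = True  # 100x100 px at 5 um/px -> 0.25 mm2
        tissue = TissueMask(mask, um_per_px=5.0)
        labels = NucleiLabels(np.zeros((100, 100), dtype=np.int32), 0,
                              np.empty((0, 2)))
        assert nuclei_density(labels, tissue) == 0.0
        labels = _labels_from_mask(np.eye(100, dtype=bool)[:, ::2][:50, :50])
        # density = n / 0.25 mm2
        assert nuclei_density(labels, tissue) == pytest.approx(
            labels.n_objects / 0.25)

    def test_zero_area_raises(self):
        tissue = TissueMask(np.zeros((4, 4), dtype=bool), 1.0)
        labels = NucleiLabels(np.zeros((4, 4), dtype=np.int32), 0,
                              np.empty((0, 2)))
        with pytest.raises(ValueError):
            nuclei_density(labels, tissue)


class TestBuildZones:
    def test_single_nucleus_band_areas_match_annuli(self):
        # disk nucleus r=15 um at 0.2 um/px; bands cyto 3 / cap 2 / para 3 um
        h = w = 400
        px = 0.2
        yy, xx = np.mgrid[0:h, 0:w]
        r_px = 15.0 / px
        nucleus = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2 <= r_px**2
        tissue = TissueMask(np.ones((h, w), dtype=bool), px)
        zones = build_zones(_labels_from_mask(nucleus), tissue,
                            ZoneParams(3.0, 2.0, 3.0, nest_gap_um=0.0))
        px_area = px**2
        r_nuc_eff = 15.0  # um
        r_cell = r_nuc_eff + 3.0
        areas = {
            Zone.CAPSULAR: np.pi * ((r_cell + 2) ** 2 - r_cell**2),
            Zone.PARACAPSULAR: np.pi * ((r_cell + 5) ** 2 - (r_cell + 2) ** 2),
        }
        for zone, analytic in areas.items():
            measured = (zones == zone).sum() * px_area
            assert measured == pytest.approx(analytic, rel=0.02)

    def test_zero_widths_leave_only_cell_regions_territorial(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:22, 18:22] = True
        tissue = TissueMask(np.ones((40, 40), dtype=bool), 1.0)
        zones = build_zones(_labels_from_mask(mask), tissue,
                            ZoneParams(0.0, 0.0, 0.0, 0.0))
        territorial = np.isin(zones, TERRITORIAL_ZONES)
        assert np.array_equal(territorial, mask)

    def test_matches_brute_force_distance_loop(self, rng):
        h = w = 48
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(4):
            r0, c0 = rng.integers(8, h - 8, 2)
            yy, xx = np.mgrid[0:h, 0:w]
            mask |= (yy - r0) ** 2 + (xx - c0) ** 2 <= 9
        tissue = TissueMask(np.ones((h, w), dtype=bool), 1.0)
        # nest_gap 0 so the oracle (which has no closing) applies
        zones = build_zones(_labels_from_mask(mask), tissue,
                            ZoneParams(2.0, 2.0, 3.0, nest_gap_um=0.0))
        want = oracles.zone_loop(mask, tissue.mask, 1.0, 2.0, 2.0, 3.0)
        assert np.array_equal(np.asarray(zones, dtype=int), want)

    def test_empty_nuclei_warns_and_is_all_interterritorial(self):
        tissue = TissueMask(np.ones((16, 16), dtype=bool), 1.0)
        labels = NucleiLabels(np.zeros((16, 16), dtype=np.int32), 0,
                              np.empty((0, 2)))
        with pytest.warns(UserWarning):
            zones = build_zones(labels, tissue)
        assert np.all(zones == Zone.INTERTERRITORIAL)

    def test_partition_covers_every_pixel_once(self, mixed_core):
        image, truth = mixed_core
        assert set(np.unique(truth.zone_map_true)) <= {int(z) for z in Zone}
        # non-tissue outside, a zone inside: exact partition by construction
        inside = truth.zone_map_true[truth.tissue_mask]
        assert np.all(inside != Zone.NON_TISSUE)
        outside = truth.zone_map_true[~truth.tissue_mask]
        assert np.all(outside == Zone.NON_TISSUE)

    def test_capsular_area_monotone_in_width(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 30:34] = True
        tissue = TissueMask(np.ones((64, 64), dtype=bool), 1.0)
        labels = _labels_from_mask(mask)
        areas = []
        for width in (1.0, 2.0, 4.0, 8.0):
            zones = build_zones(labels, tissue,
                                ZoneParams(2.0, width, 3.0, 0.0))
            areas.append(int((zones == Zone.CAPSULAR).sum()))
        assert areas == sorted(areas)

    def test_nest_merge_is_idempotent(self):
        from skimage import morphology

        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.2
        closed_once = morphology.closing(mask, morphology.disk(3))
        closed_twice = morphology.closing(closed_once, morphology.disk(3))
        assert np.array_equal(closed_once, closed_twice)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            ZoneParams(cyto_dilation_um=-1.0)
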