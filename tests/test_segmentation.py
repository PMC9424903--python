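"""Region segmentation against analytic geometry and polygon oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from spatialtme.segmentation import (
    SegmentationParams,
    RegionMaskSet,
    assign_regions,
    extract_invasive_front,
    partition_center,
    rasterize_tumor_mask,
    segment_field,
)


def _square_mask(field_um, res, side_um):
    """Centered solid square mask built directly on the raster."""
    n = int(round(field_um / res))
    half = side_um / 2.0
    centers = (np.arange(n) + 0.5) * res - field_um / 2.0
    inside = np.abs(centers) <= half
    return np.outer(inside, inside)


def _disc_mask(field_um, res, radius_um):
    n = int(round(field_um / res))
    centers = (np.arange(n) + 0.5) * res - field_um / 2.0
    xx, yy = np.meshgrid(centers, centers)
    return xx**2 + yy**2 <= radius_um**2


def area_um2(mask, res):
    return mask.sum() * res**2


class TestRasterize:
    def test_no_tumor_cells_gives_empty_mask(self):
        mask = rasterize_tumor_mask(np.array([]), np.array([]), 400.0, 4.0, 10.0)
        assert not mask.any()

    def test_single_cell_disc_area(self):
        """One cell dilated by radius r covers ~ pi r^2 on a fine grid."""
        res, r = 0.5, 50.0
        mask = rasterize_tumor_mask(np.array([200.0]), np.array([200.0]), 400.0, res, r)
        assert area_um2(mask, res) == pytest.approx(np.pi * r**2, rel=0.02)

    def test_dense_grid_saturates_field(self):
        g = np.arange(2.0, 400.0, 8.0)
        xx, yy = np.meshgrid(g, g)
        mask = rasterize_tumor_mask(xx.ravel(), yy.ravel(), 400.0, 4.0, 10.0)
        assert mask.all()

    def test_bad_resolution_raises(self):
        with pytest.raises(ValueError):
            rasterize_tumor_mask(np.array([1.0]), np.array([1.0]), 400.0, 0.0, 10.0)


class TestInvasiveFront:
    def test_empty_mask_gives_empty_band(self):
        mask = np.zeros((100, 100), dtype=bool)
        assert not extract_invasive_front(mask, 4.0, 300.0).any()

    def test_square_band_area_matches_analytic_value(self):
        """600x600 µm square, 300 µm Euclidean band: four 600x300 edge
        rectangles plus four quarter-disc corners of radius 300."""
        res = 4.0
        mask = _square_mask(2000.0, res, 600.0)
        band = extract_invasive_front(mask, res, 300.0)
        expected = 4 * 600.0 * 300.0 + np.pi * 300.0**2
        assert area_um2(band, res) == pytest.approx(expected, rel=0.02)

    def test_disc_band_area_matches_annulus(self):
        """Disc r=200 µm, 300 µm band: area = pi (500² - 200²)."""
        res = 4.0
        mask = _disc_mask(1884.0, res, 200.0)
        band = extract_invasive_front(mask, res, 300.0)
        assert area_um2(band, res) == pytest.approx(np.pi * (500.0**2 - 200.0**2), rel=0.02)

    def test_band_monotone_in_width(self):
        res = 4.0
        mask = _disc_mask(800.0, res, 120.0)
        prev = np.zeros_like(mask)
        for width in (50.0, 150.0, 300.0):
            band = extract_invasive_front(mask, res, width)
            assert (band | prev).sum() == band.sum()  # superset of narrower band
            prev = band

    def test_band_resolution_convergence(self):
        areas = []
        for res in (4.0, 2.0):
            mask = _disc_mask(1884.0, res, 200.0)
            areas.append(area_um2(extract_invasive_front(mask, res, 300.0), res))
        assert abs(areas[1] - areas[0]) / areas[0] < 0.02

    def test_bad_band_raises(self):
        with pytest.raises(ValueError):
            extract_invasive_front(np.ones((10, 10), dtype=bool), 4.0, 0.0)


class TestPartitionCenter:
    def _two_discs(self, gap_um, res=2.0, radius_um=100.0, field_um=1000.0):
        n = int(round(field_um / res))
        centers = (np.arange(n) + 0.5) * res
        xx, yy = np.meshgrid(centers, centers)
        cy = field_um / 2.0
        x1 = field_um / 2.0 - radius_um - gap_um / 2.0
        x2 = field_um / 2.0 + radius_um + gap_um / 2.0
        return ((xx - x1) ** 2 + (yy - cy) ** 2 <= radius_um**2) | (
            (xx - x2) ** 2 + (yy - cy) ** 2 <= radius_um**2
        )

    def test_all_tumor_ct_means_empty_isa(self):
        mask = np.ones((100, 100), dtype=bool)
        tn, isa = partition_center(mask, 4.0)
        assert tn.all()
        assert not isa.any()

    def test_small_gap_closed_into_single_nest(self):
        """10 µm gap, 20 µm closing radius: TN becomes one component."""
        from scipy import ndimage

        mask = self._two_discs(gap_um=10.0)
        assert ndimage.label(mask)[1] == 2
        tn, _ = partition_center(mask, 2.0, closing_radius_um=20.0)
        assert ndimage.label(tn)[1] == 1

    def test_wide_gap_labeled_stroma(self):
        """100 µm gap stays open at 20 µm closing; gap pixels become ISA."""
        from scipy import ndimage

        mask = self._two_discs(gap_um=100.0)
        tn, isa = partition_center(mask, 2.0, closing_radius_um=20.0)
        assert ndimage.label(tn)[1] == 2
        # the midpoint between the discs is intratumoral stroma
        assert isa[250, 250]

    def test_partition_is_exact(self):
        mask = self._two_discs(gap_um=60.0)
        tn, isa = partition_center(mask, 2.0)
        assert not (tn & isa).any()
        assert (tn | isa).sum() == tn.sum() + isa.sum()
        assert (tn >= mask).all()  # closing is extensive

    def test_empty_mask_gives_empty_partition(self):
        mask = np.zeros((50, 50), dtype=bool)
        tn, isa = partition_center(mask, 4.0)
        assert not tn.any() and not isa.any()


class TestAssignRegions:
    def _maskset(self):
        res, field_um = 4.0, 400.0
        n = int(round(field_um / res))
        tn = np.zeros((n, n), dtype=bool)
        tn[40:60, 40:60] = True  # 160..240 µm square
        isa = np.zeros_like(tn)
        isa[40:60, 60:70] = True
        if_mask = np.zeros_like(tn)
        if_mask[20:40, 40:60] = True
        return RegionMaskSet(
            grid_resolution_um=res, field_size_um=field_um, band_width_um=300.0,
            masks={"IF": if_mask, "TN": tn, "ISA": isa},
        )

    def test_cell_labels_match_pixel_regions(self):
        masks = self._maskset()
        cells = pd.DataFrame(
            {"x_um": [200.0, 250.0, 200.0, 10.0], "y_um": [200.0, 200.0, 100.0, 10.0]}
        )
        labeled = assign_regions(cells, masks)
        assert list(labeled["region"]) == ["TN", "ISA", "IF", "OUTSIDE"]

    def test_out_of_bounds_cells_excluded(self):
        masks = self._maskset()
        cells = pd.DataFrame({"x_um": [200.0, -5.0, 400.0], "y_um": [200.0, 10.0, 10.0]})
        labeled = assign_regions(cells, masks)
        assert len(labeled) == 1

    def test_idempotent(self):
        masks = self._maskset()
        cells = pd.DataFrame({"x_um": [200.0, 250.0], "y_um": [200.0, 200.0]})
        once = assign_regions(cells, masks)
        twice = assign_regions(once, masks)
        assert list(once["region"]) == list(twice["region"])

    def test_boundary_cell_takes_external_band_label(self):
        """A cell sitting exactly on the tumor boundary but outside the
        mask falls into the first IF pixel (half-open convention)."""
        res, field_um = 4.0, 400.0
        n = int(round(field_um / res))
        tumor = np.zeros((n, n), dtype=bool)
        tumor[25:50, 25:50] = True  # tumor: 100..200 µm
        if_mask = extract_invasive_front(tumor, res, 300.0)
        masks = RegionMaskSet(
            grid_resolution_um=res, field_size_um=field_um, band_width_um=300.0,
            masks={"IF": if_mask, "TN": tumor, "ISA": np.zeros_like(tumor)},
        )
        cell = pd.DataFrame({"x_um": [200.0], "y_um": [150.0]})  # x=200 is outside [100,200)
        assert assign_regions(cell, masks)["region"].iloc[0] == "IF"

    def test_against_polygon_oracle(self, field, tissue_params):
        """Segmenting a simulated field from ground-truth tumor cells:
        region assignment of TN-core cells agrees with a shapely
        point-in-polygon test on the ground-truth nest discs."""
        cells, nests = field
        params = SegmentationParams()
        masks = segment_field(
            cells, tissue_params.field_size_um, params,
            tumor_flag=(cells["true_lineage"] == "tumor").to_numpy(),
        )
        labeled = assign_regions(cells, masks)
        discs = [Point(nst.center_x_um, nst.center_y_um).buffer(nst.radius_um) for nst in nests]
        # cells well inside a nest (margin > raster tolerance) must be TN
        margin = params.grid_resolution_um + params.dilation_radius_um
        inner = [Point(n_.center_x_um, n_.center_y_um).buffer(n_.radius_um - margin) for n_ in nests]
        pts = [Point(x, y) for x, y in zip(labeled["x_um"], labeled["y_um"])]
        core = np.array([any(d.contains(p) for d in inner) for p in pts])
        assert (labeled.loc[core, "region"] == "TN").all()
        # cells far from every nest (beyond closing reach) are never TN
        far = np.array(
            [all(p.distance(d) > params.ct_closing_radius_um for d in discs) for p in pts]
        )
        assert not (labeled.loc[far, "region"] == "TN").any()
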