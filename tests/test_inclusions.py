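"""Nucleus segmentation, border exclusion, cell partition, foci counting."""

import numpy as np
import pytest

from oxidtools.inclusions import (
    CellRecord,
    FociParams,
    ImagePair,
    assign_cell_regions,
    detect_foci,
    exclude_border,
    quantify_image,
    segment_nuclei,
    summarize_inclusions,
)
from oxidtools.simulate import ImageSimConfig, simulate_images


def _disk_image(centers, radius=6, shape=(100, 100), amplitude=100.0, background=5.0):
    rows, cols = np.indices(shape)
    img = np.full(shape, background)
    for r, c in centers:
        img += amplitude * ((rows - r) ** 2 + (cols - c) ** 2 <= radius**2)
    return img


class TestSegmentNuclei:
    def test_five_disjoint_disks(self):
        img = _disk_image([(20, 20), (20, 70), (50, 45), (80, 20), (80, 70)])
        mask = segment_nuclei(img)
        assert len(mask) == 5
        assert not any(n.touches_border for n in mask.nuclei)

    def test_blank_image_warns_zero_labels(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_nuclei(np.zeros((50, 50)))
        assert len(mask) == 0

    def test_overlapping_disks_merge(self):
        img = _disk_image([(50, 45), (50, 52)])
        assert len(segment_nuclei(img)) == 1

    def test_border_flag(self):
        img = _disk_image([(0, 50), (50, 50)])
        mask = segment_nuclei(img)
        flags = sorted(n.touches_border for n in mask.nuclei)
        assert flags == [False, True]

    def test_small_speckle_removed(self):
        img = _disk_image([(50, 50)])
        img[10, 10] = 200.0  # single hot pixel, below min_nucleus_area
        assert len(segment_nuclei(img, min_nucleus_area=20)) == 1


class TestExcludeBorder:
    def test_border_nuclei_removed(self):
        img = _disk_image([(0, 20), (30, 99), (60, 50)])
        mask = segment_nuclei(img)
        kept = exclude_border(mask)
        assert len(mask) == 3 and len(kept) == 1
        assert not kept.nuclei[0].touches_border
        # labels of removed nuclei are zeroed in the label image
        assert set(np.unique(kept.labels)) == {0, kept.nuclei[0].label}

    def test_identity_when_no_border_contact(self):
        mask = segment_nuclei(_disk_image([(30, 30), (70, 70)]))
        kept = exclude_border(mask)
        assert [n.label for n in kept.nuclei] == [n.label for n in mask.nuclei]

    def test_all_border_gives_empty_mask(self):
        mask = segment_nuclei(_disk_image([(0, 30), (99, 70)]))
        assert len(exclude_border(mask)) == 0


class TestAssignRegions:
    def test_single_nucleus_owns_everything(self):
        mask = segment_nuclei(_disk_image([(50, 50)]))
        regions = assign_cell_regions(mask, (100, 100))
        assert set(np.unique(regions)) == {1}

    def test_mirrored_nuclei_split_at_midline(self):
        mask = segment_nuclei(_disk_image([(50, 30), (50, 70)]))
        regions = assign_cell_regions(mask, (100, 100))
        assert (regions[:, :50] == 1).all()
        assert (regions[:, 51:] == 2).all()
        assert (regions[:, 50] == 1).all()  # equidistant column: lower label wins

    def test_each_region_contains_its_centroid(self):
        mask = segment_nuclei(_disk_image([(20, 20), (30, 80), (80, 40)]))
        regions = assign_cell_regions(mask, (100, 100))
        for n in mask.nuclei:
            r, c = (int(round(x)) for x in n.centroid)
            assert regions[r, c] == n.label

    def test_empty_mask_raises(self):
        with pytest.warns(UserWarning):
            mask = segment_nuclei(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="no countable cells"):
            assign_cell_regions(mask, (20, 20))


class TestDetectFoci:
    def _pair_with_spots(self, spot_centers, amplitude=80.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, cols = np.indices((100, 100))
        protein = np.full((100, 100), 10.0)
        for r, c in spot_centers:
            protein += amplitude * np.exp(
                -((rows - r) ** 2 + (cols - c) ** 2) / (2 * 1.5**2)
            )
        protein += rng.normal(0, 2.0, (100, 100))
        return np.clip(protein, 0, None)

    def test_flat_region_has_no_foci(self):
        regions = np.ones((50, 50), dtype=int)
        counts = detect_foci(np.full((50, 50), 7.0), regions)
        assert counts == {1: 0}

    def test_three_separated_spots_counted(self):
        protein = self._pair_with_spots([(25, 25), (25, 75), (75, 50)])
        regions = np.ones((100, 100), dtype=int)
        counts = detect_foci(protein, regions)
        assert counts[1] == 3

    def test_huge_k_mad_suppresses_everything(self):
        protein = self._pair_with_spots([(25, 25), (75, 75)])
        regions = np.ones((100, 100), dtype=int)
        counts = detect_foci(protein, regions, FociParams(k_mad=1e9))
        assert counts[1] == 0

    def test_counts_monotone_in_k_mad(self):
        protein = self._pair_with_spots([(20, 20), (50, 50), (80, 80)], seed=4)
        regions = np.ones((100, 100), dtype=int)
        previous = None
        for k in (2.0, 4.0, 8.0, 16.0, 1e6):
            n = detect_foci(protein, regions, FociParams(k_mad=k))[1]
            if previous is not None:
                assert n <= previous
            previous = n

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FociParams(spot_scale_px=0.5)
        with pytest.raises(ValueError):
            FociParams(k_mad=0)


class TestSummarize:
    def _cell(self, label, n_foci):
        return CellRecord(label=label, centroid=(0.0, 0.0), n_foci=n_foci)

    def test_percent_examples(self):
        cells = [self._cell(i, 1 if i < 3 else 0) for i in range(9)]
        summary = summarize_inclusions(cells)
        assert summary.n_cells_counted == 9
        assert summary.percent_with_inclusions == 33.33

    def test_extremes(self):
        assert summarize_inclusions(
            [self._cell(i, 0) for i in range(10)]
        ).percent_with_inclusions == 0.00
        assert summarize_inclusions(
            [self._cell(i, 2) for i in range(4)]
        ).percent_with_inclusions == 100.00

    def test_no_cells_raises(self):
        with pytest.raises(ValueError, match="no countable cells"):
            summarize_inclusions([])


class TestEndToEnd:
    def test_border_cells_never_counted(self):
        cfg = ImageSimConfig(n_nuclei=30, fraction_border=0.3, seed=9)
        pair, truth = simulate_images(cfg)
        cells, summary = quantify_image(pair)
        assert summary.n_cells_counted == truth.n_countable
        border_centers = [c.center for c in truth.cells if c.touches_border]
        for cell in cells:
            nearest = min(
                truth.cells,
                key=lambda t: (t.center[0] - cell.centroid[0]) ** 2
                + (t.center[1] - cell.centroid[1]) ** 2,
            )
            assert nearest.center not in border_centers

    def test_determinism(self):
        pair, _ = simulate_images(ImageSimConfig(seed=21))
        _, s1 = quantify_image(pair)
        _, s2 = quantify_image(pair)
        assert s1 == s2

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ImagePair(np.zeros((10, 10)), np.zeros((10, 12)))
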