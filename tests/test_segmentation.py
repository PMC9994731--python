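"""Compartment segmentation: cell outline, ice split, channel derivation."""

import numpy as np
import pytest
from scipy import ndimage

import cryoraman as cr
from cryoraman.errors import EmptyChannelError, NoCellError
from cryoraman.segmentation import (
    detect_edges,
    segment_all_cells,
    segment_cell,
    segment_ice,
    derive_channels,
)

from conftest import sweep_params


def _disk_map(center=(22, 22), radius=10.0, inside=100.0, outside=5.0, shape=(45, 45)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.where(disk, inside, outside), disk


class TestSegmentCell:
    def test_noise_free_disk_recovered(self):
        """A sharp disk (amplitude 100 on background 5) is recovered near-exactly."""
        values, disk = _disk_map()
        cell = segment_cell(values)
        iou = (cell & disk).sum() / (cell | disk).sum()
        assert iou >= 0.90
        cm = ndimage.center_of_mass(cell)
        assert np.hypot(cm[0] - 22, cm[1] - 22) <= 1.0

    def test_border_touching_cell_rejected(self):
        values, _ = _disk_map(center=(5, 22))
        with pytest.raises(NoCellError):
            segment_cell(values)

    def test_all_zero_map_rejected(self):
        with pytest.raises(NoCellError):
            segment_cell(np.zeros((45, 45)))

    def test_tiny_component_rejected(self):
        values, _ = _disk_map(radius=3.5)
        with pytest.raises(NoCellError):  # covers the <50-pixel regime too
            segment_cell(values)

    def test_mask_iou_and_centroid_across_seeded_phantoms(self):
        """Across 20 noise-free geometries: IoU >= 0.90, centroid within 1 px."""
        for params in sweep_params(noise_sd=0.0):
            scene = cr.generate_scene(params)
            amide = cr.compute_intensity_map(
                cr.render_cube(scene), cr.default_bands()[1]
            )
            cell = segment_cell(amide)
            truth = scene.truth_masks.cell
            iou = (cell & truth).sum() / (cell | truth).sum()
            assert iou >= 0.90, f"seed {params.seed}: IoU {iou:.3f}"
            cm = ndimage.center_of_mass(cell)
            ct = ndimage.center_of_mass(truth)
            assert np.hypot(cm[0] - ct[0], cm[1] - ct[1]) <= 1.0


def test_segment_all_cells_finds_both_disks():
    """A raster with two cells yields both components, largest first."""
    rr, cc = np.mgrid[0:45, 0:45]
    a = (rr - 13) ** 2 + (cc - 13) ** 2 <= 8**2
    b = (rr - 32) ** 2 + (cc - 32) ** 2 <= 6**2
    values = np.where(a | b, 100.0, 5.0)
    cells = segment_all_cells(values)
    assert len(cells) == 2
    assert cells[0].sum() > cells[1].sum()
    assert (cells[0] & a).sum() / (cells[0] | a).sum() >= 0.9
    assert (cells[1] & b).sum() / (cells[1] | b).sum() >= 0.9
    # the single-cell entry point picks the larger one
    single = segment_cell(values)
    np.testing.assert_array_equal(single, cells[0])


def test_edge_sensitivity_monotone(baseline_output):
    """Raising the sensitivity multiplier never admits more edge pixels."""
    values = baseline_output.maps["amide"].values
    counts = [
        detect_edges(values, s).sum() for s in (0.5, 0.6, 0.65, 0.7, 0.8, 0.9)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSegmentIce:
    def test_no_intracellular_signal_gives_empty_inner_mask(self, baseline_output):
        assert not baseline_output.masks.ice_intracellular.any()

    def test_intracellular_pocket_recovered(self):
        """A pocket matching extracellular ice intensity is found within 1 px."""
        scene = cr.generate_scene(
            cr.SceneParams(intracellular_ice_fraction=0.07, noise_sd=0.0, seed=4)
        )
        out = cr.run_analyze(
            cr.render_cube(scene), config=cr.AnalysisConfig(allow_iif=True)
        )
        truth = scene.truth_masks.ice_intracellular
        found = out.masks.ice_intracellular
        dilated_truth = ndimage.binary_dilation(truth, np.ones((3, 3), bool))
        assert (found & ~dilated_truth).sum() == 0  # no far-off false ice
        missed_interior = ndimage.binary_erosion(truth, np.ones((3, 3), bool)) & ~found
        assert missed_interior.sum() == 0

    def test_constant_map_yields_empty_masks(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[8:12, 8:12] = True
        ice_out, ice_in = segment_ice(np.full((20, 20), 2.0), cell)
        assert not ice_out.any() and not ice_in.any()

    def test_singleton_inner_components_discarded(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        values = np.full((20, 20), 0.1)
        values[2:4, 2:4] = 10.0   # extracellular ice block
        values[8, 8] = 10.0       # lone supra-threshold pixel inside the cell
        ice_out, ice_in = segment_ice(values, cell)
        assert ice_out[2, 2] and not ice_in.any()


class TestDeriveChannels:
    def test_complement_identity(self, baseline_output):
        m = baseline_output.masks
        np.testing.assert_array_equal(m.channel, ~m.cell & ~m.ice_extracellular)

    def test_empty_channel_raises(self):
        cell = np.zeros((10, 10), dtype=bool)
        ice = np.ones((10, 10), dtype=bool)
        with pytest.raises(EmptyChannelError):
            derive_channels(cell, ice)

    def test_channel_iou_against_truth(self, sweep_outputs):
        for scene, out in sweep_outputs:
            t, f = scene.truth_masks.channel, out.masks.channel
            assert (t & f).sum() / (t | f).sum() >= 0.90


def test_partition_property_on_all_outputs(sweep_outputs):
    """Cell, extracellular ice, and channel tile the image exactly once."""
    for _, out in sweep_outputs:
        m = out.masks
        m.validate()
        total = m.cell.astype(int) + m.ice_extracellular.astype(int) + m.channel.astype(int)
        assert (total == 1).all()
        assert not (m.ice_intracellular & ~m.cell).any()


def test_cell_mask_single_interior_component(sweep_outputs):
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    for _, out in sweep_outputs:
        cell = out.masks.cell
        _, n = ndimage.label(cell, structure=four)
        assert n == 1
        assert not cell[0, :].any() and not cell[-1, :].any()
        assert not cell[:, 0].any() and not cell[:, -1].any()
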