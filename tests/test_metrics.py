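"""Partitioning ratio, heterogeneity, ice fraction, scans, profiles, and
replicate statistics."""

import numpy as np
import pytest
from scipy import ndimage

import cryoraman as cr
from cryoraman.errors import (
    DegenerateCellError,
    EmptyChannelError,
    InsufficientReplicatesError,
    NoIceError,
    NoNucleusError,
)
from cryoraman.metrics import (
    coefficient_of_variation,
    gap_profile,
    ice_area_fraction,
    line_scan,
    line_scan_ratio,
    nucleus_cytosol_ratio,
    partitioning_ratio,
    replicate_summary,
)
from cryoraman.segmentation import CompartmentMasks


def _simple_masks(shape=(20, 20)):
    cell = np.zeros(shape, dtype=bool)
    cell[6:14, 6:14] = True
    ice = np.zeros(shape, dtype=bool)
    ice[0:4, :] = True
    ice &= ~cell
    channel = ~cell & ~ice
    empty = np.zeros(shape, dtype=bool)
    return CompartmentMasks(cell, ice, empty, channel)


class TestPartitioningRatio:
    def test_uniform_map_gives_unity(self):
        res = partitioning_ratio(np.full((20, 20), 3.7), _simple_masks())
        assert res.P == pytest.approx(1.0, abs=1e-12)

    def test_known_compartment_means(self):
        """Channel at 2.0, cell at 1.0 noise-free yields P = 2."""
        masks = _simple_masks()
        values = np.where(masks.cell, 1.0, 2.0)
        res = partitioning_ratio(values, masks)
        assert res.P == pytest.approx(2.0, rel=1e-9)
        assert res.C_o == pytest.approx(2.0) and res.C_i == pytest.approx(1.0)

    def test_zero_cell_signal_degenerate(self):
        masks = _simple_masks()
        values = np.where(masks.cell, 0.0, 2.0)
        with pytest.raises(DegenerateCellError):
            partitioning_ratio(values, masks)

    def test_self_consistency_and_counts(self, sweep_outputs):
        """P equals C_o/C_i to 1e-12 on every pipeline output."""
        for _, out in sweep_outputs:
            r = out.result
            assert r.P == pytest.approx(r.C_o / r.C_i, rel=1e-12)
            assert r.n_cell >= 50
            assert r.n_channel >= 1

    def test_pixel_permutation_invariance(self):
        """P depends on compartment means only, not on pixel placement."""
        masks = _simple_masks()
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 5, masks.cell.shape)
        base = partitioning_ratio(values, masks).P
        shuffled = values.copy()
        for m in (masks.cell, masks.channel):
            vals = shuffled[m]
            shuffled[m] = rng.permutation(vals)
        assert partitioning_ratio(shuffled, masks).P == pytest.approx(base, rel=1e-12)

    def test_ice_exclusion_switch(self):
        masks = _simple_masks()
        masks.ice_intracellular[8:10, 8:10] = True
        values = np.where(masks.cell, 2.0, 3.0)
        values[masks.ice_intracellular] = 0.0
        inc = partitioning_ratio(values, masks)
        exc = partitioning_ratio(
            values, masks, cr.AnalysisConfig(include_ice_in_ci=False)
        )
        assert inc.C_i < exc.C_i  # zero-signal ice pixels dilute the included mean


class TestCoefficientOfVariation:
    def test_hand_computed_value(self):
        """Pixels {2, 2, 4, 4}: mean 3, sample SD 1.1547, CV 0.3849."""
        cell = np.zeros((9, 9), dtype=bool)
        cell[0, :4] = True
        values = np.zeros((9, 9))
        values[0, :4] = [2.0, 2.0, 4.0, 4.0]
        assert coefficient_of_variation(values, cell) == pytest.approx(0.38490, abs=1e-5)

    def test_constant_signal_zero(self):
        cell = np.ones((9, 9), dtype=bool)
        assert coefficient_of_variation(np.full((9, 9), 5.0), cell) == 0.0

    @pytest.mark.parametrize("alpha", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, alpha):
        rng = np.random.default_rng(1)
        cell = rng.uniform(size=(9, 9)) > 0.4
        values = rng.uniform(1, 10, (9, 9))
        assert coefficient_of_variation(alpha * values, cell) == pytest.approx(
            coefficient_of_variation(values, cell), rel=1e-12
        )


class TestIceAreaFraction:
    def test_counts(self):
        masks = _simple_masks()
        assert ice_area_fraction(masks) == 0.0
        masks.ice_intracellular[6:8, 6:11] = True  # 10 px inside a 64-px cell
        assert ice_area_fraction(masks) == pytest.approx(10 / 64)
        masks.ice_intracellular[:] = masks.cell
        assert ice_area_fraction(masks) == 1.0


class TestLineScan:
    def test_labels_consistent_with_masks(self, baseline_output):
        masks = baseline_output.masks
        scan = line_scan(baseline_output.maps["dmso"], masks)
        for c, lab in enumerate(scan.labels):
            expected = (
                "cell" if masks.cell[scan.row, c]
                else "ice" if masks.ice_extracellular[scan.row, c]
                else "channel"
            )
            assert lab == expected
        assert "cell" in scan.labels and "channel" in scan.labels

    def test_flat_map_flat_scan(self):
        scan = line_scan(np.full((20, 20), 2.0), _simple_masks(), row=10)
        assert np.ptp(scan.values) == 0.0

    def test_enriched_channel_visible_on_scan(self, sweep_outputs):
        """When P > 1, channel samples on the scan outshine cell samples."""
        for scene, out in sweep_outputs:
            if scene.true_P < 1.2:
                continue
            scan = line_scan(out.maps["dmso"], out.masks)
            chan = [v for v, l in zip(scan.values, scan.labels) if l == "channel"]
            cell = [v for v, l in zip(scan.values, scan.labels) if l == "cell"]
            assert np.mean(chan) > np.mean(cell)

    def test_row_out_of_range(self, baseline_output):
        with pytest.raises(IndexError):
            line_scan(baseline_output.maps["dmso"], baseline_output.masks, row=99)

    def test_line_scan_ratio_tracks_mask_estimate(self, baseline_output):
        ls = line_scan_ratio(baseline_output.maps["dmso"], baseline_output.masks)
        assert ls == pytest.approx(baseline_output.result.P, rel=0.05)


class TestGapProfile:
    def test_uniform_channel_flat_profile(self):
        masks = _simple_masks()
        gp = gap_profile(np.full((20, 20), 4.0), masks)
        assert np.allclose(gp.mean_intensity, 4.0)

    def test_solute_polarization_monotone(self):
        """Channel concentration rising away from ice gives increasing bins."""
        scene = cr.generate_scene(
            cr.SceneParams(gradient_toward_ice=True, noise_sd=0.0, seed=3)
        )
        out = cr.run_analyze(cr.render_cube(scene))
        gp = gap_profile(out.maps["dmso"], out.masks)
        assert len(gp.mean_intensity) >= 2
        assert (np.diff(gp.mean_intensity) > 0).all()

    def test_single_distance_single_bin(self):
        cell = np.zeros((9, 9), dtype=bool)
        ice = np.ones((9, 9), dtype=bool)
        ice[4, :] = False  # one channel line: all pixels at Chebyshev distance 1
        channel = ~cell & ~ice
        masks = CompartmentMasks(cell, ice, np.zeros_like(cell), channel)
        gp = gap_profile(np.full((9, 9), 2.0), masks)
        assert len(gp.distance_bins) == 1

    def test_no_ice_raises(self):
        cell = np.zeros((9, 9), dtype=bool)
        cell[3:6, 3:6] = True
        ice = np.zeros((9, 9), dtype=bool)
        masks = CompartmentMasks(cell, ice, np.zeros_like(cell), ~cell)
        with pytest.raises(NoIceError):
            gap_profile(np.ones((9, 9)), masks)


class TestNucleusCytosolRatio:
    def test_uniform_dmso_gives_unity(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        dna = np.zeros((20, 20))
        dna[8:12, 8:12] = 5.0
        assert nucleus_cytosol_ratio(np.full((20, 20), 2.0), dna, cell) == pytest.approx(1.0)

    def test_depleted_nucleus_recovered_exactly(self):
        """Homogeneous phantom with nuclear DMSO at 95% of cytosol."""
        scene = cr.generate_scene(
            cr.SceneParams(nucleus_dmso_factor=0.95, heterogeneity_sd=0.0,
                           noise_sd=0.0, seed=6)
        )
        out = cr.run_analyze(cr.render_cube(scene))
        ratio = nucleus_cytosol_ratio(
            out.maps["dmso"], out.maps["dna"], out.masks.cell
        )
        assert ratio == pytest.approx(0.95, abs=0.01)

    def test_flat_dna_raises(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        with pytest.raises(NoNucleusError):
            nucleus_cytosol_ratio(np.ones((20, 20)), np.zeros((20, 20)), cell)


class TestReplicateSummary:
    def test_degenerate_and_hand_values(self):
        s = replicate_summary([1.0, 1.0, 1.0])
        assert s.mean == 1.0 and s.se == 0.0
        s = replicate_summary([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.se == pytest.approx(1 / np.sqrt(3), rel=1e-9)

    def test_identical_groups_null(self):
        s = replicate_summary([1.0, 2.0, 3.0], other=[1.0, 2.0, 3.0])
        assert s.t == pytest.approx(0.0, abs=1e-12)
        assert s.p == pytest.approx(1.0)
        assert s.significant is False

    def test_welch_against_hand_formula(self):
        """t, df, p match the Welch-Satterthwaite closed form."""
        a = np.array([1.07, 1.01, 1.13, 1.10, 0.99, 1.12])
        b = np.array([0.21, 0.19, 0.23, 0.24, 0.18, 0.22])
        s = replicate_summary(a, other=b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        assert s.t == pytest.approx(t_hand, rel=1e-9)
        assert s.df == pytest.approx(df_hand, rel=1e-9)
        assert s.significant is True

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            replicate_summary([1.0])
        with pytest.raises(InsufficientReplicatesError):
            replicate_summary([1.0, 2.0], other=[3.0])
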