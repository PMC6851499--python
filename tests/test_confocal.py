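"""Confocal quantification tests: segmentation, masked intensities, ratios,
profiles and morphology tallies."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import find_peaks

import gvbquant as gq
from gvbquant.confocal import (
    EmptyMaskError,
    NoCellError,
    NoGVBError,
    SegmentationConfig,
    classify_gvb_morphology,
    dqbsa_ratio,
    frequency_distribution,
    gvb_cytosol_ratio,
    line_profile,
    measure_soma_area,
    normalize_to_control,
    quantify_masked_intensity,
    segment_gvb_cores,
    tau_threshold_from_controls,
)
from gvbquant.image import MultiChannelImage, max_project
from gvbquant.synth import lattice_disk_pixels

from conftest import flat_image


def _disk_image(centers, area_px, amp=60.0, shape=(128, 128), px=0.1):
    raster = np.zeros(shape)
    for center in centers:
        rr, cc = lattice_disk_pixels(center, area_px)
        raster[rr, cc] = amp
    return MultiChannelImage(channels={"gvb": raster}, pixel_size_um=px)


class TestMaxProject:
    def test_single_slice_identity(self):
        img = flat_image(7.0)
        proj = max_project([img])
        assert np.array_equal(proj.channels["gvb"], img.channels["gvb"])

    def test_elementwise_maximum(self):
        a = np.array([[1.0, 5.0]])
        b = np.array([[3.0, 2.0]])
        proj = max_project(
            [
                MultiChannelImage({"gvb": a}, 0.1),
                MultiChannelImage({"gvb": b}, 0.1),
            ]
        )
        assert np.array_equal(proj.channels["gvb"], [[3.0, 5.0]])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project([])


class TestSegmentCores:
    def test_blank_image_yields_nothing(self):
        rng = np.random.default_rng(0)
        img = MultiChannelImage(
            {"gvb": rng.normal(2.0, 1.0, (128, 128))}, 0.1
        )
        assert segment_gvb_cores(img, "gvb") == []

    def test_noiseless_disk_area_matches_lattice_oracle_exactly(self):
        img = _disk_image([(64, 64)], 50.0)
        cores = segment_gvb_cores(img, "gvb")
        assert len(cores) == 1
        assert cores[0].n_pixels == 49
        assert cores[0].area_um2 == pytest.approx(0.49)

    def test_merged_cores_split_by_watershed(self):
        # two equal cores, centres 1.5 diameters apart, merged above
        # threshold by blur -> watershed yields two objects
        img = _disk_image([(64, 58), (64, 70)], np.pi * 16)
        img.channels["gvb"] = ndi.gaussian_filter(img.channels["gvb"], 2.0)
        merged_labels, n_merged = ndi.label(
            img.channels["gvb"] > img.channels["gvb"].mean()
            + 3 * img.channels["gvb"].std()
        )
        assert n_merged == 1  # genuinely merged before watershed
        cores = segment_gvb_cores(img, "gvb")
        assert len(cores) == 2

    def test_border_objects_excluded(self):
        img = _disk_image([(2, 64)], np.pi * 16)
        assert segment_gvb_cores(img, "gvb") == []


class TestSomaArea:
    def test_square_soma_exact(self):
        raster = np.zeros((64, 64))
        raster[10:30, 10:30] = 20.0
        img = MultiChannelImage({"soma": raster}, 0.1)
        assert measure_soma_area(img, "soma", (15, 15)) == pytest.approx(4.0)

    def test_background_seed_raises(self):
        raster = np.zeros((64, 64))
        raster[10:30, 10:30] = 20.0
        img = MultiChannelImage({"soma": raster}, 0.1)
        with pytest.raises(NoCellError):
            measure_soma_area(img, "soma", (50, 50))

    def test_two_somata_independent(self):
        raster = np.zeros((64, 64))
        raster[5:15, 5:15] = 20.0
        raster[40:60, 40:60] = 20.0
        img = MultiChannelImage({"soma": raster}, 0.1)
        a1 = measure_soma_area(img, "soma", (10, 10))
        a2 = measure_soma_area(img, "soma", (50, 50))
        assert a1 == pytest.approx(1.0)
        assert a2 == pytest.approx(4.0)


class TestClassifyCells:
    def test_recovers_ground_truth_statuses(self, survey_scene):
        _, _, truth, image = survey_scene
        records = gq.classify_cells(image)
        labels = truth.soma_label_image()
        by_id = {c.cell_id: c for c in truth.cells}
        matched = tau_ok = gvb_ok = 0
        for rec in records:
            rr, cc = np.nonzero(rec.nucleus_mask)
            r = int(rec.offset[0] + rr.mean())
            c = int(rec.offset[1] + cc.mean())
            lbl = labels[r, c]
            if lbl:
                cell = by_id[lbl]
                matched += 1
                tau_ok += cell.tau_status == rec.tau_positive
                gvb_ok += cell.gvb_status == rec.gvb_positive
        assert matched >= 0.95 * len(truth.cells)
        assert tau_ok >= 0.95 * matched
        assert gvb_ok >= 0.92 * matched

    def test_counting_semantics_on_records(self):
        # 10 cells: 5 tau+, 4 GVB+ all of which are tau+ ->
        # P(tau+|GVB+) = 100%, P(GVB+|tau+) = 80%
        from gvbquant.confocal import CellRecord, GVBCore

        def rec(i, tau, gvb):
            cores = (
                [GVBCore(1, (0.0, 0.0), 0.4, 40, {})] if gvb else []
            )
            return CellRecord(
                cell_id=i, offset=(0, 0), soma_mask=np.ones((2, 2), bool),
                nucleus_mask=np.zeros((2, 2), bool), soma_area_um2=1.0,
                tau_intensity_au=10.0 if tau else 0.0, tau_positive=tau,
                gvb_cores=cores,
            )

        records = [rec(i, i < 5, i < 4) for i in range(10)]
        tau_pos = [r for r in records if r.tau_positive]
        gvb_pos = [r for r in records if r.gvb_positive]
        double = [r for r in records if r.tau_positive and r.gvb_positive]
        assert len(double) / len(gvb_pos) == 1.0
        assert len(double) / len(tau_pos) == pytest.approx(0.8)

    def test_no_puncta_signal_means_no_gvb_positive(self):
        optics = gq.survey_optics(image_shape=(768, 768))
        params = gq.PopulationParams(
            n_cells=20, p_tau=0.5, p_gvb_given_tau=0.0, p_gvb_given_no_tau=0.0
        )
        truth = gq.generate_population(params, optics, 55)
        image = gq.render_image(truth, optics, 56)
        records = gq.classify_cells(image)
        assert records
        assert not any(r.gvb_positive for r in records)

    def test_control_derived_tau_threshold(self):
        optics = gq.survey_optics(image_shape=(768, 768))
        params = gq.PopulationParams(n_cells=15, p_tau=0.0, p_gvb_given_no_tau=0.0)
        truth = gq.generate_population(params, optics, 57)
        image = gq.render_image(truth, optics, 58)
        controls = gq.classify_cells(image)
        thr = tau_threshold_from_controls(controls)
        vals = np.array([r.tau_intensity_au for r in controls])
        assert thr == pytest.approx(vals.mean() + 2 * vals.std())


class TestMaskedIntensity:
    def test_uniform_field(self):
        img = flat_image(10.0)
        roi = np.zeros((64, 64), bool)
        roi[5:20, 5:20] = True
        mean, n = quantify_masked_intensity(img, "gvb", roi)
        assert mean == 10.0
        assert n == 225

    def test_hand_arithmetic_with_center_excluded(self):
        raster = np.zeros((3, 3))
        raster.flat[:] = np.arange(1, 10)
        img = MultiChannelImage({"gvb": raster}, 0.1)
        roi = np.ones((3, 3), bool)
        excl = np.zeros((3, 3), bool)
        excl[1, 1] = True
        mean, n = quantify_masked_intensity(img, "gvb", roi, excl)
        assert mean == pytest.approx(5.0)
        assert n == 8

    def test_signal_inside_exclusion_never_changes_result(self):
        rng = np.random.default_rng(1)
        raster = rng.normal(10, 1, (32, 32))
        roi = np.ones((32, 32), bool)
        excl = np.zeros((32, 32), bool)
        excl[10:15, 10:15] = True
        img = MultiChannelImage({"gvb": raster.copy()}, 0.1)
        before = quantify_masked_intensity(img, "gvb", roi, excl)
        raster[12, 12] += 1e6
        img2 = MultiChannelImage({"gvb": raster}, 0.1)
        after = quantify_masked_intensity(img2, "gvb", roi, excl)
        assert before == after

    def test_empty_effective_mask_raises(self):
        img = flat_image(1.0)
        roi = np.zeros((64, 64), bool)
        with pytest.raises(EmptyMaskError):
            quantify_masked_intensity(img, "gvb", roi)


class TestNormalizeToControl:
    def test_divide_by_control_mean(self):
        assert normalize_to_control([6, 9], [2, 4]) == [2.0, 3.0]

    def test_control_normalizes_to_unit_mean(self):
        control = [1.5, 2.5, 3.0]
        assert np.mean(normalize_to_control(control, control)) == pytest.approx(1.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0, 0.0])


class TestDqbsaRatio:
    @staticmethod
    def _scene(reporter_value=10.0, structure_value=None):
        raster = np.full((96, 96), reporter_value)
        struct = np.zeros((96, 96), bool)
        struct[40:46, 40:46] = True
        if structure_value is not None:
            raster[struct] = structure_value
        cytosol = np.zeros((96, 96), bool)
        cytosol[20:76, 20:76] = True
        img = MultiChannelImage({"dqbsa": raster}, 0.1)
        return img, [struct], cytosol

    def test_uniform_reporter_gives_unit_ratio(self):
        img, masks, cytosol = self._scene(10.0)
        records = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=0)
        assert records[0].ratio == pytest.approx(1.0, abs=1e-6)

    def test_twofold_structure(self):
        img, masks, cytosol = self._scene(10.0, 20.0)
        records = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=0)
        assert records[0].ratio == pytest.approx(2.0, abs=1e-6)

    def test_scale_invariance_and_offset_shift(self):
        img, masks, cytosol = self._scene(10.0, 20.0)
        base = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=0)[0]
        img.channels["dqbsa"] *= 3.0
        scaled = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=0)[0]
        assert scaled.ratio == pytest.approx(base.ratio, abs=1e-9)
        # additive offset c: ratio -> (s + c) / (b + c), analytically
        img2, masks, cytosol = self._scene(10.0, 20.0)
        img2.channels["dqbsa"] += 5.0
        shifted = dqbsa_ratio(img2, "dqbsa", masks, [True], cytosol, rng_seed=0)[0]
        assert shifted.ratio == pytest.approx((20 + 5) / (10 + 5), abs=1e-6)

    def test_seeded_background_rois_reproducible(self):
        rng = np.random.default_rng(3)
        img, masks, cytosol = self._scene(10.0, 20.0)
        img.channels["dqbsa"] += rng.normal(0, 1, img.shape)
        a = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=9)[0]
        b = dqbsa_ratio(img, "dqbsa", masks, [True], cytosol, rng_seed=9)[0]
        assert a.ratio == b.ratio


class TestFrequencyDistribution:
    def test_single_value(self):
        edges, pct = frequency_distribution([1.2])
        assert pct[2] == 100.0
        assert edges[2] == pytest.approx(1.0)

    def test_counting(self):
        edges, pct = frequency_distribution([0.4, 0.6, 1.2, 2.6])
        assert pct[0] == pct[1] == pct[2] == pct[5] == 25.0
        assert pct.sum() == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.lognormal(0.5, 0.6, size=rng.integers(1, 400))
            _, pct = frequency_distribution(vals)
            assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frequency_distribution([])


class TestGvbCytosolRatio:
    @staticmethod
    def _scene(gvb_mean, cyto_mean):
        marker = np.zeros((96, 96))
        soma = np.zeros((96, 96))
        soma[20:76, 20:76] = 20.0
        rr, cc = lattice_disk_pixels((48, 48), np.pi * 16)
        marker[rr, cc] = 60.0
        reporter = np.full((96, 96), float(cyto_mean))
        reporter[rr, cc] = gvb_mean
        return MultiChannelImage(
            {"gvb": marker, "soma": soma, "dqbsa": reporter}, 0.1
        )

    def test_uniform_reporter(self):
        img = self._scene(10.0, 10.0)
        assert gvb_cytosol_ratio(img, "dqbsa") == pytest.approx(1.0, abs=1e-6)

    def test_arithmetic(self):
        img = self._scene(63.0, 10.0)
        assert gvb_cytosol_ratio(img, "dqbsa") == pytest.approx(6.3, abs=1e-6)

    def test_no_gvb_roi_raises(self):
        img = self._scene(10.0, 10.0)
        rng = np.random.default_rng(0)
        img.channels["gvb"] = rng.normal(2, 1, (96, 96))
        with pytest.raises(NoGVBError):
            gvb_cytosol_ratio(img, "dqbsa")


class TestLineProfile:
    def test_uniform_channel_constant(self):
        img = flat_image(4.0)
        profile = line_profile(img, (5, 5), (50, 50), 40)
        assert np.allclose(profile.intensity["gvb"], 4.0)
        assert np.all(np.diff(profile.sample_positions_um) > 0)

    def test_gaussian_spot_peaks_at_center(self):
        raster = np.zeros((64, 64))
        raster[32, 32] = 100.0
        raster = ndi.gaussian_filter(raster, 3.0)
        img = MultiChannelImage({"gvb": raster}, 0.1)
        profile = line_profile(img, (32, 2), (32, 62), 61)
        assert np.argmax(profile.intensity["gvb"]) == 30

    def test_ring_shows_two_peaks_flanking_core_peak(self, confocal_cell_scene):
        _, truth, _ = confocal_cell_scene
        # noiseless render of the same truth for clean peak counting
        optics = gq.confocal_optics(
            image_shape=(256, 256), gaussian_sd=0.0, background_gradient_amp=0.0
        )
        image = gq.render_image(truth, optics, 1)
        gvb = next(
            g for c in truth.cells for g in c.gvb_list if g.n_cores_in_ring == 1
        )
        r0, c0 = gvb.center
        span = gvb.ring_inner_radius_px + 6
        profile = line_profile(
            image, (r0, c0 - span), (r0, c0 + span), int(4 * span)
        )
        mem_peaks, _ = find_peaks(profile.intensity["membrane"], prominence=5)
        core_peaks, _ = find_peaks(profile.intensity["gvb"], prominence=5)
        assert len(core_peaks) == 1
        assert len(mem_peaks) == 2
        assert mem_peaks[0] < core_peaks[0] < mem_peaks[1]

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            line_profile(flat_image(1.0), (5, 5), (5, 5))


class TestMorphology:
    @staticmethod
    def _ring(shape=(64, 64), center=(32, 32), radius=12):
        mask = np.zeros(shape, bool)
        rr, cc = lattice_disk_pixels(center, np.pi * radius**2)
        mask[rr, cc] = True
        return mask

    @staticmethod
    def _core(center, area_um2):
        from gvbquant.confocal import GVBCore

        return GVBCore(1, center, area_um2, int(area_um2 / 0.01), {})

    def test_single_core(self):
        res = classify_gvb_morphology(
            [self._core((32, 32), 0.4)], [self._ring()], 0.1
        )
        assert res["single"] == 1 and res["multiple"] == 0 and res["filling"] == 0

    def test_two_cores_is_multiple(self):
        cores = [self._core((28, 32), 0.3), self._core((36, 32), 0.3)]
        res = classify_gvb_morphology(cores, [self._ring()], 0.1)
        assert res["multiple"] == 1

    def test_fill_fraction_threshold(self):
        ring = self._ring(radius=5.6)  # interior ~0.98 um^2 at 0.1 um/px
        interior_area = ring.sum() * 0.01
        res = classify_gvb_morphology(
            [self._core((32, 32), 0.85 * interior_area)], [ring], 0.1,
            fill_fraction_threshold=0.8,
        )
        assert res["filling"] == 1

    def test_unenclosed_core_counted_separately(self):
        res = classify_gvb_morphology(
            [self._core((5, 5), 0.4)], [self._ring()], 0.1
        )
        assert res["unenclosed"] == 1
        assert res["single"] + res["multiple"] + res["filling"] == 0
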