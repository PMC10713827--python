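"""Segmentation: illumination, nuclei, viability, compartment algebra,
neurite morphometry."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import edcprofiler as e
from edcprofiler.segmentation import (
    CROSS,
    FieldImage,
    ViabilityRule,
    classify_viability,
    correct_illumination,
    derive_compartments,
    extract_neurites,
    segment_cells,
    segment_field,
    segment_nuclei,
)

PITCH = e.PIXEL_PITCH_UM


def _image(**channels):
    shape = next(iter(channels.values())).shape
    full = {ch: channels.get(ch, np.zeros(shape)) for ch in e.CHANNELS}
    return FieldImage(channels=full)


class TestFieldImage:
    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="missing channels"):
            FieldImage(channels={"DNA": np.zeros((128, 128))})

    def test_shape_mismatch_rejected(self):
        chans = {ch: np.zeros((128, 128)) for ch in e.CHANNELS}
        chans["TH"] = np.zeros((64, 64))
        with pytest.raises(ValueError, match="differ"):
            FieldImage(channels=chans)


class TestIlluminationCorrection:
    def test_constant_image_unchanged_up_to_constant(self):
        img = _image(DNA=np.full((128, 128), 500.0))
        out = correct_illumination(img).channels["DNA"]
        assert np.ptp(out) < 1e-9
        assert out.max() <= 500.0 + 1e-9

    def test_linear_ramp_flattened(self):
        rng = np.random.default_rng(0)
        base = rng.normal(200, 10, (256, 256)).clip(0)
        ramp = np.linspace(0, 300, 256)[None, :] * np.ones((256, 1))
        img = _image(MAP2=base + ramp)
        out = correct_illumination(img).channels["MAP2"]
        cv_before = (base + ramp).mean(axis=0).std() / (base + ramp).mean()
        cv_after = out.mean(axis=0).std() / out.mean()
        assert cv_after < cv_before

    def test_all_zero_stays_zero(self):
        img = _image(DNA=np.zeros((128, 128)))
        out = correct_illumination(img).channels["DNA"]
        assert np.all(out == 0)

    def test_nonnegative_output(self, vehicle_field):
        channels, _, _ = vehicle_field
        out = correct_illumination(FieldImage(channels=dict(channels)))
        for a in out.channels.values():
            assert a.min() >= 0


class TestSegmentNuclei:
    def test_rendered_nuclei_all_found(self, vehicle_field):
        channels, truth, _ = vehicle_field
        img = correct_illumination(FieldImage(channels=dict(channels)))
        labels = segment_nuclei(img.channels["DNA"])
        assert labels.max() == len(truth)

    def test_blank_image_zero_labels(self):
        labels = segment_nuclei(np.zeros((128, 128)))
        assert labels.max() == 0

    def test_touching_nuclei_split_by_watershed(self):
        # two disks overlapping slightly but with distinct cores
        a = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        a[(yy - 64) ** 2 + (xx - 45) ** 2 <= 20**2] = 1000
        a[(yy - 64) ** 2 + (xx - 82) ** 2 <= 20**2] = 1000
        labels = segment_nuclei(a, threshold=500)
        assert labels.max() == 2


class TestViability:
    @pytest.mark.parametrize(
        "area,mean,living",
        [
            (2500, 1000, True),   # large and dim -> living
            (2000, 1000, False),  # boundary area, strict 'larger than'
            (2500, 1500, False),  # boundary intensity, strict 'lower than'
            (900, 3000, False),   # small and bright -> apoptotic
        ],
    )
    def test_rule_boundaries(self, area, mean, living):
        side = int(np.ceil(np.sqrt(area)))
        labels = np.zeros((side + 4, side + 4), dtype=np.int32)
        flat = np.zeros(labels.shape, dtype=bool).ravel()
        flat[: area] = True
        labels[flat.reshape(labels.shape)] = 1
        dna = np.where(labels == 1, float(mean), 0.0)
        flags, count = classify_viability(labels, dna, ViabilityRule())
        assert flags[1] is living
        assert count == int(living)

    def test_generator_mixture_counts(self, render_params):
        channels, truth = e.generate_field(
            ("vehicle", 0.0),
            e.EffectModel.null(apoptotic_fraction=0.35),
            render_params,
            seed=11,
            n_cells=10,
        )
        img = correct_illumination(FieldImage(channels=dict(channels)))
        labels = segment_nuclei(img.channels["DNA"])
        flags, count = classify_viability(labels, img.channels["DNA"])
        assert count == sum(t.living for t in truth)

    def test_label_permutation_invariance(self, segmented_vehicle_field):
        img, masks, corrected, _ = segmented_vehicle_field
        labels = masks.nucleus_labels
        perm = np.zeros(labels.max() + 1, dtype=np.int32)
        perm[1:] = np.random.default_rng(0).permutation(labels.max()) + 1
        _, count_a = classify_viability(labels, corrected.channels["DNA"])
        _, count_b = classify_viability(perm[labels], corrected.channels["DNA"])
        assert count_a == count_b


class TestSegmentCells:
    def test_one_nucleus_one_blob(self):
        yy, xx = np.mgrid[0:128, 0:128]
        blob = (yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2
        nuc = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 15**2).astype(np.int32)
        cells = segment_cells(np.where(blob, 3000.0, 0.0), nuc, {1: True}, threshold=1000)
        assert set(np.unique(cells)) == {0, 1}
        assert ((cells == 1) & blob).sum() == blob.sum()

    def test_two_nuclei_partition_exact(self):
        yy, xx = np.mgrid[0:128, 0:160]
        blob = (np.abs(yy - 64) <= 30) & (np.abs(xx - 80) <= 70)
        nuc = np.zeros(blob.shape, dtype=np.int32)
        nuc[(yy - 64) ** 2 + (xx - 40) ** 2 <= 12**2] = 1
        nuc[(yy - 64) ** 2 + (xx - 120) ** 2 <= 12**2] = 2
        cells = segment_cells(
            np.where(blob, 3000.0, 0.0), nuc, {1: True, 2: True}, threshold=1000
        )
        union = (cells == 1) | (cells == 2)
        assert union.sum() == blob.sum()          # partition covers the blob
        assert ((cells == 1) & (cells == 2)).sum() == 0

    def test_blob_without_nucleus_is_background(self):
        yy, xx = np.mgrid[0:128, 0:128]
        blob = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
        nuc = ((yy - 100) ** 2 + (xx - 100) ** 2 <= 12**2).astype(np.int32)
        map2 = np.where(blob, 3000.0, 0.0)
        map2[(yy - 100) ** 2 + (xx - 100) ** 2 <= 18**2] = 3000.0
        cells = segment_cells(map2, nuc, {1: True}, threshold=1000)
        assert cells[blob].max() == 0      # unreachable blob unassigned
        assert (cells == 1).any()

    def test_apoptotic_nucleus_yields_no_cell(self):
        yy, xx = np.mgrid[0:128, 0:128]
        nuc = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 12**2).astype(np.int32)
        map2 = np.where((yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2, 3000.0, 0.0)
        cells = segment_cells(map2, nuc, {1: False}, threshold=1000)
        assert cells.max() == 0


class TestCompartmentAlgebra:
    def test_square_cell_membrane_area(self):
        cells = np.zeros((40, 40), dtype=np.int32)
        cells[10:30, 10:30] = 1  # 20x20 square
        nuclei = np.zeros_like(cells)
        cyto, mem = derive_compartments(cells, nuclei, membrane_width_px=5)
        assert (mem == 1).sum() == 20**2 - 10**2

    def test_thin_cell_is_all_membrane(self):
        cells = np.zeros((40, 40), dtype=np.int32)
        cells[10:18, 5:35] = 1  # 8 px across < 2*5
        _, mem = derive_compartments(cells, np.zeros_like(cells))
        assert ((mem == 1) == (cells == 1)).all()

    def test_nucleus_equals_cell_gives_empty_cytoplasm(self):
        cells = np.zeros((40, 40), dtype=np.int32)
        cells[10:30, 10:30] = 1
        cyto, _ = derive_compartments(cells, cells.copy())
        assert (cyto == 1).sum() == 0

    def test_set_identities_on_segmented_field(self, segmented_vehicle_field):
        """cytoplasm = cell \\ nucleus and membrane = cell \\ erode(cell, 5),
        exactly, per label, and nuclei never leak into other cells."""
        _, masks, _, _ = segmented_vehicle_field
        for lab in masks.living_labels:
            cell = masks.cell_labels == lab
            nuc = masks.nucleus_labels == lab
            cyto = masks.cytoplasm_labels == lab
            mem = masks.membrane_labels == lab
            assert ((cell & ~nuc) == cyto).all()
            eroded = ndi.binary_erosion(cell, structure=CROSS, iterations=5)
            assert ((cell & ~eroded) == mem).all()
            assert mem.sum() <= cell.sum()
            other_nuc = (masks.nucleus_labels > 0) & (masks.nucleus_labels != lab)
            assert not (cell & other_nuc).any()

    def test_segmentation_is_deterministic(self, vehicle_field):
        channels, _, _ = vehicle_field
        img = FieldImage(channels=dict(channels))
        m1, _ = segment_field(img)
        m2, _ = segment_field(img)
        assert np.array_equal(m1.cell_labels, m2.cell_labels)
        assert np.array_equal(m1.neurite_skeleton, m2.neurite_skeleton)


class TestNeurites:
    def test_straight_segment_length(self):
        """A 100-px horizontal line measures ~99 steps x 0.1628 um."""
        cells = np.zeros((64, 128), dtype=np.int32)
        cells[30:33, 10:110] = 1  # 100 px long, 3 px wide
        map2 = np.where(cells > 0, 3000.0, 0.0)
        _, lengths, _ = extract_neurites(
            map2, cells, soma_opening_radius_px=8, min_fragment_px=0
        )
        expected = 99 * PITCH
        assert lengths[1] == pytest.approx(expected, abs=3 * PITCH)

    def test_y_shape_has_one_branch_point(self):
        cells = np.zeros((128, 128), dtype=np.int32)
        cells[20:90, 63:66] = 1  # stem
        for i in range(40):      # two arms
            cells[90 + i // 2, 64 - 2 - i // 2 : 64 - i // 2] = 1
            cells[90 + i // 2, 64 + i // 2 : 64 + 2 + i // 2] = 1
        map2 = np.where(cells > 0, 3000.0, 0.0)
        _, _, branches = extract_neurites(
            map2, cells, soma_opening_radius_px=8, min_fragment_px=0
        )
        assert branches[1] == 1

    def test_no_neurites_reports_zero(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        cells[(yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2] = 1  # round soma only
        map2 = np.where(cells > 0, 3000.0, 0.0)
        _, lengths, branches = extract_neurites(map2, cells)
        assert lengths[1] == 0.0
        assert branches[1] == 0

    def test_generator_length_recovered_within_15_percent(self, render_params):
        """Total skeleton length over fields tracks the rendered walk length."""
        meas, truth = 0.0, 0.0
        for seed in range(6):
            channels, gt = e.generate_field(
                ("vehicle", 0.0), e.EffectModel.null(), render_params, seed=seed, n_cells=6
            )
            masks, _ = segment_field(FieldImage(channels=dict(channels)))
            meas += sum(masks.neurite_length_um.values())
            truth += sum(g.neurite_length_px for g in gt if g.living) * PITCH
        assert meas / truth == pytest.approx(1.0, abs=0.15)
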