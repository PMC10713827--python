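"""Feature catalogue and extraction: GLCM, intensity, shape, context,
well aggregation."""

import numpy as np
import pandas as pd
import pytest

import edcprofiler as e
from edcprofiler.catalogue import (
    CATALOGUE,
    FEATURE_NAMES,
    HEADLINE_FEATURES,
    schema_hash,
)
from edcprofiler.features import (
    extract_field_features,
    featurize_well,
    glcm_metrics,
    pearson,
)
from edcprofiler.segmentation import CompartmentMasks, FieldImage, segment_field

PITCH = e.PIXEL_PITCH_UM


class TestCatalogue:
    def test_exactly_126_unique_ordered_features(self):
        assert len(CATALOGUE) == 126
        assert len(set(FEATURE_NAMES)) == 126
        # order is part of the schema: hash is reproducible
        assert schema_hash() == schema_hash()

    def test_headline_features_exist(self):
        for key, name in HEADLINE_FEATURES.items():
            assert name in FEATURE_NAMES, key

    def test_classes_partition(self):
        counts = pd.Series([f.feature_class for f in CATALOGUE]).value_counts()
        assert counts["intensity"] == 48
        assert counts["shape"] == 20
        assert counts["texture"] == 24
        assert counts["context"] == 34


class TestGLCM:
    def test_constant_region_asm_one_contrast_zero(self):
        vals = np.full((20, 20), 7.0)
        m = glcm_metrics(vals, np.ones((20, 20), dtype=bool))
        assert m["asm"] == pytest.approx(1.0)
        assert m["contrast"] == pytest.approx(0.0)
        assert m["correlation"] == 0.0  # undefined -> 0 with flag semantics

    def test_checkerboard_horizontal_asm_half(self):
        """Distance-1 horizontal pairs on a two-level checkerboard are all
        (a,b) or (b,a): the symmetric GLCM has two equal cells, ASM = 0.5,
        and contrast is maximal for the quantization."""
        board = np.indices((16, 16)).sum(axis=0) % 2 * 100.0
        m = glcm_metrics(board, np.ones((16, 16), bool), angles=(0.0,))
        assert m["asm"] == pytest.approx(0.5, abs=0.01)
        assert m["contrast"] == pytest.approx(15.0**2, rel=0.01)

    def test_glcm_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1000, (30, 30))
        from skimage.feature import graycomatrix

        q = np.clip((vals - vals.min()) / np.ptp(vals) * 16, 0, 15).astype(np.uint8)
        g = graycomatrix(q, [1], [0], levels=16, symmetric=True)
        p = g[:, :, 0, 0] / g[:, :, 0, 0].sum()
        assert p.sum() == pytest.approx(1.0)

    def test_metrics_match_skimage_graycoprops(self):
        """Independent cross-check of ASM/contrast/homogeneity/correlation
        against skimage's reference formulas on the same quantized image."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, (24, 24))
        mask = np.ones((24, 24), bool)
        mine = glcm_metrics(vals, mask, angles=(0.0,))
        lo, hi = np.percentile(vals, (1, 99))
        q = np.clip((vals - lo) / (hi - lo) * 16, 0, 15).astype(np.uint8)
        g = graycomatrix(q, [1], [0.0], levels=16, symmetric=True, normed=True)
        assert mine["asm"] == pytest.approx(float(graycoprops(g, "ASM")[0, 0]), rel=1e-3)
        assert mine["contrast"] == pytest.approx(
            float(graycoprops(g, "contrast")[0, 0]), rel=1e-3
        )
        assert mine["homogeneity"] == pytest.approx(
            float(graycoprops(g, "homogeneity")[0, 0]), rel=1e-3
        )
        assert mine["correlation"] == pytest.approx(
            float(graycoprops(g, "correlation")[0, 0]), rel=1e-3, abs=1e-3
        )

    def test_asm_invariant_under_monotone_rescale(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, (24, 24))
        mask = np.ones((24, 24), bool)
        a = glcm_metrics(vals, mask)["asm"]
        b = glcm_metrics(vals * 3.0 + 10.0, mask)["asm"]
        assert a == pytest.approx(b)


def _single_cell_masks(shape=(64, 64), cell_box=(10, 50), nuc_box=(22, 38)):
    cells = np.zeros(shape, dtype=np.int32)
    cells[cell_box[0] : cell_box[1], cell_box[0] : cell_box[1]] = 1
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[nuc_box[0] : nuc_box[1], nuc_box[0] : nuc_box[1]] = 1
    from edcprofiler.segmentation import derive_compartments

    cyto, mem = derive_compartments(cells, nuclei)
    return CompartmentMasks(
        nucleus_labels=nuclei,
        cell_labels=cells,
        cytoplasm_labels=cyto,
        membrane_labels=mem,
        neurite_skeleton=np.zeros(shape, bool),
        viability={1: True},
        neurite_length_um={1: 0.0},
        branch_points={1: 0},
    )


def _field_image(shape=(64, 64), **channels):
    full = {ch: channels.get(ch, np.zeros(shape)) for ch in e.CHANNELS}
    return FieldImage(channels=full)


class TestIntensityAndShape:
    def test_constant_channel_mean_everywhere(self):
        masks = _single_cell_masks()
        img = _field_image(TH=np.full((64, 64), 123.0))
        per_cell, _ = extract_field_features(img, masks)
        for comp in ("cell", "cytoplasm", "membrane", "nucleus"):
            assert per_cell[f"{comp}_TH_intensity_mean"].iloc[0] == pytest.approx(123.0)
            assert per_cell[f"{comp}_TH_intensity_std"].iloc[0] == pytest.approx(0.0)

    def test_membrane_rim_intensity_isolated(self):
        """Rim pixels at 5000, interior at 1000: membrane mean must be 5000."""
        masks = _single_cell_masks()
        th = np.where(masks.membrane_labels == 1, 5000.0, 1000.0)
        per_cell, _ = extract_field_features(_field_image(TH=th), masks)
        assert per_cell["membrane_TH_intensity_mean"].iloc[0] == pytest.approx(5000.0)

    def test_square_cell_area_um2(self):
        masks = _single_cell_masks(cell_box=(10, 30))  # 20x20 cell
        per_cell, _ = extract_field_features(_field_image(), masks)
        assert per_cell["cell_shape_area_um2"].iloc[0] == pytest.approx(400 * PITCH**2)

    def test_disk_form_factor_near_one_and_solidity_one(self):
        yy, xx = np.mgrid[0:64, 0:64]
        cells = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2).astype(np.int32)
        nuclei = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 8**2).astype(np.int32)
        from edcprofiler.segmentation import derive_compartments

        cyto, mem = derive_compartments(cells, nuclei)
        masks = CompartmentMasks(nuclei, cells, cyto, mem, np.zeros((64, 64), bool), {1: True})
        per_cell, _ = extract_field_features(_field_image(), masks)
        assert per_cell["cell_shape_form_factor"].iloc[0] == pytest.approx(1.0, abs=0.1)
        # pixelated disk boundaries leave small concavities vs the hull
        assert per_cell["cell_shape_solidity"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_intensity_scales_linearly(self):
        masks = _single_cell_masks()
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 1000, (64, 64))
        a, _ = extract_field_features(_field_image(ASYN=base), masks)
        b, _ = extract_field_features(_field_image(ASYN=base * 2.5), masks)
        assert b["cell_ASYN_intensity_mean"].iloc[0] == pytest.approx(
            2.5 * a["cell_ASYN_intensity_mean"].iloc[0]
        )


class TestContext:
    def test_self_correlation_is_one(self):
        masks = _single_cell_masks()
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, (64, 64))
        per_cell, _ = extract_field_features(_field_image(TH=x, ASYN=x.copy()), masks)
        assert per_cell["cell_corr_TH_ASYN"].iloc[0] == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 500)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20000), rng.normal(size=20000)
        assert abs(pearson(x, y)) < 0.1

    def test_degenerate_correlation_zero(self):
        assert pearson(np.array([1.0]), np.array([2.0])) == 0.0
        assert pearson(np.full(10, 5.0), np.arange(10.0)) == 0.0


class TestWellAggregation:
    def test_well_row_has_exactly_126_features(self, segmented_vehicle_field):
        img, masks, corrected, _ = segmented_vehicle_field
        result = extract_field_features(corrected, masks)
        row = featurize_well([result])
        assert row[list(FEATURE_NAMES)].size == 126
        assert row[list(FEATURE_NAMES)].notna().all()

    def test_identical_fields_mean_idempotent(self, segmented_vehicle_field):
        img, masks, corrected, _ = segmented_vehicle_field
        result = extract_field_features(corrected, masks)
        one = featurize_well([result])
        two = featurize_well([result, result])
        pd.testing.assert_series_equal(
            one[list(FEATURE_NAMES)], two[list(FEATURE_NAMES)]
        )

    def test_field_order_permutation_invariant(self, render_params):
        results = []
        for seed in (1, 2, 3):
            channels, _ = e.generate_field(
                ("vehicle", 0.0), e.EffectModel.null(), render_params, seed=seed, n_cells=4
            )
            masks, corrected = segment_field(FieldImage(channels=dict(channels)))
            results.append(extract_field_features(corrected, masks))
        fwd = featurize_well(results)
        rev = featurize_well(results[::-1])
        pd.testing.assert_series_equal(fwd[list(FEATURE_NAMES)], rev[list(FEATURE_NAMES)])

    def test_aggregation_matches_brute_force_mean(self):
        """Well values equal hand-computed means of per-cell values."""
        masks_a = _single_cell_masks()
        rng = np.random.default_rng(6)
        imgs = [_field_image(ASYN=rng.uniform(0, 1000, (64, 64))) for _ in range(3)]
        results = [extract_field_features(im, masks_a) for im in imgs]
        row = featurize_well(results)
        per_cell_vals = [
            r[0]["cell_ASYN_intensity_mean"].iloc[0] for r in results
        ]
        assert row["cell_ASYN_intensity_mean"] == pytest.approx(np.mean(per_cell_vals))

    def test_zero_living_cells_yields_nan_row(self):
        empty = CompartmentMasks(
            nucleus_labels=np.zeros((64, 64), np.int32),
            cell_labels=np.zeros((64, 64), np.int32),
            cytoplasm_labels=np.zeros((64, 64), np.int32),
            membrane_labels=np.zeros((64, 64), np.int32),
            neurite_skeleton=np.zeros((64, 64), bool),
            viability={},
        )
        result = extract_field_features(_field_image(), empty)
        with pytest.warns(UserWarning, match="zero living cells"):
            row = featurize_well([result])
        per_cell_feats = [f.name for f in CATALOGUE if f.level == "cell"]
        assert row[per_cell_feats].isna().all()
        assert row["n_living_cells"] == 0
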