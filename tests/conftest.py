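"""Shared fixtures: small rendered fields and featurized plates.

Everything is generated programmatically at test time; expensive plates are
session-scoped so several tests can share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import edcprofiler as e
from edcprofiler.pipeline import RunConfig, featurize_plate


@pytest.fixture(scope="session")
def render_params() -> e.RenderParams:
    return e.RenderParams()


@pytest.fixture(scope="session")
def vehicle_field(render_params):
    """One noisy vehicle field with 6 cells plus its ground truth and masks."""
    channels, truth, gt_masks = e.generate_field(
        ("vehicle", 0.0),
        e.EffectModel.null(),
        render_params,
        seed=42,
        n_cells=6,
        return_masks=True,
    )
    return channels, truth, gt_masks


@pytest.fixture(scope="session")
def segmented_vehicle_field(vehicle_field):
    from edcprofiler.segmentation import segment_field

    channels, truth, gt_masks = vehicle_field
    img = e.FieldImage(channels=dict(channels), well="B02", field=0)
    masks, corrected = segment_field(img)
    return img, masks, corrected, truth


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """Plate config reduced to 2 fields/well for plate-level tests."""
    return RunConfig(fields_per_well=2)


@pytest.fixture(scope="session")
def null_plate_table(small_config) -> pd.DataFrame:
    """Featurized plate with no injected effects (treated == vehicle)."""
    return featurize_plate(small_config, e.EffectModel.null(0.08), seed=202)


@pytest.fixture(scope="session")
def synthetic_well_table() -> pd.DataFrame:
    """Numbers-only well table (no imaging) for stats and profiling tests:
    4 compounds x 4 doses x 6 wells + 12 vehicle wells, a known shift on
    one feature at the top dose."""
    rng = np.random.default_rng(7)
    rows = []
    for comp in e.COMPOUNDS:
        for dose in e.DOSES_UM:
            for rep in range(6):
                base = rng.normal(100, 5)
                shift = 40.0 if dose == 2.0 else 0.0
                rows.append(
                    {
                        "well": f"{comp}_{dose}_{rep}",
                        "compound": comp,
                        "dose_uM": dose,
                        "replicate": rep % 2,
                        "signal": base + shift,
                        "flat": rng.normal(50, 5),
                    }
                )
    for rep in range(12):
        rows.append(
            {
                "well": f"veh_{rep}",
                "compound": e.VEHICLE,
                "dose_uM": 0.0,
                "replicate": rep % 2,
                "signal": rng.normal(100, 5),
                "flat": rng.normal(50, 5),
            }
        )
    return pd.DataFrame(rows)
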