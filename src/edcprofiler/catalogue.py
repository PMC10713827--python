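"""The fixed 126-feature phenotypic catalogue.

The catalogue is data, not code: a deterministic, ordered registry of
feature descriptors grouped in four blocks —

* intensity (48): {cell, cytoplasm, membrane, nucleus} x {TH, ASYN, MAP2}
  x {mean, median, std, integrated}
* shape (20): {cell, cytoplasm, membrane, nucleus} x {area_um2,
  perimeter_um, eccentricity, solidity, form_factor}
* texture (24): {cell, cytoplasm} x {ASYN, TH, MAP2} x {asm, contrast,
  correlation, homogeneity} from a 16-level symmetric GLCM
* context (34): channel-pair Pearson correlations per {cell, cytoplasm,
  nucleus} (18), population counts and densities, neurite morphometry,
  nuclear DNA content, and the named composite readouts (alpha-synuclein
  intensity in TH-positive cells, TH/alpha-synuclein double-positive
  surface intensity, MAP2 cell surface per nucleus).

Any edit to the registry changes ``schema_hash()``, which is recorded in
every output table.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass

COMPARTMENTS = ("cell", "cytoplasm", "membrane", "nucleus")
INTENSITY_CHANNELS = ("TH", "ASYN", "MAP2")
INTENSITY_STATS = ("mean", "median", "std", "integrated")
SHAPE_METRICS = ("area_um2", "perimeter_um", "eccentricity", "solidity", "form_factor")
TEXTURE_COMPARTMENTS = ("cell", "cytoplasm")
TEXTURE_METRICS = ("asm", "contrast", "correlation", "homogeneity")
CORR_COMPARTMENTS = ("cell", "cytoplasm", "nucleus")
CHANNEL_PAIRS = (
    ("DNA", "TH"),
    ("DNA", "ASYN"),
    ("DNA", "MAP2"),
    ("TH", "ASYN"),
    ("TH", "MAP2"),
    ("ASYN", "MAP2"),
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    feature_class: str  # shape | intensity | texture | context
    compartment: str    # cell | cytoplasm | membrane | nucleus | field
    channel: str        # channel, channel pair, or "" for channel-free
    level: str          # "cell" (averaged over living cells) or "field"


def _build() -> list[FeatureDescriptor]:
    feats: list[FeatureDescriptor] = []
    for comp, ch, stat in itertools.product(
        COMPARTMENTS, INTENSITY_CHANNELS, INTENSITY_STATS
    ):
        feats.append(
            FeatureDescriptor(
                f"{comp}_{ch}_intensity_{stat}", "intensity", comp, ch, "cell"
            )
        )
    for comp, m in itertools.product(COMPARTMENTS, SHAPE_METRICS):
        feats.append(FeatureDescriptor(f"{comp}_shape_{m}", "shape", comp, "", "cell"))
    for comp, ch, m in itertools.product(
        TEXTURE_COMPARTMENTS, ("ASYN", "TH", "MAP2"), TEXTURE_METRICS
    ):
        feats.append(
            FeatureDescriptor(f"{comp}_{ch}_texture_{m}", "texture", comp, ch, "cell")
        )
    for comp, (a, b) in itertools.product(CORR_COMPARTMENTS, CHANNEL_PAIRS):
        feats.append(
            FeatureDescriptor(f"{comp}_corr_{a}_{b}", "context", comp, f"{a}/{b}", "cell")
        )
    field_feats = [
        ("living_cell_count", ""),
        ("total_nucleus_count", ""),
        ("apoptotic_fraction", ""),
        ("cell_density_per_mm2", ""),
        ("fraction_th_positive", "TH"),
        ("nn_soma_distance_mean_um", ""),
        ("nn_soma_distance_std_um", ""),
        ("asyn_intensity_in_th_pos_cells", "ASYN"),
        ("th_asyn_double_pos_surface_intensity", "TH/ASYN"),
        ("th_asyn_double_pos_area_fraction", "TH/ASYN"),
    ]
    for name, ch in field_feats:
        feats.append(FeatureDescriptor(name, "context", "field", ch, "field"))
    feats.append(
        FeatureDescriptor("neurite_length_per_cell_um", "context", "cell", "MAP2", "cell")
    )
    feats.append(
        FeatureDescriptor("branch_points_per_cell", "context", "cell", "MAP2", "cell")
    )
    feats.append(
        FeatureDescriptor(
            "map2_surface_per_nucleus_um2", "context", "field", "MAP2", "field"
        )
    )
    for stat in ("mean", "std", "integrated"):
        feats.append(
            FeatureDescriptor(
                f"nucleus_DNA_intensity_{stat}", "context", "nucleus", "DNA", "cell"
            )
        )
    return feats


CATALOGUE: tuple[FeatureDescriptor, ...] = tuple(_build())
FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in CATALOGUE)
N_FEATURES = len(CATALOGUE)

assert N_FEATURES == 126, f"catalogue must have 126 features, has {N_FEATURES}"
assert len(set(FEATURE_NAMES)) == N_FEATURES, "feature names must be unique"

#: headline readouts discussed throughout the analysis, mapped to their
#: catalogue names
HEADLINE_FEATURES = {
    "living_cells": "living_cell_count",
    "asyn_in_th_pos": "asyn_intensity_in_th_pos_cells",
    "neurite_length": "neurite_length_per_cell_um",
    "branch_points": "branch_points_per_cell",
    "th_overall": "cell_TH_intensity_mean",
    "th_membrane": "membrane_TH_intensity_mean",
    "th_asyn_surface": "th_asyn_double_pos_surface_intensity",
    "map2_surface_per_nucleus": "map2_surface_per_nucleus_um2",
    "map2_asyn_correlation": "cell_corr_ASYN_MAP2",
    "asyn_texture_asm": "cell_ASYN_texture_asm",
}


def schema_hash() -> str:
    """Stable hash of the ordered feature schema."""
    payload = json.dumps(
        [[f.name, f.feature_class, f.compartment, f.channel, f.level] for f in CATALOGUE]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def schema_records() -> list[dict[str, str]]:
    return [
        {
            "name": f.name,
            "class": f.feature_class,
            "compartment": f.compartment,
            "channel": f.channel,
            "level": f.level,
        }
        for f in CATALOGUE
    ]
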