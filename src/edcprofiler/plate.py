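"""Plate layouts and per-condition effect models.

A 384-well plate has rows A-P and columns 1-24; edge wells (row A, row P,
column 1, column 24) are excluded from every layout because evaporation and
optical artefacts make them unusable in practice.

Conditions are (compound, dose) pairs: four endocrine-disrupting chemicals
(BPA, BPS, PFOS, PFOA) at 0.01, 0.1, 1 and 2 uM, plus a methanol vehicle
control at dose 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COMPOUNDS = ("BPA", "BPS", "PFOS", "PFOA")
VEHICLE = "vehicle"
DOSES_UM = (0.01, 0.1, 1.0, 2.0)

#: bisphenols vs perfluoroalkyls; compounds in the same class share the
#: direction (not the magnitude) of their phenotypic signature.
COMPOUND_CLASS = {"BPA": "BP", "BPS": "BP", "PFOS": "PF", "PFOA": "PF"}

_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows of a 384-well plate
_N_COLS = 24


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> well ID such as 'B02'."""
    return f"{_ROWS[row]}{col + 1:02d}"


def is_edge_well(well: str) -> bool:
    row, col = well[0], int(well[1:])
    return row in (_ROWS[0], _ROWS[-1]) or col in (1, _N_COLS)


def inner_wells() -> list[str]:
    """All 308 usable wells of a 384-well plate, row-major."""
    return [
        well_name(r, c)
        for r in range(1, len(_ROWS) - 1)
        for c in range(1, _N_COLS - 1)
    ]


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of conditions to wells.

    ``table`` has one row per well with columns
    ``well, compound, dose_uM, replicate`` and is validated on construction:
    no edge wells, vehicle wells at dose 0, compound wells at dose > 0.
    """

    table: pd.DataFrame
    fields_per_well: int = 16

    def __post_init__(self) -> None:
        required = {"well", "compound", "dose_uM", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout table missing columns: {sorted(missing)}")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be positive")
        if self.table["well"].duplicated().any():
            dups = self.table.loc[self.table["well"].duplicated(), "well"]
            raise ValueError(f"duplicate wells in layout: {list(dups)}")
        for w in self.table["well"]:
            if is_edge_well(w):
                raise ValueError(f"edge well {w!r} is not usable")
        known = set(COMPOUNDS) | {VEHICLE}
        unknown = set(self.table["compound"]) - known
        if unknown:
            raise ValueError(f"unknown compounds: {sorted(unknown)}")
        veh = self.table["compound"] == VEHICLE
        if (self.table.loc[veh, "dose_uM"] != 0).any():
            raise ValueError("vehicle wells must have dose_uM = 0")
        if (self.table.loc[~veh, "dose_uM"] <= 0).any():
            raise ValueError("compound wells must have dose_uM > 0")

    @property
    def wells(self) -> list[str]:
        return list(self.table["well"])

    def __len__(self) -> int:
        return len(self.table)


def design_layout(
    n_vehicle_wells: int = 15,
    wells_per_condition: int = 3,
    compounds: tuple[str, ...] = COMPOUNDS,
    doses_uM: tuple[float, ...] = DOSES_UM,
    fields_per_well: int = 16,
    n_replicates: int = 2,
) -> PlateLayout:
    """Build a layout mirroring the study design.

    Vehicle wells come first, then ``wells_per_condition`` technical
    replicates of every (compound, dose) condition; wells are assigned
    row-major over the inner 308 wells and split round-robin across
    ``n_replicates`` biological replicates.
    """
    conditions: list[tuple[str, float]] = [(VEHICLE, 0.0)] * n_vehicle_wells
    for comp, dose in itertools.product(compounds, doses_uM):
        conditions.extend([(comp, dose)] * wells_per_condition)
    avail = inner_wells()
    if len(conditions) > len(avail):
        raise ValueError(
            f"{len(conditions)} wells requested but only {len(avail)} usable"
        )
    rows = [
        {
            "well": avail[i],
            "compound": comp,
            "dose_uM": dose,
            "replicate": i % n_replicates,
        }
        for i, (comp, dose) in enumerate(conditions)
    ]
    return PlateLayout(pd.DataFrame(rows), fields_per_well=fields_per_well)


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative phenotypic effect of one (compound, dose) condition.

    Intensity multipliers act on rendered fluorophore brightness; the
    neurite multipliers shrink random-walk length and branch probability.
    """

    asyn_intensity_mult: float = 1.0
    th_cyto_mult: float = 1.0
    th_membrane_mult: float = 1.0
    neurite_length_mult: float = 1.0
    branch_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in ("asyn_intensity_mult", "th_cyto_mult", "th_membrane_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("neurite_length_mult", "branch_mult"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "asyn_intensity_mult": self.asyn_intensity_mult,
            "th_cyto_mult": self.th_cyto_mult,
            "th_membrane_mult": self.th_membrane_mult,
            "neurite_length_mult": self.neurite_length_mult,
            "branch_mult": self.branch_mult,
        }


_NULL_EFFECT = ConditionEffect()

# Monotone multiplier ladders over doses (0.01, 0.1, 1, 2) uM.  Bisphenols
# weigh more on alpha-synuclein accumulation and neurite loss; the
# perfluoroalkyls weigh more on TH up-regulation, so that the two compound
# classes carry distinct but overlapping signatures.
_DEFAULT_LADDERS = {
    "BP": {
        "asyn_intensity_mult": (1.06, 1.16, 1.30, 1.45),
        "th_cyto_mult": (1.04, 1.10, 1.20, 1.30),
        "th_membrane_mult": (1.05, 1.12, 1.24, 1.34),
        "neurite_length_mult": (0.97, 0.91, 0.84, 0.76),
        "branch_mult": (0.96, 0.89, 0.81, 0.74),
    },
    "PF": {
        "asyn_intensity_mult": (1.04, 1.10, 1.22, 1.34),
        "th_cyto_mult": (1.06, 1.14, 1.28, 1.40),
        "th_membrane_mult": (1.07, 1.17, 1.32, 1.45),
        "neurite_length_mult": (0.98, 0.93, 0.87, 0.80),
        "branch_mult": (0.97, 0.92, 0.85, 0.79),
    },
}


@dataclass(frozen=True)
class EffectModel:
    """Per-condition effect table plus condition-independent parameters.

    ``apoptotic_fraction`` is deliberately shared by every condition
    including vehicle: the compounds do not affect viability, so the
    living-cell count is a null readout by construction.
    """

    effects: dict[tuple[str, float], ConditionEffect] = field(default_factory=dict)
    apoptotic_fraction: float = 0.08

    def __post_init__(self) -> None:
        if not (0 <= self.apoptotic_fraction < 1):
            raise ValueError("apoptotic_fraction must be in [0, 1)")
        for (comp, dose), eff in self.effects.items():
            if comp == VEHICLE and eff != _NULL_EFFECT:
                raise ValueError("vehicle condition must have unit multipliers")
            if comp not in COMPOUNDS and comp != VEHICLE:
                raise ValueError(f"unknown compound {comp!r}")

    def for_condition(self, compound: str, dose_uM: float) -> ConditionEffect:
        if compound == VEHICLE:
            return _NULL_EFFECT
        if compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {compound!r}")
        return self.effects.get((compound, dose_uM), _NULL_EFFECT)

    @classmethod
    def null(cls, apoptotic_fraction: float = 0.0) -> "EffectModel":
        """All multipliers 1: treated and vehicle wells are exchangeable."""
        return cls(effects={}, apoptotic_fraction=apoptotic_fraction)

    @classmethod
    def default(cls) -> "EffectModel":
        """Dose-dependent effects with class-shared signature directions."""
        effects: dict[tuple[str, float], ConditionEffect] = {}
        for comp in COMPOUNDS:
            ladder = _DEFAULT_LADDERS[COMPOUND_CLASS[comp]]
            for i, dose in enumerate(DOSES_UM):
                effects[(comp, dose)] = ConditionEffect(
                    **{k: v[i] for k, v in ladder.items()}
                )
        return cls(effects=effects)

    @classmethod
    def single_feature(
        cls, dose_uM: float = 2.0, **multipliers: float
    ) -> "EffectModel":
        """Inject one effect at one dose for every compound; all else null.

        Used for parameter-recovery checks, e.g.
        ``EffectModel.single_feature(2.0, asyn_intensity_mult=1.5)``.
        """
        eff = ConditionEffect(**multipliers)
        return cls(
            effects={(c, dose_uM): eff for c in COMPOUNDS},
            apoptotic_fraction=0.0,
        )

    def with_apoptotic_fraction(self, frac: float) -> "EffectModel":
        return replace(self, apoptotic_fraction=frac)


def layout_to_csv(layout: PlateLayout, path) -> None:
    t = layout.table.copy()
    t["fields"] = layout.fields_per_well
    t.to_csv(path, index=False)


def layout_from_csv(path) -> PlateLayout:
    t = pd.read_csv(path)
    fields = int(t["fields"].iloc[0]) if "fields" in t.columns else 16
    return PlateLayout(
        t[["well", "compound", "dose_uM", "replicate"]], fields_per_well=fields
    )
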