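"""End-to-end orchestration: simulate -> segment -> featurize -> profile ->
classify -> dose-response, with a single resolved configuration and a
reproducibility manifest.

One master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage_index,))`` so any
stage can be rerun in isolation and still see its own stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import features as feat
from . import profiling, stats
from .catalogue import FEATURE_NAMES, HEADLINE_FEATURES, schema_hash, schema_records
from .plate import EffectModel, PlateLayout, design_layout, layout_from_csv
from .segmentation import FieldImage, ViabilityRule, segment_field
from .synthetic import RenderParams, field_filename, iter_plate_fields, read_field

_STAGES = ("simulate", "segment", "featurize", "profile", "classify", "stats")

_META_COLS = ("well", "compound", "dose_uM", "replicate", "n_fields", "n_living_cells")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline in one place.

    Defaults follow the printed analysis constants: 2000 px / 1500 viability
    thresholds, 5-px membrane rim, 0.1628 um pixel pitch, 10% test split,
    5-fold grid search, 10-fold CV, significance tiers at .05/.01/.001.
    The *small* plate preset (4 fields/well, 256 px fields) keeps a full
    plate tractable on one CPU; the study-scale preset uses 16 fields.
    """

    # plate design: control-majority, as in the study (many vehicle wells
    # against 4 compounds x 4 doses x 3 technical replicates)
    n_vehicle_wells: int = 36
    wells_per_condition: int = 3
    fields_per_well: int = 4
    n_replicates: int = 2
    # rendering
    image_size_px: int = 256
    pixel_pitch_um: float = 0.1628
    mean_cells_per_field: float = 7.0
    # segmentation
    viability_min_area_px: float = 2000.0
    viability_max_mean_intensity: float = 1500.0
    membrane_width_px: int = 5
    soma_opening_radius_px: int = 8
    illumination_sigma_px: float = 64.0
    dna_threshold: float | None = None   # None -> Otsu per field
    map2_threshold: float | None = None
    # classification
    test_fraction: float = 0.10
    grid_cv_folds: int = 5
    cv_folds: int = 10
    scale_before_split: bool = False
    classifiers: tuple[str, ...] = ("lda", "lgbm", "xgb")
    # profiling / embedding
    embed_methods: tuple[str, ...] = ("umap",)
    # stats
    alpha: float = 0.05

    def render_params(self) -> RenderParams:
        return RenderParams(
            image_shape=(self.image_size_px, self.image_size_px),
            pixel_pitch_um=self.pixel_pitch_um,
            mean_cells_per_field=self.mean_cells_per_field,
        )

    def viability_rule(self) -> ViabilityRule:
        return ViabilityRule(
            min_area_px=self.viability_min_area_px,
            max_mean_intensity=self.viability_max_mean_intensity,
        )

    def layout(self) -> PlateLayout:
        return design_layout(
            n_vehicle_wells=self.n_vehicle_wells,
            wells_per_condition=self.wells_per_condition,
            fields_per_well=self.fields_per_well,
            n_replicates=self.n_replicates,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("classifiers", "embed_methods"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def segment_and_featurize_field(
    image: FieldImage, config: RunConfig
) -> tuple[pd.DataFrame, dict[str, float]]:
    masks, corrected = segment_field(
        image,
        rule=config.viability_rule(),
        illumination_sigma_px=config.illumination_sigma_px,
        dna_threshold=config.dna_threshold,
        map2_threshold=config.map2_threshold,
        membrane_width_px=config.membrane_width_px,
        soma_opening_radius_px=config.soma_opening_radius_px,
    )
    return feat.extract_field_features(corrected, masks)


def featurize_plate(
    config: RunConfig,
    effects: EffectModel | None = None,
    seed: int = 0,
    layout: PlateLayout | None = None,
) -> pd.DataFrame:
    """In-memory simulate -> segment -> featurize for a whole plate.

    Returns the well feature table: one row per well with metadata columns
    and the 126 catalogue features.  ``seed`` drives only the simulation;
    segmentation and featurization are deterministic.
    """
    effects = effects if effects is not None else EffectModel.default()
    layout = layout or config.layout()
    params = config.render_params()
    per_well: dict[str, list] = {w: [] for w in layout.wells}
    meta = {r.well: r for r in layout.table.itertuples(index=False)}
    for row, fidx, channels, _truth in iter_plate_fields(layout, effects, params, seed):
        img = FieldImage(
            channels={k: v for k, v in channels.items()},
            pixel_pitch_um=config.pixel_pitch_um,
            well=row.well,
            field=fidx,
        )
        per_well[row.well].append(segment_and_featurize_field(img, config))
    rows = []
    for well, results in per_well.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = feat.featurize_well(results)
        m = meta[well]
        rows.append(
            {
                "well": well,
                "compound": m.compound,
                "dose_uM": m.dose_uM,
                "replicate": m.replicate,
                **s.to_dict(),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["schema_hash"] = schema_hash()
    return table


def featurize_image_dir(in_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Segment + featurize a plate previously written to disk."""
    in_dir = Path(in_dir)
    layout = layout_from_csv(in_dir / "layout.csv")
    rows = []
    for r in layout.table.itertuples(index=False):
        results = []
        for fidx in range(layout.fields_per_well):
            path = in_dir / field_filename(r.well, fidx)
            if not path.exists():
                raise FileNotFoundError(f"missing field image: {path}")
            channels = read_field(path)
            img = FieldImage(
                channels=channels,
                pixel_pitch_um=config.pixel_pitch_um,
                well=r.well,
                field=fidx,
            )
            results.append(segment_and_featurize_field(img, config))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = feat.featurize_well(results)
        rows.append(
            {
                "well": r.well,
                "compound": r.compound,
                "dose_uM": r.dose_uM,
                "replicate": r.replicate,
                **s.to_dict(),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["schema_hash"] = schema_hash()
    return table


def classification_experiment(
    config: RunConfig,
    effects: EffectModel | None = None,
    seed: int = 0,
    table: pd.DataFrame | None = None,
) -> dict[str, clf.ClassifierReport]:
    """Featurize a plate (unless a table is given) and run the full
    train/tune/evaluate/importance procedure for every classifier kind."""
    if table is None:
        table = featurize_plate(config, effects, seed=stage_seed(seed, "simulate"))
    return clf.run_classification(
        table,
        kinds=config.classifiers,
        seed=stage_seed(seed, "classify"),
        spec=clf.SplitSpec(test_fraction=config.test_fraction, seed=stage_seed(seed, "classify")),
        cv_folds=config.grid_cv_folds,
        cv_k=config.cv_folds,
        scale_before_split=config.scale_before_split,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(
    config: RunConfig,
    seed: int,
    out_dir: str | Path,
    effects: EffectModel | None = None,
) -> dict:
    """Full pipeline run with all artefacts on disk.

    Writes: images/ (TIFF fields + layout + ground truth), the well feature
    table (CSV + Parquet + schema JSON), profiling outputs (distance
    matrix, Newick dendrogram, embeddings), per-classifier reports,
    dose-response stats, the resolved config and a manifest with hashes,
    seeds and per-stage runtimes.
    """
    from .synthetic import generate_plate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effects = effects if effects is not None else EffectModel.default()
    runtimes: dict[str, float] = {}
    layout = config.layout()
    params = config.render_params()

    t0 = time.perf_counter()
    img_dir = out / "images"
    generate_plate(layout, effects, params, seed=stage_seed(seed, "simulate"), out_dir=img_dir)
    runtimes["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = featurize_image_dir(img_dir, config)
    runtimes["featurize"] = time.perf_counter() - t0
    table.to_csv(out / "well_features.csv", index=False)
    table.to_parquet(out / "well_features.parquet")
    (out / "feature_schema.json").write_text(
        json.dumps({"schema_hash": schema_hash(), "features": schema_records()}, indent=1)
    )

    t0 = time.perf_counter()
    ok = ~table[list(FEATURE_NAMES)].isna().all(axis=1)
    sub = table.loc[ok].reset_index(drop=True).copy()
    feats = sub[list(FEATURE_NAMES)]
    sub[list(FEATURE_NAMES)] = feats.fillna(feats.median())  # rare missing composites
    scaled = profiling.robust_scale(sub)
    profiles = profiling.aggregate_profiles(scaled)
    dm, _Z, order, newick = profiling.cosine_distance_matrix(profiles)
    dm.to_csv(out / "condition_cosine_distance.csv")
    (out / "condition_dendrogram.nwk").write_text(newick + "\n")
    labels = clf.label_wells(scaled.table)
    for method in config.embed_methods if len(scaled.table) >= 10 else ():
        coords, sil = profiling.embed_wells(
            scaled.table, method=method, seed=stage_seed(seed, "profile"), labels=labels
        )
        coords = coords.assign(label=labels.to_numpy())
        coords.to_csv(out / f"embedding_{method}.csv", index=False)
        if sil is not None:
            (out / f"embedding_{method}_silhouette.json").write_text(
                json.dumps({"silhouette": sil})
            )
    runtimes["profile"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reports = classification_experiment(config, effects, seed=seed, table=table)
    runtimes["classify"] = time.perf_counter() - t0
    (out / "classification.json").write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=1)
    )

    t0 = time.perf_counter()
    dr = stats.dose_response_table(table.loc[ok], features=HEADLINE_FEATURES)
    dr.to_csv(out / "dose_response.csv", index=False)
    runtimes["stats"] = time.perf_counter() - t0

    config.to_yaml(out / "config_resolved.yaml")
    manifest = {
        "config_hash": config.config_hash(),
        "schema_hash": schema_hash(),
        "master_seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES},
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
        "output_checksums": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.suffix in {".csv", ".json", ".nwk", ".yaml"}
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "table": table,
        "reports": reports,
        "dose_response": dr,
        "manifest": manifest,
        "out_dir": out,
    }
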