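"""Per-cell and per-field phenotypic feature extraction.

Implements the four feature classes of the catalogue — shape, intensity,
GLCM texture and context — per compartment, plus the named composite
readouts, and the field -> well aggregation (living-cell means for
per-cell features, field means for field-level features).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .catalogue import (
    CHANNEL_PAIRS,
    COMPARTMENTS,
    CORR_COMPARTMENTS,
    FEATURE_NAMES,
    INTENSITY_CHANNELS,
    INTENSITY_STATS,
    SHAPE_METRICS,
    TEXTURE_COMPARTMENTS,
    TEXTURE_METRICS,
)
from .segmentation import CompartmentMasks, FieldImage

GLCM_LEVELS = 16
GLCM_PERCENTILES = (1.0, 99.0)
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_metrics(
    values: np.ndarray,
    mask: np.ndarray,
    levels: int = GLCM_LEVELS,
    angles: tuple[float, ...] = _GLCM_ANGLES,
) -> dict[str, float]:
    """Texture metrics from a symmetric, direction-averaged GLCM.

    Pixels are quantized to ``levels`` gray levels over the masked region's
    1st-99th intensity percentiles; pairs crossing the mask boundary are
    excluded via a sentinel level.  A constant region has a single
    co-occurrence cell: ASM = 1, contrast = 0, and correlation is
    undefined and reported as 0.
    """
    vals = values[mask]
    if vals.size < 2:
        return {"asm": 0.0, "contrast": 0.0, "correlation": 0.0, "homogeneity": 0.0, "entropy": 0.0}
    lo, hi = np.percentile(vals, GLCM_PERCENTILES)
    if hi <= lo:  # constant region
        q = np.zeros(values.shape, dtype=np.uint8)
    else:
        q = np.clip((values - lo) / (hi - lo) * levels, 0, levels - 1).astype(np.uint8)
    q = np.where(mask, q, levels).astype(np.uint8)  # sentinel outside mask
    glcm = graycomatrix(
        q, distances=[1], angles=list(angles), levels=levels + 1, symmetric=True
    )
    p = glcm[:levels, :levels, 0, :].astype(np.float64).mean(axis=2)
    total = p.sum()
    if total == 0:
        return {"asm": 0.0, "contrast": 0.0, "correlation": 0.0, "homogeneity": 0.0, "entropy": 0.0}
    p /= total
    i, j = np.indices(p.shape)
    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    pi = p.sum(axis=1)
    mu = float((np.arange(p.shape[0]) * pi).sum())
    var = float(((np.arange(p.shape[0]) - mu) ** 2 * pi).sum())
    if var <= 0:
        correlation = 0.0
    else:
        correlation = float((((i - mu) * (j - mu) * p).sum()) / var)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def _compartment_mask(
    masks: CompartmentMasks, comp: str, label: int, bb=None
) -> np.ndarray:
    arr = {
        "cell": masks.cell_labels,
        "cytoplasm": masks.cytoplasm_labels,
        "membrane": masks.membrane_labels,
        "nucleus": masks.nucleus_labels,
    }[comp]
    if bb is not None:
        arr = arr[bb]
    return arr == label


def _bbox_slices(labels: np.ndarray) -> dict[int, tuple[slice, slice]]:
    out = {}
    for p in regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        out[p.label] = (slice(r0, r1), slice(c0, c1))
    return out


def _union_bbox(boxes: list[tuple[slice, slice] | None]) -> tuple[slice, slice] | None:
    boxes = [b for b in boxes if b is not None]
    if not boxes:
        return None
    r0 = min(b[0].start for b in boxes)
    r1 = max(b[0].stop for b in boxes)
    c0 = min(b[1].start for b in boxes)
    c1 = max(b[1].stop for b in boxes)
    return (slice(r0, r1), slice(c0, c1))


def _shape_metrics(mask: np.ndarray, pitch: float) -> dict[str, float]:
    """Size/shape metrics of one (possibly multi-part or ringed) region."""
    if not mask.any():
        return {m: 0.0 for m in SHAPE_METRICS}
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = float(props.area)
    perim_px = float(props.perimeter)
    form = 4 * np.pi * area_px / perim_px**2 if perim_px > 0 else 0.0
    return {
        "area_um2": area_px * pitch**2,
        "perimeter_um": perim_px * pitch,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "form_factor": float(form),
    }


def shape_features(
    masks: CompartmentMasks,
    pixel_pitch_um: float,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Per-living-cell shape metrics for all four compartments.

    Cells touching the image border get NaN shape features when
    ``exclude_border`` is set (their geometry is truncated); they keep
    their intensity features.
    """
    h, w = masks.cell_labels.shape
    rows = []
    boxes = _bbox_slices(masks.cell_labels)
    nboxes = _bbox_slices(masks.nucleus_labels)
    for lab in masks.living_labels:
        row: dict[str, float] = {"label": lab}
        bb = _union_bbox([boxes.get(lab), nboxes.get(lab)])
        if bb is None:
            rows.append({**row, **{f"{c}_shape_{m}": 0.0 for c in COMPARTMENTS for m in SHAPE_METRICS}})
            continue
        on_border = (
            bb[0].start == 0 or bb[1].start == 0 or bb[0].stop == h or bb[1].stop == w
        )
        for comp in COMPARTMENTS:
            sub = _compartment_mask(masks, comp, lab, bb)
            if exclude_border and on_border:
                vals = {m: np.nan for m in SHAPE_METRICS}
            else:
                vals = _shape_metrics(sub, pixel_pitch_um)
            row.update({f"{comp}_shape_{m}": v for m, v in vals.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def intensity_features(masks: CompartmentMasks, image: FieldImage) -> pd.DataFrame:
    """Mean/median/std/integrated intensity per channel and compartment,
    plus nuclear DNA content, per living cell.  Empty compartments report 0."""
    rows = []
    boxes = _bbox_slices(masks.cell_labels)
    nboxes = _bbox_slices(masks.nucleus_labels)
    for lab in masks.living_labels:
        row: dict[str, float] = {"label": lab}
        bb = _union_bbox([boxes.get(lab), nboxes.get(lab)])
        for comp in COMPARTMENTS:
            cmask = _compartment_mask(masks, comp, lab, bb) if bb else np.zeros((0, 0), bool)
            for ch in INTENSITY_CHANNELS:
                if bb is None or not cmask.any():
                    stats = dict.fromkeys(INTENSITY_STATS, 0.0)
                else:
                    v = image.channels[ch][bb][cmask].astype(np.float64)
                    stats = {
                        "mean": float(v.mean()),
                        "median": float(np.median(v)),
                        "std": float(v.std()),
                        "integrated": float(v.sum()),
                    }
                row.update({f"{comp}_{ch}_intensity_{s}": x for s, x in stats.items()})
        nmask = _compartment_mask(masks, "nucleus", lab, bb) if bb else None
        if nmask is not None and nmask.any():
            v = image.channels["DNA"][bb][nmask].astype(np.float64)
            row["nucleus_DNA_intensity_mean"] = float(v.mean())
            row["nucleus_DNA_intensity_std"] = float(v.std())
            row["nucleus_DNA_intensity_integrated"] = float(v.sum())
        else:
            row["nucleus_DNA_intensity_mean"] = 0.0
            row["nucleus_DNA_intensity_std"] = 0.0
            row["nucleus_DNA_intensity_integrated"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def texture_features(masks: CompartmentMasks, image: FieldImage) -> pd.DataFrame:
    """GLCM texture metrics for ASYN/TH/MAP2 on cell and cytoplasm."""
    rows = []
    boxes = _bbox_slices(masks.cell_labels)
    for lab in masks.living_labels:
        row: dict[str, float] = {"label": lab}
        bb = boxes.get(lab)
        for comp in TEXTURE_COMPARTMENTS:
            cmask = _compartment_mask(masks, comp, lab, bb) if bb else np.zeros((0, 0), bool)
            for ch in ("ASYN", "TH", "MAP2"):
                if bb is None or not cmask.any():
                    met = dict.fromkeys(TEXTURE_METRICS, 0.0)
                else:
                    met = glcm_metrics(image.channels[ch][bb].astype(np.float64), cmask)
                row.update(
                    {f"{comp}_{ch}_texture_{m}": met[m] for m in TEXTURE_METRICS}
                )
        rows.append(row)
    return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when undefined (< 2 pixels or zero variance)."""
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _pair_correlations(
    image: FieldImage, bb, cmask: np.ndarray
) -> dict[tuple[str, str], float]:
    """All channel-pair Pearson r over one compartment in one pass."""
    if cmask.sum() < 2:
        return {pair: 0.0 for pair in CHANNEL_PAIRS}
    stack = np.stack(
        [image.channels[ch][bb][cmask].astype(np.float64) for ch in ("DNA", "TH", "ASYN", "MAP2")]
    )
    idx = {"DNA": 0, "TH": 1, "ASYN": 2, "MAP2": 3}
    sd = stack.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(stack)
    out = {}
    for a, b in CHANNEL_PAIRS:
        if sd[idx[a]] == 0 or sd[idx[b]] == 0:
            out[(a, b)] = 0.0
        else:
            out[(a, b)] = float(r[idx[a], idx[b]])
    return out


def context_features(
    masks: CompartmentMasks,
    image: FieldImage,
    th_threshold: float | None = None,
    asyn_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell channel correlations + neurite morphometry, and the
    field-level context block (counts, densities, composites).

    Thresholds for TH-positivity and double-positive pixels default to
    per-field Otsu on the respective channel.  With no TH-positive cell the
    composite ``asyn_intensity_in_th_pos_cells`` is NaN (missing).
    """
    pitch = image.pixel_pitch_um
    th = image.channels["TH"].astype(np.float64)
    asyn = image.channels["ASYN"].astype(np.float64)
    if th_threshold is None:
        th_threshold = threshold_otsu(th) if np.ptp(th) > 0 else np.inf
    if asyn_threshold is None:
        asyn_threshold = threshold_otsu(asyn) if np.ptp(asyn) > 0 else np.inf

    boxes = _bbox_slices(masks.cell_labels)
    nboxes = _bbox_slices(masks.nucleus_labels)
    rows = []
    th_pos_flags: dict[int, bool] = {}
    asyn_cell_means: dict[int, float] = {}
    dp_per_cell: list[float] = []
    dp_area = 0.0
    cell_area = 0.0
    for lab in masks.living_labels:
        row: dict[str, float] = {"label": lab}
        bb = _union_bbox([boxes.get(lab), nboxes.get(lab)])
        for comp in CORR_COMPARTMENTS:
            if bb is None:
                row.update({f"{comp}_corr_{a}_{b}": 0.0 for a, b in CHANNEL_PAIRS})
                continue
            cmask = _compartment_mask(masks, comp, lab, bb)
            corrs = _pair_correlations(image, bb, cmask)
            row.update({f"{comp}_corr_{a}_{b}": corrs[(a, b)] for a, b in CHANNEL_PAIRS})
        row["neurite_length_per_cell_um"] = masks.neurite_length_um.get(lab, 0.0)
        row["branch_points_per_cell"] = float(masks.branch_points.get(lab, 0))
        if bb is not None:
            cmask = _compartment_mask(masks, "cell", lab, bb)
            if cmask.any():
                tv = th[bb][cmask]
                av = asyn[bb][cmask]
                th_pos_flags[lab] = bool(tv.mean() > th_threshold)
                asyn_cell_means[lab] = float(av.mean())
                dp = (tv > th_threshold) & (av > asyn_threshold)
                dp_per_cell.append(float(((tv[dp] + av[dp]) / 2.0).sum()))
                dp_area += float(dp.sum())
                cell_area += float(cmask.sum())
        rows.append(row)

    per_cell = pd.DataFrame(rows)

    n_total = len(masks.viability)
    n_living = masks.living_count
    h, w = masks.cell_labels.shape
    field_area_mm2 = h * w * (pitch / 1000.0) ** 2
    centroids = [
        p.centroid
        for p in regionprops(masks.nucleus_labels)
        if masks.viability.get(p.label, False)
    ]
    if len(centroids) >= 2:
        d = pdist(np.asarray(centroids)) * pitch
        nn = []
        dm = np.asarray(centroids)
        from scipy.spatial.distance import squareform

        sq = squareform(d)
        np.fill_diagonal(sq, np.inf)
        nn = sq.min(axis=1)
        nn_mean, nn_std = float(np.mean(nn)), float(np.std(nn))
    else:
        nn_mean, nn_std = 0.0, 0.0
    th_pos_labels = [l for l, f in th_pos_flags.items() if f]
    asyn_in_th_pos = (
        float(np.mean([asyn_cell_means[l] for l in th_pos_labels]))
        if th_pos_labels
        else np.nan
    )
    field_row = {
        "living_cell_count": float(n_living),
        "total_nucleus_count": float(n_total),
        "apoptotic_fraction": (n_total - n_living) / n_total if n_total else 0.0,
        "cell_density_per_mm2": n_living / field_area_mm2,
        "fraction_th_positive": (
            len(th_pos_labels) / n_living if n_living else 0.0
        ),
        "nn_soma_distance_mean_um": nn_mean,
        "nn_soma_distance_std_um": nn_std,
        "asyn_intensity_in_th_pos_cells": asyn_in_th_pos,
        "th_asyn_double_pos_surface_intensity": (
            float(np.mean(dp_per_cell)) if dp_per_cell else 0.0
        ),
        "th_asyn_double_pos_area_fraction": dp_area / cell_area if cell_area else 0.0,
        "map2_surface_per_nucleus_um2": (
            float((masks.cell_labels > 0).sum()) * pitch**2 / n_living
            if n_living
            else 0.0
        ),
    }
    return per_cell, field_row


def extract_field_features(
    image: FieldImage,
    masks: CompartmentMasks,
    exclude_border_shapes: bool = True,
    th_threshold: float | None = None,
    asyn_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """All feature blocks for one field.

    Returns (per-cell table, field-level dict); the per-cell table has one
    row per living cell and one column per cell-level catalogue feature.
    """
    ctx_cells, field_row = context_features(
        masks, image, th_threshold=th_threshold, asyn_threshold=asyn_threshold
    )
    parts = [
        intensity_features(masks, image),
        shape_features(masks, image.pixel_pitch_um, exclude_border=exclude_border_shapes),
        texture_features(masks, image),
        ctx_cells,
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(), field_row
    per_cell = parts[0]
    for p in parts[1:]:
        per_cell = per_cell.merge(p, on="label", how="outer")
    per_cell.insert(0, "well", image.well)
    per_cell.insert(1, "field", image.field)
    return per_cell, field_row


def featurize_well(
    field_results: list[tuple[pd.DataFrame, dict[str, float]]],
) -> pd.Series:
    """Aggregate fields to one well row with exactly 126 feature values.

    Per-cell features are averaged over all living cells pooled across the
    well's fields; field-level features are averaged over fields.  A well
    with zero living cells yields an all-NaN row (excluded downstream).
    """
    if not field_results:
        raise ValueError("featurize_well needs at least one field")
    cell_tables = [t for t, _ in field_results if not t.empty]
    field_rows = pd.DataFrame([f for _, f in field_results])
    out: dict[str, float] = {}
    if cell_tables:
        pooled = pd.concat(cell_tables, ignore_index=True)
        n_cells = len(pooled)
    else:
        warnings.warn("well has zero living cells; emitting NaN feature row")
        pooled = pd.DataFrame()
        n_cells = 0
    for name in FEATURE_NAMES:
        if name in field_rows.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[name] = float(np.nanmean(field_rows[name].to_numpy(dtype=float)))
        elif not pooled.empty and name in pooled.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[name] = float(np.nanmean(pooled[name].to_numpy(dtype=float)))
        else:
            out[name] = np.nan
    s = pd.Series(out, index=FEATURE_NAMES, dtype=float)
    s["n_fields"] = len(field_results)
    s["n_living_cells"] = n_cells
    return s
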