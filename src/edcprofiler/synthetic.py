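"""Synthetic multichannel plate-image generator.

Renders 16-bit 4-channel (DNA/Hoechst, TH, alpha-synuclein, MAP2)
fluorescence fields that emulate cultured midbrain dopaminergic neurons:
elliptical nuclei, somata with a TH rim at the cell edge, and neurites grown
as branching biased random walks.  Condition effects enter as multiplicative
factors on channel intensities, walk length and branch probability, so every
injected effect is recoverable by the downstream segmentation + feature
pipeline.

A configurable minority of nuclei is rendered apoptotic: small (< 2000 px)
and bright (mean > 1500), violating the living-cell rule by construction.

All randomness flows from ``numpy.random.Generator`` seeded per (well,
field), so identical inputs give bit-identical images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .plate import VEHICLE, ConditionEffect, EffectModel, PlateLayout

#: fixed channel order used in every multipage TIFF written by this module
CHANNELS = ("DNA", "TH", "ASYN", "MAP2")

#: camera pixel pitch; 2000 px ~ 53 um^2 and 5 px ~ 0.81 um at this pitch
PIXEL_PITCH_UM = 0.1628


@dataclass(frozen=True)
class RenderParams:
    """Geometry, intensity and noise parameters of the renderer.

    Intensities are on a 16-bit scale with ~200 background so that the
    viability rule's nuclear mean-intensity threshold of 1500 separates the
    dim living nuclei (~900-1250) from bright apoptotic ones (~2600-3600).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_pitch_um: float = PIXEL_PITCH_UM
    mean_cells_per_field: float = 7.0
    max_cells_per_field: int = 24
    cell_margin_px: int = 34
    min_cell_separation_px: float = 66.0

    background: float = 200.0
    gradient_amplitude: float = 40.0
    noise_gain: float = 0.5          # photons per intensity unit (shot noise)
    read_noise_sd: float = 25.0

    nucleus_radius_px: tuple[float, float] = (27.0, 32.0)
    nucleus_intensity: tuple[float, float] = (900.0, 1250.0)
    apoptotic_radius_px: tuple[float, float] = (12.0, 16.0)
    apoptotic_intensity: tuple[float, float] = (2600.0, 3600.0)

    soma_extra_radius_px: float = 10.0
    map2_soma_intensity: float = 4000.0
    map2_neurite_intensity: float = 3000.0
    th_soma_intensity: float = 2800.0
    th_rim_intensity: float = 5400.0
    th_rim_width_px: int = 4
    th_neurite_intensity: float = 900.0
    th_negative_intensity: float = 350.0
    th_positive_fraction: float = 0.85
    asyn_soma_intensity: float = 2400.0
    asyn_nucleus_intensity: float = 1100.0
    asyn_neurite_intensity: float = 800.0

    n_neurites_range: tuple[int, int] = (2, 4)
    neurite_mean_length_px: float = 110.0
    neurite_length_sd_px: float = 25.0
    neurite_min_length_px: float = 25.0
    branch_prob_per_step: float = 0.025
    walk_angle_jitter: float = 0.18

    cell_cv: float = 0.10       # cell-to-cell lognormal spread of intensities
    well_cv: float = 0.04       # well-level biological variability
    replicate_cv: float = 0.03  # plate-level offset of a biological replicate


@dataclass
class CellGroundTruth:
    """One record per rendered cell, consistent with the image pre-noise."""

    well: str
    field: int
    cell_index: int
    row: float
    col: float
    living: bool
    th_positive: bool
    nucleus_area_px: int
    nucleus_mean_intensity: float
    neurite_length_px: float
    branch_count: int
    asyn_soma_intensity: float
    th_soma_intensity: float
    th_rim_intensity: float
    map2_soma_area_px: int


def _ellipse_mask(shape, center, a, b, angle):
    dr = (np.arange(shape[0]) - center[0])[:, None]
    dc = (np.arange(shape[1]) - center[1])[None, :]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stamp_disk(mask: np.ndarray, r: int, c: int) -> None:
    """Stamp a ~2-px-wide stroke element at (r, c), clipped to the image."""
    h, w = mask.shape
    for dr, dc in ((0, 0), (0, 1), (1, 0)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            mask[rr, cc] = True


def _grow_neurites(
    shape,
    start_r: float,
    start_c: float,
    soma_radius: float,
    n_neurites: int,
    params: RenderParams,
    length_mult: float,
    branch_mult: float,
    rng: np.random.Generator,
    soma_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int]:
    """Branching biased random walks from the soma edge.

    Returns (binary neurite mask, centerline length in px, branch count).
    The walk takes unit steps with angular jitter; a branch event forks the
    remainder of the walk at ~55 degrees with 60% of the remaining length.
    The reported ground-truth length is the Euclidean length of the chain
    of *newly visited* centerline pixels (diagonal moves count sqrt(2)), so
    self-overlaps and branch/parent overlaps are not double-counted — this
    is the quantity a topology-preserving skeleton can recover.
    """
    mask = np.zeros(shape, dtype=bool)
    visited: set[tuple[int, int]] = set()
    total_len = 0.0
    branches = 0
    base_angles = rng.uniform(0, 2 * np.pi) + np.arange(n_neurites) * (
        2 * np.pi / n_neurites
    )
    stack: list[tuple[float, float, float, float]] = []
    for theta in base_angles:
        length = rng.normal(params.neurite_mean_length_px, params.neurite_length_sd_px)
        length = max(params.neurite_min_length_px, length) * length_mult
        r0 = start_r + soma_radius * np.sin(theta)
        c0 = start_c + soma_radius * np.cos(theta)
        stack.append((r0, c0, theta, length))
    p_branch = params.branch_prob_per_step * branch_mult
    while stack:
        r, c, theta, remaining = stack.pop()
        prev = (int(round(r)), int(round(c)))
        while remaining > 0:
            theta += rng.normal(0.0, params.walk_angle_jitter)
            r += np.sin(theta)
            c += np.cos(theta)
            if not (1 <= r < shape[0] - 1 and 1 <= c < shape[1] - 1):
                break
            cur = (int(round(r)), int(round(c)))
            _stamp_disk(mask, *cur)
            outside = soma_mask is None or not soma_mask[cur]
            if cur != prev and cur not in visited and outside:
                visited.add(cur)
                total_len += float(np.hypot(cur[0] - prev[0], cur[1] - prev[1]))
            prev = cur
            remaining -= 1.0
            if remaining > 8 and rng.random() < p_branch:
                branches += 1
                sign = 1.0 if rng.random() < 0.5 else -1.0
                stack.append((r, c, theta + sign * 0.95, remaining * 0.6))
                remaining *= 0.75
    return mask, total_len, branches


def _place_centers(
    n: int, params: RenderParams, rng: np.random.Generator
) -> list[tuple[float, float]]:
    h, w = params.image_shape
    m = params.cell_margin_px
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(300):
            r = rng.uniform(m, h - m)
            c = rng.uniform(m, w - m)
            if all(
                np.hypot(r - rr, c - cc) >= params.min_cell_separation_px
                for rr, cc in centers
            ):
                centers.append((r, c))
                break
        # silently place fewer cells if the field is saturated
    return centers


@dataclass(frozen=True)
class WellMultipliers:
    """Per-well lognormal biological variability applied on top of the
    condition effect; vehicle wells get these too (they model culture
    heterogeneity, not treatment)."""

    asyn: float = 1.0
    th_cyto: float = 1.0
    th_membrane: float = 1.0
    neurite_length: float = 1.0
    branch: float = 1.0

    @classmethod
    def draw(cls, cv: float, rng: np.random.Generator) -> "WellMultipliers":
        if cv <= 0:
            return cls()
        vals = np.exp(rng.normal(0.0, cv, size=5))
        return cls(*vals)


def generate_field(
    condition: tuple[str, float],
    effects: EffectModel,
    params: RenderParams = RenderParams(),
    seed: int | np.random.Generator = 0,
    n_cells: int | None = None,
    well: str = "B02",
    field_index: int = 0,
    well_multipliers: WellMultipliers | None = None,
    return_masks: bool = False,
):
    """Render one field for a (compound, dose_uM) condition.

    Returns a dict mapping channel name -> uint16 image, plus the per-cell
    ground-truth records.  ``n_cells`` overrides the Poisson draw; a count
    that cannot physically fit the field raises ``ValueError``.
    """
    h, w = params.image_shape
    if h < 128 or w < 128:
        raise ValueError("image size must be at least 128x128")
    compound, dose = condition
    eff: ConditionEffect = effects.for_condition(compound, dose)
    wm = well_multipliers or WellMultipliers()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    if n_cells is None:
        n_cells = int(rng.poisson(params.mean_cells_per_field))
    if n_cells > params.max_cells_per_field or n_cells * np.pi * (
        params.nucleus_radius_px[1] + params.soma_extra_radius_px
    ) ** 2 > 2.0 * h * w:
        raise ValueError(f"{n_cells} cells cannot fit a {h}x{w} field")

    chan = {name: np.zeros((h, w), dtype=np.float64) for name in CHANNELS}
    truth: list[CellGroundTruth] = []
    centers = _place_centers(n_cells, params, rng)
    gt_masks = {
        "nucleus": np.zeros((h, w), dtype=np.int32),
        "soma": np.zeros((h, w), dtype=bool),
        "neurite": np.zeros((h, w), dtype=bool),
    }

    # pass 1: sample every cell's geometry so the union of somata is known
    # before any neurite is grown (a walk crossing a neighbouring soma is
    # invisible to segmentation and must not count as ground-truth length)
    geom = []
    for i, (r, c) in enumerate(centers):
        apoptotic = rng.random() < effects.apoptotic_fraction
        cell_f = np.exp(rng.normal(0.0, params.cell_cv, size=4))
        if apoptotic:
            a = rng.uniform(*params.apoptotic_radius_px)
            b = rng.uniform(params.apoptotic_radius_px[0], a)
            ang = rng.uniform(0, np.pi)
            nuc = _ellipse_mask((h, w), (r, c), a, b, ang)
            inten = rng.uniform(*params.apoptotic_intensity)
            geom.append(
                dict(i=i, r=r, c=c, apoptotic=True, nuc=nuc, inten=inten, cell_f=cell_f)
            )
            gt_masks["nucleus"][nuc] = i + 1
            continue
        a = rng.uniform(*params.nucleus_radius_px)
        b = rng.uniform(params.nucleus_radius_px[0], a)
        ang = rng.uniform(0, np.pi)
        nuc = _ellipse_mask((h, w), (r, c), a, b, ang)
        nuc_inten = rng.uniform(*params.nucleus_intensity)
        soma_a = a + params.soma_extra_radius_px
        soma_b = b + params.soma_extra_radius_px
        soma = _ellipse_mask((h, w), (r, c), soma_a, soma_b, ang)
        rim = soma & ~_ellipse_mask(
            (h, w),
            (r, c),
            soma_a - params.th_rim_width_px,
            soma_b - params.th_rim_width_px,
            ang,
        )
        th_pos = rng.random() < params.th_positive_fraction
        n_neur = int(
            rng.integers(params.n_neurites_range[0], params.n_neurites_range[1] + 1)
        )
        geom.append(
            dict(
                i=i, r=r, c=c, apoptotic=False, nuc=nuc, inten=nuc_inten,
                cell_f=cell_f, soma=soma, rim=rim, soma_a=soma_a,
                soma_b=soma_b, th_pos=th_pos, n_neur=n_neur,
            )
        )
        gt_masks["nucleus"][nuc] = i + 1
        gt_masks["soma"] |= soma
    soma_union = gt_masks["soma"]

    # pass 2: paint channels and grow neurites
    for g_ in geom:
        i, r, c, nuc, cell_f = g_["i"], g_["r"], g_["c"], g_["nuc"], g_["cell_f"]
        if g_["apoptotic"]:
            chan["DNA"][nuc] += g_["inten"]
            # condensed apoptotic bodies retain faint, diffuse markers
            chan["ASYN"][nuc] += 300.0 * cell_f[1]
            truth.append(
                CellGroundTruth(
                    well=well, field=field_index, cell_index=i, row=r, col=c,
                    living=False, th_positive=False,
                    nucleus_area_px=int(nuc.sum()),
                    nucleus_mean_intensity=g_["inten"],
                    neurite_length_px=0.0, branch_count=0,
                    asyn_soma_intensity=0.0, th_soma_intensity=0.0,
                    th_rim_intensity=0.0, map2_soma_area_px=0,
                )
            )
            continue
        soma, rim = g_["soma"], g_["rim"]
        nuc_inten, th_pos = g_["inten"], g_["th_pos"]
        chan["DNA"][nuc] += nuc_inten
        neur_mask, neur_len, n_branch = _grow_neurites(
            (h, w), r, c,
            max(2.0, min(g_["soma_a"], g_["soma_b"]) - 2.0),
            g_["n_neur"], params,
            eff.neurite_length_mult * wm.neurite_length,
            eff.branch_mult * wm.branch,
            rng,
            soma_mask=soma_union,
        )
        neur_mask &= ~soma_union
        gt_masks["neurite"] |= neur_mask

        map2_soma = params.map2_soma_intensity * cell_f[0]
        chan["MAP2"][soma] += map2_soma
        chan["MAP2"][neur_mask] += params.map2_neurite_intensity * cell_f[0]

        asyn_val = params.asyn_soma_intensity * eff.asyn_intensity_mult * wm.asyn * cell_f[1]
        chan["ASYN"][soma & ~nuc] += asyn_val
        chan["ASYN"][nuc] += params.asyn_nucleus_intensity * cell_f[1]
        chan["ASYN"][neur_mask] += (
            params.asyn_neurite_intensity * eff.asyn_intensity_mult * wm.asyn * cell_f[1]
        )

        if th_pos:
            th_val = params.th_soma_intensity * eff.th_cyto_mult * wm.th_cyto * cell_f[2]
            rim_val = params.th_rim_intensity * eff.th_membrane_mult * wm.th_membrane * cell_f[2]
            # rim replaces (not adds to) the soma fill so the membrane
            # readout scales directly with its multiplier
            chan["TH"][soma & ~rim] += th_val
            chan["TH"][rim] += rim_val
            chan["TH"][neur_mask] += params.th_neurite_intensity * eff.th_cyto_mult * wm.th_cyto * cell_f[2]
        else:
            th_val, rim_val = 0.0, 0.0
            chan["TH"][soma] += params.th_negative_intensity * cell_f[2]

        truth.append(
            CellGroundTruth(
                well=well, field=field_index, cell_index=i, row=r, col=c,
                living=True, th_positive=th_pos,
                nucleus_area_px=int(nuc.sum()),
                nucleus_mean_intensity=nuc_inten,
                neurite_length_px=neur_len, branch_count=n_branch,
                asyn_soma_intensity=asyn_val,
                th_soma_intensity=th_val, th_rim_intensity=rim_val,
                map2_soma_area_px=int(soma.sum()),
            )
        )

    # background plane + smooth illumination gradient + camera noise
    gr = rng.uniform(-1, 1, size=2)
    rr, cc = np.mgrid[0:h, 0:w]
    gradient = params.gradient_amplitude * (
        gr[0] * (rr / h - 0.5) + gr[1] * (cc / w - 0.5) + 1.0
    )
    out: dict[str, np.ndarray] = {}
    g = params.noise_gain
    for name in CHANNELS:
        img = chan[name] + params.background + gradient
        img = rng.poisson(np.clip(img, 0, None) * g) / g
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        out[name] = np.clip(img, 0, 65535).round().astype(np.uint16)
    if return_masks:
        return out, truth, gt_masks
    return out, truth


def _field_rng(seed: int, well_idx: int, field_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(well_idx, field_idx))
    )


def iter_plate_fields(
    layout: PlateLayout,
    effects: EffectModel,
    params: RenderParams = RenderParams(),
    seed: int = 0,
):
    """Yield (well_row, field_index, channels, ground_truth) for every field.

    Per-well biological variability and per-replicate plate offsets are
    drawn from dedicated streams so that the result is independent of
    iteration order.
    """
    rep_ids = sorted(layout.table["replicate"].unique())
    rep_mult = {
        rep: WellMultipliers.draw(
            params.replicate_cv,
            np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(999_000, int(rep)))
            ),
        )
        for rep in rep_ids
    }
    for widx, row in enumerate(layout.table.itertuples(index=False)):
        wrng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(widx, 999_999))
        )
        wmul = WellMultipliers.draw(params.well_cv, wrng)
        rmul = rep_mult[row.replicate]
        combined = WellMultipliers(
            asyn=wmul.asyn * rmul.asyn,
            th_cyto=wmul.th_cyto * rmul.th_cyto,
            th_membrane=wmul.th_membrane * rmul.th_membrane,
            neurite_length=wmul.neurite_length * rmul.neurite_length,
            branch=wmul.branch * rmul.branch,
        )
        for fidx in range(layout.fields_per_well):
            channels, truth = generate_field(
                (row.compound, row.dose_uM),
                effects,
                params,
                seed=_field_rng(seed, widx, fidx),
                well=row.well,
                field_index=fidx,
                well_multipliers=combined,
            )
            yield row, fidx, channels, truth


def field_filename(well: str, field_index: int) -> str:
    return f"{well}_f{field_index:02d}.tif"


def generate_plate(
    layout: PlateLayout,
    effects: EffectModel,
    params: RenderParams = RenderParams(),
    seed: int = 0,
    out_dir: str | Path = ".",
) -> pd.DataFrame:
    """Render every field of a plate to disk.

    Writes one multipage TIFF per field (pages in ``CHANNELS`` order), a
    ``layout.csv`` and a ``ground_truth.csv``; returns the ground-truth
    table.  Deterministic under (layout, effects, params, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_rows = []
    for row, fidx, channels, truth in iter_plate_fields(layout, effects, params, seed):
        stack = np.stack([channels[c] for c in CHANNELS])
        tifffile.imwrite(
            out / field_filename(row.well, fidx),
            stack,
            photometric="minisblack",
            metadata={"axes": "CYX", "channels": list(CHANNELS)},
        )
        gt_rows.extend(dataclasses.asdict(t) for t in truth)
    from .plate import layout_to_csv

    layout_to_csv(layout, out / "layout.csv")
    gt = pd.DataFrame(gt_rows)
    gt.to_csv(out / "ground_truth.csv", index=False)
    return gt


def read_field(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multipage field TIFF back into a channel dict."""
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != len(CHANNELS):
        raise ValueError(
            f"{path}: expected a {len(CHANNELS)}-page TIFF, got shape {stack.shape}"
        )
    return {name: stack[i] for i, name in enumerate(CHANNELS)}
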