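"""Compartment segmentation of multichannel neuron fields.

The segmentation follows the compartment definitions used throughout the
analysis: nuclei from the DNA channel; the *cell* is the MAP2-positive area
claimed by a living nucleus; *cytoplasm* = cell minus nucleus; *membrane* =
the 5-pixel-wide window inside the cell edge (cell minus its 5-step
erosion).  A living cell is a nucleus strictly larger than 2000 px with a
mean DNA intensity strictly below 1500; smaller, brighter nuclei show DNA
compaction and are called apoptotic.

Everything here is deterministic: no randomness enters this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, remove_small_objects, skeletonize
from skimage.segmentation import watershed

from .synthetic import CHANNELS, PIXEL_PITCH_UM

#: structuring element for the membrane rim erosion: 3x3 cross, 5 iterations
#: (city-block radius 5, i.e. a 5-pixel-wide rim)
CROSS = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class FieldImage:
    """One microscope field: four co-registered 2-D channels."""

    channels: dict[str, np.ndarray]
    pixel_pitch_um: float = PIXEL_PITCH_UM
    well: str = ""
    field: int = 0

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        for ch, a in self.channels.items():
            if a.ndim != 2:
                raise ValueError(f"channel {ch} is not 2-D")
            if np.min(a) < 0:
                raise ValueError(f"channel {ch} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class ViabilityRule:
    """Living cell: nucleus area strictly > min_area_px AND mean DNA
    intensity strictly < max_mean_intensity."""

    min_area_px: float = 2000.0
    max_mean_intensity: float = 1500.0


@dataclass
class CompartmentMasks:
    """Label-consistent compartment masks for one field.

    The same label L refers to the same cell in every array; apoptotic
    nuclei keep their nucleus label but have no cell/cytoplasm/membrane.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    membrane_labels: np.ndarray
    neurite_skeleton: np.ndarray
    viability: dict[int, bool]
    neurite_length_um: dict[int, float] = dc_field(default_factory=dict)
    branch_points: dict[int, int] = dc_field(default_factory=dict)

    @property
    def living_labels(self) -> list[int]:
        return sorted(l for l, v in self.viability.items() if v)

    @property
    def living_count(self) -> int:
        return sum(self.viability.values())


def correct_illumination(
    image: FieldImage, sigma_px: float = 64.0, clip_percentile: float = 25.0
) -> FieldImage:
    """Remove the smooth illumination gradient from every channel.

    The background is a wide Gaussian low-pass of the image clipped at its
    ``clip_percentile`` so that bright foreground (somata, neurites) does
    not inflate the estimate and get over-subtracted around cells.  The
    estimate's minimum is retained, so a flat image passes through
    unchanged (idempotence on already-flat inputs) and the output stays
    non-negative.
    """
    corrected = {}
    for name, arr in image.channels.items():
        a = arr.astype(np.float64)
        lo = np.percentile(a, clip_percentile)
        clipped = np.minimum(a, lo)
        # estimate on an 8x downsampled copy: the background is smooth by
        # assumption, and the full-resolution Gaussian would dominate runtime
        ds = 8
        h, w = a.shape
        hp, wp = -h % ds, -w % ds
        small = np.pad(clipped, ((0, hp), (0, wp)), mode="edge")
        small = small.reshape(
            (h + hp) // ds, ds, (w + wp) // ds, ds
        ).mean(axis=(1, 3))
        bg_small = ndi.gaussian_filter(small, sigma=max(sigma_px / ds, 1.0))
        bg = np.repeat(np.repeat(bg_small, ds, axis=0), ds, axis=1)[:h, :w]
        out = a - (bg - bg.min())
        corrected[name] = np.clip(out, 0, None)
    return FieldImage(
        channels=corrected,
        pixel_pitch_um=image.pixel_pitch_um,
        well=image.well,
        field=image.field,
    )


def segment_nuclei(
    dna_channel: np.ndarray,
    threshold: float | None = None,
    min_size_px: int = 120,
    min_peak_distance_px: int = 12,
) -> np.ndarray:
    """Label nuclei: threshold (Otsu when None), then split touching
    components by a distance-transform watershed."""
    from skimage.feature import peak_local_max

    a = np.asarray(dna_channel, dtype=np.float64)
    if threshold is None:
        if np.ptp(a) == 0:
            return np.zeros(a.shape, dtype=np.int32)
        threshold = threshold_otsu(a)
    fg = a > threshold
    fg = remove_small_objects(fg, max_size=min_size_px - 1)
    if not fg.any():
        return np.zeros(a.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance_px, labels=ndi.label(fg)[0]
    )
    markers = np.zeros(a.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(fg)
        return labels.astype(np.int32)
    labels = watershed(-dist, markers, mask=fg)
    return labels.astype(np.int32)


def classify_viability(
    nucleus_labels: np.ndarray,
    dna_channel: np.ndarray,
    rule: ViabilityRule = ViabilityRule(),
) -> tuple[dict[int, bool], int]:
    """Apply the living-cell rule per nucleus label.

    Returns ({label: living}, living_count).  The rule is strict on both
    sides: area must exceed ``min_area_px`` and the mean must fall below
    ``max_mean_intensity``.
    """
    flags: dict[int, bool] = {}
    for p in regionprops(nucleus_labels, intensity_image=dna_channel):
        flags[p.label] = bool(
            p.area > rule.min_area_px
            and p.intensity_mean < rule.max_mean_intensity
        )
    return flags, sum(flags.values())


def segment_cells(
    map2_channel: np.ndarray,
    nucleus_labels: np.ndarray,
    viability: dict[int, bool],
    threshold: float | None = None,
    max_reach_px: float = 400.0,
    min_size_px: int = 20,
) -> np.ndarray:
    """Partition the MAP2-positive area among living nuclei.

    A seeded watershed on distance-from-nucleus floods each connected
    MAP2 component from the living nuclei it contains; components holding
    no living nucleus stay background, as do pixels beyond
    ``max_reach_px`` from every nucleus.  Apoptotic nuclei seed nothing,
    and pixels of any nucleus are never assigned to another cell.
    """
    a = np.asarray(map2_channel, dtype=np.float64)
    living = np.isin(nucleus_labels, [l for l, v in viability.items() if v])
    markers = np.where(living, nucleus_labels, 0).astype(np.int32)
    if markers.max() == 0:
        return np.zeros(a.shape, dtype=np.int32)
    if threshold is None:
        if np.ptp(a) == 0:
            return np.zeros(a.shape, dtype=np.int32)
        threshold = threshold_otsu(a)
    fg = a > threshold
    fg = remove_small_objects(fg, max_size=min_size_px - 1)
    mask = fg | living
    dist_to_nuc = ndi.distance_transform_edt(markers == 0)
    cells = watershed(dist_to_nuc, markers, mask=mask).astype(np.int32)
    cells[dist_to_nuc > max_reach_px] = 0
    # a nucleus pixel belongs to its own cell only
    other_nucleus = (nucleus_labels > 0) & (nucleus_labels != cells)
    cells[other_nucleus] = 0
    return cells


def derive_compartments(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    membrane_width_px: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Cytoplasm = cell minus nucleus; membrane = cell minus its
    ``membrane_width_px``-step erosion (3x3 cross), computed per label so
    rims also appear along shared watershed boundaries."""
    cytoplasm = np.where(
        (cell_labels > 0) & (nucleus_labels == cell_labels), 0, cell_labels
    ).astype(np.int32)
    membrane = np.zeros_like(cell_labels, dtype=np.int32)
    for p in regionprops(cell_labels):
        rmin, cmin, rmax, cmax = p.bbox
        box = cell_labels[rmin:rmax, cmin:cmax] == p.label
        interior = ndi.binary_erosion(
            box, structure=CROSS, iterations=membrane_width_px
        )
        rim = box & ~interior
        membrane[rmin:rmax, cmin:cmax][rim] = p.label
    return cytoplasm, membrane


def _skeleton_length_steps(skel: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Sum inter-pixel steps per cell label: 1 per 4-neighbour edge,
    sqrt(2) per diagonal edge, both endpoints on the skeleton and in the
    same cell."""
    out: dict[int, float] = {}
    lab = np.where(skel, labels, 0)
    h, w = lab.shape
    for (dr, dc), wgt in (
        ((0, 1), 1.0),
        ((1, 0), 1.0),
        ((1, 1), np.sqrt(2)),
        ((1, -1), np.sqrt(2)),
    ):
        a = lab[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        b = lab[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
        both = (a > 0) & (a == b)
        if both.any():
            vals, counts = np.unique(a[both], return_counts=True)
            for v, n in zip(vals, counts):
                out[int(v)] = out.get(int(v), 0.0) + wgt * n
    return out


def _prune_spurs(skel: np.ndarray, iterations: int) -> np.ndarray:
    """Iteratively delete endpoint pixels (<= 1 skeleton neighbour)."""
    kernel = np.ones((3, 3))
    s = skel.copy()
    for _ in range(iterations):
        nb = ndi.convolve(s.astype(np.uint8), kernel, mode="constant") - s
        endpoints = s & (nb <= 1)
        if not endpoints.any():
            break
        s = s & ~endpoints
    return s


def extract_neurites(
    map2_channel: np.ndarray,
    cell_labels: np.ndarray,
    pixel_pitch_um: float = PIXEL_PITCH_UM,
    soma_opening_radius_px: int = 8,
    spur_prune_iters: int = 5,
    soma_guard_px: int = 0,
    min_fragment_px: int = 8,
) -> tuple[np.ndarray, dict[int, float], dict[int, int]]:
    """Skeletonize the neurite network and attribute it to cells.

    The soma is the morphological opening of the cell mask with a disk of
    radius ``soma_opening_radius_px``; the remainder is thinned to a
    one-pixel skeleton.  Length counts inter-pixel steps (diagonals as
    sqrt(2)) scaled by the pixel pitch and is measured on the unpruned
    skeleton; branch points are junction clusters (>= 3 skeleton
    neighbours) counted after spur pruning.

    Returns (skeleton, {label: length_um}, {label: branch_points}); cells
    without neurites report 0 for both.
    """
    cellmask = cell_labels > 0
    if not cellmask.any():
        return np.zeros_like(cellmask, dtype=bool), {}, {}
    from skimage.morphology import isotropic_opening

    soma = isotropic_opening(cellmask, soma_opening_radius_px)
    if soma_guard_px:
        # a guard band around the soma suppresses ragged-boundary fragments
        # left by the opening on noisy masks
        soma = ndi.binary_dilation(soma, structure=disk(soma_guard_px))
    neurite_mask = cellmask & ~soma
    if min_fragment_px > 1:
        neurite_mask = remove_small_objects(neurite_mask, max_size=min_fragment_px - 1)
    skel = skeletonize(neurite_mask)

    lengths_steps = _skeleton_length_steps(skel, cell_labels)
    labels_present = [int(l) for l in np.unique(cell_labels) if l > 0]
    lengths = {l: lengths_steps.get(l, 0.0) * pixel_pitch_um for l in labels_present}

    pruned = _prune_spurs(skel, spur_prune_iters)
    nb = ndi.convolve(pruned.astype(np.uint8), np.ones((3, 3)), mode="constant") - pruned
    junctions = pruned & (nb >= 3)
    jl, nj = ndi.label(junctions, structure=np.ones((3, 3)))
    branch: dict[int, int] = {l: 0 for l in labels_present}
    for j in range(1, nj + 1):
        labs = cell_labels[jl == j]
        labs = labs[labs > 0]
        if labs.size:
            owner = int(np.bincount(labs).argmax())
            branch[owner] = branch.get(owner, 0) + 1
    return skel, lengths, branch


def segment_field(
    image: FieldImage,
    rule: ViabilityRule = ViabilityRule(),
    illumination_sigma_px: float = 64.0,
    dna_threshold: float | None = None,
    map2_threshold: float | None = None,
    membrane_width_px: int = 5,
    soma_opening_radius_px: int = 8,
) -> tuple[CompartmentMasks, FieldImage]:
    """Full per-field segmentation: illumination correction, nuclei,
    viability, cells, compartments and neurites.

    Returns the masks and the illumination-corrected image the masks were
    computed on (features should use the same corrected intensities).
    """
    corr = correct_illumination(image, sigma_px=illumination_sigma_px)
    nuclei = segment_nuclei(corr.channels["DNA"], threshold=dna_threshold)
    viability, _ = classify_viability(nuclei, corr.channels["DNA"], rule)
    cells = segment_cells(
        corr.channels["MAP2"], nuclei, viability, threshold=map2_threshold
    )
    cytoplasm, membrane = derive_compartments(
        cells, nuclei, membrane_width_px=membrane_width_px
    )
    skel, lengths, branches = extract_neurites(
        corr.channels["MAP2"],
        cells,
        pixel_pitch_um=image.pixel_pitch_um,
        soma_opening_radius_px=soma_opening_radius_px,
    )
    masks = CompartmentMasks(
        nucleus_labels=nuclei,
        cell_labels=cells,
        cytoplasm_labels=cytoplasm,
        membrane_labels=membrane,
        neurite_skeleton=skel,
        viability=viability,
        neurite_length_um=lengths,
        branch_points=branches,
    )
    return masks, corr
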