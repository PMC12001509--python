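"""Synthetic two-channel microscopy scenes with ground truth.

Each scene holds non-overlapping model cells on a dark background. A cell
is a 2D disk with, from the centre outwards:

* a nucleus disk (painted only in the nuclei channel),
* a perinuclear halo annulus (signal channel),
* a cytoplasm annulus (signal channel),
* a membrane annulus broken by random angular gaps (signal channel),
  painted at ``cytoplasm_intensity * membrane_enrichment``.

All intensities are painted as exact constants before noise, so in a
noise-free scene the ratio of the membrane-annulus mean to the cytoplasm
mean equals the configured enrichment, per cell and exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SceneSpec",
    "ConditionPreset",
    "GroundTruth",
    "generate_scene",
    "generate_condition_set",
    "default_presets",
]

#: Default pixel size of the emulated acquisition, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.082

# Margin (px) kept between neighbouring cell disks and the image border.
_PLACEMENT_MARGIN = 2
# Rejection-sampling budget per requested cell.
_ATTEMPTS_PER_CELL = 200


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic scene."""

    image_height_px: int = 512
    image_width_px: int = 512
    n_cells: int = 12
    cell_radius_px: tuple[float, float] = (38.0, 48.0)
    nucleus_radius_fraction: float = 0.42
    membrane_thickness_px: int = 3
    cytoplasm_intensity: float = 1000.0
    membrane_enrichment: float = 1.5
    perinuclear_intensity: float = 1800.0
    nuclei_channel_intensity: float = 3000.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    bit_depth: int = 16
    seed: int = 0
    # geometry details of the painted artefacts (not exposed per-condition)
    halo_thickness_px: int = 5
    n_membrane_gaps: int = 3
    gap_angle_deg: tuple[float, float] = (12.0, 30.0)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        lo, hi = self.cell_radius_px
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError(f"invalid cell radius range {self.cell_radius_px!r}")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError(
                "nucleus_radius_fraction must lie in (0, 1), got "
                f"{self.nucleus_radius_fraction}"
            )
        if self.membrane_thickness_px <= 0:
            raise ValueError("membrane_thickness_px must be positive")
        if self.halo_thickness_px < 0:
            raise ValueError("halo_thickness_px must be non-negative")
        # nucleus + halo + membrane must fit inside the smallest cell
        min_radius = lo
        nucleus = min_radius * self.nucleus_radius_fraction
        if nucleus + self.halo_thickness_px + self.membrane_thickness_px >= min_radius:
            raise ValueError(
                "impossible geometry: nucleus + halo + membrane do not fit "
                f"inside a cell of radius {min_radius}"
            )
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.cytoplasm_intensity <= 0 or self.membrane_enrichment <= 0:
            raise ValueError("intensities and enrichment must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition, as a multiplier on membrane enrichment."""

    condition_label: str
    enrichment_multiplier: float

    def __post_init__(self) -> None:
        if self.enrichment_multiplier <= 0:
            raise ValueError("enrichment_multiplier must be positive")


def default_presets() -> list[ConditionPreset]:
    """Condition presets whose multipliers mirror the study design
    (control plus three treatments with ~1.33-1.35x membrane enrichment)."""
    return [
        ConditionPreset("CTRL", 1.0),
        ConditionPreset("FK", 1.347),
        ConditionPreset("TH", 1.331),
        ConditionPreset("FK+TH", 1.331),
    ]


@dataclass
class GroundTruth:
    """Per-scene truth used to validate the analysis pipeline.

    Label maps use 0 for background and the (1-based) cell index for
    painted pixels; nucleus, halo and membrane supports are pairwise
    disjoint by construction.
    """

    nucleus_labels: np.ndarray
    halo_labels: np.ndarray
    membrane_labels: np.ndarray
    cell_table: pd.DataFrame
    n_requested: int = 0
    n_placed: int = 0

    def __post_init__(self) -> None:
        overlap = (self.nucleus_labels > 0) & (self.membrane_labels > 0)
        if overlap.any():
            raise AssertionError("nucleus and membrane supports overlap")


_CELL_COLUMNS = [
    "cell",
    "center_row",
    "center_col",
    "cell_radius_px",
    "nucleus_radius_px",
    "cytoplasm_value",
    "membrane_value",
    "enrichment",
]


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centres and radii."""
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = _ATTEMPTS_PER_CELL * max(spec.n_cells, 1)
    lo, hi = spec.cell_radius_px
    while len(centers) < spec.n_cells and attempts > 0:
        attempts -= 1
        r = rng.uniform(lo, hi)
        margin = r + _PLACEMENT_MARGIN
        if (
            spec.image_height_px <= 2 * margin
            or spec.image_width_px <= 2 * margin
        ):
            break
        cy = rng.uniform(margin, spec.image_height_px - margin)
        cx = rng.uniform(margin, spec.image_width_px - margin)
        ok = all(
            np.hypot(cy - oy, cx - ox) > r + orad + _PLACEMENT_MARGIN
            for (oy, ox), orad in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def _paint_cell(
    spec: SceneSpec,
    rng: np.random.Generator,
    idx: int,
    center: tuple[float, float],
    radius: float,
    nuclei: np.ndarray,
    signal: np.ndarray,
    gt_nuc: np.ndarray,
    gt_halo: np.ndarray,
    gt_mem: np.ndarray,
) -> dict:
    cy, cx = center
    r_nuc = radius * spec.nucleus_radius_fraction
    r_halo = r_nuc + spec.halo_thickness_px
    r_mem_in = radius - spec.membrane_thickness_px

    # local window around the disk
    r0 = max(int(np.floor(cy - radius)) - 1, 0)
    r1 = min(int(np.ceil(cy + radius)) + 2, spec.image_height_px)
    c0 = max(int(np.floor(cx - radius)) - 1, 0)
    c1 = min(int(np.ceil(cx + radius)) + 2, spec.image_width_px)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rows - cy, cols - cx)

    in_nucleus = dist <= r_nuc
    in_halo = (dist > r_nuc) & (dist <= r_halo)
    in_cyto = (dist > r_halo) & (dist <= r_mem_in)
    in_ring = (dist > r_mem_in) & (dist <= radius)

    # random angular gaps break the ring into open fragments
    angle = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
    gap_mask = np.zeros_like(angle, dtype=bool)
    for _ in range(spec.n_membrane_gaps):
        start = rng.uniform(0.0, 360.0)
        width = rng.uniform(*spec.gap_angle_deg)
        stop = (start + width) % 360.0
        if start <= stop:
            gap_mask |= (angle >= start) & (angle < stop)
        else:
            gap_mask |= (angle >= start) | (angle < stop)
    in_membrane = in_ring & ~gap_mask
    in_gap = in_ring & gap_mask

    membrane_value = spec.cytoplasm_intensity * spec.membrane_enrichment

    nuc_win = nuclei[r0:r1, c0:c1]
    sig_win = signal[r0:r1, c0:c1]
    nuc_win[in_nucleus] = spec.nuclei_channel_intensity
    sig_win[in_halo] = spec.perinuclear_intensity
    sig_win[in_cyto | in_gap] = spec.cytoplasm_intensity
    sig_win[in_membrane] = membrane_value

    gt_nuc[r0:r1, c0:c1][in_nucleus] = idx
    gt_halo[r0:r1, c0:c1][in_halo] = idx
    gt_mem[r0:r1, c0:c1][in_membrane] = idx

    return {
        "cell": idx,
        "center_row": cy,
        "center_col": cx,
        "cell_radius_px": radius,
        "nucleus_radius_px": r_nuc,
        "cytoplasm_value": spec.cytoplasm_intensity,
        "membrane_value": membrane_value,
        "enrichment": spec.membrane_enrichment,
    }


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene.

    Returns
    -------
    image : uint8/uint16 array, shape ``(2, H, W)``
        Channel 0 is the nuclei channel, channel 1 the signal channel.
    truth : GroundTruth
        Label maps for nucleus, perinuclear halo and membrane supports,
        plus the per-cell table of painted values.

    Identical ``spec`` (including seed) yields a bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    nuclei = np.zeros(shape, dtype=np.float64)
    signal = np.zeros(shape, dtype=np.float64)
    gt_nuc = np.zeros(shape, dtype=np.uint16)
    gt_halo = np.zeros(shape, dtype=np.uint16)
    gt_mem = np.zeros(shape, dtype=np.uint16)

    centers, radii = _place_cells(spec, rng)
    records = [
        _paint_cell(spec, rng, i + 1, c, r, nuclei, signal, gt_nuc, gt_halo, gt_mem)
        for i, (c, r) in enumerate(zip(centers, radii))
    ]
    cell_table = pd.DataFrame(records, columns=_CELL_COLUMNS)

    channels = []
    for plane in (nuclei, signal):
        noisy = plane
        if spec.poisson_noise:
            noisy = rng.poisson(noisy).astype(np.float64)
        if spec.gaussian_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.gaussian_noise_sd, size=shape)
        noisy = np.clip(np.rint(noisy), 0, spec.max_value)
        channels.append(noisy)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = np.stack(channels).astype(dtype)

    truth = GroundTruth(
        nucleus_labels=gt_nuc,
        halo_labels=gt_halo,
        membrane_labels=gt_mem,
        cell_table=cell_table,
        n_requested=spec.n_cells,
        n_placed=len(records),
    )
    return image, truth


def _derive_seed(base_seed: int, condition_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), condition_index, replicate])
    return int(ss.generate_state(1)[0])


def generate_condition_set(
    base: SceneSpec,
    presets: Sequence[ConditionPreset],
    images_per_condition: int,
    outdir: str | Path,
    write_ground_truth: bool = True,
) -> pd.DataFrame:
    """Render ``images_per_condition`` scenes per condition preset.

    Writes one two-page TIFF per scene (pages: nuclei, signal), optional
    ground-truth label TIFFs and per-cell CSVs, and ``manifest.csv``
    mapping file -> condition -> replicate -> seed. Seeds derive
    deterministically from ``base.seed`` and the condition/replicate
    indices, so a rerun reproduces every image byte for byte.
    """
    labels = [p.condition_label for p in presets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels in presets: {labels}")
    n_control = sum(1 for p in presets if p.enrichment_multiplier == 1.0)
    if n_control != 1:
        raise ValueError(
            "exactly one preset must have enrichment_multiplier == 1 "
            f"(the control); found {n_control}"
        )
    if images_per_condition <= 0:
        raise ValueError("images_per_condition must be positive")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, preset in enumerate(presets):
        for rep in range(images_per_condition):
            seed = _derive_seed(base.seed, ci, rep)
            spec = replace(
                base,
                membrane_enrichment=base.membrane_enrichment
                * preset.enrichment_multiplier,
                seed=seed,
            )
            image, truth = generate_scene(spec)
            safe = preset.condition_label.replace("+", "p").replace(" ", "_")
            stem = f"scene_{safe}_{rep:02d}"
            path = outdir / f"{stem}.tif"
            tifffile.imwrite(path, image, photometric="minisblack")
            if write_ground_truth:
                tifffile.imwrite(
                    outdir / f"{stem}_gt.tif",
                    np.stack(
                        [truth.nucleus_labels, truth.halo_labels, truth.membrane_labels]
                    ),
                    photometric="minisblack",
                )
                truth.cell_table.to_csv(outdir / f"{stem}_cells.csv", index=False)
            rows.append(
                {
                    "file": path.name,
                    "condition": preset.condition_label,
                    "replicate": rep,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["file", "condition", "replicate", "seed"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
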