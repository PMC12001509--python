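"""Image and table I/O, run configuration and logging.

Conventions fixed here and relied on everywhere else:

* pixel coordinates are 0-based, row-major ``(row, column)``;
* channels are identified by configured order (default: page 0 nuclei,
  page 1 signal), never by wavelength metadata;
* every file write is atomic (temp file + rename) so an interrupted run
  never leaves a truncated table or image behind.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("perimem")

__all__ = [
    "ImageChannel",
    "RunConfig",
    "read_scene",
    "write_scene",
    "export_measurements",
    "atomic_write_bytes",
    "atomic_write_dataframe",
    "load_config",
    "log_config",
]

MEASUREMENT_COLUMNS = [
    "image_id",
    "condition",
    "label",
    "area_px",
    "perimeter_px",
    "circularity",
    "upq_intensity",
    "upq_normalized",
]


@dataclass(frozen=True)
class ImageChannel:
    """One 2D channel plus the metadata the pipeline needs."""

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    role: str  # "nuclei" or "signal"

    def __post_init__(self) -> None:
        if self.role not in ("nuclei", "signal"):
            raise ValueError(f"unknown channel role {self.role!r}")
        px = self.pixels
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if px.size and int(px.max()) >= 2**self.bit_depth:
            raise ValueError(
                f"pixel value {int(px.max())} exceeds bit depth {self.bit_depth}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class RunConfig:
    """All tunable parameters of one analysis run.

    The segmentation cut-offs are deliberate, documented choices — the
    original acquisition parameters were applied consistently across
    conditions but their numeric values are not fixed by any contract,
    so everything here can be overridden from a config file or the CLI.
    """

    # segmentation
    nuclei_min_area_px: int = 100
    expansion_distance_px: float = 10.0  # ~0.8 um at 0.082 um/px
    threshold_method: str = "multiotsu"  # multiotsu | otsu | fixed | quantile
    threshold_value: float | None = None  # for "fixed"
    threshold_quantile: float = 0.98  # for "quantile"
    fragment_area_min_px: int = 50
    fragment_area_max_px: int = 50000
    circularity_max: float = 0.3
    # statistics
    alpha: float = 0.05
    adjustment: str = "bonferroni"  # bonferroni | holm
    control_label: str = "CTRL"
    # io
    channel_order: tuple[str, str] = ("nuclei", "signal")
    bit_depth: int = 16
    pixel_size_um: float = 0.082
    output_dir: str = "perimem_out"
    write_xlsx: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fragment_area_min_px < self.fragment_area_max_px:
            raise ValueError("fragment area range must satisfy min < max")
        if not 0 < self.circularity_max <= 1:
            raise ValueError("circularity_max must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.expansion_distance_px < 0:
            raise ValueError("expansion_distance_px must be non-negative")
        if sorted(self.channel_order) != ["nuclei", "signal"]:
            raise ValueError("channel_order must name 'nuclei' and 'signal'")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    File keys mirror the RunConfig field names; unknown keys are an error
    (they are almost always typos of real parameters).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "channel_order" in data:
        data["channel_order"] = tuple(data["channel_order"])
    return RunConfig(**data)


def log_config(config: RunConfig) -> None:
    """Record every configured parameter at run start (reproducibility)."""
    for f in dataclasses.fields(config):
        logger.info("config %s = %r", f.name, getattr(config, f.name))


# ---------------------------------------------------------------------------
# atomic writes


def atomic_write_bytes(path: str | Path, payload: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_dataframe(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees binary round-trip of float64 through the CSV
    atomic_write_bytes(
        path, df.to_csv(index=False, float_format="%.17g").encode("utf-8")
    )


# ---------------------------------------------------------------------------
# images


def read_scene(
    path: str | Path, config: RunConfig | None = None
) -> list[ImageChannel]:
    """Read a two-channel TIFF into tagged channels.

    Channels are assigned roles by the configured page order. Bit depth
    comes from the array dtype and must match the configured depth.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scene file not found: {path}")
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types for bad files
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    if stack.ndim == 2:
        raise ValueError(f"{path} has a single channel; two are required")
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(
            f"{path} has unexpected shape {stack.shape}; expected (>=2, H, W)"
        )
    bit_depth = stack.dtype.itemsize * 8
    if bit_depth != config.bit_depth:
        raise ValueError(
            f"{path}: bit depth {bit_depth} does not match configured "
            f"{config.bit_depth}"
        )
    return [
        ImageChannel(
            pixels=stack[i],
            bit_depth=bit_depth,
            pixel_size_um=config.pixel_size_um,
            role=role,
        )
        for i, role in enumerate(config.channel_order)
    ]


def write_scene(path: str | Path, image: np.ndarray) -> None:
    """Write a (2, H, W) stack as a multi-page TIFF, atomically."""
    import io

    buf = io.BytesIO()
    tifffile.imwrite(buf, image, photometric="minisblack")
    atomic_write_bytes(path, buf.getvalue())


# ---------------------------------------------------------------------------
# measurement export


def export_measurements(
    records: Iterable | pd.DataFrame,
    path: str | Path,
    allow_empty: bool = False,
    write_xlsx: bool = False,
) -> pd.DataFrame:
    """Write one row per retained fragment to CSV (canonical) and
    optionally to a spreadsheet next to it.

    ``records`` may be a DataFrame or an iterable of FragmentRecord-like
    objects (anything dataclasses.asdict accepts).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if df.empty and not allow_empty:
        raise ValueError(
            "no fragment records to export (pass allow_empty=True to write "
            "a header-only table)"
        )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    df = df[MEASUREMENT_COLUMNS]
    atomic_write_dataframe(df, path)
    if write_xlsx:
        xlsx = Path(path).with_suffix(".xlsx")
        df.to_excel(xlsx, index=False)
    logger.info("wrote %d fragment rows to %s", len(df), path)
    return df
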