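"""Per-fragment intensity scoring and condition-level summaries.

The per-object score is the upper-quartile (75th percentile) pixel
intensity, which is far less sensitive to background pixels and outliers
than the mean. Scores are pooled across images per condition, divided by
the control condition's median (so the control median is exactly 1), and
summarised as median + IQR for violin plots.

Percentile convention, used for both the per-object score and the IQR:
linear interpolation between order statistics at rank ``q * (n - 1)``
(0-based). This is numpy's default and is applied uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import LabelMap

logger = logging.getLogger("perimem")

__all__ = [
    "FragmentRecord",
    "ConditionTable",
    "SummaryStats",
    "upper_quartile_intensity",
    "measure_fragments",
    "pool_measurements",
    "normalize_to_control",
    "summarize",
    "violin_plot",
]


@dataclass
class FragmentRecord:
    """One retained membrane fragment and its measurements."""

    image_id: str
    condition: str
    label: int
    area_px: int
    perimeter_px: float
    circularity: float
    upq_intensity: float
    upq_normalized: float = float("nan")

    def __post_init__(self) -> None:
        if self.upq_intensity < 0:
            raise ValueError("upq_intensity must be non-negative")


@dataclass
class ConditionTable:
    """Fragment records pooled per condition."""

    records: dict[str, list[FragmentRecord]]
    control_label: str

    def __post_init__(self) -> None:
        if self.control_label not in self.records:
            raise ValueError(
                f"control condition {self.control_label!r} absent from table "
                f"(have {sorted(self.records)})"
            )

    @property
    def n_per_condition(self) -> dict[str, int]:
        return {c: len(rs) for c, rs in self.records.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": r.image_id,
                "condition": r.condition,
                "label": r.label,
                "area_px": r.area_px,
                "perimeter_px": r.perimeter_px,
                "circularity": r.circularity,
                "upq_intensity": r.upq_intensity,
                "upq_normalized": r.upq_normalized,
            }
            for recs in self.records.values()
            for r in recs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "image_id",
                "condition",
                "label",
                "area_px",
                "perimeter_px",
                "circularity",
                "upq_intensity",
                "upq_normalized",
            ],
        )


@dataclass(frozen=True)
class SummaryStats:
    condition: str
    median: float
    q25: float
    q75: float
    n: int


def upper_quartile_intensity(pixel_values) -> float:
    """75th-percentile pixel intensity of one object.

    Linear interpolation between order statistics; permutation-invariant.
    """
    values = np.asarray(pixel_values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("upper_quartile_intensity requires a non-empty input")
    return float(np.percentile(values, 75))


def measure_fragments(
    signal_pixels: np.ndarray,
    fragments: LabelMap,
    shape_table: pd.DataFrame,
    image_id: str,
    condition: str,
) -> list[FragmentRecord]:
    """Score every retained fragment of one image with its UpQ intensity."""
    shapes = shape_table.set_index("label")
    out = []
    for label in range(1, fragments.n_objects + 1):
        mask = fragments.labels == label
        upq = upper_quartile_intensity(np.asarray(signal_pixels)[mask])
        s = shapes.loc[label]
        out.append(
            FragmentRecord(
                image_id=image_id,
                condition=condition,
                label=label,
                area_px=int(s["area_px"]),
                perimeter_px=float(s["perimeter_px"]),
                circularity=float(s["circularity"]),
                upq_intensity=upq,
            )
        )
    return out


def pool_measurements(
    per_image_records: list[FragmentRecord],
    manifest: pd.DataFrame,
    control_label: str,
) -> ConditionTable:
    """Group fragment records by condition using the image manifest.

    Every condition present in the manifest appears in the table, even
    with zero fragments (a warning is logged); a record whose image_id is
    not in the manifest is an error.
    """
    known = set(manifest["file"].astype(str))
    by_condition: dict[str, list[FragmentRecord]] = {
        c: [] for c in manifest["condition"].astype(str).unique()
    }
    cond_of = dict(
        zip(manifest["file"].astype(str), manifest["condition"].astype(str))
    )
    for rec in per_image_records:
        if rec.image_id not in known:
            raise ValueError(f"record references unknown image_id {rec.image_id!r}")
        cond = cond_of[rec.image_id]
        if rec.condition and rec.condition != cond:
            raise ValueError(
                f"record condition {rec.condition!r} disagrees with manifest "
                f"({cond!r}) for image {rec.image_id!r}"
            )
        by_condition[cond].append(replace(rec, condition=cond))
    # deterministic, input-order-independent layout
    for cond, recs in by_condition.items():
        recs.sort(key=lambda r: (r.image_id, r.label))
        if not recs:
            logger.warning("condition %r has zero fragments", cond)
    return ConditionTable(records=by_condition, control_label=control_label)


def normalize_to_control(table: ConditionTable) -> ConditionTable:
    """Divide every UpQ score by the control condition's raw median.

    After this, the control condition's median normalized score is
    exactly 1; applying the function twice is the identity on already
    normalized values (scale invariance).
    """
    control = table.records[table.control_label]
    if not control:
        raise ValueError(
            f"control condition {table.control_label!r} has no records"
        )
    ref = float(np.median([r.upq_intensity for r in control]))
    if ref <= 0 or not np.isfinite(ref):
        raise ValueError(f"control median {ref} is unusable for normalization")
    records = {
        cond: [replace(r, upq_normalized=r.upq_intensity / ref) for r in recs]
        for cond, recs in table.records.items()
    }
    return ConditionTable(records=records, control_label=table.control_label)


def _percentiles(values: np.ndarray) -> tuple[float, float, float]:
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)


def summarize(table: ConditionTable, normalized: bool = True) -> list[SummaryStats]:
    """Median and 25-75% IQR per condition, for the violin plots."""
    out = []
    for cond in table.records:
        recs = table.records[cond]
        if not recs:
            out.append(SummaryStats(cond, float("nan"), float("nan"), float("nan"), 0))
            continue
        values = np.array(
            [r.upq_normalized if normalized else r.upq_intensity for r in recs]
        )
        med, q25, q75 = _percentiles(values)
        out.append(SummaryStats(cond, med, q25, q75, len(recs)))
    return out


def violin_plot(
    table: ConditionTable,
    path: str | Path,
    normalized: bool = True,
    order: list[str] | None = None,
):
    """Violin plot of per-fragment scores per condition, with median and
    IQR overlaid; written to ``path`` (format from the suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    df = table.to_dataframe()
    column = "upq_normalized" if normalized else "upq_intensity"
    order = order or list(table.records)
    fig, ax = plt.subplots(figsize=(1.6 * max(len(order), 2) + 1, 4))
    sns.violinplot(
        data=df, x="condition", y=column, order=order, inner="quartile",
        cut=0, ax=ax,
    )
    ax.set_ylabel(
        "normalized UpQ intensity (fold of control median)"
        if normalized
        else "UpQ intensity (counts)"
    )
    ax.set_xlabel("")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
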