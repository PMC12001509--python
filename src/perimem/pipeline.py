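"""End-to-end orchestration: images -> segmentation -> quantification ->
group statistics -> report files.

Both entry points are deterministic for a fixed config: the synthetic
path derives every image seed from the config seed, and the analysis
itself is seed-free. Stage products (images, raw measurements) are
cached on disk with an input hash, so rerunning a pipeline whose inputs
did not change reuses the earlier artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import group_stats, imaging_io, quantification, scene_synth, segmentation
from .imaging_io import RunConfig, atomic_write_bytes, atomic_write_dataframe

logger = logging.getLogger("perimem")

__all__ = [
    "PipelineError",
    "RunReport",
    "analyze_image",
    "segment_manifest",
    "quantify_and_test",
    "run_ingest_experiment",
    "run_synthetic_experiment",
]


class PipelineError(RuntimeError):
    """Raised with the failing stage name so the CLI can tag its exit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    config: dict
    image_counts: pd.DataFrame  # image_id, condition, nuclei, candidates, retained
    summaries: list[quantification.SummaryStats]
    kw: group_stats.KWResult | None
    comparisons: list[group_stats.DunnComparison]
    output_paths: dict[str, Path]

    def __post_init__(self) -> None:
        bad = self.image_counts[
            self.image_counts["retained"] > self.image_counts["candidates"]
        ]
        if len(bad):
            raise AssertionError("retained fragments exceed candidates")
        missing = [str(p) for p in self.output_paths.values() if not Path(p).exists()]
        if missing:
            raise AssertionError(f"declared outputs missing: {missing}")


def _hash_obj(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, (bytes, bytearray)):
            h.update(part)
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _cache_valid(stamp: Path, digest: str, outputs: Sequence[Path]) -> bool:
    return (
        stamp.exists()
        and stamp.read_text().strip() == digest
        and all(p.exists() for p in outputs)
    )


def analyze_image(
    channels: list[imaging_io.ImageChannel],
    image_id: str,
    condition: str,
    config: RunConfig,
) -> tuple[list[quantification.FragmentRecord], dict]:
    """Segment and score one image; returns records plus object counts."""
    by_role = {c.role: c for c in channels}
    nuclei = segmentation.segment_nuclei(by_role["nuclei"], config.nuclei_min_area_px)
    exclusion = segmentation.build_exclusion_mask(
        nuclei, config.expansion_distance_px
    )
    candidates = segmentation.detect_membrane_fragments(
        by_role["signal"],
        exclusion,
        threshold_method=config.threshold_method,
        threshold_value=config.threshold_value,
        threshold_quantile=config.threshold_quantile,
    )
    shapes = segmentation.measure_all_shapes(candidates)
    retained, _ = segmentation.filter_fragments(
        candidates,
        shapes,
        area_range=(config.fragment_area_min_px, config.fragment_area_max_px),
        circularity_max=config.circularity_max,
    )
    retained_shapes = segmentation.measure_all_shapes(retained)
    records = quantification.measure_fragments(
        by_role["signal"].pixels, retained, retained_shapes, image_id, condition
    )
    counts = {
        "image_id": image_id,
        "condition": condition,
        "nuclei": nuclei.n_objects,
        "candidates": candidates.n_objects,
        "retained": retained.n_objects,
    }
    return records, counts


def _validate_manifest(manifest: pd.DataFrame, config: RunConfig, root: Path):
    if manifest.empty:
        raise PipelineError("validate", "manifest is empty")
    required = {"file", "condition"}
    if not required <= set(manifest.columns):
        raise PipelineError(
            "validate", f"manifest lacks columns {sorted(required - set(manifest.columns))}"
        )
    conditions = set(manifest["condition"].astype(str))
    if config.control_label not in conditions:
        raise PipelineError(
            "validate",
            f"control condition {config.control_label!r} absent from manifest "
            f"(conditions: {sorted(conditions)})",
        )
    for fname in manifest["file"].astype(str):
        if not (root / fname).exists():
            raise PipelineError("validate", f"image file missing: {root / fname}")


def segment_manifest(
    manifest: pd.DataFrame, config: RunConfig, image_root: Path, outdir: Path
) -> tuple[list[quantification.FragmentRecord], pd.DataFrame]:
    """Run segmentation + scoring over every manifest image, with an
    input-hash cache on the raw measurement table."""
    raw_path = outdir / "measurements_raw.csv"
    counts_path = outdir / "image_counts.csv"
    stamp = outdir / "segment.hash"
    file_hashes = [
        hashlib.sha256((image_root / f).read_bytes()).hexdigest()
        for f in manifest["file"].astype(str)
    ]
    digest = _hash_obj(dataclasses.asdict(config), manifest.to_dict("list"), file_hashes)
    if _cache_valid(stamp, digest, [raw_path, counts_path]):
        logger.info("segment stage cache hit; reusing %s", raw_path)
        df = pd.read_csv(raw_path)
        records = [
            quantification.FragmentRecord(
                image_id=str(r.image_id),
                condition=str(r.condition),
                label=int(r.label),
                area_px=int(r.area_px),
                perimeter_px=float(r.perimeter_px),
                circularity=float(r.circularity),
                upq_intensity=float(r.upq_intensity),
            )
            for r in df.itertuples()
        ]
        return records, pd.read_csv(counts_path)

    records: list[quantification.FragmentRecord] = []
    count_rows = []
    for row in manifest.itertuples():
        path = image_root / str(row.file)
        try:
            channels = imaging_io.read_scene(path, config)
            recs, counts = analyze_image(
                channels, str(row.file), str(row.condition), config
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("segment", f"{path}: {exc}") from exc
        records.extend(recs)
        count_rows.append(counts)
    counts_df = pd.DataFrame(
        count_rows,
        columns=["image_id", "condition", "nuclei", "candidates", "retained"],
    )
    imaging_io.export_measurements(records, raw_path, allow_empty=True)
    atomic_write_dataframe(counts_df, counts_path)
    atomic_write_bytes(stamp, digest.encode())
    return records, counts_df


def quantify_and_test(
    records: list[quantification.FragmentRecord],
    manifest: pd.DataFrame,
    config: RunConfig,
    outdir: Path,
) -> tuple[
    quantification.ConditionTable,
    list[quantification.SummaryStats],
    group_stats.KWResult | None,
    list[group_stats.DunnComparison],
    dict[str, Path],
]:
    try:
        table = quantification.pool_measurements(
            records, manifest, config.control_label
        )
        table = quantification.normalize_to_control(table)
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    summaries = quantification.summarize(table)

    paths: dict[str, Path] = {}
    measurements_path = outdir / "measurements.csv"
    imaging_io.export_measurements(
        table.to_dataframe(), measurements_path, allow_empty=True,
        write_xlsx=config.write_xlsx,
    )
    paths["measurements"] = measurements_path

    summary_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries],
        columns=["condition", "median", "q25", "q75", "n"],
    )
    summary_path = outdir / "summary.csv"
    atomic_write_dataframe(summary_df, summary_path)
    paths["summary"] = summary_path

    groups = {
        cond: [r.upq_normalized for r in recs]
        for cond, recs in table.records.items()
        if recs
    }
    kw = None
    comparisons: list[group_stats.DunnComparison] = []
    if len(groups) >= 2:
        try:
            kw = group_stats.kruskal_wallis(list(groups.values()))
            comparisons = group_stats.dunn_many_to_one(
                groups, config.control_label, adjustment=config.adjustment
            )
        except Exception as exc:
            raise PipelineError("stats", str(exc)) from exc
        stats_path = outdir / "stats.csv"
        group_stats.write_stats_report(kw, comparisons, stats_path)
        paths["stats"] = stats_path

    violin_path = outdir / "violin.png"
    try:
        quantification.violin_plot(table, violin_path, order=list(table.records))
        paths["violin"] = violin_path
    except Exception as exc:  # plotting must not sink an analysis run
        logger.warning("violin plot failed: %s", exc)
    return table, summaries, kw, comparisons, paths


def run_ingest_experiment(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig,
    image_root: str | Path | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Analyze existing TIFFs listed in a manifest (file, condition[,
    replicate, seed])."""
    imaging_io.log_config(config)
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        if image_root is None:
            image_root = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    if image_root is None:
        raise PipelineError("validate", "image_root required with an in-memory manifest")
    image_root = Path(image_root)
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    _validate_manifest(manifest, config, image_root)
    records, counts_df = segment_manifest(manifest, config, image_root, outdir)
    table, summaries, kw, comparisons, paths = quantify_and_test(
        records, manifest, config, outdir
    )
    paths["image_counts"] = outdir / "image_counts.csv"
    if not paths["image_counts"].exists():
        atomic_write_dataframe(counts_df, paths["image_counts"])
    return RunReport(
        config=dataclasses.asdict(config),
        image_counts=counts_df,
        summaries=summaries,
        kw=kw,
        comparisons=comparisons,
        output_paths=paths,
    )


def run_synthetic_experiment(
    config: RunConfig,
    base_spec: scene_synth.SceneSpec | None = None,
    presets: Sequence[scene_synth.ConditionPreset] | None = None,
    images_per_condition: int = 3,
    outdir: str | Path | None = None,
) -> RunReport:
    """Synthesize a condition set and push it through the full analysis."""
    presets = list(presets) if presets is not None else scene_synth.default_presets()
    labels = {p.condition_label for p in presets}
    if config.control_label not in labels:
        raise PipelineError(
            "validate",
            f"control condition {config.control_label!r} not among presets "
            f"{sorted(labels)}",
        )
    base_spec = base_spec or scene_synth.SceneSpec(seed=config.seed)
    outdir = Path(outdir if outdir is not None else config.output_dir)
    image_dir = outdir / "images"
    image_dir.mkdir(parents=True, exist_ok=True)

    stamp = image_dir / "simulate.hash"
    digest = _hash_obj(
        dataclasses.asdict(base_spec),
        [dataclasses.asdict(p) for p in presets],
        images_per_condition,
    )
    manifest_path = image_dir / "manifest.csv"
    if _cache_valid(stamp, digest, [manifest_path]):
        logger.info("simulate stage cache hit; reusing %s", image_dir)
        manifest = pd.read_csv(manifest_path)
    else:
        try:
            manifest = scene_synth.generate_condition_set(
                base_spec, presets, images_per_condition, image_dir
            )
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        atomic_write_bytes(stamp, digest.encode())
    return run_ingest_experiment(manifest, config, image_root=image_dir, outdir=outdir)
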