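"""One-command orchestration of the full counting workflow.

Per region: locate the region mask, draw the counting subvolumes, then for
each subvolume crop the intensity volume (with a physical pad so objects
straddling the window are segmented whole), classify voxels, split
instances by watershed, apply the volume filter under the centroid-in-window
counting rule, and summarize densities. Subvolumes are processed
independently in plan order; the run is fully deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io
from .classify import compute_features, predict
from .counting import (
    DensitySummary,
    SubvolumeCount,
    VolumeFilterParams,
    derive_filter_params,
    summarize_region,
    volume_filter_count,
)
from .instances import InstanceLabels, watershed_split
from .sampling import Subvolume, region_mask, region_volume, sample_subvolumes
from .types import ClassifierModel, RegionLabelMap, VolumeImage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_region_count", "run_from_config", "segment_volume"]

DEFAULT_PAD_UM = 10.0


def segment_volume(
    volume: VolumeImage,
    model: ClassifierModel,
    prob_threshold: float = 0.5,
    connectivity: int = 26,
) -> InstanceLabels:
    """Classify a whole volume and split the foreground into instances."""
    scales = tuple(model.fingerprint.get("scales_um", ()))
    features = compute_features(volume, scales_um=scales)
    prob = predict(model, features, threshold=prob_threshold)
    return watershed_split(prob.mask, volume.spacing, connectivity=connectivity)


def _padded_crop(volume: VolumeImage, sub: Subvolume, pad_um: float) -> tuple[VolumeImage, Subvolume]:
    """Crop a subvolume with a physical pad (clamped to the grid); returns
    the crop plus the counting window re-expressed in crop coordinates."""
    pad_vox = [int(np.ceil(pad_um / s)) for s in volume.spacing]
    lo = [max(0, o - p) for o, p in zip(sub.origin, pad_vox)]
    hi = [
        min(n, o + e + p)
        for n, o, e, p in zip(volume.data.shape, sub.origin, sub.extent, pad_vox)
    ]
    crop = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    window = Subvolume(
        origin=tuple(o - l for o, l in zip(sub.origin, lo)),
        extent=sub.extent,
        spacing=sub.spacing,
        region_id=sub.region_id,
    )
    return VolumeImage(data=crop, spacing=volume.spacing), window


def count_subvolumes(
    volume: VolumeImage,
    model: ClassifierModel,
    subvolumes: Sequence[Subvolume],
    filter_params: VolumeFilterParams | None = None,
    prob_threshold: float = 0.5,
    pad_um: float = DEFAULT_PAD_UM,
    connectivity: int = 26,
) -> tuple[list[SubvolumeCount], VolumeFilterParams]:
    """Segment and count every subvolume.

    When ``filter_params`` is None the thresholds are derived from the
    pooled empirical instance-volume distribution across all subvolumes
    before counting.
    """
    per_sub: list[tuple[InstanceLabels, Subvolume]] = []
    for i, sub in enumerate(subvolumes):
        try:
            crop, window = _padded_crop(volume, sub, pad_um)
            instances = segment_volume(
                crop, model, prob_threshold=prob_threshold, connectivity=connectivity
            )
        except Exception as exc:  # annotate failures with their location
            raise RuntimeError(f"segmentation failed at subvolume {i} of region "
                               f"{sub.region_id}: {exc}") from exc
        per_sub.append((instances, window))

    if filter_params is None:
        pooled = np.concatenate(
            [inst.volumes_um3 for inst, _ in per_sub]
        ) if per_sub else np.zeros(0)
        filter_params = derive_filter_params(pooled)
        logger.info("derived volume filter: v_min=%.1f v_ref=%.1f v_max=%.1f um^3",
                    filter_params.v_min, filter_params.v_ref, filter_params.v_max)

    counts = [
        volume_filter_count(instances, filter_params, window=window)
        for instances, window in per_sub
    ]
    return counts, filter_params


def run_region_count(
    volume: VolumeImage,
    labelmap: RegionLabelMap,
    model: ClassifierModel,
    region_id: int,
    n_subvolumes: int = 15,
    edge_um: float = 100.0,
    inclusion_threshold: float = 1.0,
    seed: int = 0,
    filter_params: VolumeFilterParams | None = None,
    prob_threshold: float = 0.5,
    pad_um: float = DEFAULT_PAD_UM,
    specimen_id: str = "",
) -> tuple[DensitySummary, list[SubvolumeCount]]:
    """Full workflow for one region: sample, segment, count, summarize."""
    labelmap.check_aligned(volume)
    mask = region_mask(labelmap, region_id)
    vol_mm3 = region_volume(mask, volume.spacing)
    plan = sample_subvolumes(
        mask,
        volume.spacing,
        n=n_subvolumes,
        edge_um=edge_um,
        inclusion_threshold=inclusion_threshold,
        seed=seed,
        region_id=region_id,
    )
    counts, _ = count_subvolumes(
        volume,
        model,
        plan.subvolumes,
        filter_params=filter_params,
        prob_threshold=prob_threshold,
        pad_um=pad_um,
    )
    summary = summarize_region(
        counts,
        vol_mm3,
        region_id=region_id,
        specimen_id=specimen_id,
        region_name=labelmap.name_table.get(region_id, str(region_id)),
        seed=seed,
    )
    return summary, counts


@dataclass
class RunConfig:
    """Serializable record of one counting run (file paths + parameters)."""

    volume_path: str
    labelmap_path: str
    model_path: str
    output_dir: str
    region_ids: list[int]
    specimen_id: str = "specimen"
    n_subvolumes: int = 15
    edge_um: float = 100.0
    inclusion_threshold: float = 1.0
    seed: int = 0
    prob_threshold: float = 0.5
    pad_um: float = DEFAULT_PAD_UM
    spacing_override: tuple[float, float, float] | None = None
    filter_params: dict | None = None  # {"v_min":..., "v_ref":..., "v_max":...}
    overrides: dict = dataclass_field(default_factory=dict)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load YAML/JSON config; keyword overrides win over file values."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        from .types import asdict_shallow

        d = asdict_shallow(self)
        if d["spacing_override"] is not None:
            d["spacing_override"] = list(d["spacing_override"])
        return d


def run_from_config(config: RunConfig) -> list[DensitySummary]:
    """Execute a configured run; writes report, per-subvolume detail and a
    manifest under the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume = io.read_volume(config.volume_path, spacing_override=config.spacing_override)
    labelmap = io.read_labelmap(config.labelmap_path, companion_shape=volume.shape)
    model = io.load_model(config.model_path)
    fp = None
    if config.filter_params:
        fp = VolumeFilterParams(**config.filter_params)

    summaries: list[DensitySummary] = []
    detail_rows: list[dict] = []
    for region_id in config.region_ids:
        summary, counts = run_region_count(
            volume,
            labelmap,
            model,
            region_id,
            n_subvolumes=config.n_subvolumes,
            edge_um=config.edge_um,
            inclusion_threshold=config.inclusion_threshold,
            seed=config.seed,
            filter_params=fp,
            prob_threshold=config.prob_threshold,
            pad_um=config.pad_um,
            specimen_id=config.specimen_id,
        )
        summaries.append(summary)
        for i, c in enumerate(counts):
            detail_rows.append(
                {
                    "region_id": region_id,
                    "subvolume_index": i,
                    "origin_z": c.subvolume.origin[0] if c.subvolume else -1,
                    "origin_y": c.subvolume.origin[1] if c.subvolume else -1,
                    "origin_x": c.subvolume.origin[2] if c.subvolume else -1,
                    "raw_count": c.raw_count,
                    "filtered_count": c.filtered_count,
                    "volume_mm3": c.volume_mm3,
                    "density_per_mm3": c.density,
                }
            )

    io.write_report(summaries, out / "report.csv")
    import pandas as pd

    pd.DataFrame(detail_rows).to_csv(out / "subvolumes.csv", index=False)
    manifest = {"config": config.to_dict(), "n_regions": len(summaries)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summaries
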