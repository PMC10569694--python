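"""Volume filtering, per-subvolume counting, density and total-number
estimation, and cross-specimen variability statistics.

The volume filter maps each instance volume V (um^3) to a count
contribution: debris below ``v_min`` contributes 0; a plausible single
neuron (``v_min <= V <= v_max``) contributes 1; an oversized object is
treated as a fused cluster and contributes ``max(2, round(V / v_ref))``,
partitioning its volume by the mean single-neuron size.

Counting rule: an instance belongs to a counting window iff its centroid
lies inside the window. Edge fragments whose centers fall outside are not
counted, which keeps the per-window expectation unbiased under uniform
placement; callers should therefore segment a margin around the window (see
:mod:`stereocount.pipeline`) so windowed instances carry near-complete
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .instances import InstanceLabels
from .sampling import Subvolume

__all__ = [
    "VolumeFilterParams",
    "SubvolumeCount",
    "DensitySummary",
    "filter_contribution",
    "volume_filter_count",
    "density",
    "summarize_region",
    "cv",
    "percent_difference",
    "derive_filter_params",
]


@dataclass(frozen=True)
class VolumeFilterParams:
    """Volume-filter thresholds in um^3; requires 0 < v_min <= v_ref <= v_max."""

    v_min: float
    v_ref: float
    v_max: float

    def __post_init__(self) -> None:
        if not (0 < self.v_min <= self.v_ref <= self.v_max):
            raise ValueError(
                f"require 0 < v_min <= v_ref <= v_max, got "
                f"({self.v_min}, {self.v_ref}, {self.v_max})"
            )


def filter_contribution(volume_um3: float, params: VolumeFilterParams) -> int:
    """Count contribution of one instance of the given volume."""
    v = float(volume_um3)
    if v < params.v_min:
        return 0
    if v <= params.v_max:
        return 1
    # nearest-integer partition by mean neuron size, floor 2; half-way
    # rounds up so the rule is monotone in V
    return max(2, int(np.floor(v / params.v_ref + 0.5)))


def derive_filter_params(
    volumes_um3: Sequence[float],
    min_factor: float = 0.25,
    max_factor: float = 2.0,
) -> VolumeFilterParams:
    """Derive filter thresholds from an empirical instance-volume sample.

    ``v_ref`` is the median of the mid-range volumes. The mid-range is
    bracketed around the volume-weighted median (the volume at which the
    cumulative sorted-volume sum crosses half the total): sub-resolution
    debris can outnumber real nuclei by a wide margin but carries almost no
    total volume, so count-based percentiles would collapse onto the debris
    mode while the weighted median stays on the nucleus mode.
    ``v_min = min_factor * v_ref`` and ``v_max = max_factor * v_ref``.
    """
    v = np.asarray(volumes_um3, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("cannot derive filter parameters from an empty volume sample")
    v_sorted = np.sort(v)
    cum = np.cumsum(v_sorted)
    v_w = float(v_sorted[np.searchsorted(cum, cum[-1] / 2.0)])
    mid = v[(v >= min_factor * v_w) & (v <= 2.5 * v_w)]
    v_ref = float(np.median(mid if mid.size else v))
    return VolumeFilterParams(v_min=min_factor * v_ref, v_ref=v_ref, v_max=max_factor * v_ref)


@dataclass
class SubvolumeCount:
    """Counting result for one subvolume."""

    subvolume: Subvolume | None
    raw_count: int
    filtered_count: int
    volumes_um3: np.ndarray
    volume_mm3: float

    @property
    def density(self) -> float:
        """Neurons per mm^3 over the realized subvolume volume."""
        return self.filtered_count / self.volume_mm3


def _window_selector(instances: InstanceLabels, window: Subvolume) -> np.ndarray:
    """Boolean selector over instances whose centroid lies in the window.

    The window covers voxels [origin, origin + extent); with voxel-center
    coordinates that is the half-open slab [origin - 0.5, origin + extent - 0.5)
    per axis.
    """
    c = instances.centroids_vox
    lo = np.asarray(window.origin) - 0.5
    hi = lo + np.asarray(window.extent)
    return np.all((c >= lo) & (c < hi), axis=1)


def volume_filter_count(
    instances: InstanceLabels,
    params: VolumeFilterParams,
    window: Subvolume | None = None,
) -> SubvolumeCount:
    """Apply the volume filter and count instances in a counting window.

    Without a window the whole instance grid is the window. With one, only
    instances whose centroid falls inside it are counted (whole-object
    rule), against the window's realized physical volume.
    """
    volumes = instances.volumes_um3
    if window is None:
        keep = np.ones(len(volumes), dtype=bool)
        from .types import UM3_PER_MM3

        volume_mm3 = float(np.prod(instances.labels.shape)) * float(
            np.prod(instances.spacing)
        ) / UM3_PER_MM3
        sub = None
    else:
        keep = _window_selector(instances, window)
        volume_mm3 = window.volume_mm3
        sub = window
    kept = volumes[keep]
    filtered = int(sum(filter_contribution(v, params) for v in kept))
    return SubvolumeCount(
        subvolume=sub,
        raw_count=int(keep.sum()),
        filtered_count=filtered,
        volumes_um3=kept,
        volume_mm3=volume_mm3,
    )


def remove_debris(instances: InstanceLabels, params: VolumeFilterParams) -> InstanceLabels:
    """Drop instances the volume filter scores as debris (V < v_min) and
    relabel consecutively. Fused clusters stay single objects — the filter
    raises their count but cannot split them spatially."""
    keep_ids = np.nonzero(instances.volumes_um3 >= params.v_min)[0] + 1
    lut = np.zeros(instances.count + 1, dtype=np.int32)
    lut[keep_ids] = np.arange(1, len(keep_ids) + 1, dtype=np.int32)
    return InstanceLabels(labels=lut[instances.labels], spacing=instances.spacing)


def density(count: SubvolumeCount) -> float:
    """Neurons per mm^3: filtered count over the realized physical volume."""
    if count.volume_mm3 <= 0:
        raise ValueError("subvolume physical volume must be > 0")
    return count.filtered_count / count.volume_mm3


@dataclass
class DensitySummary:
    """Per-region summary over a set of counting subvolumes."""

    region_id: int
    n_subvolumes: int
    mean_density: float
    sd_density: float
    region_volume_mm3: float
    estimated_total: int
    seed: int
    specimen_id: str = ""
    region_name: str = ""
    subvolume_edge_um: float = float("nan")


def summarize_region(
    counts: Sequence[SubvolumeCount],
    region_volume_mm3: float,
    region_id: int | None = None,
    specimen_id: str = "",
    region_name: str = "",
    seed: int = 0,
) -> DensitySummary:
    """Mean and sample SD (n-1) of subvolume densities, plus the total
    estimate ``round(mean density x region volume)``.

    All counts must come from one region; needs >= 2 subvolumes for the SD.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 subvolumes to summarize a region")
    sub_regions = {c.subvolume.region_id for c in counts if c.subvolume is not None}
    if len(sub_regions) > 1:
        raise ValueError(f"counts mix regions {sorted(sub_regions)}")
    if region_id is None:
        region_id = sub_regions.pop() if sub_regions else 0
    elif sub_regions and sub_regions != {region_id}:
        raise ValueError(f"counts belong to region {sub_regions.pop()}, not {region_id}")
    dens = np.array([density(c) for c in counts])
    mean = float(dens.mean())
    sd = float(dens.std(ddof=1))
    edges = {round(max(c.subvolume.edge_um), 6) for c in counts if c.subvolume is not None}
    edge = edges.pop() if len(edges) == 1 else float("nan")
    return DensitySummary(
        region_id=int(region_id),
        n_subvolumes=len(counts),
        mean_density=mean,
        sd_density=sd,
        region_volume_mm3=float(region_volume_mm3),
        estimated_total=int(round(mean * region_volume_mm3)),
        seed=seed,
        specimen_id=specimen_id,
        region_name=region_name,
        subvolume_edge_um=edge,
    )


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def percent_difference(raw_density: float, corrected_density: float) -> float:
    """|raw - corrected| / corrected x 100."""
    if corrected_density <= 0:
        raise ValueError("corrected density must be > 0")
    return abs(raw_density - corrected_density) / corrected_density * 100.0
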