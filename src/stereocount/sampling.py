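"""Design-based random placement of cubic counting subvolumes inside a
labeled region, plus region-volume measurement.

Placement is independent uniform sampling over all grid positions where the
cube fits, with rejection of cubes whose in-region voxel fraction falls
below ``inclusion_threshold`` (default 1.0: every cube voxel must carry the
region's label, which guarantees counts are attributed to a single region).
Accepted cubes may overlap; the estimator stays unbiased either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import RegionLabelMap, UM3_PER_MM3

__all__ = [
    "Subvolume",
    "SamplingPlan",
    "region_mask",
    "region_volume",
    "sample_subvolumes",
    "cube_extent_voxels",
]


@dataclass(frozen=True)
class Subvolume:
    """An axis-aligned cubic counting window.

    ``origin`` and ``extent`` are in voxels (z, y, x). The realized physical
    edges are ``extent * spacing`` — this realized volume, not the nominal
    cube volume, is used as the density denominator downstream.
    """

    origin: tuple[int, int, int]
    extent: tuple[int, int, int]
    spacing: tuple[float, float, float]
    region_id: int = 0

    @property
    def edge_um(self) -> tuple[float, float, float]:
        return tuple(e * s for e, s in zip(self.extent, self.spacing))  # type: ignore[return-value]

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.edge_um)) / UM3_PER_MM3

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + e) for o, e in zip(self.origin, self.extent))  # type: ignore[return-value]


@dataclass
class SamplingPlan:
    """The accepted subvolumes for one region, plus sampling provenance."""

    region_id: int
    n_subvolumes: int
    edge_um: float
    inclusion_threshold: float
    seed: int
    subvolumes: list[Subvolume] = field(default_factory=list)
    n_rejected: int = 0

    def to_json(self) -> str:
        payload = {
            "region_id": self.region_id,
            "n_subvolumes": self.n_subvolumes,
            "edge_um": self.edge_um,
            "inclusion_threshold": self.inclusion_threshold,
            "seed": self.seed,
            "n_rejected": self.n_rejected,
            "subvolumes": [
                {
                    "origin": list(s.origin),
                    "extent": list(s.extent),
                    "spacing": list(s.spacing),
                    "region_id": s.region_id,
                }
                for s in self.subvolumes
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SamplingPlan":
        payload = json.loads(text)
        subvolumes = [
            Subvolume(
                origin=tuple(s["origin"]),
                extent=tuple(s["extent"]),
                spacing=tuple(s["spacing"]),
                region_id=s["region_id"],
            )
            for s in payload.pop("subvolumes")
        ]
        return cls(subvolumes=subvolumes, **payload)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path) -> "SamplingPlan":
        return cls.from_json(Path(path).read_text())


def region_mask(labelmap: RegionLabelMap, region_id: int) -> np.ndarray:
    """Binary mask of one region; errors list the available IDs."""
    present = labelmap.region_ids
    if region_id not in present:
        raise ValueError(
            f"region {region_id} absent from label map; available IDs: {present.tolist()}"
        )
    return labelmap.labels == region_id


def region_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Physical volume of a mask in mm^3 (voxel count x voxel volume)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("region mask is empty")
    voxel_um3 = float(np.prod(np.asarray(spacing, dtype=float)))
    return n * voxel_um3 / UM3_PER_MM3


def cube_extent_voxels(edge_um: float, spacing: Sequence[float]) -> tuple[int, int, int]:
    """Voxel extent of a cube of nominal physical edge: round per axis, min 1.

    At (4, 1.8, 1.8) um spacing a 100 um cube becomes (25, 56, 56) voxels.
    """
    return tuple(max(1, int(round(edge_um / s))) for s in np.asarray(spacing, dtype=float))  # type: ignore[return-value]


def sample_subvolumes(
    mask: np.ndarray,
    spacing: Sequence[float],
    n: int = 15,
    edge_um: float = 100.0,
    inclusion_threshold: float = 1.0,
    seed: int = 0,
    region_id: int = 0,
    retry_cap: int | None = None,
) -> SamplingPlan:
    """Draw ``n`` uniformly-placed counting cubes inside a region mask.

    Origins are uniform over every position where the cube fits in the grid;
    a placement is accepted iff the fraction of its voxels inside the mask
    is >= ``inclusion_threshold``. Identical inputs and seed give an
    identical plan.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not 0.0 < inclusion_threshold <= 1.0:
        raise ValueError("inclusion_threshold must lie in (0, 1]")
    spacing = tuple(float(s) for s in spacing)
    extent = cube_extent_voxels(edge_um, spacing)
    shape = mask.shape
    max_origin = tuple(s - e for s, e in zip(shape, extent))
    if any(m < 0 for m in max_origin):
        raise ValueError(
            f"a {edge_um} um cube (extent {extent} voxels) does not fit in grid of shape {shape}"
        )
    if retry_cap is None:
        retry_cap = 10_000 * n

    rng = np.random.default_rng(seed)
    cube_voxels = int(np.prod(extent))
    plan = SamplingPlan(
        region_id=region_id,
        n_subvolumes=n,
        edge_um=float(edge_um),
        inclusion_threshold=float(inclusion_threshold),
        seed=int(seed),
    )
    tries = 0
    while len(plan.subvolumes) < n:
        if tries >= retry_cap:
            accepted = len(plan.subvolumes)
            rate = accepted / tries if tries else 0.0
            raise RuntimeError(
                f"retry cap {retry_cap} exhausted after accepting {accepted}/{n} subvolumes "
                f"(acceptance rate {rate:.2e}); the region is too small or thin for a "
                f"{edge_um} um cube at threshold {inclusion_threshold}"
            )
        origin = tuple(int(rng.integers(0, m + 1)) for m in max_origin)
        tries += 1
        sub = tuple(slice(o, o + e) for o, e in zip(origin, extent))
        frac = mask[sub].sum() / cube_voxels
        if frac >= inclusion_threshold - 1e-12:
            plan.subvolumes.append(
                Subvolume(origin=origin, extent=extent, spacing=spacing, region_id=region_id)
            )
        else:
            plan.n_rejected += 1
    return plan
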