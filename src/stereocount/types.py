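"""Core domain types shared across the pipeline.

Axis order is (z, y, x) everywhere, 0-based voxel indexing; physical
positions are voxel-center based, i.e. voxel ``(i, j, k)`` sits at
``(i*dz, j*dy, k*dx)`` micrometres. Spacing is mandatory metadata — there is
no implicit "isotropic 1 um" fallback, because the volume filter and the
watershed topography both depend on physical units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "VolumeImage",
    "RegionLabelMap",
    "SparseAnnotations",
    "ClassifierModel",
]

UM3_PER_MM3 = 1e9


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (dz, dy, dx), got {spacing!r}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing!r}")
    return spacing


@dataclass
class VolumeImage:
    """A 3D intensity grid with physical voxel spacing in micrometres.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Voxel intensities in (z, y, x) order. Any numeric dtype is accepted
        and never rescaled implicitly.
    spacing : tuple of float
        Physical voxel size ``(dz, dy, dx)`` in micrometres, each > 0.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))  # type: ignore[return-value]

    @property
    def physical_volume_mm3(self) -> float:
        return float(np.prod(self.data.shape)) * self.voxel_volume_um3 / UM3_PER_MM3


@dataclass
class RegionLabelMap:
    """Integer region-ID grid aligned to a :class:`VolumeImage`.

    Label 0 is reserved for "outside brain / unlabeled". Every nonzero ID
    present in ``labels`` must appear in ``name_table``; when no sidecar
    table is supplied the table is auto-populated with stringified IDs.
    """

    labels: np.ndarray
    name_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label map must hold integers, got dtype {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("region labels must be non-negative")
        present = self.region_ids
        if not self.name_table:
            self.name_table = {int(i): str(int(i)) for i in present}
        else:
            self.name_table = {int(k): str(v) for k, v in self.name_table.items()}
            missing = [int(i) for i in present if int(i) not in self.name_table]
            if missing:
                raise ValueError(f"region IDs missing from name table: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted nonzero region IDs present in the grid."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def check_aligned(self, volume: VolumeImage) -> None:
        if self.labels.shape != volume.data.shape:
            raise ValueError(
                f"label map shape {self.labels.shape} does not match volume shape {volume.data.shape}"
            )


@dataclass
class SparseAnnotations:
    """Sparse voxel annotations: neuron (class 1) and background (class 0).

    ``coords`` is an (N, 3) integer array of (z, y, x) voxel indices and
    ``classes`` the matching (N,) vector with values in {0, 1}.
    """

    coords: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        self.classes = np.asarray(self.classes, dtype=np.int64).ravel()
        if self.coords.shape[1] != 3:
            raise ValueError("annotation coordinates must be (N, 3) (z, y, x)")
        if self.coords.shape[0] != self.classes.shape[0]:
            raise ValueError("coords and classes length mismatch")
        bad = set(np.unique(self.classes)) - {0, 1}
        if bad:
            raise ValueError(f"annotation classes must be 0 or 1, found {sorted(bad)}")

    @property
    def n_neuron(self) -> int:
        return int(np.sum(self.classes == 1))

    @property
    def n_background(self) -> int:
        return int(np.sum(self.classes == 0))

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        if self.coords.size == 0:
            return
        if self.coords.min() < 0 or np.any(self.coords >= np.asarray(shape)):
            raise ValueError(f"annotation coordinates fall outside volume of shape {shape}")

    @staticmethod
    def concatenate(parts: list["SparseAnnotations"]) -> "SparseAnnotations":
        return SparseAnnotations(
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.classes for p in parts]),
        )


@dataclass
class ClassifierModel:
    """A trained random-forest voxel classifier plus its provenance.

    The fingerprint records the feature configuration (feature names, scales
    and the voxel spacing the features were computed at); prediction refuses
    feature stacks whose fingerprint differs from training, so a model can
    only be reused across volumes that share spacing and feature settings.
    """

    estimator: Any
    fingerprint: dict[str, Any]
    metadata: dict[str, Any] = field(default_factory=dict)

    def check_compatible(self, fingerprint: Mapping[str, Any]) -> None:
        if dict(fingerprint) != dict(self.fingerprint):
            raise ValueError(
                "feature configuration fingerprint does not match training: "
                f"model={self.fingerprint!r} vs features={dict(fingerprint)!r}"
            )


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying large arrays."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
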