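"""Readers and writers for every on-disk representation the pipeline touches.

Formats: multi-page TIFF for volumes and instance grids, NIfTI-1 for label
maps and displacement fields, CSV for sparse annotations and reports, and a
single serialized-model file with an embedded JSON fingerprint.

All read/write pairs are lossless round trips at declared precision, and all
grids are (z, y, x); readers never transpose silently.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .types import ClassifierModel, RegionLabelMap, SparseAnnotations, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_annotations",
    "write_annotations",
    "save_model",
    "load_model",
    "write_report",
    "read_report",
    "read_displacement_field",
    "write_displacement_field",
    "REPORT_COLUMNS",
]

_SPACING_KEY = "spacing_um_zyx"

REPORT_COLUMNS = [
    "specimen_id",
    "region_id",
    "region_name",
    "n_subvolumes",
    "subvolume_edge_um",
    "mean_density_per_mm3",
    "sd_density_per_mm3",
    "region_volume_mm3",
    "estimated_total",
    "seed",
]


# ---------------------------------------------------------------------------
# volumes (TIFF)
# ---------------------------------------------------------------------------

def write_volume(volume: VolumeImage, path) -> Path:
    """Write a volume as a multi-page TIFF with spacing embedded as JSON."""
    path = Path(path)
    description = json.dumps({_SPACING_KEY: list(volume.spacing)})
    tifffile.imwrite(path, volume.data, description=description)
    return path


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    # our own files: JSON in the ImageDescription tag
    page0 = tf.pages[0]
    desc = page0.description or ""
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and _SPACING_KEY in meta:
            dz, dy, dx = (float(v) for v in meta[_SPACING_KEY])
            return (dz, dy, dx)
    except (json.JSONDecodeError, ValueError, TypeError):
        pass
    # ImageJ-style files: z spacing in metadata, x/y from resolution tags
    ij = tf.imagej_metadata or {}
    dz = ij.get("spacing")
    tags = page0.tags
    if dz and "XResolution" in tags and "YResolution" in tags:
        xr = tags["XResolution"].value
        yr = tags["YResolution"].value
        dx = xr[1] / xr[0] if xr[0] else None
        dy = yr[1] / yr[0] if yr[0] else None
        if dx and dy:
            return (float(dz), float(dy), float(dx))
    return None


def read_volume(path, spacing_override: Sequence[float] | None = None) -> VolumeImage:
    """Read a 3D TIFF stack into a :class:`VolumeImage`.

    Parameters
    ----------
    path : path-like
        Multi-page TIFF (or single-file 3D TIFF).
    spacing_override : (dz, dy, dx) in um, optional
        Required when the TIFF metadata carries no spacing. Never silently
        defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_tiff(tf)
    if data.ndim == 2:
        raise ValueError(f"{path} holds a 2D image; a 3D stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path} holds a {data.ndim}D array; expected 3D (z, y, x)")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)  # type: ignore[assignment]
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel-spacing metadata; pass spacing_override=(dz, dy, dx) in um"
        )
    return VolumeImage(data=data, spacing=spacing)


# ---------------------------------------------------------------------------
# label maps (NIfTI or TIFF + optional sidecar CSV)
# ---------------------------------------------------------------------------

def write_labelmap(labelmap: RegionLabelMap, path, sidecar: bool = True) -> Path:
    """Write a label map as NIfTI-1 (``.nii``/``.nii.gz``) or TIFF.

    With ``sidecar=True`` a companion ``<stem>_names.csv`` (id,name) is
    written next to the grid.
    """
    path = Path(path)
    data = labelmap.labels.astype(np.uint32)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
    else:
        tifffile.imwrite(path, data)
    if sidecar and labelmap.name_table:
        _sidecar_path(path).write_text(
            "id,name\n"
            + "\n".join(f"{i},{labelmap.name_table[i]}" for i in sorted(labelmap.name_table))
            + "\n"
        )
    return path


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + "_names.csv")


def read_labelmap(path, sidecar=None, companion_shape: tuple[int, int, int] | None = None) -> RegionLabelMap:
    """Read an integer region label map (NIfTI or TIFF).

    ``sidecar`` may point to a CSV with columns ``id,name``; when omitted the
    default ``<stem>_names.csv`` is used if present, otherwise region names
    are the stringified IDs. Non-integer voxel values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    else:
        data = tifffile.imread(path)
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.mod(data, 1) == 0):
            raise ValueError(f"{path} contains non-integer voxel values; not a label map")
        data = data.astype(np.int64)
    if data.min() < 0:
        raise ValueError("region label maps must be non-negative")
    data = data.astype(np.uint32)
    if companion_shape is not None and data.shape != tuple(companion_shape):
        raise ValueError(
            f"label map shape {data.shape} does not match companion volume shape {tuple(companion_shape)}"
        )
    name_table: dict[int, str] = {}
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar_path.exists():
        table = pd.read_csv(sidecar_path)
        name_table = {int(r["id"]): str(r["name"]) for _, r in table.iterrows()}
        # tolerate tables that describe a superset of the IDs present
        present = set(int(i) for i in np.unique(data) if i > 0)
        name_table = {k: v for k, v in name_table.items() if k in present} or name_table
        for i in present - set(name_table):
            name_table[i] = str(i)
    return RegionLabelMap(labels=data, name_table=name_table)


# ---------------------------------------------------------------------------
# sparse annotations (CSV: z,y,x,class)
# ---------------------------------------------------------------------------

def write_annotations(ann: SparseAnnotations, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"z": ann.coords[:, 0], "y": ann.coords[:, 1], "x": ann.coords[:, 2], "class": ann.classes}
    )
    df.to_csv(path, index=False)
    return path


def read_annotations(path) -> SparseAnnotations:
    df = pd.read_csv(path)
    required = {"z", "y", "x", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    coords = df[["z", "y", "x"]].to_numpy(dtype=np.int64)
    return SparseAnnotations(coords=coords, classes=df["class"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# classifier model (joblib payload + JSON fingerprint with checksum)
# ---------------------------------------------------------------------------

def _fingerprint_digest(fingerprint: dict) -> str:
    return hashlib.sha256(json.dumps(fingerprint, sort_keys=True).encode()).hexdigest()


def save_model(model: ClassifierModel, path) -> Path:
    """Serialize a trained model; the fingerprint is checksummed so that a
    tampered file refuses to load."""
    path = Path(path)
    payload = {
        "estimator": model.estimator,
        "fingerprint": model.fingerprint,
        "metadata": model.metadata,
        "fingerprint_sha256": _fingerprint_digest(model.fingerprint),
    }
    joblib.dump(payload, path)
    return path


def load_model(path) -> ClassifierModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = joblib.load(path)
    expected = payload.get("fingerprint_sha256")
    actual = _fingerprint_digest(payload["fingerprint"])
    if expected != actual:
        raise ValueError(f"model fingerprint checksum mismatch in {path}; refusing to load")
    return ClassifierModel(
        estimator=payload["estimator"],
        fingerprint=payload["fingerprint"],
        metadata=payload.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# density reports (CSV)
# ---------------------------------------------------------------------------

def write_report(summaries: Iterable, path) -> Path:
    """Write one CSV row per :class:`~stereocount.counting.DensitySummary`."""
    path = Path(path)
    rows = []
    for s in summaries:
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "region_id": s.region_id,
                "region_name": s.region_name,
                "n_subvolumes": s.n_subvolumes,
                "subvolume_edge_um": s.subvolume_edge_um,
                "mean_density_per_mm3": s.mean_density,
                "sd_density_per_mm3": s.sd_density,
                "region_volume_mm3": s.region_volume_mm3,
                "estimated_total": s.estimated_total,
                "seed": s.seed,
            }
        )
    if not rows:
        warnings.warn("writing report with no summaries: header-only file", stacklevel=2)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# dense displacement fields (NIfTI, shape (3, Z, Y, X), um)
# ---------------------------------------------------------------------------

def write_displacement_field(field: np.ndarray, path) -> Path:
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError(f"displacement field must have shape (3, Z, Y, X), got {field.shape}")
    nib.save(nib.Nifti1Image(field, affine=np.eye(4)), Path(path))
    return Path(path)


def read_displacement_field(path) -> np.ndarray:
    field = np.asanyarray(nib.load(Path(path)).dataobj).astype(np.float32)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError(f"displacement field must have shape (3, Z, Y, X), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    return field
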