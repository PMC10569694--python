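"""Synthetic LSM-like phantoms with ground truth.

Generates volumes that emulate a NeuN-stained light-sheet channel: bright
ellipsoidal nuclei on a textured background, anisotropic voxels, Gaussian
blur, Gaussian and/or Poisson noise, and a controllable fraction of
near-contact ("touching") nucleus pairs with known merge topology. Also
provides dense-displacement resampling to emulate uncorrected-morphology
deformation, and sparse-annotation sampling from ground truth.

Defaults are chosen for plausibility, not optical fidelity, and are all
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates

from .types import RegionLabelMap, SparseAnnotations, VolumeImage, UM3_PER_MM3

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_region_phantom",
    "apply_deformation",
    "make_scale_field",
    "sample_annotations",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic nucleus phantom.

    ``extent`` is in voxels (z, y, x), ``spacing`` in um. ``target_density``
    is in nuclei per mm^3; the realized count is Poisson-distributed.
    ``touching_fraction`` of nuclei are placed as near-contact pairs whose
    centers sit at 0.9x the sum of their radii, giving watershed tests a
    known merge topology.
    """

    extent: tuple[int, int, int] = (30, 113, 113)
    spacing: tuple[float, float, float] = (4.0, 1.8, 1.8)
    target_density: float = 30_000.0
    radius_mean_um: float = 4.5
    radius_sd_um: float = 0.35
    fg_mean: float = 180.0
    fg_sd: float = 15.0
    bg_mean: float = 100.0
    bg_sd: float = 8.0
    texture_scale_um: float = 8.0
    blur_sigma_um: float = 1.2
    noise_gaussian_sd: float = 8.0
    noise_poisson: bool = False
    touching_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ValueError("target_density must be > 0")
        if self.radius_mean_um <= 0 or self.radius_sd_um < 0:
            raise ValueError("nucleus radii must be positive")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must lie in [0, 1]")
        self.extent = tuple(int(e) for e in self.extent)  # type: ignore[assignment]
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def physical_extent_um(self) -> np.ndarray:
        return np.asarray(self.extent, dtype=float) * np.asarray(self.spacing, dtype=float)

    @property
    def physical_volume_mm3(self) -> float:
        return float(np.prod(self.physical_extent_um)) / UM3_PER_MM3


@dataclass
class GroundTruth:
    """Ground-truth instances for a phantom.

    ``labels`` holds instance IDs 1..K (0 background) on the phantom grid;
    ``centroids_um`` are physical (z, y, x) centroids of the rendered voxels;
    ``volumes_um3`` the rendered per-instance volumes.
    """

    labels: np.ndarray
    centroids_um: np.ndarray
    volumes_um3: np.ndarray
    region_ids: np.ndarray | None = None
    semiaxes_um: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.centroids_um)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if len(ids) != k:
            raise ValueError(
                f"ground truth inconsistent: {len(ids)} rendered instances vs {k} centroids"
            )

    @property
    def count(self) -> int:
        return len(self.centroids_um)


# ---------------------------------------------------------------------------
# nucleus placement
# ---------------------------------------------------------------------------

def _place_nuclei(
    rng: np.random.Generator,
    lo_um: np.ndarray,
    hi_um: np.ndarray,
    spec: PhantomSpec,
    density: float,
    max_tries: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place nucleus centers uniformly in the box [lo_um, hi_um) um.

    Returns (centers_um (N,3), radii_um (N,)). A ``touching_fraction`` of
    nuclei are laid down as pairs at center distance 0.9*(r1+r2); all other
    placements are rejection-sampled to keep centroid separation above the
    sum of radii.
    """
    box = hi_um - lo_um
    volume_mm3 = float(np.prod(box)) / UM3_PER_MM3
    expected = density * volume_mm3
    if expected < 1.0:
        raise ValueError(
            f"expected nucleus count {expected:.3g} < 1; enlarge the phantom extent or density"
        )
    n = int(rng.poisson(expected))
    radii = rng.normal(spec.radius_mean_um, spec.radius_sd_um, size=n)
    radii = np.clip(radii, spec.radius_mean_um / 3.0, None)

    n_pairs = int(np.floor(spec.touching_fraction * n / 2.0))
    centers: list[np.ndarray] = []
    placed_r: list[float] = []

    def far_enough(c: np.ndarray, r: float, slack: float = 1.0) -> bool:
        for cj, rj in zip(centers, placed_r):
            if np.linalg.norm(c - cj) <= slack * (r + rj):
                return False
        return True

    idx = 0
    # touching pairs first: anchor placed like a single, partner on a random
    # direction at 0.9x the radii sum
    for _ in range(n_pairs):
        r1, r2 = radii[idx], radii[idx + 1]
        for _ in range(max_tries):
            c1 = lo_um + rng.uniform(size=3) * box
            if not far_enough(c1, r1, slack=1.05):
                continue
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            c2 = c1 + d * 0.9 * (r1 + r2)
            if np.any(c2 < lo_um) or np.any(c2 >= hi_um) or not far_enough(c2, r2, slack=1.05):
                continue
            centers.extend([c1, c2])
            placed_r.extend([r1, r2])
            break
        else:
            raise RuntimeError("could not place a touching pair; phantom too crowded")
        idx += 2
    # remaining singles: strictly non-touching
    for k in range(idx, n):
        r = radii[k]
        for _ in range(max_tries):
            c = lo_um + rng.uniform(size=3) * box
            if far_enough(c, r, slack=1.05):
                centers.append(c)
                placed_r.append(r)
                break
        else:
            raise RuntimeError("could not place a nucleus; phantom too crowded")
    if not centers:
        return np.zeros((0, 3)), np.zeros((0,))
    return np.asarray(centers), np.asarray(placed_r)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_instances(
    extent: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize ellipsoids into an instance grid.

    Semi-axes are the nucleus radius jittered per-axis by U(0.92, 1.08).
    Where two ellipsoids overlap, each voxel goes to the nucleus with the
    smaller normalized ellipsoidal distance.
    """
    labels = np.zeros(extent, dtype=np.uint32)
    best = np.full(extent, np.inf, dtype=np.float32)
    sp = np.asarray(spacing)
    semiaxes = radii_um[:, None] * rng.uniform(0.92, 1.08, size=(len(radii_um), 3))
    for k, (c, axes) in enumerate(zip(centers_um, semiaxes), start=1):
        lo = np.maximum(np.floor((c - axes) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((c + axes) / sp).astype(int) + 1, extent)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) * sp[0] - c[0]) / axes[0],
            (np.arange(lo[1], hi[1]) * sp[1] - c[1]) / axes[1],
            (np.arange(lo[2], hi[2]) * sp[2] - c[2]) / axes[2],
            indexing="ij",
        )
        d = (zz**2 + yy**2 + xx**2).astype(np.float32)
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        inside = (d <= 1.0) & (d < best[sub])
        labels[sub][inside] = k
        best[sub][inside] = d[inside]
    return labels, semiaxes


def _finalize_ground_truth(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    region_of_center: np.ndarray | None = None,
    semiaxes: np.ndarray | None = None,
) -> GroundTruth:
    """Relabel consecutively, dropping nuclei that rendered to zero voxels."""
    sp = np.asarray(spacing)
    voxel_volume = float(np.prod(sp))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    relabel = np.zeros(int(labels.max()) + 1, dtype=np.uint32)
    relabel[ids] = np.arange(1, len(ids) + 1, dtype=np.uint32)
    out = relabel[labels]
    centroids = np.zeros((len(ids), 3))
    coords = np.nonzero(out)
    vals = out[coords]
    for axis in range(3):
        centroids[:, axis] = np.bincount(vals, weights=coords[axis], minlength=len(ids) + 1)[1:]
    centroids = centroids / counts[:, None] * sp[None, :]
    region_ids = None
    if region_of_center is not None:
        region_ids = region_of_center[ids - 1]
    kept_semiaxes = semiaxes[ids - 1] if semiaxes is not None else None
    return GroundTruth(
        labels=out,
        centroids_um=centroids,
        volumes_um3=counts.astype(float) * voxel_volume,
        region_ids=region_ids,
        semiaxes_um=kept_semiaxes,
    )


def _render_intensity(spec: PhantomSpec, labels: np.ndarray, n_instances: int,
                      rng: np.random.Generator) -> np.ndarray:
    sp = np.asarray(spec.spacing)
    img = np.full(spec.extent, spec.bg_mean, dtype=np.float32)
    if spec.bg_sd > 0:
        texture = rng.standard_normal(spec.extent).astype(np.float32)
        texture = gaussian_filter(texture, sigma=spec.texture_scale_um / sp)
        tsd = texture.std()
        if tsd > 0:
            img += texture * (spec.bg_sd / tsd)
    if n_instances:
        fg = rng.normal(spec.fg_mean, spec.fg_sd, size=n_instances + 1).astype(np.float32)
        mask = labels > 0
        img[mask] = fg[labels[mask]]
    if spec.blur_sigma_um > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma_um / sp)
    if spec.noise_gaussian_sd > 0:
        img += rng.normal(0.0, spec.noise_gaussian_sd, size=spec.extent).astype(np.float32)
    if spec.noise_poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
    return img


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Generate a phantom volume and its ground truth.

    The nucleus count is drawn Poisson(target_density x physical volume);
    centers are uniform except for the touching pairs. Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo = np.zeros(3)
    hi = spec.physical_extent_um
    centers, radii = _place_nuclei(rng, lo, hi, spec, spec.target_density)
    labels, semiaxes = _render_instances(spec.extent, spec.spacing, centers, radii, rng)
    truth = _finalize_ground_truth(labels, spec.spacing, semiaxes=semiaxes)
    img = _render_intensity(spec, truth.labels, truth.count, rng)
    return VolumeImage(data=img, spacing=spec.spacing), truth


def generate_region_phantom(
    n_regions: int,
    spec: PhantomSpec,
    density_factors: Sequence[float] | None = None,
    margin_voxels: int = 2,
    min_region_edge_um: float = 100.0,
) -> tuple[VolumeImage, RegionLabelMap, GroundTruth]:
    """Phantom partitioned into labeled regions with (optionally) differing
    ground-truth densities.

    The volume is split into ``n_regions`` slabs along y, surrounded by a
    zero-label margin. ``density_factors[i]`` scales ``spec.target_density``
    for region ``i + 1``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if density_factors is None:
        density_factors = [1.0] * n_regions
    if len(density_factors) != n_regions:
        raise ValueError("density_factors length must equal n_regions")
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing)
    extent = np.asarray(spec.extent)
    if np.any(extent <= 2 * margin_voxels):
        raise ValueError("extent too small for the requested margin")

    region_grid = np.zeros(spec.extent, dtype=np.uint32)
    inner_lo = np.full(3, margin_voxels)
    inner_hi = extent - margin_voxels
    edges = np.linspace(inner_lo[1], inner_hi[1], n_regions + 1).round().astype(int)

    notes: list[str] = []
    all_centers: list[np.ndarray] = []
    all_radii: list[np.ndarray] = []
    region_of_center: list[int] = []
    for i in range(n_regions):
        y0, y1 = edges[i], edges[i + 1]
        region_grid[inner_lo[0]:inner_hi[0], y0:y1, inner_lo[2]:inner_hi[2]] = i + 1
        lo_um = np.array([inner_lo[0], y0, inner_lo[2]]) * sp
        hi_um = np.array([inner_hi[0], y1, inner_hi[2]]) * sp
        if np.any(hi_um - lo_um < min_region_edge_um):
            msg = f"region {i + 1} is thinner than {min_region_edge_um} um on some axis"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        centers, radii = _place_nuclei(
            rng, lo_um, hi_um, spec, spec.target_density * density_factors[i]
        )
        all_centers.append(centers)
        all_radii.append(radii)
        region_of_center.extend([i + 1] * len(centers))

    centers = np.concatenate(all_centers) if all_centers else np.zeros((0, 3))
    radii = np.concatenate(all_radii) if all_radii else np.zeros((0,))
    labels, semiaxes = _render_instances(spec.extent, spec.spacing, centers, radii, rng)
    truth = _finalize_ground_truth(
        labels, spec.spacing, np.asarray(region_of_center), semiaxes=semiaxes
    )
    truth.notes.extend(notes)
    img = _render_intensity(spec, truth.labels, truth.count, rng)
    name_table = {i + 1: f"region_{i + 1}" for i in range(n_regions)}
    return (
        VolumeImage(data=img, spacing=spec.spacing),
        RegionLabelMap(labels=region_grid, name_table=name_table),
        truth,
    )


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def apply_deformation(
    grid: np.ndarray,
    field: np.ndarray,
    spacing: Sequence[float],
    mode: str = "intensity",
) -> np.ndarray:
    """Resample a grid through a dense displacement field.

    ``field`` has shape (3, Z, Y, X) holding per-voxel (dz, dy, dx)
    displacements in um: the output at voxel v takes its value from the
    input at ``v + field[:, v] / spacing``. A zero field is the identity.
    ``mode='labels'`` uses nearest-neighbor interpolation and never invents
    IDs; ``mode='intensity'`` uses trilinear interpolation.
    """
    grid = np.asarray(grid)
    field = np.asarray(field)
    if field.shape != (3, *grid.shape):
        raise ValueError(f"field shape {field.shape} does not match grid shape {grid.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    if mode not in {"intensity", "labels"}:
        raise ValueError("mode must be 'intensity' or 'labels'")
    sp = np.asarray(spacing, dtype=float).reshape(3, 1, 1, 1)
    coords = np.indices(grid.shape, dtype=np.float64) + field / sp
    order = 1 if mode == "intensity" else 0
    out = map_coordinates(grid.astype(np.float64 if mode == "intensity" else grid.dtype),
                          coords, order=order, mode="constant", cval=0)
    if mode == "labels":
        out = out.astype(grid.dtype)
    return out


def make_scale_field(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    scale: float,
    center_um: Sequence[float] | None = None,
) -> np.ndarray:
    """Displacement field that shrinks (scale < 1) or dilates the content
    uniformly about ``center_um`` (default: volume center).

    The sampled point for output voxel v is ``c + (v - c)/scale``, so
    rendered objects scale by ``scale`` per axis and volumes by scale^3.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    sp = np.asarray(spacing, dtype=float)
    if center_um is None:
        center_um = (np.asarray(shape) - 1) * sp / 2.0
    c = np.asarray(center_um, dtype=float).reshape(3, 1, 1, 1)
    pos = np.indices(shape, dtype=np.float64) * sp.reshape(3, 1, 1, 1)
    return ((pos - c) * (1.0 / scale - 1.0)).astype(np.float32)


# ---------------------------------------------------------------------------
# sparse annotations from ground truth
# ---------------------------------------------------------------------------

def sample_annotations(
    truth: GroundTruth,
    n_nuclei: int = 20,
    voxels_per_nucleus: int = 5,
    background_factor: float = 1.0,
    seed: int = 0,
    min_nucleus_voxels: int = 3,
) -> SparseAnnotations:
    """Emulate sparse manual labeling: point annotations inside ``n_nuclei``
    distinct ground-truth instances plus background strokes of comparable
    voxel count (``background_factor`` x the foreground count).

    Background voxels are drawn at >= 1 voxel distance from any nucleus so
    the strokes do not sit on blurred rims.
    """
    rng = np.random.default_rng(seed)
    ids, counts = np.unique(truth.labels[truth.labels > 0], return_counts=True)
    eligible = ids[counts >= min_nucleus_voxels]
    if len(eligible) < n_nuclei:
        raise ValueError(
            f"only {len(eligible)} instances with >= {min_nucleus_voxels} voxels; "
            f"cannot annotate {n_nuclei} nuclei"
        )
    chosen = rng.choice(eligible, size=n_nuclei, replace=False)
    fg_coords = []
    for i in chosen:
        vox = np.argwhere(truth.labels == i)
        take = min(voxels_per_nucleus, len(vox))
        sel = rng.choice(len(vox), size=take, replace=False)
        fg_coords.append(vox[sel])
    fg_coords = np.concatenate(fg_coords)

    n_bg = max(1, int(round(background_factor * len(fg_coords))))
    away = ~binary_dilation(truth.labels > 0, iterations=1)
    bg_pool = np.argwhere(away)
    if len(bg_pool) < n_bg:
        bg_pool = np.argwhere(truth.labels == 0)
    sel = rng.choice(len(bg_pool), size=n_bg, replace=False)
    bg_coords = bg_pool[sel]

    coords = np.concatenate([fg_coords, bg_coords])
    classes = np.concatenate([np.ones(len(fg_coords), int), np.zeros(len(bg_coords), int)])
    return SparseAnnotations(coords=coords, classes=classes)
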