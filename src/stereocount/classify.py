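"""Sparse-label random-forest voxel classification.

The feature family is the standard interactive-segmentation set: per scale
sigma (in um, converted to per-axis voxel sigmas so anisotropy is handled
physically) — Gaussian-smoothed intensity, gradient magnitude, Laplacian of
Gaussian, difference of Gaussians (sigma vs 2 sigma), and the three sorted
Hessian eigenvalues — plus the raw intensity. Training uses only the
annotated voxels; ~20 annotated nuclei plus background strokes are enough
in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.ensemble import RandomForestClassifier

from .types import ClassifierModel, SparseAnnotations, VolumeImage

__all__ = [
    "FeatureStack",
    "ProbabilityMap",
    "DEFAULT_SCALES_UM",
    "compute_features",
    "train",
    "predict",
]

DEFAULT_SCALES_UM = (1.6, 3.2, 6.4)

_PER_SCALE = ("gauss", "grad_mag", "log", "dog", "hess_ev0", "hess_ev1", "hess_ev2")


@dataclass
class FeatureStack:
    """Per-voxel feature vectors over a volume.

    ``data`` has shape (n_features, Z, Y, X), float32. The fingerprint ties
    the stack to the feature names, scales and voxel spacing it was computed
    with, and must match between training and prediction.
    """

    data: np.ndarray
    feature_names: list[str]
    scales_um: tuple[float, ...]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != len(self.feature_names):
            raise ValueError("feature stack shape inconsistent with feature names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    @property
    def fingerprint(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "scales_um": [round(float(s), 6) for s in self.scales_um],
            "spacing_um": [round(float(s), 6) for s in self.spacing],
        }

    def at(self, coords: np.ndarray) -> np.ndarray:
        """Feature matrix (N, n_features) at the given (N, 3) voxel coords."""
        return self.data[:, coords[:, 0], coords[:, 1], coords[:, 2]].T


@dataclass
class ProbabilityMap:
    """Per-voxel neuron-class probability plus the paired binary mask."""

    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return self.probabilities >= self.threshold


def _gaussian_derivative(data, sigma_vox, order, spacing):
    """Gaussian derivative w.r.t. physical coordinates (um)."""
    out = gaussian_filter(data, sigma=sigma_vox, order=order)
    denom = 1.0
    for o, s in zip(order, spacing):
        denom *= s**o
    return out / denom


def compute_features(volume: VolumeImage, scales_um=DEFAULT_SCALES_UM) -> FeatureStack:
    """Compute the multi-scale feature stack for one volume.

    Scales are physical (um); each is divided by the per-axis spacing so an
    anisotropic grid gets anisotropic voxel sigmas. A scale smaller than
    half the coarsest voxel dimension is degenerate on that axis and raises
    a warning.
    """
    scales_um = tuple(float(s) for s in scales_um)
    if any(s <= 0 for s in scales_um):
        raise ValueError("scales must be positive")
    spacing = volume.spacing
    coarsest = max(spacing)
    for s in scales_um:
        if s < 0.5 * coarsest:
            warnings.warn(
                f"scale {s} um is below half the coarsest voxel dimension ({coarsest} um); "
                "the feature is degenerate on that axis",
                stacklevel=2,
            )
    data = volume.data.astype(np.float32)
    names: list[str] = ["raw"]
    planes: list[np.ndarray] = [data]
    for sigma in scales_um:
        sig_vox = tuple(sigma / s for s in spacing)
        smoothed = gaussian_filter(data, sigma=sig_vox)

        d1 = [
            _gaussian_derivative(data, sig_vox, tuple(int(a == i) for i in range(3)), spacing)
            for a in range(3)
        ]
        grad_mag = np.sqrt(d1[0] ** 2 + d1[1] ** 2 + d1[2] ** 2)

        # full Hessian in physical units
        h = np.empty((3, 3) + data.shape, dtype=np.float32)
        for a in range(3):
            for b in range(a, 3):
                order = [0, 0, 0]
                order[a] += 1
                order[b] += 1
                h[a, b] = _gaussian_derivative(data, sig_vox, tuple(order), spacing)
                h[b, a] = h[a, b]
        log = h[0, 0] + h[1, 1] + h[2, 2]
        hmat = np.moveaxis(h.reshape(3, 3, -1), -1, 0)
        eig = np.linalg.eigvalsh(hmat).astype(np.float32)  # ascending
        evs = [eig[:, k].reshape(data.shape) for k in range(3)]

        big = gaussian_filter(data, sigma=tuple(2 * v for v in sig_vox))
        dog = smoothed - big

        planes.extend([smoothed, grad_mag.astype(np.float32), log, dog, *evs])
        names.extend(f"{base}_s{sigma:g}" for base in _PER_SCALE)

    stack = np.stack(planes).astype(np.float32)
    return FeatureStack(
        data=stack, feature_names=names, scales_um=scales_um, spacing=spacing
    )


def train(
    features: FeatureStack,
    ann: SparseAnnotations,
    n_trees: int = 100,
    seed: int = 0,
    max_depth: int | None = None,
) -> ClassifierModel:
    """Fit a random forest on the annotated voxels only.

    Both classes must be present (training needs cell bodies *and*
    background). Same features, annotations and seed give a model with
    identical predictions.
    """
    ann.check_inside(features.shape)
    if ann.n_neuron == 0 or ann.n_background == 0:
        raise ValueError(
            "annotations must contain both classes (neuron=1 and background=0); "
            f"got {ann.n_neuron} neuron and {ann.n_background} background voxels"
        )
    X = features.at(ann.coords)
    y = ann.classes
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ClassifierModel(
        estimator=forest,
        fingerprint=features.fingerprint,
        metadata={
            "n_neuron_annotations": ann.n_neuron,
            "n_background_annotations": ann.n_background,
            "n_trees": n_trees,
            "max_depth": max_depth,
            "seed": seed,
        },
    )


def predict(model: ClassifierModel, features: FeatureStack, threshold: float = 0.5) -> ProbabilityMap:
    """Per-voxel neuron probability for a feature stack.

    Refuses stacks whose configuration fingerprint differs from the one the
    model was trained on.
    """
    model.check_compatible(features.fingerprint)
    shape = features.shape
    X = features.data.reshape(features.data.shape[0], -1).T
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    p_neuron = proba[:, classes.index(1)].reshape(shape).astype(np.float32)
    return ProbabilityMap(probabilities=p_neuron, threshold=threshold)
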