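import numpy as np
import pytest

from stereocount import (
    PhantomSpec,
    apply_deformation,
    generate_phantom,
    generate_region_phantom,
    make_scale_field,
    region_volume,
    sample_annotations,
)
from stereocount.phantom import _place_nuclei


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(target_density=0)
    with pytest.raises(ValueError):
        PhantomSpec(touching_fraction=1.5)
    with pytest.raises(ValueError):
        PhantomSpec(radius_mean_um=-1)


def test_expected_count_below_one_errors():
    with pytest.raises(ValueError, match="enlarge"):
        generate_phantom(PhantomSpec(extent=(2, 2, 2), target_density=100.0))


def test_same_seed_bit_identical():
    spec = PhantomSpec(extent=(12, 40, 40), seed=11)
    v1, t1 = generate_phantom(spec)
    v2, t2 = generate_phantom(spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(t1.labels, t2.labels)
    np.testing.assert_array_equal(t1.centroids_um, t2.centroids_um)


def test_ground_truth_consistency(small_phantom):
    _, truth = small_phantom
    ids = np.unique(truth.labels)
    ids = ids[ids > 0]
    assert truth.count == len(ids) == len(truth.centroids_um) == len(truth.volumes_um3)
    # consecutive labels 1..K
    np.testing.assert_array_equal(ids, np.arange(1, truth.count + 1))


def test_poisson_count_oracle():
    """Mean realized count over 50 seeds sits within 3 SE of the Poisson
    mean lambda = target_density x physical volume."""
    spec = PhantomSpec(extent=(20, 80, 80), seed=0)  # lambda ~ 50
    lam = spec.target_density * spec.physical_volume_mm3
    counts = [generate_phantom(PhantomSpec(extent=spec.extent, seed=s))[1].count
              for s in range(50)]
    se = np.sqrt(lam / len(counts))
    assert abs(np.mean(counts) - lam) < 3 * se


def test_touching_fraction_zero_separation():
    """With touching_fraction=0 every placed pair of centers is farther
    apart than the sum of the two radii."""
    spec = PhantomSpec(extent=(20, 80, 80), touching_fraction=0.0, seed=3)
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_nuclei(
        rng, np.zeros(3), spec.physical_extent_um, spec, spec.target_density
    )
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    rsum = radii[:, None] + radii[None, :]
    off_diag = ~np.eye(len(centers), dtype=bool)
    assert np.all(d[off_diag] > rsum[off_diag])


def test_touching_pairs_are_near_contact():
    spec = PhantomSpec(extent=(20, 80, 80), touching_fraction=1.0, seed=5)
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_nuclei(
        rng, np.zeros(3), spec.physical_extent_um, spec, spec.target_density
    )
    n_pairs = len(centers) // 2
    for k in range(n_pairs):
        c1, c2 = centers[2 * k], centers[2 * k + 1]
        r1, r2 = radii[2 * k], radii[2 * k + 1]
        assert np.linalg.norm(c1 - c2) == pytest.approx(0.9 * (r1 + r2), rel=1e-9)


def test_rendered_volume_matches_analytic_ellipsoid():
    """At fine isotropic spacing the rendered volumes approach
    (4/3) pi a b c."""
    spec = PhantomSpec(
        extent=(60, 60, 60), spacing=(1.0, 1.0, 1.0), target_density=15000.0,
        radius_sd_um=0.0, touching_fraction=0.0, seed=2,
    )
    _, truth = generate_phantom(spec)
    assert truth.count >= 2
    analytic = 4.0 / 3.0 * np.pi * np.prod(truth.semiaxes_um, axis=1)
    # exclude nuclei cut by the volume border
    r = truth.semiaxes_um.max(axis=1)
    inside = np.all(
        (truth.centroids_um > r[:, None] + 1) &
        (truth.centroids_um < np.array(spec.physical_extent_um) - r[:, None] - 1),
        axis=1,
    )
    assert inside.sum() >= 1
    rel = truth.volumes_um3[inside] / analytic[inside]
    assert np.all(np.abs(rel - 1) < 0.15)


# ---------------------------------------------------------------------------
# region phantoms
# ---------------------------------------------------------------------------

def test_region_phantom_single_region_ids():
    _, lm, _ = generate_region_phantom(1, PhantomSpec(extent=(16, 60, 60), seed=1))
    assert set(np.unique(lm.labels)) == {0, 1}


def test_region_phantom_margin_is_zero():
    _, lm, _ = generate_region_phantom(2, PhantomSpec(extent=(16, 70, 70), seed=1))
    assert np.all(lm.labels[:2] == 0) and np.all(lm.labels[-2:] == 0)
    assert np.all(lm.labels[:, :2] == 0) and np.all(lm.labels[:, -2:] == 0)
    assert np.all(lm.labels[:, :, :2] == 0) and np.all(lm.labels[:, :, -2:] == 0)


def test_region_phantom_density_ratio():
    """Regions at densities (d, 2d): ground-truth count ratio within
    Poisson error of 2 (counts pooled over seeds)."""
    n1 = n2 = 0
    for seed in range(4):
        _, lm, truth = generate_region_phantom(
            2, PhantomSpec(extent=(20, 90, 90), seed=seed), density_factors=[1.0, 2.0]
        )
        n1 += int(np.sum(truth.region_ids == 1))
        n2 += int(np.sum(truth.region_ids == 2))
    ratio = n2 / n1
    # se of ratio via delta method
    se = ratio * np.sqrt(1 / n1 + 1 / n2)
    assert abs(ratio - 2.0) < 3 * se


def test_region_phantom_small_region_warns():
    with pytest.warns(UserWarning, match="thinner"):
        generate_region_phantom(
            4, PhantomSpec(extent=(16, 70, 70), seed=1), min_region_edge_um=100.0
        )


def test_region_phantom_invalid_inputs():
    with pytest.raises(ValueError):
        generate_region_phantom(0, PhantomSpec())
    with pytest.raises(ValueError):
        generate_region_phantom(2, PhantomSpec(), density_factors=[1.0])


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def test_deformation_zero_field_identity(small_phantom):
    vol, truth = small_phantom
    field = np.zeros((3, *vol.shape), dtype=np.float32)
    out = apply_deformation(vol.data, field, vol.spacing, mode="intensity")
    np.testing.assert_allclose(out, vol.data, rtol=0, atol=1e-5)
    lab = apply_deformation(truth.labels, field, vol.spacing, mode="labels")
    np.testing.assert_array_equal(lab, truth.labels)


def test_deformation_label_mode_no_new_ids(small_phantom):
    vol, truth = small_phantom
    rng = np.random.default_rng(0)
    field = rng.normal(0, 2.0, size=(3, *vol.shape)).astype(np.float32)
    out = apply_deformation(truth.labels, field, vol.spacing, mode="labels")
    assert set(np.unique(out)) <= set(np.unique(truth.labels))
    assert out.dtype == truth.labels.dtype


def test_deformation_rejects_bad_field(small_phantom):
    vol, _ = small_phantom
    field = np.zeros((3, *vol.shape), dtype=np.float32)
    field[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        apply_deformation(vol.data, field, vol.spacing)
    with pytest.raises(ValueError, match="shape"):
        apply_deformation(vol.data, field[:, :-1], vol.spacing)


def test_uniform_shrink_scales_region_volume():
    """A global shrink by factor s multiplies measured region volume by
    ~s^3, so naive density scales by 1/s^3."""
    shape = (40, 60, 60)
    spacing = (2.0, 2.0, 2.0)
    labels = np.zeros(shape, dtype=np.uint16)
    labels[8:32, 12:48, 12:48] = 1
    s = 0.85
    field = make_scale_field(shape, spacing, s)
    shrunk = apply_deformation(labels, field, spacing, mode="labels")
    v0 = region_volume(labels == 1, spacing)
    v1 = region_volume(shrunk == 1, spacing)
    # one-voxel discretization bound per axis on a (24, 36, 36)-voxel box
    n = np.array([24, 36, 36])
    lo = np.prod((s * n - 1) / n)
    hi = np.prod((s * n + 1) / n)
    assert lo <= v1 / v0 <= hi
    assert v1 / v0 == pytest.approx(s**3, rel=0.08)


# ---------------------------------------------------------------------------
# annotations from ground truth
# ---------------------------------------------------------------------------

def test_sample_annotations_contract(small_phantom):
    _, truth = small_phantom
    ann = sample_annotations(truth, n_nuclei=10, voxels_per_nucleus=4, seed=1)
    assert ann.n_neuron > 0 and ann.n_background > 0
    assert ann.n_background == ann.n_neuron
    # neuron annotations inside instances, background outside
    fg = ann.coords[ann.classes == 1]
    bg = ann.coords[ann.classes == 0]
    assert np.all(truth.labels[fg[:, 0], fg[:, 1], fg[:, 2]] > 0)
    assert np.all(truth.labels[bg[:, 0], bg[:, 1], bg[:, 2]] == 0)
    # covers exactly 10 distinct instances
    covered = np.unique(truth.labels[fg[:, 0], fg[:, 1], fg[:, 2]])
    assert len(covered) == 10


def test_sample_annotations_too_few_instances(small_phantom):
    _, truth = small_phantom
    with pytest.raises(ValueError, match="cannot annotate"):
        sample_annotations(truth, n_nuclei=truth.count + 5)
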