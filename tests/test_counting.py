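import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereocount import (
    PhantomSpec,
    Subvolume,
    VolumeFilterParams,
    cv,
    density,
    derive_filter_params,
    generate_phantom,
    percent_difference,
    summarize_region,
    volume_filter_count,
)
from stereocount.counting import SubvolumeCount, filter_contribution, remove_debris
from stereocount.instances import InstanceLabels, connected_components

from conftest import render_sphere_mask

PARAMS = VolumeFilterParams(v_min=200.0, v_ref=500.0, v_max=1000.0)


def test_params_ordering_validation():
    with pytest.raises(ValueError):
        VolumeFilterParams(v_min=600, v_ref=500, v_max=1000)
    with pytest.raises(ValueError):
        VolumeFilterParams(v_min=0, v_ref=500, v_max=1000)
    with pytest.raises(ValueError):
        VolumeFilterParams(v_min=100, v_ref=1500, v_max=1000)


def test_contribution_rule_examples():
    # {50, 600, 700} -> 0 + 1 + 1 = 2
    assert sum(filter_contribution(v, PARAMS) for v in (50, 600, 700)) == 2
    # fused 1950 um^3 at v_ref 500 -> round(3.9) = 4
    assert filter_contribution(1950, PARAMS) == 4
    # boundary cases
    assert filter_contribution(199.999, PARAMS) == 0
    assert filter_contribution(200.0, PARAMS) == 1
    assert filter_contribution(1000.0, PARAMS) == 1
    assert filter_contribution(1000.001, PARAMS) == 2  # floor of 2
    assert filter_contribution(1249.0, PARAMS) == 2  # round(2.498)


@given(
    v=st.floats(min_value=0, max_value=1e6),
    v_ref=st.floats(min_value=10, max_value=1e4),
    lo=st.floats(min_value=0.01, max_value=1.0),
    hi=st.floats(min_value=1.0, max_value=10.0),
)
@settings(max_examples=200, deadline=None)
def test_contribution_matches_piecewise_oracle(v, v_ref, lo, hi):
    params = VolumeFilterParams(v_min=lo * v_ref, v_ref=v_ref, v_max=hi * v_ref)
    got = filter_contribution(v, params)
    if v < params.v_min:
        expect = 0
    elif v <= params.v_max:
        expect = 1
    else:
        expect = max(2, int(np.floor(v / params.v_ref + 0.5)))
    assert got == expect


def test_contribution_monotone_in_volume():
    vols = np.linspace(0, 5000, 2001)
    contribs = [filter_contribution(v, PARAMS) for v in vols]
    assert all(b >= a for a, b in zip(contribs, contribs[1:]))


def test_volume_filter_degeneracy_vmax_inf():
    params = VolumeFilterParams(v_min=200, v_ref=500, v_max=np.inf)
    vols = [50, 150, 200, 600, 5000, 50000]
    got = sum(filter_contribution(v, params) for v in vols)
    assert got == sum(1 for v in vols if v >= 200)


def test_fused_triple_counted_as_three():
    """A merged component of 3 overlapping nuclei that instance separation
    failed to split contributes ~3 via volume partitioning."""
    spacing = (1.0, 1.0, 1.0)
    r = 6.0
    shape = (30, 44, 30)
    centers = [(15, 12, 15), (15, 12 + 1.4 * r, 15), (15, 12 + 2.8 * r, 15)]
    mask = np.zeros(shape, dtype=bool)
    for c in centers:
        mask |= render_sphere_mask(shape, spacing, c, r)
    inst = connected_components(mask)  # one merged instance
    assert inst.count == 1
    single = render_sphere_mask(shape, spacing, (15, 22, 15), r).sum()
    params = VolumeFilterParams(v_min=0.25 * single, v_ref=float(single), v_max=2 * single)
    count = volume_filter_count(inst, params)
    assert count.filtered_count == 3


def test_windowed_counting_centroid_rule():
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels[1:3, 1:3, 1:3] = 1      # centroid (1.5, 1.5, 1.5) vox
    labels[1:3, 7:9, 7:9] = 2      # centroid outside the window
    inst = InstanceLabels(labels, (1.0, 1.0, 1.0))
    window = Subvolume(origin=(0, 0, 0), extent=(5, 5, 5), spacing=(1.0, 1.0, 1.0))
    params = VolumeFilterParams(v_min=1, v_ref=8, v_max=100)
    count = volume_filter_count(inst, params, window=window)
    assert count.raw_count == 1
    assert count.filtered_count == 1
    assert count.volume_mm3 == pytest.approx(125e-9)


def test_density_arithmetic():
    sub = Subvolume(origin=(0, 0, 0), extent=(25, 56, 56), spacing=(4, 1.8, 1.8))
    c = SubvolumeCount(subvolume=sub, raw_count=30, filtered_count=30,
                       volumes_um3=np.full(30, 500.0), volume_mm3=sub.volume_mm3)
    # realized denominator is 100 x 100.8 x 100.8 um^3, not (100 um)^3
    assert c.volume_mm3 == pytest.approx(100 * 100.8 * 100.8 * 1e-9)
    assert density(c) == pytest.approx(30 / (100 * 100.8 * 100.8 * 1e-9))
    c0 = SubvolumeCount(subvolume=sub, raw_count=0, filtered_count=0,
                        volumes_um3=np.zeros(0), volume_mm3=1e-3)
    assert density(c0) == 0.0


def test_density_exact_cube():
    c = SubvolumeCount(subvolume=None, raw_count=30, filtered_count=30,
                       volumes_um3=np.zeros(30), volume_mm3=1e-3)
    assert density(c) == pytest.approx(30000.0)


def _count(d, region=1):
    sub = Subvolume(origin=(0, 0, 0), extent=(10, 10, 10),
                    spacing=(10.0, 10.0, 10.0), region_id=region)
    return SubvolumeCount(subvolume=sub, raw_count=int(d * 1e-3),
                          filtered_count=int(d * 1e-3), volumes_um3=np.zeros(0),
                          volume_mm3=1e-3)


def test_summarize_mean_and_sample_sd():
    counts = [_count(d) for d in (10000, 20000, 30000)]
    s = summarize_region(counts, region_volume_mm3=2.0)
    assert s.mean_density == pytest.approx(20000.0)
    assert s.sd_density == pytest.approx(10000.0)  # sample SD, n-1
    assert s.estimated_total == 40000
    assert s.n_subvolumes == 3


def test_summarize_identical_densities_sd_zero():
    s = summarize_region([_count(15000)] * 3, region_volume_mm3=1.0)
    assert s.sd_density == 0.0


def test_summarize_requires_two_subvolumes():
    with pytest.raises(ValueError, match="at least 2"):
        summarize_region([_count(1000)], 1.0)


def test_summarize_mixed_regions_error():
    with pytest.raises(ValueError, match="mix"):
        summarize_region([_count(1000, region=1), _count(1000, region=2)], 1.0)


def test_total_estimate_poisson_oracle():
    """Ground-truth path on a phantom at known lambda: estimated total
    within 3 sqrt(lambda V) of the true count."""
    spec = PhantomSpec(seed=21)
    _, truth = generate_phantom(spec)
    inst = InstanceLabels(truth.labels.astype(np.int32), spec.spacing)
    params = derive_filter_params(inst.volumes_um3)
    from stereocount import region_volume, sample_subvolumes

    mask = np.ones(spec.extent, dtype=bool)
    plan = sample_subvolumes(mask, spec.spacing, n=15, edge_um=100, seed=21)
    counts = [volume_filter_count(inst, params, window=s) for s in plan.subvolumes]
    s = summarize_region(counts, region_volume(mask, spec.spacing), region_id=0)
    lam = spec.target_density * spec.physical_volume_mm3
    assert abs(s.estimated_total - truth.count) < 3 * np.sqrt(lam)


# ---------------------------------------------------------------------------
# cv / percent difference
# ---------------------------------------------------------------------------

def test_cv_examples():
    assert cv([1, 1, 1]) == 0.0
    assert cv([2, 4]) == pytest.approx(np.sqrt(2) / 3)


def test_cv_errors():
    with pytest.raises(ValueError):
        cv([5.0])
    with pytest.raises(ValueError):
        cv([-1.0, 1.0])


def test_cv_concentrates_on_poisson_prediction(rng):
    """Per-specimen mean densities simulated as averages of n Poisson
    subvolume counts: CV approaches 1/sqrt(n lambda) as n grows."""
    lam, vol = 30.0, 1e-3
    for n, tol in ((10, 0.5), (100, 0.35)):
        cvs = []
        for _ in range(40):
            specimens = rng.poisson(lam, size=(6, n)).mean(axis=1) / vol
            cvs.append(cv(specimens))
        predicted = 1 / np.sqrt(n * lam)
        assert np.median(cvs) == pytest.approx(predicted, rel=tol)


def test_percent_difference_examples():
    assert percent_difference(1.07, 1.00) == pytest.approx(7.0)
    assert percent_difference(5.0, 5.0) == 0.0
    assert percent_difference(0.5, 1.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        percent_difference(1.0, 0.0)


# ---------------------------------------------------------------------------
# derived parameters, debris removal, invariants
# ---------------------------------------------------------------------------

def test_derive_filter_params_robust_to_debris(rng):
    nuclei = rng.normal(550, 60, size=50)
    debris = rng.uniform(5, 30, size=300)  # debris outnumbers nuclei 6:1
    params = derive_filter_params(np.r_[nuclei, debris])
    assert 400 < params.v_ref < 700
    assert params.v_min == pytest.approx(0.25 * params.v_ref)
    assert params.v_max == pytest.approx(2.0 * params.v_ref)


def test_derive_filter_params_empty():
    with pytest.raises(ValueError):
        derive_filter_params([])


def test_remove_debris(small_phantom):
    _, truth = small_phantom
    inst = InstanceLabels(truth.labels.astype(np.int32), (4, 1.8, 1.8))
    params = VolumeFilterParams(v_min=np.median(inst.volumes_um3), v_ref=1e4, v_max=1e5)
    cleaned = remove_debris(inst, params)
    assert cleaned.count == np.sum(inst.volumes_um3 >= params.v_min)
    assert np.all(cleaned.volumes_um3 >= params.v_min)


def test_adding_a_neuron_never_decreases_count():
    vols = [300.0, 700.0, 1500.0]
    base = sum(filter_contribution(v, PARAMS) for v in vols)
    for extra in (250.0, 600.0, 2000.0):
        assert sum(filter_contribution(v, PARAMS) for v in vols + [extra]) >= base


def test_unit_scale_invariance():
    """Consistent rescaling of spacing and filter volumes leaves the
    filtered count unchanged and scales density by the cube factor."""
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[2:5, 2:5, 2:5] = 1
    f = 10.0  # e.g. re-expressing um as 100-nm units
    inst_um = InstanceLabels(labels, (1.0, 1.0, 1.0))
    inst_scaled = InstanceLabels(labels, (f, f, f))
    p_um = VolumeFilterParams(10.0, 20.0, 40.0)
    p_scaled = VolumeFilterParams(10.0 * f**3, 20.0 * f**3, 40.0 * f**3)
    c_um = volume_filter_count(inst_um, p_um)
    c_scaled = volume_filter_count(inst_scaled, p_scaled)
    assert c_um.filtered_count == c_scaled.filtered_count
    assert c_um.density == pytest.approx(c_scaled.density * f**3)
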