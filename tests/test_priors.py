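"""Atlas construction: interface/skeleton/intensity/volume priors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from massp.geometry import signed_distance
from massp.grids import LabelVolume, ScalarVolume, VolumeGrid
from massp.priors import (
    build_atlas,
    build_intensity_histograms,
    build_volume_priors,
    dense_interface_priors,
    interface_distance,
    rescale_factor,
    robust_stats,
    sampling_region,
    sparsify_top_k,
)

from conftest import mini_phantom_spec
from massp.phantom import make_cohort


def test_interface_distance_hand_values():
    phi_i = np.full((1, 1, 1), -0.3)
    phi_j = np.full((1, 1, 1), 0.4)
    d = interface_distance(phi_i, phi_j, delta=1.0)
    assert d[0, 0, 0] == pytest.approx(-0.3)  # max(-0.3, -0.6): in the band
    d_far = interface_distance(np.full((1, 1, 1), -5.0), np.full((1, 1, 1), 6.0), 1.0)
    assert d_far[0, 0, 0] == pytest.approx(5.0)  # outside the band
    d_same = interface_distance(phi_i, phi_i, delta=1.0, same=True)
    assert np.array_equal(d_same, phi_i)  # i == i: the whole interior


def test_interface_distance_printed_form_is_nonpositive(rng):
    phi_i = rng.normal(size=(6, 6, 6))
    phi_j = rng.normal(size=(6, 6, 6))
    d = interface_distance(phi_i, phi_j, form="printed")
    assert (d <= 0).all()


def test_interface_distance_contracts():
    with pytest.raises(ValueError):
        interface_distance(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))
    with pytest.raises(ValueError):
        interface_distance(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), delta=0.0)


def test_identical_delineations_give_sigma_delta(mini_cohort):
    """With N identical subjects the variance term vanishes: sigma = delta
    and the prior peaks exactly on the band surface (mu = 0)."""
    truth = mini_cohort[0].truth
    phis = np.stack(
        [np.stack([signed_distance(truth.labels == i) for i in (1, 2, 3)])] * 3
    )
    dense = dense_interface_priors(phis, delta=1.0)
    peak = 1.0 / np.sqrt(2 * np.pi)  # value of the Gaussian form at mu=0, sigma=1
    code = 0  # pair (1, 1): d = phi_1, zero on the boundary of structure 1
    d0 = phis[0, 0]
    near_zero = np.abs(d0) < 0.05
    if near_zero.any():
        assert dense[..., code][near_zero].max() == pytest.approx(peak, rel=0.05)
    assert dense.max() <= peak + 1e-12


def test_sparse_top_k_matches_dense_oracle(mini_cohort):
    ids = [1, 2, 3]
    phis = np.stack(
        [
            np.stack([signed_distance(s.truth.labels == i) for i in ids])
            for s in mini_cohort
        ]
    )
    dense = dense_interface_priors(phis, delta=1.0)
    for k in (2, 4):
        vals, codes = sparsify_top_k(dense, k)
        expect = -np.sort(-dense, axis=-1)[..., :k]
        assert np.allclose(vals[..., :k], expect)
        # kept codes point at entries with the kept values
        flat_d = dense.reshape(-1, dense.shape[-1])
        flat_v = vals.reshape(-1, k)
        flat_c = codes.reshape(-1, k)
        sel = flat_c >= 0
        assert np.allclose(
            flat_d[np.arange(flat_d.shape[0])[:, None].repeat(k, 1)[sel], flat_c[sel]],
            flat_v[sel],
        )


def test_rescale_is_a_fixed_point(rng):
    vmax = rng.random(10000)
    f = rescale_factor(vmax)
    scaled = vmax * f
    assert np.percentile(scaled, 95) == pytest.approx(0.95, abs=1e-9)
    assert rescale_factor(scaled) == pytest.approx(1.0, abs=1e-12)


def test_atlas_clip_property_and_rescale(mini_atlas):
    s = mini_atlas.n_structures
    region = mini_atlas.region
    vmax = mini_atlas.prior_values[..., 0][region]
    assert np.percentile(vmax, 95) == pytest.approx(0.95, abs=1e-9)
    for a in range(s):
        code = a * s + a
        hit = mini_atlas.prior_pairs == code
        b_ii = np.where(hit, mini_atlas.prior_values, 0.0).sum(axis=-1)
        excess = mini_atlas.skeleton_priors[..., a] > b_ii + 1e-15
        assert int(excess.sum()) == 0


def test_priors_translation_equivariance():
    spec = mini_phantom_spec(3)
    cohort = make_cohort(spec, 3)
    ids = [1, 2, 3]
    phis = np.stack(
        [
            np.stack([signed_distance(s.truth.labels == i) for i in ids])
            for s in cohort
        ]
    )
    shift = (2, 0, 0)
    phis_shifted = np.roll(phis, shift, axis=(2, 3, 4))
    d1 = dense_interface_priors(phis, 1.0)
    d2 = dense_interface_priors(phis_shifted, 1.0)
    interior = np.zeros(d1.shape[:3], bool)
    interior[4:-4, 4:-4, 4:-4] = True  # away from wrap-around faces
    assert np.allclose(np.roll(d1, shift, axis=(0, 1, 2))[interior], d2[interior])


def test_robust_stats_values():
    loc, scale = robust_stats(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert loc == pytest.approx(3.0)
    assert scale == pytest.approx(2.0 / 1.349, rel=1e-12)


def test_robust_scale_estimates_normal_sigma(rng):
    x = rng.standard_normal(100_000)
    _, scale = robust_stats(x)
    assert scale == pytest.approx(1.0, abs=0.02)


def test_robust_stats_degenerate_and_errors():
    _, scale = robust_stats(np.array([2.0, 2.0, 2.0]))
    assert scale > 0  # floored, no downstream division by zero
    with pytest.raises(ValueError):
        robust_stats(np.array([1.0]))


@settings(derandomize=True, max_examples=25)
@given(
    st.lists(st.floats(-100, 100), min_size=2, max_size=50),
    st.floats(0.1, 10),
    st.floats(-50, 50),
)
def test_robust_stats_affine_equivariance(values, a, b):
    from hypothesis import assume

    loc, scale = robust_stats(np.array(values))
    assume(scale > 1e-5)  # away from the degenerate-sample floor
    loc2, scale2 = robust_stats(a * np.array(values) + b)
    assert loc2 == pytest.approx(a * loc + b, rel=1e-9, abs=1e-9)
    assert scale2 == pytest.approx(max(a * scale, 1e-6), rel=1e-9, abs=1e-9)


def _two_ball_cohort(v1: float, v2: float):
    grid = VolumeGrid.isotropic(16)
    labels = np.zeros((16, 16, 16), int)
    labels[3:6, 3:6, 3:6] = 1
    labels[9:13, 9:13, 9:13] = 2
    lv = LabelVolume(grid, labels)
    c1 = np.where(labels == 1, v1, np.where(labels == 2, v2, 0.1))
    return lv, c1


def test_histograms_disjoint_intensities_disjoint_support():
    lv, img = _two_ball_cohort(5.0, 9.0)
    subj = [[ScalarVolume(lv.grid, img)], [ScalarVolume(lv.grid, img)]]
    phis = np.stack(
        [np.stack([signed_distance(lv.labels == i) for i in (1, 2)])] * 2
    )
    region = sampling_region([lv, lv], 10.0)
    hist, ranges, sigmas = build_intensity_histograms(subj, phis, region, n_bins=50)
    h11 = hist[0, 0]  # pair (1,1)
    h22 = hist[3, 0]  # pair (2,2)
    assert h11.any() and h22.any()
    assert not np.any((h11 > 0) & (h22 > 0))
    # structures are far apart: cross-pair bands are empty
    assert not hist[1, 0].any() and not hist[2, 0].any()


def test_histogram_fusion_is_geometric_mean():
    from massp.priors import fused_likelihood

    h = np.array([[0.2, 0.8, 1.0], [0.5, 1.0, 0.1], [1.0, 0.4, 0.9]])
    bins = np.array([[1], [0], [2]])
    out = fused_likelihood(h, bins)
    assert out[0] == pytest.approx((0.8 * 0.5 * 0.9) ** (1 / 3))


def test_histogram_zero_range_rejected():
    lv, _ = _two_ball_cohort(5.0, 9.0)
    flat = [[ScalarVolume(lv.grid, np.ones((16, 16, 16)))]] * 2
    phis = np.stack(
        [np.stack([signed_distance(lv.labels == i) for i in (1, 2)])] * 2
    )
    region = sampling_region([lv, lv], 10.0)
    with pytest.raises(ValueError, match="range"):
        build_intensity_histograms(flat, phis, region)


def test_volume_prior_constant_case():
    lv, _ = _two_ball_cohort(1, 2)
    mu, sigma = build_volume_priors([lv, lv])
    assert mu[0] == pytest.approx(np.log(27.0))  # 3^3 voxels of 1 mm^3
    assert (sigma > 0).all()


def test_volume_prior_voxel_scaling_law():
    grid2 = VolumeGrid((16, 16, 16), (2.0, 1.0, 1.0), np.diag([2.0, 1, 1, 1]))
    labels = np.zeros((16, 16, 16), int)
    labels[3:6, 3:6, 3:6] = 1
    lv1, _ = _two_ball_cohort(1, 2)
    lv2 = LabelVolume(grid2, np.where(labels == 1, 1, np.where(lv1.labels == 2, 2, 0)))
    mu1, _ = build_volume_priors([lv1, lv1])
    mu2, _ = build_volume_priors([lv2, lv2])
    assert mu2[0] - mu1[0] == pytest.approx(np.log(2.0))


def test_cohort_contract_errors(mini_cohort):
    with pytest.raises(ValueError, match="at least 2"):
        build_volume_priors([mini_cohort[0].truth])
    # a subject missing one structure is rejected
    bad = mini_cohort[0].truth
    stripped = LabelVolume(
        bad.grid, np.where(bad.labels == 3, 0, bad.labels), {1: "a", 2: "b", 3: "c"}
    )
    with pytest.raises(ValueError, match="empty in one subject|same structures"):
        build_volume_priors([stripped, mini_cohort[1].truth])


def test_build_atlas_relabel_permutation_invariance(mini_cohort):
    """Renaming structure ids permutes the prior entries but not their
    content."""
    perm = {1: 5, 2: 1, 3: 2}
    relabeled = []
    for s in mini_cohort[:3]:
        lab = np.zeros_like(s.truth.labels)
        for old, new in perm.items():
            lab[s.truth.labels == old] = new
        relabeled.append(LabelVolume(s.truth.grid, lab))
    a1 = build_atlas(
        [s.truth for s in mini_cohort[:3]], [s.contrasts for s in mini_cohort[:3]]
    )
    a2 = build_atlas(relabeled, [s.contrasts for s in mini_cohort[:3]])
    # structure order: a1 ids (1,2,3) -> a2 ids sorted (1,2,5) = old (2,3,1)
    old_for_new = {new: old for old, new in perm.items()}
    for new_idx, new_id in enumerate(a2.structure_ids):
        old_idx = a1.structure_index(old_for_new[new_id])
        assert np.allclose(
            a2.skeleton_priors[..., new_idx], a1.skeleton_priors[..., old_idx]
        )
        assert np.allclose(a2.mu_logv[new_idx], a1.mu_logv[old_idx])
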