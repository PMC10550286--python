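"""Voxel-wise group models, cluster correction, and ROI extraction."""

import numpy as np
import pytest

from nrplast.group import (
    PlasticityGLM,
    cohens_f,
    find_clusters,
    roi_extract,
    sphere_roi_mask,
    stack_nrp_maps,
    two_sample_nrp_map,
)
from nrplast.nrp import NRPMap

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def make_maps(rng, n, mask, offset=0.0, per_subject=None):
    maps = []
    for i in range(n):
        vol = np.full(mask.shape, np.nan)
        vals = rng.standard_normal(int(mask.sum())) + offset
        if per_subject is not None:
            vals = per_subject[i] + 0 * vals
        vol[mask] = vals
        maps.append(NRPMap(nrp=vol, valid=mask.copy(), affine=AFF))
    return maps


@pytest.fixture(scope="module")
def small_mask():
    m = np.zeros((12, 12, 12), bool)
    m[2:10, 2:10, 2:10] = True
    return m


def test_stack_requires_matching_geometry(small_mask, rng):
    maps = make_maps(rng, 3, small_mask)
    other = NRPMap(nrp=np.zeros((10, 10, 10)), valid=np.ones((10, 10, 10), bool), affine=AFF)
    with pytest.raises(ValueError):
        stack_nrp_maps([maps[0], other])
    Y, mask, _ = stack_nrp_maps(maps)
    assert Y.shape == (3, int(small_mask.sum()))
    assert np.array_equal(mask, small_mask)


def test_two_sample_identical_groups_t_zero(small_mask, rng):
    maps = make_maps(rng, 4, small_mask)
    res = two_sample_nrp_map(maps, [NRPMap(m.nrp.copy(), m.valid.copy(), m.affine)
                                    for m in maps])
    np.testing.assert_allclose(res.t["group"][res.mask], 0.0, atol=1e-12)


def test_two_sample_constant_shift_monotone_t(small_mask, rng):
    base = make_maps(rng, 6, small_mask)
    res_small = two_sample_nrp_map(
        [NRPMap(m.nrp + 0.5, m.valid, m.affine) for m in base], base)
    res_big = two_sample_nrp_map(
        [NRPMap(m.nrp + 2.0, m.valid, m.affine) for m in base], base)
    t_small = res_small.t["group"][res_small.mask]
    t_big = res_big.t["group"][res_big.mask]
    assert (t_small > 0).all() and (t_big > t_small).all()


def test_two_sample_null_voxel_calibration(default_mask):
    """Same-distribution groups: ~0.5% of voxels reach p < 0.005."""
    rng = np.random.default_rng(77)
    maps = make_maps(rng, 30, default_mask)
    res = two_sample_nrp_map(maps[:15], maps[15:])
    frac = float((res.p["group"][res.mask] < 0.005).mean())
    V = int(res.mask.sum())
    se = np.sqrt(0.005 * 0.995 / V)
    assert abs(frac - 0.005) < 3 * se


def test_two_sample_subject_order_invariance(small_mask, rng):
    a = make_maps(rng, 5, small_mask)
    b = make_maps(rng, 5, small_mask, offset=0.3)
    res = two_sample_nrp_map(a, b)
    res_perm = two_sample_nrp_map(a[::-1], b[::-1])
    np.testing.assert_allclose(res.t["group"][res.mask],
                               res_perm.t["group"][res_perm.mask])


# ---------------------------------------------------------------------------
# interaction GLM
# ---------------------------------------------------------------------------

def test_interaction_glm_exact_on_noise_free_construction(small_mask):
    """NRP = 1 * gain in both groups: gain coefficient 1, interaction 0."""
    rng = np.random.default_rng(5)
    n = 16
    gains = rng.normal(0.1, 0.2, n)
    groups = np.array(["ASD"] * 8 + ["TD"] * 8)
    maps = make_maps(rng, n, small_mask, per_subject=gains)
    res = PlasticityGLM(maps, groups, gains).fit()
    np.testing.assert_allclose(res.beta["gain"][res.mask], 1.0, atol=1e-10)
    np.testing.assert_allclose(res.beta["group:gain"][res.mask], 0.0, atol=1e-10)


def test_interaction_glm_single_voxel_matches_statsmodels(rng):
    """On 1-voxel maps the fit reduces to a standard moderated regression."""
    import statsmodels.api as sm

    n = 24
    mask = np.ones((1, 1, 1), bool)
    gains = rng.normal(0.05, 0.15, n)
    groups = np.array(["ASD"] * 12 + ["TD"] * 12)
    y = rng.standard_normal(n)
    maps = [NRPMap(nrp=np.full((1, 1, 1), y[i]), valid=mask.copy(), affine=AFF)
            for i in range(n)]
    model = PlasticityGLM(maps, groups, gains)
    res = model.fit()
    g = (groups == "ASD").astype(float)
    gc = gains - gains.mean()
    X = sm.add_constant(np.column_stack([g, gc, g * gc]))
    ref = sm.OLS(y, X).fit()
    for j, term in enumerate(["intercept", "group", "gain", "group:gain"]):
        assert res.beta[term][0, 0, 0] == pytest.approx(ref.params[j])
        assert res.t[term][0, 0, 0] == pytest.approx(ref.tvalues[j])
        assert res.p[term][0, 0, 0] == pytest.approx(ref.pvalues[j])
    slopes = model.simple_slopes(res)
    assert slopes["TD"][0, 0, 0] == pytest.approx(ref.params[2])
    assert slopes["ASD"][0, 0, 0] == pytest.approx(ref.params[2] + ref.params[3])


def test_interaction_glm_rejects_degenerate_gain(small_mask, rng):
    maps = make_maps(rng, 8, small_mask)
    groups = np.array(["ASD"] * 4 + ["TD"] * 4)
    gains = np.array([0.1, 0.1, 0.1, 0.1, 0.0, 0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="zero gain variance"):
        PlasticityGLM(maps, groups, gains)


def test_interaction_glm_permuted_gain_null_calibration(default_mask):
    """Shuffling gains across subjects leaves a ~nominal interaction type I rate."""
    rng = np.random.default_rng(11)
    n = 40
    groups = np.array(["ASD"] * 20 + ["TD"] * 20)
    gains = rng.normal(0.05, 0.15, n)
    maps = make_maps(rng, n, default_mask)
    res = PlasticityGLM(maps, groups, rng.permutation(gains)).fit()
    frac = float((res.p["group:gain"][res.mask] < 0.05).mean())
    V = int(res.mask.sum())
    se = np.sqrt(0.05 * 0.95 / V)
    assert abs(frac - 0.05) < 3 * se


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def test_find_clusters_empty_on_null_map(small_mask):
    t_vol = np.zeros(small_mask.shape)
    assert find_clusters(t_vol, 3.0, AFF) == []


def test_cluster_correct_positive_control(small_mask):
    """A compact t~6 blob amid null noise is the unique significant cluster."""
    rng = np.random.default_rng(42)
    blob = np.zeros(small_mask.shape, bool)
    blob[4:9, 4:9, 4:8] = True  # 200 voxels
    blob &= small_mask
    n = 30
    offsets = np.where(blob, 3.0, 0.0)  # ~t=6 at n=15/group, sd 1
    maps = []
    for i in range(n):
        vol = np.full(small_mask.shape, np.nan)
        noise = rng.standard_normal(small_mask.shape)
        vol[small_mask] = (noise + (offsets if i < 15 else 0.0))[small_mask]
        maps.append(NRPMap(nrp=vol, valid=small_mask.copy(), affine=AFF))
    res = two_sample_nrp_map(maps[:15], maps[15:])
    sig = res.cluster_correct("group", n_perm=200, seed=9)
    assert len(sig) == 1
    assert blob[sig[0].peak_voxel]
    assert sig[0].extent >= blob.sum() * 0.8
    # corrected p monotone nonincreasing in extent among all clusters
    allc = res.cluster_correct("group", n_perm=200, seed=9, return_all=True)
    by_extent = sorted(allc, key=lambda c: c.extent)
    ps = [c.corrected_p for c in by_extent]
    assert all(p2 <= p1 for p1, p2 in zip(ps, ps[1:]))


def test_cluster_correct_requires_seed_and_min_perms(small_mask, rng):
    maps = make_maps(rng, 8, small_mask)
    res = two_sample_nrp_map(maps[:4], maps[4:])
    with pytest.raises(ValueError):
        res.cluster_correct("group", n_perm=50, seed=1)
    with pytest.raises(ValueError):
        res.cluster_correct("group", n_perm=200, seed=None)


# ---------------------------------------------------------------------------
# effect size and ROI extraction
# ---------------------------------------------------------------------------

def test_cohens_f_identity():
    assert cohens_f(0.44) == pytest.approx(np.sqrt(0.44 / 0.56))
    with pytest.raises(ValueError):
        cohens_f(1.0)


def test_roi_extract_uniform_sphere_and_enumeration(small_mask, rng):
    c_vol = np.where(small_mask, 1.7, np.nan)
    m = NRPMap(nrp=c_vol, valid=small_mask.copy(), affine=AFF)
    center_mm = AFF[:3, :3] @ np.array([6, 6, 6]) + AFF[:3, 3]
    assert roi_extract(m, center_mm=center_mm) == pytest.approx(1.7)
    # enumeration oracle on a random map
    vol = np.full(small_mask.shape, np.nan)
    vol[small_mask] = rng.standard_normal(int(small_mask.sum()))
    m2 = NRPMap(nrp=vol, valid=small_mask.copy(), affine=AFF)
    roi = sphere_roi_mask(small_mask.shape, AFF, center_mm, 6.0)
    picked = [vol[tuple(ix)] for ix in np.argwhere(roi & small_mask)]
    assert roi_extract(m2, center_mm=center_mm) == pytest.approx(np.mean(picked))
    # sphere fully outside the mask
    with pytest.raises(ValueError):
        roi_extract(m2, center_mm=(-100.0, -100.0, -100.0))
    with pytest.raises(ValueError):
        roi_extract(m2)  # neither center nor mask
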