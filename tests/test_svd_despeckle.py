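import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cmi3dsvd.block_matching import PatchGroup
from cmi3dsvd.svd_despeckle import (
    LogGroup,
    despeckle_group,
    destensorize,
    estimate_sigma_log,
    exp_transform,
    log_transform,
    shrinkage_weights,
    svd_soft_threshold,
)

from helpers import destensorize_oracle, svd_soft_threshold_oracle


def make_group(tensor, origins=None, scores=None, cluster_id=0):
    tensor = np.asarray(tensor, dtype=float)
    k = tensor.shape[2]
    if origins is None:
        origins = tuple((0, i) for i in range(k))
    if scores is None:
        scores = (1.0,) + tuple(0.5 for _ in range(k - 1))
    return PatchGroup(tensor=tensor, origins=tuple(origins),
                      mi_scores=tuple(scores), cluster_id=cluster_id)


class TestLogTransform:
    def test_zero_pixel_offset_one(self):
        g = make_group(np.zeros((5, 5, 1)))
        assert log_transform(g, offset=1.0).matrix.max() == 0.0

    def test_round_trip(self, rng):
        t = rng.uniform(0, 255, size=(5, 5, 3))
        g = make_group(t)
        lg = log_transform(g, offset=1.0)
        np.testing.assert_allclose(exp_transform(lg), t, atol=1e-12)

    def test_multiplicative_becomes_additive(self, rng):
        y = rng.uniform(1, 200, size=(5, 5, 2))
        s = rng.uniform(0.5, 2.0, size=(5, 5, 2))
        lg_prod = log_transform(make_group(y * s), offset=0.0)
        lg_y = log_transform(make_group(y), offset=0.0)
        lg_s = log_transform(make_group(s), offset=0.0)
        np.testing.assert_allclose(lg_prod.matrix, lg_y.matrix + lg_s.matrix,
                                   atol=1e-10)

    def test_negative_intensity_raises(self):
        with pytest.raises(ValueError):
            log_transform(make_group(np.full((5, 5, 1), -1.0)))

    def test_unfolding_is_column_major(self):
        # guard the documented unfolding convention (column m <-> slice m)
        g = PatchGroup(np.arange(18.0).reshape(3, 3, 2, order="F"),
                       ((0, 0), (0, 1)), (1.0, 0.5))
        lg = log_transform(g, offset=1.0)
        for m in range(2):
            np.testing.assert_allclose(
                lg.matrix[:, m], np.log(g.tensor[:, :, m].ravel(order="F") + 1.0))


class TestEstimateSigmaLog:
    def test_zero(self):
        assert estimate_sigma_log(0.0) == 0.0

    def test_small_sigma_first_order(self, rng):
        est = estimate_sigma_log(0.1)
        # independent Monte-Carlo oracle with a different RNG stream
        g = rng.standard_normal(10**6)
        oracle = np.log(np.maximum(1 + 0.1 * g, 1e-2)).std()
        assert est == pytest.approx(oracle, rel=0.05)
        assert est == pytest.approx(0.1, rel=0.05)

    def test_monotone_in_sigma(self):
        values = [estimate_sigma_log(s) for s in (0.1, 0.3, 0.6, 1.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            estimate_sigma_log(-0.1)


class TestShrinkageWeights:
    def test_zero_sigma_no_shrinkage(self):
        w = shrinkage_weights(np.array([5.0, 3.0, 1.0]), 0.0, k=8).w
        np.testing.assert_array_equal(w, 0.0)

    def test_noise_dominated_component_blows_up(self):
        s = np.array([10.0, 0.1])
        w = shrinkage_weights(s, sigma_log=0.5, k=8, r=1.0).w
        # s[1]^2 = 0.01 <= k sigma^2 = 2 -> weight ~ sigma^2 sqrt(k)/eps
        assert w[1] > 1e10
        assert w[1] > s[1]

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10),
           st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing_over_descending_spectrum(self, vals, sigma):
        s = np.sort(np.array(vals))[::-1]
        w = shrinkage_weights(s, sigma_log=sigma, k=4).w
        assert (np.diff(w) >= -1e-12).all()

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            shrinkage_weights(np.array([1.0, 5.0]), 0.1, k=4)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            shrinkage_weights(np.array([-1.0]), 0.1, k=4)


class Weights:
    """Minimal stand-in so svd_soft_threshold can be driven directly."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)


class TestSvdSoftThreshold:
    def test_zero_weights_identity(self, rng):
        m = rng.standard_normal((25, 8))
        np.testing.assert_allclose(svd_soft_threshold(m, Weights(np.zeros(8))),
                                   m, atol=1e-10)

    def test_rank1_full_shrinkage(self):
        m = np.outer(np.ones(5), np.arange(1.0, 4.0))
        s1 = np.linalg.svd(m, compute_uv=False)[0]
        out = svd_soft_threshold(m, Weights(np.full(3, s1 + 1)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_diagonal_case(self):
        m = np.diag([5.0, 3.0, 1.0])
        out = svd_soft_threshold(m, Weights([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out, np.diag([3.0, 1.0, 0.0]), atol=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            m = rng.standard_normal((25, 8))
            w = np.sort(rng.uniform(0, 2, size=8))
            out = svd_soft_threshold(m, Weights(w))
            oracle = svd_soft_threshold_oracle(m, w)
            assert np.linalg.norm(out - oracle) < 1e-8

    @given(arrays(np.float64, (6, 4), elements=st.floats(-50, 50)),
           st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_never_increases_energy_or_singulars(self, m, w_val):
        w = Weights(np.full(4, w_val))
        out = svd_soft_threshold(m, w)
        assert np.linalg.norm(out) <= np.linalg.norm(m) + 1e-9
        s_in = np.linalg.svd(m, compute_uv=False)
        s_out = np.linalg.svd(out, compute_uv=False)
        assert (s_out <= s_in + 1e-9).all()

    def test_nonfinite_raises(self):
        m = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            svd_soft_threshold(m, Weights(np.zeros(3)))


class TestDespeckleGroup:
    def test_sigma_zero_noop(self, rng):
        t = rng.uniform(0, 255, size=(5, 5, 6))
        g = make_group(t)
        out = despeckle_group(g, sigma_speckle=0.0)
        np.testing.assert_allclose(out.tensor, t, atol=1e-8)
        assert out.origins == g.origins
        assert out.mi_scores == g.mi_scores

    def test_denoising_gain_on_identical_patches(self, rng):
        clean = rng.uniform(40, 200, size=(5, 5))
        k = 12
        noisy = np.stack(
            [clean * np.maximum(1 + 0.2 * rng.standard_normal((5, 5)), 0)
             for _ in range(k)], axis=-1)
        g = make_group(noisy)
        out = despeckle_group(g, sigma_speckle=0.2)
        err_in = np.mean([np.linalg.norm(noisy[:, :, m] - clean) for m in range(k)])
        err_out = np.mean([np.linalg.norm(out.tensor[:, :, m] - clean) for m in range(k)])
        assert err_out < err_in

    def test_output_nonnegative(self, rng):
        t = rng.uniform(0, 30, size=(5, 5, 4))
        out = despeckle_group(make_group(t), sigma_speckle=0.8)
        assert out.tensor.min() >= 0.0


class TestDestensorize:
    @pytest.mark.filterwarnings("ignore:.*covered by no group")
    def test_single_slice_placement(self, rng):
        patch = rng.uniform(0, 255, size=(5, 5, 1))
        g = make_group(patch, origins=((2, 3),), scores=(1.0,))
        out = destensorize([g], (10, 12), fallback=np.zeros((10, 12)))
        np.testing.assert_array_equal(out[2:7, 3:8], patch[:, :, 0])
        assert out[0, 0] == 0.0

    def test_identical_overlapping_slices(self):
        t = np.full((5, 5, 2), 33.0)
        g = make_group(t, origins=((0, 0), (0, 2)), scores=(1.0, 0.4))
        out = destensorize([g], (5, 7))
        np.testing.assert_allclose(out, 33.0, atol=1e-12)

    @pytest.mark.filterwarnings("ignore:.*covered by no group")
    def test_matches_per_pixel_oracle(self, rng):
        groups = []
        for _ in range(5):
            k = int(rng.integers(1, 5))
            origins = [(int(rng.integers(0, 12)), int(rng.integers(0, 12)))]
            seen = set(origins)
            while len(origins) < k:
                o = (int(rng.integers(0, 12)), int(rng.integers(0, 12)))
                if o not in seen:
                    origins.append(o)
                    seen.add(o)
            scores = (1.0,) + tuple(rng.uniform(0, 1, size=k - 1))
            groups.append(make_group(rng.uniform(0, 255, size=(5, 5, k)),
                                     origins=origins, scores=scores))
        fallback = rng.uniform(0, 255, size=(16, 16))
        out = destensorize(groups, (16, 16), fallback=fallback)
        oracle = destensorize_oracle(groups, (16, 16), fallback=fallback)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    @pytest.mark.filterwarnings("ignore:.*covered by no group")
    def test_zero_weight_pixels_fall_back_to_mean(self, rng):
        # second slice has NMI=1 -> q=0; its exclusive footprint must use
        # the unweighted mean instead of 0/0
        t = np.stack([np.full((5, 5), 10.0), np.full((5, 5), 70.0)], axis=-1)
        g = make_group(t, origins=((0, 0), (8, 8)), scores=(1.0, 1.0))
        out = destensorize([g], (13, 13), fallback=np.zeros((13, 13)))
        assert out[10, 10] == pytest.approx(70.0)
        assert out[2, 2] == pytest.approx(10.0)

    def test_uncovered_pixels_warn_and_copy_fallback(self, rng):
        g = make_group(rng.uniform(0, 255, size=(5, 5, 1)),
                       origins=((0, 0),), scores=(1.0,))
        fallback = np.full((10, 10), 42.0)
        with pytest.warns(UserWarning, match="no group"):
            out = destensorize([g], (10, 10), fallback=fallback)
        assert out[9, 9] == 42.0

    @pytest.mark.filterwarnings("ignore:.*covered by no group")
    def test_constant_groups_reconstruct_constant(self):
        groups = [make_group(np.full((5, 5, 3), 99.0),
                             origins=((0, 0), (1, 1), (2, 2)),
                             scores=(1.0, 0.3, 0.8))]
        out = destensorize(groups, (7, 7), fallback=np.full((7, 7), 99.0))
        np.testing.assert_allclose(out, 99.0, atol=1e-12)
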