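"""Loss-function oracles: hand arithmetic, closed forms and brute force."""
import numpy as np
import pytest
from scipy import ndimage

from he2plex import objectives
from he2plex.nn import autograd as ag
from he2plex.nn.autograd import Tensor, grad
from he2plex.objectives import (LossWeights, RandomConvEncoder, adv_loss_D,
                                adv_loss_G, gaussian_kernel1d,
                                gaussian_pyramid, info_nce,
                                patch_contrastive_loss, pyramid_loss,
                                r1_penalty, total_losses, upsample_bilinear2)


def mean_score_disc(y, x):
    """Stub discriminator: per-sample mean of the marker input."""
    y = ag.astensor(y)
    return ag.tmean(y, axis=tuple(range(1, y.ndim)))


def const_fakes(values, n=1, c=2, size=8):
    """Constant images at full/half/quarter scales (bilinear upsampling of a
    constant stays constant, so the stub sees exactly these values)."""
    scales = [1.0, 0.5, 0.25]
    return {s: Tensor(np.full((n, c, int(size * s), int(size * s)), v))
            for s, v in zip(scales, values)}


def test_adv_G_zero_when_discriminator_outputs_one_on_fakes():
    fakes = const_fakes([1.0, 1.0, 1.0])
    assert adv_loss_G(mean_score_disc, fakes, Tensor(np.zeros((1, 2, 8, 8)))
                      ).data == pytest.approx(0.0, abs=1e-12)


def test_adv_D_is_one_when_discriminator_outputs_zero_everywhere():
    fakes = const_fakes([0.0, 0.0, 0.0])
    y = Tensor(np.zeros((1, 2, 8, 8)))
    x = Tensor(np.zeros((1, 2, 8, 8)))
    assert adv_loss_D(mean_score_disc, y, fakes, x
                      ).data == pytest.approx(1.0, abs=1e-12)


def test_adv_D_hand_arithmetic_with_fixed_scores():
    # real scored 0.8; fakes at the three scales scored 0.2, 0.4, 0.6
    fakes = const_fakes([0.2, 0.4, 0.6])
    y = Tensor(np.full((1, 2, 8, 8), 0.8))
    x = Tensor(np.zeros((1, 2, 8, 8)))
    expected = ((0.8 - 1) ** 2 * 3 + 0.2 ** 2 + 0.4 ** 2 + 0.6 ** 2) / 3
    assert adv_loss_D(mean_score_disc, y, fakes, x
                      ).data == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.2267, abs=5e-5)


def test_empty_scale_set_raises():
    with pytest.raises(ValueError, match="empty"):
        adv_loss_G(mean_score_disc, {}, Tensor(np.zeros((1, 1, 4, 4))))


def test_detachment_discriminator_loss_ignores_generator_graph():
    src = Tensor(np.random.default_rng(0).random((1, 2, 8, 8)),
                 requires_grad=True)
    fakes = {1.0: ag.sigmoid(src),
             0.5: ag.avg_pool2d(ag.sigmoid(src), 2),
             0.25: ag.avg_pool2d(ag.sigmoid(src), 4)}
    y = Tensor(np.random.default_rng(1).random((1, 2, 8, 8)))
    loss_d = adv_loss_D(mean_score_disc, y, fakes, y)
    (g,) = grad(loss_d, [src])
    np.testing.assert_array_equal(g.data, np.zeros_like(src.data))


# ---------------------------------------------------------------------------
# Gaussian pyramid
# ---------------------------------------------------------------------------

def test_constant_image_preserved_across_octaves():
    prims = gaussian_pyramid(np.full((16, 16), 3.25), n_octaves=3)
    for p in prims:
        np.testing.assert_allclose(p.data, 3.25, rtol=1e-12)


def test_octave_primary_sizes():
    prims = gaussian_pyramid(np.zeros((64, 64)), n_octaves=3)
    assert [p.shape for p in prims] == [(64, 64), (32, 32), (16, 16)]


def test_impulse_pyramid_matches_dense_convolution_oracle():
    img = np.zeros((32, 32))
    img[16, 16] = 1.0
    n_gs, sigma = 3, 1.0
    prims = gaussian_pyramid(img, n_octaves=2, n_gs=n_gs, sigma=sigma)
    k1 = gaussian_kernel1d(sigma)
    k2 = np.outer(k1, k1)
    dense = img.copy()
    for _ in range(n_gs):  # dense 2-D convolution, then decimation
        dense = ndimage.convolve(dense, k2, mode="constant")
    np.testing.assert_allclose(prims[1].data, dense[::2, ::2], atol=1e-12)


def test_random_image_pyramid_matches_composed_kernel_oracle():
    rng = np.random.default_rng(5)
    img = rng.random((24, 24))
    prims = gaussian_pyramid(img, n_octaves=2, n_gs=2, sigma=1.0)
    k1 = gaussian_kernel1d(1.0)
    dense = img.copy()
    for _ in range(2):  # separable correlation, mirror boundaries
        dense = ndimage.correlate1d(dense, k1, axis=0, mode="mirror")
        dense = ndimage.correlate1d(dense, k1, axis=1, mode="mirror")
    np.testing.assert_allclose(prims[1].data, dense[::2, ::2], atol=1e-10)


def test_too_small_image_raises_or_truncates():
    with pytest.raises(ValueError, match="too small"):
        gaussian_pyramid(np.zeros((2, 2)), n_octaves=4)
    prims = gaussian_pyramid(np.zeros((2, 2)), n_octaves=4, strict=False)
    assert len(prims) == 2


def test_pyramid_loss_identities():
    rng = np.random.default_rng(6)
    y = rng.random((1, 2, 16, 16))
    assert pyramid_loss(y, y).data == pytest.approx(0.0, abs=1e-12)
    # single octave, weight 1 -> plain mean absolute error
    yh = rng.random((1, 2, 16, 16))
    assert pyramid_loss(y, yh, weights=(1.0,)).data == pytest.approx(
        np.abs(y - yh).mean(), rel=1e-12)
    # constants differing by c with octave weights w_r -> sum_r w_r * c
    c, w = 0.37, (1.0, 0.5, 0.25)
    a = np.full((1, 1, 16, 16), 1.0)
    b = np.full((1, 1, 16, 16), 1.0 + c)
    assert pyramid_loss(a, b, weights=w).data == pytest.approx(
        sum(w) * c, rel=1e-9)


def test_pyramid_loss_symmetry_and_triangle_bound():
    rng = np.random.default_rng(7)
    a, b, c = (rng.random((1, 1, 16, 16)) for _ in range(3))
    lab = pyramid_loss(a, b).data
    lba = pyramid_loss(b, a).data
    assert lab == pytest.approx(lba, rel=1e-12)
    assert pyramid_loss(a, c).data <= lab + pyramid_loss(b, c).data + 1e-12


def test_pyramid_loss_shape_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        pyramid_loss(np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 16, 16)))


def test_bilinear_upsample_preserves_constants_and_interpolates():
    const = upsample_bilinear2(Tensor(np.full((1, 1, 4, 4), 2.5)))
    np.testing.assert_allclose(const.data, 2.5, rtol=1e-12)
    ramp = upsample_bilinear2(Tensor(np.array([[[[0.0, 1.0]]]])))
    np.testing.assert_allclose(ramp.data[0, 0, 0], [0.0, 0.25, 0.75, 1.0])


# ---------------------------------------------------------------------------
# InfoNCE
# ---------------------------------------------------------------------------

def test_info_nce_closed_form_single_orthogonal_negative():
    anchor = Tensor(np.array([[1.0, 0.0]]))
    # positives: itself at location 0; the other location is orthogonal
    both = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    anchors = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    loss = info_nce(anchors, both, tau=1.0)
    expected = -np.log(np.e / (np.e + 1.0))
    assert loss.data == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.3133, abs=5e-5)


@pytest.mark.parametrize("n_neg", [1, 2, 4])
def test_info_nce_orthogonal_negatives_match_brute_force(n_neg):
    p = n_neg + 1
    basis = np.eye(p)
    loss = info_nce(Tensor(basis), Tensor(basis), tau=1.0)
    # brute-force softmax oracle
    logits = basis @ basis.T
    per = [-np.log(np.exp(logits[i, i]) / np.exp(logits[i]).sum())
           for i in range(p)]
    assert loss.data == pytest.approx(np.mean(per), rel=1e-9)
    assert loss.data == pytest.approx(-np.log(np.e / (np.e + n_neg)), rel=1e-9)


def test_info_nce_monotone_in_positive_alignment():
    rng = np.random.default_rng(8)
    neg = rng.standard_normal((4, 8))
    neg /= np.linalg.norm(neg, axis=1, keepdims=True)
    losses = []
    for align in (0.2, 0.5, 0.9):
        anchor = neg.copy()
        pos = align * anchor + (1 - align ** 2) ** 0.5 * np.roll(anchor, 1, 1)
        # only the diagonal (positive) similarity changes systematically
        l = info_nce(Tensor(anchor), Tensor(anchor * align + pos * 0), tau=0.5)
        losses.append(float(l.data))
    assert losses[0] > losses[1] > losses[2]


def test_adaptive_weight_is_uniform_at_step_zero():
    rng = np.random.default_rng(9)
    enc = RandomConvEncoder(3, width=4, n_layers=2, seed=0)
    yh = Tensor(rng.random((1, 2, 16, 16)), requires_grad=True)
    y = rng.random((1, 2, 16, 16))
    # at t=0 the schedule gives w=1 for every patch: the weighted loss equals
    # the unweighted one
    l0 = patch_contrastive_loss(yh, y, enc, None, n_patches=8, step=0,
                                total_steps=10, rng=np.random.default_rng(1))
    l1 = patch_contrastive_loss(yh, y, enc, None, n_patches=8, step=0,
                                total_steps=10, rng=np.random.default_rng(1),
                                weight_fn=lambda u: np.zeros_like(u))
    assert l0.data == pytest.approx(l1.data, rel=1e-12)


def test_contrastive_needs_at_least_two_patches():
    enc = RandomConvEncoder(3, width=4, n_layers=1, seed=0)
    with pytest.raises(ValueError, match="2 patch"):
        patch_contrastive_loss(Tensor(np.zeros((1, 1, 4, 4))),
                               np.zeros((1, 1, 4, 4)), enc, None, n_patches=1)


def test_contrastive_gradient_reaches_generated_image():
    rng = np.random.default_rng(10)
    enc = RandomConvEncoder(3, width=4, n_layers=2, seed=0)
    yh = Tensor(rng.random((1, 2, 16, 16)), requires_grad=True)
    loss = patch_contrastive_loss(yh, rng.random((1, 2, 16, 16)), enc, None,
                                  n_patches=8, rng=np.random.default_rng(2))
    (g,) = grad(loss, [yh])
    assert np.abs(g.data).max() > 0


# ---------------------------------------------------------------------------
# R1 penalty
# ---------------------------------------------------------------------------

def test_r1_linear_discriminator_equals_element_count():
    def lin(y, x):
        y = ag.astensor(y)
        return ag.tsum(y, axis=(1, 2, 3))

    y = np.random.default_rng(11).random((2, 3, 4, 4))
    pen = r1_penalty(lin, y, None)
    assert pen.data == pytest.approx(y[0].size, rel=1e-12)


def test_r1_constant_discriminator_is_zero():
    def const(y, x):
        y = ag.astensor(y)
        return ag.tmean(y, axis=(1, 2, 3)) * 0.0 + 5.0

    pen = r1_penalty(const, np.random.random((1, 2, 4, 4)), None)
    assert pen.data == pytest.approx(0.0, abs=1e-12)


def test_r1_matches_finite_difference_gradient_norm():
    rng = np.random.default_rng(12)
    w = Tensor(rng.standard_normal((2, 2, 3, 3)) * 0.5)

    def disc(y, x):
        y = ag.astensor(y)
        h = ag.tanh(ag.conv2d(y, w, padding=1))
        return ag.tmean(h, axis=(1, 2, 3))

    y0 = rng.random((1, 2, 5, 5))
    pen = float(r1_penalty(disc, y0, None).data)
    eps = 1e-5
    num = 0.0
    it = np.nditer(y0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        yp, ym = y0.copy(), y0.copy()
        yp[i] += eps
        ym[i] -= eps
        d = (float(disc(yp, None).data[0]) - float(disc(ym, None).data[0])) / (2 * eps)
        num += d * d
    assert pen == pytest.approx(num, rel=1e-3)


# ---------------------------------------------------------------------------
# total losses
# ---------------------------------------------------------------------------

def test_total_losses_linear_combination_arithmetic():
    w = LossWeights(lambda_gp=5.0, lambda_contrast=1.0, lambda_r1=1.0)
    lg, ld, bd = total_losses(Tensor(0.5), Tensor(0.7), Tensor(0.2),
                              Tensor(0.1), Tensor(0.3), w)
    assert lg.data == pytest.approx(0.5 + 5.0 * 0.2 + 1.0 * 0.1)
    assert lg.data == pytest.approx(1.6)
    assert ld.data == pytest.approx(0.7 + 0.3)
    w0 = LossWeights(lambda_gp=0.0, lambda_contrast=0.0, lambda_r1=0.0)
    lg0, _, _ = total_losses(Tensor(0.5), Tensor(0.7), Tensor(9.9),
                             Tensor(9.9), Tensor(9.9), w0)
    assert lg0.data == pytest.approx(0.5)


def test_total_losses_flags_nan_term_by_name():
    w = LossWeights()
    with pytest.raises(FloatingPointError, match="pyramid"):
        total_losses(Tensor(0.1), Tensor(0.1), Tensor(np.nan), Tensor(0.1),
                     Tensor(0.1), w)
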