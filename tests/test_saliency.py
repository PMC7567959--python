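"""Grad-CAM correctness on hand-checkable models and the anchor-aligned
group averaging."""

import numpy as np
import pytest

from olfbulb import ArchitectureSpec, SmallCNN, average_saliency, gradcam, mask_center_of_mass
from olfbulb.saliency import SaliencyMap


@pytest.fixture(scope="module")
def toy_model():
    """Tiny network whose last-conv feature maps are hand-checkable:
    10x10 single-channel input -> conv(32) -> pool -> conv(32) -> pool."""
    return SmallCNN(ArchitectureSpec(input_size=(10, 10), channels=1), seed=7)


def test_gradcam_nonnegative_and_normalised(toy_model, rng):
    x = rng.random((10, 10, 1))
    m = gradcam(toy_model, x, class_index=0)
    assert m.relevance.shape == (10, 10)
    assert np.all(m.relevance >= 0)
    assert m.relevance.max() == pytest.approx(1.0)


def test_gradcam_matches_manual_weighted_rectified_sum(toy_model, rng):
    """Recompute the map by hand from the model's own activations and
    gradients: channel weights = spatial mean gradient, map = upsampled
    ReLU of the weighted channel sum."""
    from skimage.transform import resize

    x = rng.random((10, 10, 1))
    grad, act, _ = toy_model.grad_wrt_last_conv(x, 1)
    weights = grad[0].mean(axis=(0, 1))
    manual = np.maximum((act[0] * weights).sum(axis=-1), 0.0)
    manual = resize(manual, (10, 10), order=1, mode="edge", preserve_range=True)
    if manual.max() > 0:
        manual = manual / manual.max()
    got = gradcam(toy_model, x, class_index=1).relevance
    assert np.allclose(got, manual, atol=1e-12)


def test_gradcam_gradient_matches_finite_differences(toy_model, rng):
    """d(logit)/d(last conv activations) vs central differences of the
    head forward pass, at points where pooling is locally smooth (strict
    argmax or strictly-below elements; ReLU-zero ties are kinks where
    finite differences are undefined)."""
    x = rng.random((10, 10, 1))
    grad, act, _ = toy_model.grad_wrt_last_conv(x, 0)
    eps = 1e-5
    checked = 0
    h2, w2 = act.shape[1] // 2, act.shape[2] // 2
    for _ in range(200):
        i = (0, int(rng.integers(h2 * 2)), int(rng.integers(w2 * 2)),
             int(rng.integers(act.shape[3])))
        window = act[0, (i[1] // 2) * 2:(i[1] // 2) * 2 + 2,
                     (i[2] // 2) * 2:(i[2] // 2) * 2 + 2, i[3]]
        top_two = np.sort(window.ravel())[-2:]
        if top_two[1] - top_two[0] < 1e-4:  # tie: not differentiable
            continue
        ap, am = act.copy(), act.copy()
        ap[i] += eps
        am[i] -= eps
        fd = (toy_model.head_forward(ap)[0, 0] - toy_model.head_forward(am)[0, 0]) / (2 * eps)
        assert abs(fd - grad[i]) <= 1e-3 * max(abs(fd), 1e-6)
        checked += 1
    assert checked > 50


def test_constant_positive_channel_gives_uniform_map():
    model = SmallCNN(ArchitectureSpec(input_size=(10, 10), channels=1), seed=0)
    x = np.zeros((10, 10, 1))
    # conv1/conv2 weights zero, biases positive -> constant positive last-conv
    model.conv1.w[:] = 0.0
    model.conv1.b[:] = 1.0
    model.conv2.w[:] = 0.0
    model.conv2.b[:] = 1.0
    model.dense1.w[:] = 0.01
    model.dense2.w[:] = 0.01
    model.dense2.w[:, 0] += 0.01  # make class 0 gradient positive
    m = gradcam(model, x, class_index=0)
    assert np.allclose(m.relevance, 1.0)


def test_input_independent_score_gives_zero_map():
    model = SmallCNN(ArchitectureSpec(input_size=(10, 10), channels=1), seed=1)
    model.dense2.w[:] = 0.0  # logits depend on nothing
    m = gradcam(model, np.random.default_rng(0).random((10, 10, 1)), class_index=0)
    assert np.all(m.relevance == 0.0)


def _map_with_blob(row, col, anchor, shape=(30, 30)):
    rel = np.zeros(shape)
    rel[row - 2:row + 3, col - 2:col + 3] = 1.0
    return SaliencyMap(relevance=rel, class_index=0, anchor=anchor)


def test_average_of_identical_maps_is_identity():
    maps = [_map_with_blob(10, 15, anchor=(20.0, 15.0)) for _ in range(5)]
    g = average_saliency(maps)
    assert np.allclose(g.mean, maps[0].relevance)
    assert g.n_maps == 5


def test_alignment_of_translated_maps():
    base = _map_with_blob(10, 15, anchor=(20.0, 15.0))
    shifted = _map_with_blob(14, 18, anchor=(24.0, 18.0))  # same blob-anchor offset
    g = average_saliency([base, base, shifted])
    # over the overlap the aligned mean must equal the base map
    com = mask_center_of_mass(g)
    assert com[0] < g.reference_anchor[0]  # blob above anchor by construction


def test_translation_equivariance_of_averaging():
    maps_a = [_map_with_blob(10, 15, (20.0, 15.0)), _map_with_blob(12, 14, (22.0, 14.0))]
    maps_b = [_map_with_blob(13, 18, (23.0, 18.0)), _map_with_blob(15, 17, (25.0, 17.0))]
    ga = average_saliency(maps_a)
    gb = average_saliency(maps_b)
    # shifting every map and anchor by (+3, +3) shifts nothing internally
    assert np.allclose(np.roll(np.roll(ga.mean, 3, axis=0), 3, axis=1), gb.mean)
    assert np.array_equal(np.roll(np.roll(ga.mask, 3, axis=0), 3, axis=1), gb.mask)


def test_average_saliency_validation():
    with pytest.raises(ValueError):
        average_saliency([])
    no_anchor = SaliencyMap(relevance=np.ones((5, 5)), class_index=0, anchor=None)
    with pytest.raises(ValueError):
        average_saliency([no_anchor])
    with pytest.raises(ValueError):
        average_saliency([_map_with_blob(10, 10, (10.0, 10.0))], threshold_quantile=1.5)
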