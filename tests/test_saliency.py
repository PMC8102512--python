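"""Grad-CAM against an analytic chain-rule oracle; occlusion sensitivity
against a brute-force sliding-window loop."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.transform import resize

from funduscam import nn
from funduscam.models import ModelConfig, build_model
from funduscam.saliency import (
    SaliencyMap,
    gradcam,
    gradcam_from_activations,
    normalize01,
    occlusion_map,
    save_heatmap,
    load_heatmap,
)


class _ChannelSumModel:
    """One conv layer; the score of every class is the sum of channel 0's
    activations, so d(score)/dA is analytically one on channel 0."""

    def __init__(self, size=8, channels=3, seed=0):
        rng = np.random.default_rng(seed)
        self.conv = nn.Conv2D(3, channels, 3, rng)
        self.size = size
        self.channels = channels

        class _Cfg:
            variant = "toy"
            input_size = size

        self.config = _Cfg()
        self.layer_id = "conv"

    def _acts(self, image):
        return self.conv.forward(np.asarray(image)[None])[0]

    def predict_proba(self, images):
        scores = np.array([[self._acts(im)[:, :, 0].sum()] * 5 for im in images])
        return nn.softmax(scores)

    def predict(self, images):
        return np.zeros(len(images), dtype=int)

    def class_score_gradients(self, image, target_class):
        acts = self._acts(image)
        grads = np.zeros_like(acts)
        grads[:, :, 0] = 1.0  # chain rule: d(sum A_0)/dA_k = [k == 0]
        return acts, grads, np.full(5, 0.2)


def test_gradcam_matches_manual_chain_rule_on_toy_model():
    """With unit gradient on channel 0, the heatmap must be the rectified,
    normalized channel-0 activation map."""
    model = _ChannelSumModel(size=8)
    image = np.random.default_rng(1).uniform(0, 1, (8, 8, 3))
    sal = gradcam(model, image, target_class=0)
    acts = model._acts(image)
    expected = normalize01(np.maximum(acts[:, :, 0], 0.0))
    assert np.allclose(sal.values, expected, atol=1e-5)


def test_gradcam_upsamples_coarse_activations_bilinearly():
    acts = np.random.default_rng(0).uniform(-1, 1, (4, 4, 2))
    grads = np.zeros((4, 4, 2))
    grads[:, :, 1] = 2.0
    out = gradcam_from_activations(acts, grads, (16, 16))
    expected = normalize01(resize(np.maximum(acts[:, :, 1] * 2.0, 0), (16, 16),
                                  order=1, mode="edge", anti_aliasing=False))
    assert out.shape == (16, 16)
    assert np.allclose(out, expected, atol=1e-10)


def test_default_target_is_predicted_label():
    model = build_model(ModelConfig(variant="plain", input_size=16,
                                    base_channels=4, seed=4))
    image = np.random.default_rng(2).uniform(0, 1, (16, 16, 3))
    predicted = int(model.predict(image[None])[0])
    assert np.array_equal(gradcam(model, image).values,
                          gradcam(model, image, target_class=predicted).values)


def test_gradcam_output_in_unit_range_with_image_shape(graded_item):
    model = build_model(ModelConfig(variant="separable", input_size=64,
                                    base_channels=4, seed=0))
    sal = gradcam(model, graded_item.image)
    assert sal.values.shape == graded_item.image.shape[:2]
    assert sal.values.min() >= 0 and sal.values.max() <= 1


def test_normalize_idempotent_and_constant_maps_to_zero():
    v = np.random.default_rng(3).uniform(0, 5, (12, 12))
    once = normalize01(v)
    assert np.allclose(normalize01(once), once, atol=1e-12)
    assert (normalize01(np.full((5, 5), 0.7)) == 0).all()


class _ConstantModel:
    config = None

    def predict_proba(self, images):
        return np.full((len(images), 5), 0.2)


def _occlusion_bruteforce(model, image, patch, stride, target):
    """Literal double loop over window positions."""
    h, w = image.shape[:2]
    base = model.predict_proba(image[None])[0][target]
    drops = np.zeros((h, w))
    cover = np.zeros((h, w))
    tops = sorted({*range(0, h - patch + 1, stride)} | {h - patch})
    lefts = sorted({*range(0, w - patch + 1, stride)} | {w - patch})
    for top in tops:
        for left in lefts:
            occ = image.copy()
            occ[top:top + patch, left:left + patch] = 0.0
            p = model.predict_proba(occ[None])[0][target]
            drops[top:top + patch, left:left + patch] += base - p
            cover[top:top + patch, left:left + patch] += 1.0
    return normalize01(np.maximum(drops / cover, 0.0))


def test_occlusion_constant_model_yields_zero_map():
    image = np.random.default_rng(0).uniform(0, 1, (16, 16, 3))
    sal = occlusion_map(_ConstantModel(), image, patch_size=4, stride=4,
                        target_class=0)
    assert (sal.values == 0).all()


def test_occlusion_single_window_covers_whole_image():
    model = build_model(ModelConfig(variant="plain", input_size=16,
                                    base_channels=4, seed=1))
    image = np.random.default_rng(1).uniform(0, 1, (16, 16, 3))
    sal = occlusion_map(model, image, patch_size=16, stride=16)
    assert len(np.unique(sal.values)) == 1  # spatially constant


def test_occlusion_matches_bruteforce_loop():
    model = build_model(ModelConfig(variant="plain", input_size=32,
                                    base_channels=4, seed=2))
    image = np.random.default_rng(5).uniform(0, 1, (32, 32, 3))
    target = int(model.predict(image[None])[0])
    sal = occlusion_map(model, image, patch_size=8, stride=4, target_class=target)
    expected = _occlusion_bruteforce(model, image, 8, 4, target)
    assert np.allclose(sal.values, expected, atol=1e-10)


def test_occlusion_validates_geometry():
    image = np.zeros((8, 8, 3))
    with pytest.raises(ValueError, match="patch_size"):
        occlusion_map(_ConstantModel(), image, patch_size=16, stride=1)
    with pytest.raises(ValueError, match="stride"):
        occlusion_map(_ConstantModel(), image, patch_size=4, stride=0)


def test_trained_attention_localizes_discriminative_quadrant(quadrant_model):
    """Both saliency methods concentrate on the only class-informative
    quadrant, and agree in rank order."""
    model, _, (x, y) = quadrant_model
    image = x[-1]  # class-4 held-out image
    cam = gradcam(model, image)
    occ = occlusion_map(model, image, patch_size=4, stride=2)
    # the occlusion peak can smear by up to half a patch past the boundary
    for sal, slack in ((cam, 0), (occ, 2)):
        peak = np.unravel_index(np.argmax(sal.values), sal.values.shape)
        assert peak[0] < 8 + slack and peak[1] < 8 + slack, sal.layer_id
        assert sal.values[:8, :8].mean() > sal.values[8:, 8:].mean(), sal.layer_id
    rho = spearmanr(cam.values.ravel(), occ.values.ravel()).statistic
    assert rho > 0


def test_overlay_blends_image_and_colormap(graded_item):
    sal = SaliencyMap(np.zeros(graded_item.image.shape[:2]))
    from funduscam.saliency import overlay

    blended = overlay(graded_item.image, sal, alpha=0.5)
    assert blended.shape == graded_item.image.shape
    assert blended.min() >= 0 and blended.max() <= 1
    # zero saliency maps to the colormap's floor color, not the raw image
    assert not np.allclose(blended, graded_item.image)


def test_heatmap_roundtrip_preserves_values_and_metadata(tmp_path, graded_item):
    model = build_model(ModelConfig(variant="plain", input_size=64,
                                    base_channels=4, seed=1))
    sal = gradcam(model, graded_item.image)
    sal.image_id = "img0"
    save_heatmap(sal, tmp_path / "img0.png")
    back = load_heatmap(tmp_path / "img0.png")
    assert np.allclose(back.values, sal.values, atol=1 / 65535)
    assert back.image_id == "img0"
    assert back.target_class == sal.target_class
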