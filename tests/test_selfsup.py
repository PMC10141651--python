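"""Mask geometry, per-modality occlusion, and the similarity pretext loss."""

import numpy as np
import pytest
from scipy import ndimage

from fusionseg.backbone import HybridFusionNet, NetworkConfig
from fusionseg.nn import Tensor
from fusionseg.phantom import PhantomSpec, generate_case
from fusionseg.preprocess import normalize
from fusionseg.phantom import ModalityStack
from fusionseg.selfsup import (
    MaskSpec,
    apply_masks,
    dual_branch_forward,
    make_mask,
    similarity_loss,
)


class TestMaskGeometry:
    @pytest.mark.parametrize(
        "strategy, pixels", [("block20", 400), ("block50", 2500), ("grid", 400), ("random", 400)]
    )
    def test_masked_pixel_counts(self, strategy, pixels):
        mask, spec = make_mask(strategy, 224, seed=3)
        assert int(mask.sum()) == pixels
        assert spec.strategy == strategy

    def test_grid_is_sixteen_five_by_five_blocks(self):
        mask, spec = make_mask("grid", 224, seed=5)
        labelled, n_components = ndimage.label(mask)
        assert n_components == 16
        sizes = ndimage.sum_labels(mask, labelled, range(1, n_components + 1))
        assert (sizes == 25).all()
        r, c = spec.window_origin
        assert mask[: r, :].sum() == 0 and mask[r + 35 :, :].sum() == 0
        assert mask[:, : c].sum() == 0 and mask[:, c + 35 :].sum() == 0

    def test_random_mask_within_window(self):
        mask, spec = make_mask("random", 128, seed=9)
        r, c = spec.window_origin
        assert int(mask.sum()) == 400
        window = mask[r : r + 35, c : c + 35]
        assert int(window.sum()) == 400  # nothing escapes the 35x35 window

    def test_mask_determinism_per_seed(self):
        m1, s1 = make_mask("random", 64, seed=4)
        m2, s2 = make_mask("random", 64, seed=4)
        np.testing.assert_array_equal(m1, m2)
        assert s1 == s2
        m3, _ = make_mask("random", 64, seed=5)
        assert not np.array_equal(m1, m3)

    def test_footprint_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            make_mask("block50", 40, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            make_mask("block7", 64, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            MaskSpec(strategy="weird", window_origin=(0, 0), seed=0)


@pytest.fixture(scope="module")
def case():
    return generate_case(PhantomSpec(image_side=64, seed=2))


class TestApplyMasks:

    def test_origins_pairwise_distinct(self, case):
        _, specs, _ = apply_masks(case, "block20", seed=1)
        origins = [s.window_origin for s in specs]
        assert len(set(origins)) == case.n_modalities == 4

    def test_unmasked_pixels_bit_identical_and_labels_untouched(self, case):
        masked, _, masks = apply_masks(case, "grid", seed=2)
        np.testing.assert_array_equal(masked.labels, case.labels)
        for clean_img, masked_img, mask in zip(case.images, masked.images, masks):
            assert (masked_img[~mask] == clean_img[~mask]).all()
            assert (masked_img[mask] == 0.0).all()

    def test_same_seed_same_placement(self, case):
        m1, s1, _ = apply_masks(case, "block20", seed=7)
        m2, s2, _ = apply_masks(case, "block20", seed=7)
        assert [a.window_origin for a in s1] == [b.window_origin for b in s2]
        assert all((x == y).all() for x, y in zip(m1.images, m2.images))

    def test_custom_fill_value(self, case):
        masked, _, masks = apply_masks(case, "block20", seed=3, fill_value=-1.5)
        assert (masked.images[0][masks[0]] == -1.5).all()

    def test_impossible_distinct_placement_rejected(self):
        imgs = [np.zeros((50, 50), dtype=np.float32) for _ in range(4)]
        stack = ModalityStack(images=imgs, labels=np.zeros((50, 50), dtype=np.int64))
        with pytest.raises(ValueError, match="distinct"):
            apply_masks(stack, "block50", seed=0)


class TestSimilarityLoss:
    def test_identical_branches_score_zero(self):
        rng = np.random.default_rng(0)
        a = Tensor(np.abs(rng.standard_normal((1, 8, 4, 4))).astype(np.float32))
        assert abs(similarity_loss(a, a).item()) < 1e-4

    def test_disjoint_supports_score_one(self):
        a = np.zeros((1, 8, 4, 4), dtype=np.float32)
        b = np.zeros((1, 8, 4, 4), dtype=np.float32)
        a[0, :4] = 1.0
        b[0, 4:] = 1.0
        loss = similarity_loss(Tensor(a), Tensor(b)).item()
        assert abs(loss - 1.0) < 1e-4

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = Tensor(rng.random((2, 4, 3, 3)).astype(np.float32))
        b = Tensor(rng.random((2, 4, 3, 3)).astype(np.float32))
        assert similarity_loss(a, b).item() == pytest.approx(similarity_loss(b, a).item())

    def test_monotone_in_cosine_similarity(self):
        """The loss falls as the masked features rotate toward the clean ones."""
        rng = np.random.default_rng(2)
        a = np.abs(rng.standard_normal((1, 4, 4, 4))).astype(np.float32)
        other = np.abs(rng.standard_normal((1, 4, 4, 4))).astype(np.float32)
        losses = []
        for t in np.linspace(0.0, 1.0, 5):
            blend = (1 - t) * other + t * a
            losses.append(similarity_loss(Tensor(a), Tensor(blend)).item())
        assert all(l1 >= l2 - 1e-6 for l1, l2 in zip(losses, losses[1:]))

    def test_literal_printed_form_does_not_vanish_for_identical_inputs(self):
        """The no-square-root variant penalizes even identical branches."""
        rng = np.random.default_rng(3)
        a = Tensor(np.abs(rng.standard_normal((1, 4, 4, 4))).astype(np.float32))
        literal = similarity_loss(a, a, literal=True).item()
        cosine = similarity_loss(a, a, literal=False).item()
        assert abs(cosine) < 1e-4
        assert abs(literal) > 1e-2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            similarity_loss(Tensor(np.zeros((1, 2, 2, 2))), Tensor(np.zeros((1, 2, 2, 3))))


@pytest.fixture(scope="module")
def branch_setup():
    cfg = NetworkConfig(n_modalities=4, n_layers=3, base_filters=4, seed=0)
    net = HybridFusionNet(cfg).eval()
    case = generate_case(PhantomSpec(image_side=32, seed=5))
    case = ModalityStack(
        images=[normalize(im) for im in case.images],
        labels=case.labels,
    )
    return net, case


class TestDualBranch:

    def test_masks_disabled_degenerates_to_zero_similarity_loss(self, branch_setup):
        net, case = branch_setup
        x = case.as_array()[None]
        pair, _ = dual_branch_forward(x, x.copy(), net)
        assert abs(similarity_loss(pair.clean_features, pair.masked_features).item()) < 1e-4

    def test_encoder_weights_shared_not_copied(self, branch_setup):
        net, _ = branch_setup
        # both branches run through the same module objects, hence the same
        # parameter arrays; verify by perturbing one weight and re-running
        x = np.random.default_rng(0).standard_normal((1, 4, 32, 32)).astype(np.float32)
        pair1, _ = dual_branch_forward(x, x * 0.5, net)
        w = net.encoders[0].layers[0].proj.weight
        w.data += 0.1
        pair2, _ = dual_branch_forward(x, x * 0.5, net)
        assert not np.allclose(pair1.clean_features.data, pair2.clean_features.data)
        assert not np.allclose(pair1.masked_features.data, pair2.masked_features.data)
        w.data -= 0.1

    def test_segmentation_uses_clean_branch_only(self, branch_setup):
        net, case = branch_setup
        x = case.as_array()[None]
        masked1, _, _ = apply_masks(case, "block20", seed=1)
        masked2, _, _ = apply_masks(case, "block20", seed=2)
        _, logits1 = dual_branch_forward(x, masked1.as_array()[None], net)
        _, logits2 = dual_branch_forward(x, masked2.as_array()[None], net)
        np.testing.assert_array_equal(logits1.data, logits2.data)

    def test_similarity_loss_reaches_shared_encoder_weights(self, branch_setup):
        net, case = branch_setup
        net.train()
        x = case.as_array()[None]
        masked, _, _ = apply_masks(case, "block20", seed=3)
        pair, _ = dual_branch_forward(x, masked.as_array()[None], net)
        loss = similarity_loss(pair.clean_features, pair.masked_features)
        net.zero_grad()
        loss.backward()
        g = net.encoders[0].layers[0].conv1.conv.weight.grad
        assert g is not None and np.abs(g).max() > 0
        net.eval()
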