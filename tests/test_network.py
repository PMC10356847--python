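import numpy as np
import pytest

from deepcenterline import nn
from deepcenterline.geometry import (
    TripletWeights, reversal_matrix, triplet_distance_sq,
)
from deepcenterline.network import (
    CELL, CenterlineModel, NetworkConfig, detection_loss, latent_loss,
    score_loss,
)


def _raw_for(model, rng, n=1, H=64, W=64):
    clips = rng.uniform(size=(n, model.config.stack, H, W))
    return model.forward_raw(clips, train=False)


class TestGridGeometry:
    def test_output_grid_is_sixteenth_of_input(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng, H=64, W=64)
        assert raw.shape[2:] == (4, 4)
        raw = _raw_for(tiny_model, rng, H=64, W=128)
        assert raw.shape[2:] == (4, 8)

    def test_non_divisible_input_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward_raw(
                rng.uniform(size=(1, tiny_model.config.stack, 100, 100)))

    def test_wrong_stack_depth_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward_raw(rng.uniform(size=(1, 3, 64, 64)))

    def test_channel_count_matches_candidates(self, tiny_model, rng):
        cfg = tiny_model.config
        raw = _raw_for(tiny_model, rng)
        assert raw.shape[1] == cfg.C * (3 * (cfg.kappa + 2) + 1)

    def test_anchors_are_cell_centers(self, tiny_model):
        a = tiny_model.anchors(2, 3)
        assert a.shape == (2, 3, 2)
        np.testing.assert_allclose(a[0, 0], [8.0, 8.0])
        np.testing.assert_allclose(a[1, 2], [40.0, 24.0])

    def test_split_merge_adjoint(self, tiny_model, rng):
        # <split(raw), g> == <raw, merge(g)> for the linear reshaping pair
        raw = rng.normal(size=(1, tiny_model.config.C
                               * tiny_model.config.per_candidate, 2, 2))
        lam, off, logit = tiny_model.split_raw(raw)
        dlam = rng.normal(size=lam.shape)
        doff = rng.normal(size=off.shape)
        dlogit = rng.normal(size=logit.shape)
        lhs = (np.sum(lam * dlam) + np.sum(off * doff)
               + np.sum(logit * dlogit))
        rhs = np.sum(raw * tiny_model.merge_raw_grad(dlam, doff, dlogit))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestDecoding:
    def test_zero_head_decodes_mean_shape_at_anchor(self, tiny_model):
        Hc, Wc = 2, 2
        cfg = tiny_model.config
        lam = np.zeros((1, Hc, Wc, cfg.C, 3, cfg.kappa))
        off = np.zeros((1, Hc, Wc, cfg.C, 3, 2))
        coords, x0 = tiny_model.candidate_coords(lam, off)
        k = tiny_model.basis.k
        np.testing.assert_allclose(x0[0, 0, 0, 0, 1], [8.0, 8.0])
        centroid = np.stack([coords[0, 0, 0, 0, 1, :k].mean(),
                             coords[0, 0, 0, 0, 1, k:].mean()])
        np.testing.assert_allclose(centroid, [8.0, 8.0], atol=1e-8)

    def test_offsets_are_in_cell_units(self, tiny_model):
        cfg = tiny_model.config
        lam = np.zeros((1, 1, 1, cfg.C, 3, cfg.kappa))
        off = np.zeros((1, 1, 1, cfg.C, 3, 2))
        off[0, 0, 0, 0, 1] = [1.0, -0.5]
        _, x0 = tiny_model.candidate_coords(lam, off)
        np.testing.assert_allclose(x0[0, 0, 0, 0, 1],
                                   [8.0 + CELL, 8.0 - 0.5 * CELL])

    def test_anchored_translation_equivariance(self, tiny_model):
        # the same (λ, off) in a different cell yields the same shape
        # translated by the cell pitch
        cfg = tiny_model.config
        rng = np.random.default_rng(0)
        lam = np.tile(rng.normal(size=(1, 1, 1, cfg.C, 3, cfg.kappa)),
                      (1, 2, 2, 1, 1, 1))
        off = np.tile(rng.normal(size=(1, 1, 1, cfg.C, 3, 2)) * 0.3,
                      (1, 2, 2, 1, 1, 1))
        coords, _ = tiny_model.candidate_coords(lam, off)
        k = tiny_model.basis.k
        d = coords[0, 0, 1, 0] - coords[0, 0, 0, 0]
        np.testing.assert_allclose(d[:, :k], CELL, atol=1e-9)
        np.testing.assert_allclose(d[:, k:], 0.0, atol=1e-9)

    def test_whitened_flip_operator_matches_point_reversal(self, tiny_model):
        rng = np.random.default_rng(1)
        lam_w = rng.normal(size=tiny_model.basis.kappa)
        basis = tiny_model.basis
        scale = tiny_model.lambda_scale
        coords = (lam_w * scale) @ basis.A + basis.mean
        coords_f = ((tiny_model.flip_op_scaled @ lam_w) * scale) @ basis.A \
            + basis.mean
        J = reversal_matrix(basis.k)
        np.testing.assert_allclose(coords_f, J @ coords, atol=1e-8)

    def test_decode_detections_roundtrip_counts(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        dets = tiny_model.decode_detections(raw, frame=5)
        assert len(dets) == 1
        cfg = tiny_model.config
        assert len(dets[0]) == 4 * 4 * cfg.C
        d = dets[0][0]
        assert d.z.shape == (3, tiny_model.basis.k, 2)
        assert d.latent.shape == (cfg.D,)
        assert d.frame == 5
        assert 0.0 <= d.score <= 1.0


class TestEncoder:
    def test_flip_invariance(self, tiny_model, rng):
        # exact at the architecture level (the two orderings are summed);
        # recomputing the flip operator introduces only float roundoff
        cfg = tiny_model.config
        lam = rng.normal(size=(1, 2, 2, cfg.C, 3, cfg.kappa))
        off = rng.normal(size=(1, 2, 2, cfg.C, 3, 2)) * 0.2
        lat = tiny_model.latents(lam, off)
        lat_f = tiny_model.latents(lam @ tiny_model.flip_op_scaled.T, off)
        np.testing.assert_allclose(lat, lat_f, atol=1e-10)

    def test_pair_exchange_invariance_is_bitwise(self, tiny_model, rng):
        cfg = tiny_model.config
        dim = 3 * (cfg.kappa + 2)
        v = rng.normal(size=(1, 7, dim))
        v_f = rng.normal(size=(1, 7, dim))
        out = tiny_model.encoder(np.concatenate([v, v_f]), train=False)
        swapped = tiny_model.encoder(np.concatenate([v_f, v]), train=False)
        np.testing.assert_array_equal(out, swapped)

    def test_latent_dimension(self, tiny_model, rng):
        cfg = tiny_model.config
        lam = rng.normal(size=(1, 1, 1, cfg.C, 3, cfg.kappa))
        off = np.zeros((1, 1, 1, cfg.C, 3, 2))
        assert tiny_model.latents(lam, off).shape[-1] == cfg.D

    def test_distinct_inputs_distinct_latents(self, tiny_model, rng):
        cfg = tiny_model.config
        lam = rng.normal(size=(1, 1, 1, cfg.C, 3, cfg.kappa))
        off = rng.normal(size=(1, 1, 1, cfg.C, 3, 2))
        lat = tiny_model.latents(lam, off).reshape(cfg.C, cfg.D)
        d = np.linalg.norm(lat[:, None] - lat[None], axis=-1)
        iu = np.triu_indices(cfg.C, 1)
        assert d[iu].min() > 1e-6  # no collapse at initialization

    def test_absolute_position_enters_inputs(self, tiny_model):
        # identical (λ, off) in different cells gets different encoder input
        cfg = tiny_model.config
        lam = np.zeros((1, 2, 2, cfg.C, 3, cfg.kappa))
        off = np.zeros((1, 2, 2, cfg.C, 3, 2))
        v, _ = tiny_model.encoder_inputs(lam, off)
        assert not np.allclose(v[0, 0, 0, 0], v[0, 1, 1, 0])


class TestDetectionLoss:
    def test_zero_when_no_visible_labels(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        assert detection_loss(tiny_model, raw, [{}], [{}]) == 0.0
        k = tiny_model.basis.k
        lab = {0: np.full((3, k, 2), -50.0)}
        assert detection_loss(tiny_model, raw, [lab], [{0: False}]) == 0.0

    def test_equals_bruteforce_min_over_candidates(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        k = tiny_model.basis.k
        lab = {}
        for wid in range(3):
            base = np.cumsum(rng.normal(size=(k, 2)), axis=0) + 30.0
            lab[wid] = np.stack([base, base + 0.3, base + 0.6])
        vis = {wid: True for wid in lab}
        loss = detection_loss(tiny_model, raw, [lab], [vis])
        dets = tiny_model.decode_detections(raw)[0]
        w = tiny_model.config.weights
        brute = np.mean([
            min(triplet_distance_sq(d.z, lab[wid], w) for d in dets)
            for wid in lab
        ])
        assert loss == pytest.approx(brute, rel=1e-9)

    def test_gradient_matches_numeric(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        k = tiny_model.basis.k
        base = np.cumsum(rng.normal(size=(k, 2)), axis=0) + 30.0
        labels = [{0: np.stack([base, base, base])}]
        vis = [{0: True}]
        _, dcoords = detection_loss(tiny_model, raw, labels, vis,
                                    with_grad=True)
        lam, off, logit = tiny_model.split_raw(raw)
        dlam = (dcoords @ tiny_model.basis.A.T) * tiny_model.lambda_scale
        dx0 = np.stack([dcoords[..., :k].sum(axis=-1),
                        dcoords[..., k:].sum(axis=-1)], axis=-1)
        draw = tiny_model.merge_raw_grad(dlam, dx0 * CELL,
                                         np.zeros_like(logit))
        rng2 = np.random.default_rng(0)
        for _ in range(12):
            idx = tuple(rng2.integers(0, s) for s in raw.shape)
            eps = 1e-5
            rp = raw.copy(); rp[idx] += eps
            rm = raw.copy(); rm[idx] -= eps
            num = (detection_loss(tiny_model, rp, labels, vis)
                   - detection_loss(tiny_model, rm, labels, vis)) / (2 * eps)
            assert draw[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestScoreLoss:
    def test_perfect_scores_zero_loss(self, tiny_model, rng):
        # no labels → target 0 everywhere; drive logits to −∞
        raw = _raw_for(tiny_model, rng)
        lam, off, logit = tiny_model.split_raw(raw)
        raw2 = tiny_model.merge_raw_grad(lam, off,
                                         np.full_like(logit, -50.0))
        assert score_loss(tiny_model, raw2, [{}], [{}]) \
            == pytest.approx(0.0, abs=1e-12)

    def test_target_range_and_loss_bound(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        k = tiny_model.basis.k
        base = np.cumsum(rng.normal(size=(k, 2)), axis=0) + 30.0
        labels = [{0: np.stack([base, base, base])}]
        loss = score_loss(tiny_model, raw, labels, [{0: True}])
        assert 0.0 <= loss <= 1.0

    def test_gradient_reaches_only_logits(self, tiny_model, rng):
        # stop-gradient contract: dlogit returned, shapes/offsets untouched
        raw = _raw_for(tiny_model, rng)
        k = tiny_model.basis.k
        base = np.cumsum(rng.normal(size=(k, 2)), axis=0) + 30.0
        labels = [{0: np.stack([base, base, base])}]
        _, dlogit = score_loss(tiny_model, raw, labels, [{0: True}],
                               with_grad=True)
        lam, off, logit = tiny_model.split_raw(raw)
        assert dlogit.shape == logit.shape
        rng2 = np.random.default_rng(1)
        for _ in range(8):
            idx = tuple(rng2.integers(0, s) for s in logit.shape)
            eps = 1e-5
            lp = logit.copy(); lp[idx] += eps
            lm = logit.copy(); lm[idx] -= eps
            rp = tiny_model.merge_raw_grad(lam, off, lp)
            rm = tiny_model.merge_raw_grad(lam, off, lm)
            num = (score_loss(tiny_model, rp, labels, [{0: True}])
                   - score_loss(tiny_model, rm, labels, [{0: True}])) \
                / (2 * eps)
            assert dlogit[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestLatentLoss:
    def test_two_candidate_closed_form(self, tiny_model, rng):
        # identical latents for a same-object pair: BCE = −log P(sq=0) → 0;
        # here we check the generic value against a direct recomputation
        raw = _raw_for(tiny_model, rng)
        k = tiny_model.basis.k
        base = np.cumsum(rng.normal(size=(k, 2)), axis=0) + 30.0
        labels = [{0: np.stack([base, base, base])}]
        vis = [{0: True}]
        loss = latent_loss(tiny_model, raw, labels, vis)
        assert np.isfinite(loss) and loss >= 0.0

    def test_no_labels_zero_loss(self, tiny_model, rng):
        raw = _raw_for(tiny_model, rng)
        assert latent_loss(tiny_model, raw, [{}], [{}]) == 0.0

    def test_gradient_updates_encoder_only(self, tiny_model, rng):
        # duplicate one candidate so a same-object pair with near-unit score
        # weight exists, which activates the pair loss
        raw = _raw_for(tiny_model, rng)
        lam, off, logit = tiny_model.split_raw(raw)
        lam[0, 0, 0, 1] = lam[0, 0, 0, 0] + 0.01
        off[0, 0, 0, 1] = off[0, 0, 0, 0]
        raw = tiny_model.merge_raw_grad(lam, off, logit)
        det = tiny_model.decode_detections(raw)[0][0]
        labels = [{0: det.z}]
        vis = [{0: True}]
        for _, layer, key in nn.collect_params(tiny_model.encoder):
            layer.grads[key][...] = 0.0
        for _, layer, key in nn.collect_params(tiny_model.backbone):
            layer.grads[key][...] = 0.0
        latent_loss(tiny_model, raw, labels, vis, with_grad=True)
        enc_norm = sum(np.abs(layer.grads[key]).sum()
                       for _, layer, key in
                       nn.collect_params(tiny_model.encoder))
        bb_norm = sum(np.abs(layer.grads[key]).sum()
                      for _, layer, key in
                      nn.collect_params(tiny_model.backbone))
        assert enc_norm > 0.0
        assert bb_norm == 0.0


class TestPersistence:
    def test_model_hdf5_roundtrip(self, tiny_model, rng, tmp_path):
        path = tmp_path / "model.h5"
        tiny_model.save(path)
        clone = CenterlineModel.load(path)
        assert clone.config == tiny_model.config
        np.testing.assert_array_equal(clone.lambda_scale,
                                      tiny_model.lambda_scale)
        clips = rng.uniform(size=(1, tiny_model.config.stack, 64, 64))
        np.testing.assert_array_equal(
            tiny_model.forward_raw(clips, train=False),
            clone.forward_raw(clips, train=False))
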