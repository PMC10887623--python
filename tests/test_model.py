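"""Architecture contracts of the disentanglement network."""

import numpy as np
import pytest

from polarct.model import CycleBundle, NetConfig, Networks
from polarct.nn import Tensor


@pytest.fixture(scope="module")
def nets():
    return Networks(NetConfig(base_channels=8, seed=3))


@pytest.fixture(scope="module")
def polar_batch():
    rng = np.random.default_rng(0)
    return Tensor(rng.uniform(-1, 1, (2, 1, 64, 32)).astype(np.float32))


class TestEncoder:
    def test_latent_spatial_dims_are_one_eighth(self, nets):
        x = Tensor(np.zeros((1, 1, 360, 192), np.float32))
        latent = nets.encode(x)
        assert latent.tensor.shape == (1, nets.config.latent_channels, 45, 24)

    def test_deterministic(self, nets, polar_batch):
        a = nets.encode(polar_batch).tensor.data
        b = nets.encode(polar_batch).tensor.data
        assert np.array_equal(a, b)

    def test_finite_output(self, nets, polar_batch):
        assert np.all(np.isfinite(nets.encode(polar_batch).tensor.data))

    def test_rejects_indivisible_dims(self, nets):
        with pytest.raises(ValueError):
            nets.encode(Tensor(np.zeros((1, 1, 60, 30), np.float32)))

    def test_row_roll_equivariance(self, nets, polar_batch):
        """Circular padding keeps the encoding seam-free: rolling the input
        by one latent stride (8 rows) rolls the latent by one row."""
        rolled_in = Tensor(np.roll(polar_batch.data, 8, axis=2))
        lat = nets.encode(polar_batch).tensor.data
        lat_rolled_in = nets.encode(rolled_in).tensor.data
        expected = np.roll(lat, 1, axis=2)
        rmse = np.sqrt(((lat_rolled_in - expected) ** 2).mean())
        assert rmse < 0.05 * (lat.max() - lat.min())


class TestDecoders:
    def test_restore_input_shape_and_range(self, nets, polar_batch):
        latent = nets.encode(polar_batch)
        for decode in (nets.decode_content, nets.decode_full):
            out = decode(latent)
            assert out.shape == polar_batch.shape
            assert np.all(np.abs(out.data) < 1.0)

    def test_decoders_have_separate_weights(self, nets):
        ids_g = {id(p) for p in nets.dec_content.parameters()}
        ids_gt = {id(p) for p in nets.dec_full.parameters()}
        assert ids_g.isdisjoint(ids_gt)

    def test_gradient_flows_to_encoder(self, nets, polar_batch):
        loss = (nets.decode_content(nets.encode(polar_batch)) ** 2.0).mean()
        nets.zero_grad()
        loss.backward()
        enc_grads = [p.grad for p in nets.encoder.parameters()]
        assert any(g is not None and np.abs(g).max() > 0 for g in enc_grads)


class TestArtifactCode:
    def test_exact_identity(self, nets, polar_batch):
        """The artifact code is the exact elementwise latent difference;
        adding the re-encoding back recovers the original latent up to one
        float32 rounding step."""
        latent = nets.encode(polar_batch)
        cleaned = nets.decode_content(latent)
        code = nets.extract_artifact_code(latent, cleaned)
        reencoded = nets.encode(cleaned)
        np.testing.assert_array_equal(
            code.tensor.data, latent.tensor.data - reencoded.tensor.data)
        np.testing.assert_allclose(code.tensor.data + reencoded.tensor.data,
                                   latent.tensor.data, atol=2e-7)

    def test_self_cancellation(self, nets, polar_batch):
        latent = nets.encode(polar_batch)
        cleaned = Tensor(polar_batch.data.copy())
        code = nets.extract_artifact_code(latent, cleaned)
        # encoding the same pixels gives the same latent: code is exactly 0
        assert np.abs(code.tensor.data).max() == 0.0

    def test_matches_elementwise_loop(self, nets):
        rng = np.random.default_rng(1)
        from polarct.model import LatentFeatures

        a = rng.normal(size=(1, 4, 3, 2)).astype(np.float32)
        b = rng.normal(size=(1, 4, 3, 2)).astype(np.float32)
        diff = (LatentFeatures(Tensor(a)) - LatentFeatures(Tensor(b))).tensor.data
        expected = np.empty_like(a)
        for idx in np.ndindex(a.shape):
            expected[idx] = a[idx] - b[idx]
        np.testing.assert_array_equal(diff, expected)


class TestSynthesis:
    def test_zero_code_gives_self_reconstruction(self, nets, polar_batch):
        from polarct.model import LatentFeatures

        latent = nets.encode(polar_batch)
        zero = LatentFeatures(Tensor(np.zeros(latent.shape, np.float32)))
        synth = nets.synthesize_artifacted(zero, latent)
        direct = nets.decode_full(latent)
        np.testing.assert_array_equal(synth.data, direct.data)

    def test_output_contract(self, nets, polar_batch):
        latent = nets.encode(polar_batch)
        code = nets.extract_artifact_code(latent, nets.decode_content(latent))
        out = nets.synthesize_artifacted(code, latent)
        assert out.shape == polar_batch.shape
        assert np.all(np.abs(out.data) < 1.0)


class TestDiscriminator:
    def test_patch_score_dims(self, nets):
        x = Tensor(np.zeros((1, 1, 64, 32), np.float32))
        scores = nets.discriminate(x, "D")
        assert scores.shape == (1, 1, 4, 2)  # four stride-2 stages: /16

    def test_batch_permutation_equivariance(self, nets):
        rng = np.random.default_rng(2)
        batch = rng.uniform(-1, 1, (3, 1, 32, 16)).astype(np.float32)
        scores = nets.discriminate(Tensor(batch), "Dt").data
        perm = [2, 0, 1]
        scores_perm = nets.discriminate(Tensor(batch[perm]), "Dt").data
        np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-6)

    def test_scores_respond_locally(self, nets):
        """Perturbing one small patch changes nearby scores only (the
        receptive field is ~78 px, stride 16 px per score cell)."""
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (1, 1, 192, 96)).astype(np.float32)
        base = nets.discriminate(Tensor(x), "D").data[0, 0]
        x2 = x.copy()
        x2[0, 0, 0:8, 0:8] += 1.0
        pert = nets.discriminate(Tensor(x2), "D").data[0, 0]
        delta = np.abs(pert - base)
        # scores whose receptive field covers the patch (top-left corner,
        # including the circular wrap to the bottom rows) react an order of
        # magnitude more strongly than distant ones, which feel the
        # perturbation only through the instance-norm statistics
        near = np.concatenate([delta[:2, :2].ravel(), delta[-1:, :2].ravel()])
        far = delta[3:10, 2:].ravel()
        assert near.max() > 10 * np.median(far)

    def test_rejects_empty_batch(self, nets):
        with pytest.raises(ValueError):
            nets.discriminate(Tensor(np.zeros((0, 1, 32, 16), np.float32)), "D")


class TestForwardCycle:
    def test_bundle_identity_and_finiteness(self, nets, polar_batch):
        rng = np.random.default_rng(4)
        clean = Tensor(rng.uniform(-1, 1, polar_batch.shape).astype(np.float32))
        bundle = nets.forward_cycle(polar_batch, clean)
        # latent identity holds to float32 rounding
        reencoded = nets.encode(bundle.artifact_removed)
        np.testing.assert_allclose(
            bundle.artifact_code.tensor.data + reencoded.tensor.data,
            bundle.latent_artifact.tensor.data, atol=2e-7)
        for name, t in bundle.tensors().items():
            assert np.all(np.isfinite(t.data)), name

    def test_cycle_output_recomputes_bitwise(self, nets, polar_batch):
        rng = np.random.default_rng(5)
        clean = Tensor(rng.uniform(-1, 1, polar_batch.shape).astype(np.float32))
        bundle = nets.forward_cycle(polar_batch, clean)
        recomputed = nets.decode_content(nets.encode(bundle.synth_artifacted))
        np.testing.assert_array_equal(bundle.synth_cleaned.data, recomputed.data)

    def test_shared_encoder_is_unique(self, nets):
        gen_params = nets.generator_parameters()
        enc_params = nets.encoder.parameters()
        # encoder parameters appear exactly once in the generator set
        ids = [id(p) for p in gen_params]
        assert all(ids.count(id(p)) == 1 for p in enc_params)
        # and there is no second encoder anywhere in the module tree
        from polarct.model import Encoder

        encoders = [v for v in vars(nets).values() if isinstance(v, Encoder)]
        assert len(encoders) == 1

    def test_shape_mismatch_rejected(self, nets, polar_batch):
        other = Tensor(np.zeros((2, 1, 32, 16), np.float32))
        with pytest.raises(ValueError):
            nets.forward_cycle(polar_batch, other)


class TestNetConfig:
    def test_five_layer_contract_enforced(self):
        with pytest.raises(ValueError):
            NetConfig(channel_multipliers=(1, 2, 4))

    def test_roundtrip(self):
        cfg = NetConfig(base_channels=16, seed=9, polar_topology=False)
        back = NetConfig.from_dict(cfg.to_dict())
        assert back == cfg
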