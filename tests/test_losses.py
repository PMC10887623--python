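"""Loss terms: fixed points, closed forms, scalar-loop oracles."""

import numpy as np
import pytest

from polarct.losses import (
    LossWeights,
    adversarial_losses,
    artifact_consistency_loss,
    cycle_loss,
    reconstruction_loss,
    total_objective,
    tv_horizontal_loss,
)
from polarct.model import CycleBundle, LatentFeatures, NetConfig, Networks
from polarct.nn import Tensor

RNG = np.random.default_rng(7)


def make_bundle(artifact_in, clean_in, artifact_removed=None, artifact_recon=None,
                clean_recon=None, synth_artifacted=None, synth_cleaned=None):
    """Bundle with hand-picked tensors (latents unused by the pixel losses)."""
    t = lambda a: Tensor(np.asarray(a, np.float32))
    dummy = LatentFeatures(t(np.zeros((1, 1, 1, 1))))
    pick = lambda x, fallback: t(x) if x is not None else t(fallback)
    return CycleBundle(
        artifact_in=t(artifact_in),
        clean_in=t(clean_in),
        latent_artifact=dummy,
        latent_clean=dummy,
        artifact_removed=pick(artifact_removed, artifact_in),
        artifact_recon=pick(artifact_recon, artifact_in),
        clean_recon=pick(clean_recon, clean_in),
        artifact_code=dummy,
        synth_artifacted=pick(synth_artifacted, artifact_in),
        synth_cleaned=pick(synth_cleaned, clean_in),
    )


class TestReconstructionLoss:
    def test_zero_at_perfect_reconstruction(self):
        a = RNG.uniform(-1, 1, (1, 1, 4, 4))
        b = RNG.uniform(-1, 1, (1, 1, 4, 4))
        assert float(reconstruction_loss(make_bundle(a, b)).data) == 0.0

    def test_constant_offset_gives_offset(self):
        a = RNG.uniform(-1, 1, (1, 1, 4, 4))
        b = RNG.uniform(-1, 1, (1, 1, 4, 4))
        bundle = make_bundle(a, b, artifact_recon=a + 0.25)
        assert float(reconstruction_loss(bundle).data) == pytest.approx(0.25, rel=1e-6)

    def test_matches_scalar_loop(self):
        a, b = RNG.uniform(-1, 1, (1, 1, 3, 5)), RNG.uniform(-1, 1, (1, 1, 3, 5))
        ra, rb = RNG.uniform(-1, 1, (1, 1, 3, 5)), RNG.uniform(-1, 1, (1, 1, 3, 5))
        bundle = make_bundle(a, b, artifact_recon=ra, clean_recon=rb)
        expected = (sum(abs(x - y) for x, y in zip(ra.ravel(), a.ravel())) / a.size
                    + sum(abs(x - y) for x, y in zip(rb.ravel(), b.ravel())) / b.size)
        assert float(reconstruction_loss(bundle).data) == pytest.approx(expected, rel=1e-5)


class TestArtifactConsistencyLoss:
    def test_zero_when_residuals_match(self):
        a = RNG.uniform(-1, 1, (1, 1, 4, 4))
        b = RNG.uniform(-1, 1, (1, 1, 4, 4))
        residual = RNG.uniform(-0.2, 0.2, (1, 1, 4, 4))
        bundle = make_bundle(a, b, artifact_removed=a - residual,
                             synth_artifacted=b + residual)
        assert float(artifact_consistency_loss(bundle).data) == pytest.approx(0.0, abs=1e-7)

    def test_one_sided_residual(self):
        a = RNG.uniform(-1, 1, (1, 1, 4, 4))
        b = RNG.uniform(-1, 1, (1, 1, 4, 4))
        r = RNG.uniform(-0.5, 0.5, (1, 1, 4, 4))
        bundle = make_bundle(a, b, artifact_removed=a, synth_artifacted=b + r)
        assert float(artifact_consistency_loss(bundle).data) == pytest.approx(
            np.abs(r).mean(), rel=1e-5)

    def test_matches_scalar_loop(self):
        a, b = RNG.uniform(-1, 1, (1, 1, 3, 4)), RNG.uniform(-1, 1, (1, 1, 3, 4))
        rem, syn = RNG.uniform(-1, 1, (1, 1, 3, 4)), RNG.uniform(-1, 1, (1, 1, 3, 4))
        bundle = make_bundle(a, b, artifact_removed=rem, synth_artifacted=syn)
        total = 0.0
        for idx in np.ndindex(a.shape):
            total += abs((a[idx] - rem[idx]) - (syn[idx] - b[idx]))
        assert float(artifact_consistency_loss(bundle).data) == pytest.approx(
            total / a.size, rel=1e-5)


class TestCycleLoss:
    def test_fixed_point_and_offset(self):
        a = RNG.uniform(-1, 1, (1, 1, 4, 4))
        b = RNG.uniform(-1, 1, (1, 1, 4, 4))
        assert float(cycle_loss(make_bundle(a, b)).data) == 0.0
        bundle = make_bundle(a, b, synth_cleaned=b + 0.125)
        assert float(cycle_loss(bundle).data) == pytest.approx(0.125, rel=1e-6)

    def test_matches_scalar_loop(self):
        b = RNG.uniform(-1, 1, (1, 1, 5, 3))
        sc = RNG.uniform(-1, 1, (1, 1, 5, 3))
        bundle = make_bundle(b.copy(), b, synth_cleaned=sc)
        expected = sum(abs(x - y) for x, y in zip(sc.ravel(), b.ravel())) / b.size
        assert float(cycle_loss(bundle).data) == pytest.approx(expected, rel=1e-5)


class TestTVLoss:
    def test_flat_residual_gives_zero(self):
        a = RNG.uniform(-1, 1, (1, 1, 6, 8))
        assert float(tv_horizontal_loss(Tensor(a + 0.7), Tensor(a)).data) == pytest.approx(
            0.0, abs=1e-9)

    def test_single_column_step_closed_form(self):
        """A height-h step between adjacent columns costs h^2/(W-1)."""
        H, W, h = 5, 9, 0.6
        u = np.zeros((1, 1, H, W), np.float32)
        u[..., W // 2 :] = h
        zero = Tensor(np.zeros_like(u))
        got = float(tv_horizontal_loss(Tensor(u), zero).data)
        assert got == pytest.approx(h * h / (W - 1), rel=1e-5)

    def test_matches_double_loop(self):
        u = RNG.uniform(-1, 1, (1, 1, 4, 6)).astype(np.float32)
        got = float(tv_horizontal_loss(Tensor(u), Tensor(np.zeros_like(u))).data)
        H, W = 4, 6
        total = 0.0
        for i in range(H):
            for j in range(W - 1):
                total += (u[0, 0, i, j + 1] - u[0, 0, i, j]) ** 2
        assert got == pytest.approx(total / (H * (W - 1)), rel=1e-5)

    def test_rejects_single_column(self):
        u = Tensor(np.zeros((1, 1, 4, 1), np.float32))
        with pytest.raises(ValueError):
            tv_horizontal_loss(u, u)


@pytest.fixture(scope="module")
def setup():
    nets = Networks(NetConfig(base_channels=4, seed=0))
    rng = np.random.default_rng(11)
    art = Tensor(rng.uniform(-1, 1, (1, 1, 32, 16)).astype(np.float32))
    cln = Tensor(rng.uniform(-1, 1, (1, 1, 32, 16)).astype(np.float32))
    return nets, nets.forward_cycle(art, cln)


class TestAdversarialLosses:
    def test_least_squares_fixed_points(self):
        from polarct.losses import _mse_to

        ones = Tensor(np.ones((1, 1, 4, 4), np.float32))
        zeros = Tensor(np.zeros((1, 1, 4, 4), np.float32))
        # perfect discriminator: real -> 1, fake -> 0
        assert float((_mse_to(ones, 1.0) + _mse_to(zeros, 0.0)).data) == 0.0
        # perfectly fooled: fake -> 1 zeroes the generator objective
        assert float(_mse_to(ones, 1.0).data) == 0.0

    def test_matches_naive_mean_square(self, setup):
        nets, bundle = setup
        losses = adversarial_losses(bundle, nets, form="lsgan")
        scores_fake = nets.discriminate(bundle.artifact_removed, "D").data
        expected = sum((v - 1.0) ** 2 for v in scores_fake.ravel()) / scores_fake.size
        assert float(losses["adv_D"].data) == pytest.approx(expected, rel=1e-5)

    def test_bce_form_available_and_positive(self, setup):
        nets, bundle = setup
        losses = adversarial_losses(bundle, nets, form="bce")
        for key in ("adv_D", "adv_Dt", "disc_D", "disc_Dt"):
            assert float(losses[key].data) > 0

    def test_unknown_form_rejected(self, setup):
        nets, bundle = setup
        with pytest.raises(ValueError):
            adversarial_losses(bundle, nets, form="wgan")

    def test_gradients_reach_generator(self, setup):
        """Every loss term moves at least one generator parameter."""
        nets, bundle = setup
        losses = adversarial_losses(bundle, nets)
        terms = {
            "adv": losses["adv_D"] + losses["adv_Dt"],
            "rec": reconstruction_loss(bundle),
            "art": artifact_consistency_loss(bundle),
            "cycle": cycle_loss(bundle),
            "tv": tv_horizontal_loss(bundle.artifact_in, bundle.artifact_removed),
        }
        for name, term in terms.items():
            nets.zero_grad()
            term.backward()
            grads = [p.grad for p in nets.generator_parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in grads), name


class TestTotalObjective:
    WEIGHTS = LossWeights(adv=1.0, art=5.0, rec=5.0, cycle=10.0, tv=100.0)

    def test_zero_terms_give_zero_total(self):
        report = total_objective(dict(adv_D=0, adv_Dt=0, rec=0, art=0, cycle=0, tv=0),
                                 self.WEIGHTS)
        assert report.total == 0.0

    def test_unit_terms_weighted_sum(self):
        """One unit of each loss (adversarial combined) weighs 121."""
        report = total_objective(
            dict(adv_D=0.5, adv_Dt=0.5, rec=1.0, art=1.0, cycle=1.0, tv=1.0),
            self.WEIGHTS)
        assert report.total == pytest.approx(121.0, rel=1e-9)

    def test_matches_naive_dot_product(self):
        rng = np.random.default_rng(13)
        terms = {k: float(v) for k, v in zip(
            ("adv_D", "adv_Dt", "rec", "art", "cycle", "tv"), rng.uniform(0, 2, 6))}
        w = LossWeights(*rng.uniform(0, 5, 5))
        report = total_objective(terms, w)
        expected = (w.adv * (terms["adv_D"] + terms["adv_Dt"]) + w.art * terms["art"]
                    + w.rec * terms["rec"] + w.cycle * terms["cycle"] + w.tv * terms["tv"])
        assert report.total == pytest.approx(expected, rel=1e-12)

    def test_doubling_tv_weight_doubles_contribution(self):
        terms = dict(adv_D=0.2, adv_Dt=0.3, rec=0.4, art=0.5, cycle=0.6, tv=0.7)
        base = total_objective(terms, LossWeights(tv=100.0)).total
        doubled = total_objective(terms, LossWeights(tv=200.0)).total
        assert doubled - base == pytest.approx(100.0 * 0.7, rel=1e-9)

    def test_non_finite_term_raises(self):
        with pytest.raises(FloatingPointError):
            total_objective(dict(adv_D=np.nan, adv_Dt=0, rec=0, art=0, cycle=0, tv=0),
                            self.WEIGHTS)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(tv=-1.0)
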