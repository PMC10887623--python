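"""Training objectives of the disentanglement network.

Six terms: two adversarial losses (one per discriminator), a
self-reconstruction loss, an artifact-consistency loss that ties the
removed artifact residual to the synthesized one, a cycle loss on the
synthetic pair, and a horizontal total-variation penalty on the artifact
residual in polar layout (where the cupping artifact is a smooth,
horizontally decaying field).

All L1 terms are reduced by the mean over batch and pixels so the weights
are resolution-independent.  The adversarial criterion defaults to
least-squares (real -> 1, fake -> 0); the logistic cross-entropy form is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CycleBundle, Networks
from .nn import Tensor, conv2d

__all__ = [
    "LossWeights",
    "LossReport",
    "adversarial_losses",
    "reconstruction_loss",
    "artifact_consistency_loss",
    "cycle_loss",
    "tv_horizontal_loss",
    "total_objective",
]


@dataclass
class LossWeights:
    """Weights of the overall objective (defaults are the trained model's
    operating point: adversarial 1.0, artifact/reconstruction 5.0,
    cycle 10.0, total variation 100.0)."""

    adv: float = 1.0
    art: float = 5.0
    rec: float = 5.0
    cycle: float = 10.0
    tv: float = 100.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"loss weight {name} must be finite and nonnegative")


@dataclass
class LossReport:
    adv_D: float
    adv_Dt: float
    rec: float
    art: float
    cycle: float
    tv: float
    total: float

    def as_dict(self) -> dict:
        return dict(vars(self))

    @property
    def finite(self) -> bool:
        return all(np.isfinite(v) for v in vars(self).values())


def _mse_to(scores: Tensor, target: float) -> Tensor:
    d = scores - target
    return (d * d).mean()


def _sigmoid(x: Tensor) -> Tensor:
    return (x * 0.5).tanh() * 0.5 + 0.5


def _bce(scores: Tensor, target: float) -> Tensor:
    p = _sigmoid(scores).clip(1e-6, 1.0 - 1e-6)
    if target == 1.0:
        return -(p.log().mean())
    return -((1.0 - p).log().mean())


def adversarial_losses(bundle: CycleBundle, nets: Networks, form: str = "lsgan") -> dict:
    """Generator- and discriminator-side adversarial objectives.

    The clean-domain discriminator judges real clean inputs against
    artifact-removed images; the artifact-domain discriminator judges real
    artifact inputs against synthesized artifacted images.  Discriminator
    objectives see detached fakes (the usual alternating-update scheme).
    """
    if form not in ("lsgan", "bce"):
        raise ValueError("adversarial form must be 'lsgan' or 'bce'")
    crit = _mse_to if form == "lsgan" else _bce

    fake_clean = bundle.artifact_removed
    fake_artifact = bundle.synth_artifacted

    gen_adv_D = crit(nets.discriminate(fake_clean, "D"), 1.0)
    gen_adv_Dt = crit(nets.discriminate(fake_artifact, "Dt"), 1.0)

    disc_D = crit(nets.discriminate(bundle.clean_in.detach(), "D"), 1.0) + \
        crit(nets.discriminate(fake_clean.detach(), "D"), 0.0)
    disc_Dt = crit(nets.discriminate(bundle.artifact_in.detach(), "Dt"), 1.0) + \
        crit(nets.discriminate(fake_artifact.detach(), "Dt"), 0.0)

    return {
        "adv_D": gen_adv_D,
        "adv_Dt": gen_adv_Dt,
        "disc_D": disc_D,
        "disc_Dt": disc_Dt,
    }


def reconstruction_loss(bundle: CycleBundle) -> Tensor:
    """Mean-L1 self-reconstruction through both encoder-decoder pathways."""
    return (bundle.artifact_recon - bundle.artifact_in).abs().mean() + \
        (bundle.clean_recon - bundle.clean_in).abs().mean()


def artifact_consistency_loss(bundle: CycleBundle) -> Tensor:
    """Mean-L1 between the removed artifact residual and the synthesized
    artifact residual: the artifact grafted onto the clean image must be
    the artifact that was taken off the artifact image."""
    removed = bundle.artifact_in - bundle.artifact_removed
    synthesized = bundle.synth_artifacted - bundle.clean_in
    return (removed - synthesized).abs().mean()


def cycle_loss(bundle: CycleBundle) -> Tensor:
    """Mean-L1 of the synthetic pair: cleaning the synthesized artifacted
    image must return the clean original."""
    return (bundle.synth_cleaned - bundle.clean_in).abs().mean()


_TV_KERNEL = None


def tv_horizontal_loss(artifact_in: Tensor, artifact_removed: Tensor) -> Tensor:
    """Mean squared forward difference along the radial (column) axis of
    the artifact residual.

    In polar layout the cupping artifact decays smoothly along the radius,
    so its squared horizontal gradient is small while content edges are
    not; penalizing it steers the residual toward pure artifact.
    Normalization is by ``N * C * H * (W - 1)`` (the mean), so a single
    column step of height h contributes ``h**2 / (W - 1)``.
    """
    global _TV_KERNEL
    if artifact_in.shape != artifact_removed.shape:
        raise ValueError("shape mismatch")
    if artifact_in.shape[-1] < 2:
        raise ValueError("need at least two columns for a horizontal difference")
    u = artifact_in - artifact_removed
    if u.data.ndim == 2:
        u = u.reshape(1, 1, *u.data.shape)
    if _TV_KERNEL is None:
        _TV_KERNEL = Tensor(np.array([[[[-1.0, 1.0]]]], dtype=np.float32))
    d = conv2d(u, _TV_KERNEL, None, stride=1, pad=0)
    return (d * d).mean()


def total_objective(terms: dict, weights: LossWeights) -> LossReport:
    """Weighted sum of the six scalar loss terms.

    ``terms`` maps ``adv_D, adv_Dt, rec, art, cycle, tv`` to floats or
    scalar tensors; a non-finite term signals training divergence.
    """
    def val(key):
        v = terms[key]
        return float(v.data) if isinstance(v, Tensor) else float(v)

    vals = {k: val(k) for k in ("adv_D", "adv_Dt", "rec", "art", "cycle", "tv")}
    for k, v in vals.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"loss term {k} is non-finite (training diverged)")
    total = (
        weights.adv * (vals["adv_D"] + vals["adv_Dt"])
        + weights.art * vals["art"]
        + weights.rec * vals["rec"]
        + weights.cycle * vals["cycle"]
        + weights.tv * vals["tv"]
    )
    return LossReport(total=total, **vals)
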