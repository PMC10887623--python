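"""The implicit disentanglement network.

One shared encoder maps images (polar layout by default) into a latent
space that mixes content and artifact features.  Two decoders read that
latent code with different contracts:

* the *content decoder* reconstructs only the artifact-free content, so
  applying encoder + content decoder to an artifact-affected image removes
  the artifact;
* the *full decoder* reconstructs everything, content and artifact alike.

The artifact code of an input is never produced by a dedicated encoder
("implicit" disentanglement): it is the residual between the latent code of
the artifact-affected image and the latent code of its artifact-removed
version.  Adding that residual to a clean image's latent code and decoding
with the full decoder synthesizes an artifact-affected version of the clean
image, which gives the training loop synthetic paired data.  Two PatchGAN
discriminators judge the artifact-removed and artifact-synthesized images
against the respective real domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    Sequential,
    Tanh,
    Tensor,
)

__all__ = [
    "NetConfig",
    "LatentFeatures",
    "CycleBundle",
    "Encoder",
    "Decoder",
    "PatchDiscriminator",
    "Networks",
]


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    The encoder has five conv layers of which exactly three downsample
    (stride 2); each decoder mirrors that with three upsampling stages.
    ``base_channels`` scales the whole network (64 for full runs, 16 for
    desk-scale experiments).  ``polar_topology`` selects circular padding
    along the row (angle) axis; in Cartesian mode both axes reflect.
    """

    base_channels: int = 64
    channel_multipliers: tuple[int, ...] = (1, 2, 4, 4, 4)
    disc_layers: int = 4
    seed: int = 0
    polar_topology: bool = True

    def __post_init__(self) -> None:
        if len(self.channel_multipliers) != 5:
            raise ValueError("the encoder is a fixed five-layer design")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    @property
    def pad_modes(self) -> tuple[str, str]:
        return ("circular", "reflect") if self.polar_topology else ("reflect", "reflect")

    @property
    def latent_channels(self) -> int:
        return self.base_channels * self.channel_multipliers[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_multipliers"] = list(self.channel_multipliers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["channel_multipliers"] = tuple(d["channel_multipliers"])
        return cls(**d)


@dataclass
class LatentFeatures:
    """Encoder output: a C x (H/8) x (W/8) feature map plus provenance."""

    tensor: Tensor
    provenance: str = ""

    @property
    def shape(self):
        return self.tensor.shape

    def __add__(self, other: "LatentFeatures") -> "LatentFeatures":
        return LatentFeatures(self.tensor + other.tensor, f"{self.provenance}+{other.provenance}")

    def __sub__(self, other: "LatentFeatures") -> "LatentFeatures":
        return LatentFeatures(self.tensor - other.tensor, f"{self.provenance}-{other.provenance}")


class Encoder(Module):
    """Five conv layers, three of them stride-2; instance norm and plain
    ReLU throughout (the decoders use LeakyReLU, the encoder does not)."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        c = cfg.base_channels
        m = cfg.channel_multipliers
        pm = cfg.pad_modes
        chans = [1] + [c * mi for mi in m]
        strides = [1, 2, 2, 2, 1]
        layers: list[Module] = []
        for i in range(5):
            k = 3 if strides[i] == 1 else 4
            layers.append(Conv2d(chans[i], chans[i + 1], k, strides[i], pm, rng))
            layers.append(InstanceNorm2d(chans[i + 1]))
            layers.append(LeakyReLU(0.0))
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("encoder input spatial dims must be divisible by 8")
        return self.net(x)


class Decoder(Module):
    """Mirror of the encoder: five conv layers, three transposed-conv
    upsampling stages, bounded tanh output in (-1, 1)."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        c = cfg.base_channels
        m = cfg.channel_multipliers
        pm = cfg.pad_modes
        chans = [c * mi for mi in reversed(m)] + [1]
        layers: list[Module] = [
            Conv2d(chans[0], chans[1], 3, 1, pm, rng),
            InstanceNorm2d(chans[1]),
            LeakyReLU(0.2),
        ]
        for i in (1, 2, 3):
            layers += [
                ConvTranspose2d(chans[i], chans[i + 1], rng),
                InstanceNorm2d(chans[i + 1]),
                LeakyReLU(0.2),
            ]
        layers += [Conv2d(chans[4], 1, 3, 1, pm, rng), Tanh()]
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class PatchDiscriminator(Module):
    """70x70-receptive-field PatchGAN: four stride-2 convs plus an output
    conv, emitting one raw score per overlapping patch."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        c = cfg.base_channels
        pm = cfg.pad_modes
        chans = [1, c, 2 * c, 4 * c, 8 * c]
        layers: list[Module] = []
        for i in range(cfg.disc_layers):
            layers.append(Conv2d(chans[i], chans[i + 1], 4, 2, pm, rng))
            if i > 0:
                layers.append(InstanceNorm2d(chans[i + 1]))
            layers.append(LeakyReLU(0.2))
        layers.append(Conv2d(chans[cfg.disc_layers], 1, 3, 1, pm, rng))
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] == 0:
            raise ValueError("empty batch")
        return self.net(x)


@dataclass
class CycleBundle:
    """All images and latent codes produced by one training forward pass.

    Naming: ``artifact_in``/``clean_in`` are the (polar) inputs from the two
    unpaired domains; ``artifact_removed`` is the content decode of the
    artifact input; ``artifact_recon``/``clean_recon`` are the
    self-reconstructions; ``artifact_code`` is the latent residual carrying
    the artifact; ``synth_artifacted`` is the clean image with that artifact
    code grafted on; ``synth_cleaned`` is its artifact-removed version,
    closing the cycle.
    """

    artifact_in: Tensor
    clean_in: Tensor
    latent_artifact: LatentFeatures
    latent_clean: LatentFeatures
    artifact_removed: Tensor
    artifact_recon: Tensor
    clean_recon: Tensor
    artifact_code: LatentFeatures
    synth_artifacted: Tensor
    synth_cleaned: Tensor

    def tensors(self) -> dict:
        return {
            "artifact_in": self.artifact_in,
            "clean_in": self.clean_in,
            "artifact_removed": self.artifact_removed,
            "artifact_recon": self.artifact_recon,
            "clean_recon": self.clean_recon,
            "synth_artifacted": self.synth_artifacted,
            "synth_cleaned": self.synth_cleaned,
        }


class Networks(Module):
    """The five subnetworks plus the feature-space bookkeeping.

    There is exactly one encoder parameter set: every encoding in the cycle
    (artifact input, clean input, artifact-removed image, synthesized
    artifacted image) goes through the same instance.
    """

    def __init__(self, cfg: NetConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        self.dec_content = Decoder(cfg, rng)   # G: content only
        self.dec_full = Decoder(cfg, rng)      # Gt: content + artifact
        self.disc_clean = PatchDiscriminator(cfg, rng)     # D: judges clean domain
        self.disc_artifact = PatchDiscriminator(cfg, rng)  # Dt: judges artifact domain

    # -- the five operations ------------------------------------------
    def encode(self, x: Tensor, provenance: str = "") -> LatentFeatures:
        return LatentFeatures(self.encoder(x), provenance)

    def decode_content(self, latent: LatentFeatures) -> Tensor:
        return self.dec_content(latent.tensor)

    def decode_full(self, latent: LatentFeatures) -> Tensor:
        return self.dec_full(latent.tensor)

    def extract_artifact_code(self, latent_artifact: LatentFeatures,
                              artifact_removed: Tensor) -> LatentFeatures:
        """Latent residual between an artifact image and its cleaned
        version: exact elementwise subtraction, nothing learned."""
        reencoded = self.encode(artifact_removed, "re-encoded cleaned")
        if reencoded.shape != latent_artifact.shape:
            raise ValueError("latent shape mismatch")
        out = latent_artifact - reencoded
        out.provenance = "artifact code"
        return out

    def synthesize_artifacted(self, artifact_code: LatentFeatures,
                              latent_clean: LatentFeatures) -> Tensor:
        if artifact_code.shape != latent_clean.shape:
            raise ValueError("latent shape mismatch")
        return self.decode_full(artifact_code + latent_clean)

    def discriminate(self, x: Tensor, which: str) -> Tensor:
        if which == "D":
            return self.disc_clean(x)
        if which == "Dt":
            return self.disc_artifact(x)
        raise ValueError("which must be 'D' or 'Dt'")

    def generator_parameters(self) -> list[Tensor]:
        return (
            self.encoder.parameters()
            + self.dec_content.parameters()
            + self.dec_full.parameters()
        )

    def discriminator_parameters(self) -> list[Tensor]:
        return self.disc_clean.parameters() + self.disc_artifact.parameters()

    # -- the full training pass ---------------------------------------
    def forward_cycle(self, artifact_in: Tensor, clean_in: Tensor) -> CycleBundle:
        """Run one complete cycle; each constituent operation is applied
        exactly once per its definition, with the shared encoder."""
        if artifact_in.shape != clean_in.shape:
            raise ValueError("both domains must share the polar grid shape")
        latent_artifact = self.encode(artifact_in, "artifact input")
        latent_clean = self.encode(clean_in, "clean input")
        artifact_removed = self.decode_content(latent_artifact)
        artifact_recon = self.decode_full(latent_artifact)
        clean_recon = self.decode_content(latent_clean)
        artifact_code = self.extract_artifact_code(latent_artifact, artifact_removed)
        synth_artifacted = self.synthesize_artifacted(artifact_code, latent_clean)
        synth_cleaned = self.decode_content(self.encode(synth_artifacted, "synth artifacted"))
        return CycleBundle(
            artifact_in=artifact_in,
            clean_in=clean_in,
            latent_artifact=latent_artifact,
            latent_clean=latent_clean,
            artifact_removed=artifact_removed,
            artifact_recon=artifact_recon,
            clean_recon=clean_recon,
            artifact_code=artifact_code,
            synth_artifacted=synth_artifacted,
            synth_cleaned=synth_cleaned,
        )

    def remove_artifacts_tensor(self, x: Tensor) -> Tensor:
        """Inference path: content decode of the shared encoding."""
        return self.decode_content(self.encode(x, "inference"))
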