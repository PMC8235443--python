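"""MCPD-Net: two modality VAEs and a fusion classification head.

The silhouette branch is a convolutional VAE over ``H x W x D`` stacks
of temporally averaged binary frames (the D temporal scales enter as
input channels): three sigmoid-activated convolution stages with 2, 4
and 8 filters, each followed by 2x max-pooling, then two dense heads of
width L (default 64) for the posterior mean and (log-variance) scale.
The decoder mirrors the encoder with nearest-neighbour upsampling and a
sigmoid output, so reconstructions live in [0, 1].

The accelerometer branch is a grouped 1-D convolutional VAE over
``t_D x 3`` windows: each axis has its own filter bank (2, 4, 8 filters,
ReLU), pooling is applied after the last convolution only, and the
decoder output head is linear (accelerations are unbounded).

The classifier consumes the concatenation of the two posterior means
(silhouette part first), passes it through two ReLU dense layers of
width 64 and a sigmoid output unit; predictions are thresholded at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv2d, Dense, GroupedConv1d, Module
from .preprocessing import PairedSample

__all__ = [
    "ModelConfig",
    "LatentGaussian",
    "Prediction",
    "ForwardResult",
    "MCPDNet",
    "reparameterize",
    "save_checkpoint",
    "load_checkpoint",
]

SIGMA_FLOOR = 1e-6
#: init gain for sigmoid-activated layers (their linear regime is 4x shallower)
SIGMOID_GAIN = 4.0
#: small init for the posterior heads: mu starts near 0 (the prior mean) and
#: the two branches' latent scales match at the classifier input
HEAD_GAIN = 0.1
#: initial log-variance bias: posteriors start narrow (sigma ~ 0.22) so early
#: reconstruction gradients are not drowned by sampling noise (a standard
#: guard against posterior collapse in short training runs); the KL term
#: relaxes sigma back toward 1 as training proceeds
LOGVAR_BIAS = -3.0

#: variant name -> (variational, alignment loss on, modalities)
VARIANTS: dict[str, tuple[bool, bool, str]] = {
    "MCPDNet": (True, True, "both"),
    "VAE_noLD": (True, False, "both"),
    "AE_LD": (False, True, "both"),
    "AE_noLD": (False, False, "both"),
    "Unimodal_Sil_VAE": (True, False, "sil"),
    "Unimodal_Acl_VAE": (True, False, "acc"),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 64-dim latents, filter
    counts (2, 4, 8) in both branches, 3x3 silhouette kernels with
    sigmoid activations and pooling per stage, length-5 accelerometer
    kernels with ReLU activations and pooling after the last stage, and
    two width-64 classifier layers.
    """

    latent: int = 64
    height: int = 64
    width: int = 80
    depth: int = 3
    acc_len: int = 250
    acc_channels: int = 3
    sil_filters: tuple[int, ...] = (2, 4, 8)
    acc_filters: tuple[int, ...] = (2, 4, 8)
    sil_kernel: int = 3
    acc_kernel: int = 5
    classifier_widths: tuple[int, ...] = (64, 64)
    seed: int = 0

    def __post_init__(self):
        for name in ("latent", "height", "width", "depth", "acc_len", "sil_kernel", "acc_kernel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        factor = 2 ** len(self.sil_filters)
        if self.height % factor or self.width % factor:
            raise ValueError(
                f"frame size {self.height}x{self.width} must be divisible by {factor} "
                f"(one 2x pooling per silhouette stage)"
            )
        if self.acc_len % 2:
            raise ValueError("acc_len must be even (one 2x pooling after the last stage)")

    @classmethod
    def from_sample(cls, sample: PairedSample, **overrides) -> "ModelConfig":
        """Infer the input geometry from one paired sample."""
        fields: dict = {}
        if sample.sil is not None:
            h, w, d = sample.sil.stack.shape
            fields.update(height=h, width=w, depth=d)
        if sample.acc is not None:
            t, c = sample.acc.window.shape
            fields.update(acc_len=t, acc_channels=c)
        fields.update(overrides)
        return cls(**fields)


@dataclass
class LatentGaussian:
    """Diagonal-Gaussian posterior (mu, sigma) of one encoder."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal shape")
        if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite and strictly positive")


@dataclass
class Prediction:
    """PD probability and the 0.5-thresholded binary label (1 = PD)."""

    p: float
    c: int = field(init=False)

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie strictly inside (0, 1), got {self.p}")
        self.c = int(self.p >= 0.5)


@dataclass
class ForwardResult:
    """Everything one full forward pass produces."""

    recon_sil: np.ndarray
    recon_acc: np.ndarray
    latent_sil: LatentGaussian
    latent_acc: LatentGaussian
    z_sil: np.ndarray
    z_acc: np.ndarray
    prediction: Prediction


def reparameterize(g: LatentGaussian, seed_or_rng) -> np.ndarray:
    """Draw z = mu + sigma * eps with eps ~ N(0, I) from a seeded stream."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return g.mu + g.sigma * rng.standard_normal(g.mu.shape)


class _SilhouetteEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        c_prev = cfg.depth
        self.convs = []
        for f in cfg.sil_filters:
            self.convs.append(Conv2d(c_prev, f, cfg.sil_kernel, rng, gain=SIGMOID_GAIN))
            c_prev = f
        factor = 2 ** len(cfg.sil_filters)
        self.n_flat = (cfg.height // factor) * (cfg.width // factor) * c_prev
        self.mu_head = Dense(self.n_flat, cfg.latent, rng, gain=HEAD_GAIN)
        self.lv_head = Dense(self.n_flat, cfg.latent, rng, gain=HEAD_GAIN)
        self.lv_head.b.data = self.lv_head.b.data + LOGVAR_BIAS

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for conv in self.convs:
            h = ad.maxpool2d(ad.sigmoid(conv(h)))
        h = ad.reshape(h, (h.shape[0], self.n_flat))
        mu = self.mu_head(h)
        sigma = ad.exp(self.lv_head(h) * 0.5) + SIGMA_FLOOR
        return mu, sigma


class _SilhouetteDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        filters = cfg.sil_filters
        factor = 2 ** len(filters)
        self.h0, self.w0, self.c0 = cfg.height // factor, cfg.width // factor, filters[-1]
        self.fc = Dense(cfg.latent, self.h0 * self.w0 * self.c0, rng, gain=SIGMOID_GAIN)
        chans = list(reversed(filters[:-1])) + [cfg.depth]
        c_prev = self.c0
        self.convs = []
        for c in chans:
            self.convs.append(Conv2d(c_prev, c, cfg.sil_kernel, rng, gain=SIGMOID_GAIN))
            c_prev = c

    def __call__(self, z: Tensor) -> Tensor:
        h = ad.sigmoid(self.fc(z))
        h = ad.reshape(h, (z.shape[0], self.h0, self.w0, self.c0))
        for conv in self.convs:
            h = ad.sigmoid(conv(ad.upsample2d(h)))
        return h


class _AccelEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        g = cfg.acc_channels
        cin = 1
        self.convs = []
        for f in cfg.acc_filters:
            self.convs.append(GroupedConv1d(g, cin, f, cfg.acc_kernel, rng))
            cin = f
        self.n_flat = (cfg.acc_len // 2) * g * cin
        self.mu_head = Dense(self.n_flat, cfg.latent, rng, gain=HEAD_GAIN)
        self.lv_head = Dense(self.n_flat, cfg.latent, rng, gain=HEAD_GAIN)
        self.lv_head.b.data = self.lv_head.b.data + LOGVAR_BIAS

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for conv in self.convs:
            h = ad.relu(conv(h))
        h = ad.maxpool1d(h)  # pooling after the last convolution only
        h = ad.reshape(h, (h.shape[0], self.n_flat))
        mu = self.mu_head(h)
        sigma = ad.exp(self.lv_head(h) * 0.5) + SIGMA_FLOOR
        return mu, sigma


class _AccelDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        g = cfg.acc_channels
        filters = cfg.acc_filters
        self.t0, self.c0 = cfg.acc_len // 2, g * filters[-1]
        self.fc = Dense(cfg.latent, self.t0 * self.c0, rng)
        chans = list(reversed(filters[:-1])) + [1]
        cin = filters[-1]
        self.convs = []
        for c in chans:
            self.convs.append(GroupedConv1d(g, cin, c, cfg.acc_kernel, rng))
            cin = c

    def __call__(self, z: Tensor) -> Tensor:
        h = ad.relu(self.fc(z))
        h = ad.reshape(h, (z.shape[0], self.t0, self.c0))
        h = ad.upsample1d(h)
        for conv in self.convs[:-1]:
            h = ad.relu(conv(h))
        return self.convs[-1](h)  # linear output head: accelerations are unbounded


class _Classifier(Module):
    def __init__(self, n_in: int, widths: tuple[int, ...], rng):
        self.layers = []
        for w in widths:
            self.layers.append(Dense(n_in, w, rng))
            n_in = w
        self.out = Dense(n_in, 1, rng)

    def __call__(self, r: Tensor) -> Tensor:
        h = r
        for layer in self.layers:
            h = ad.relu(layer(h))
        return ad.reshape(self.out(h), (h.shape[0],))  # logits


class MCPDNet(Module):
    """The two-branch VAE classifier (or one of its reduced variants).

    ``variant`` selects which branches exist, whether latents are
    sampled (VAE) or deterministic embeddings (AE), and whether the
    cross-modality alignment loss applies during training.
    """

    def __init__(self, config: ModelConfig | None = None, variant: str = "MCPDNet"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        self.config = config or ModelConfig()
        self.variant = variant
        self.variational, self.use_alignment, self.modalities = VARIANTS[variant]
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        self.sil_encoder = self.sil_decoder = None
        self.acc_encoder = self.acc_decoder = None
        if self.modalities in ("both", "sil"):
            self.sil_encoder = _SilhouetteEncoder(cfg, rng)
            self.sil_decoder = _SilhouetteDecoder(cfg, rng)
        if self.modalities in ("both", "acc"):
            self.acc_encoder = _AccelEncoder(cfg, rng)
            self.acc_decoder = _AccelDecoder(cfg, rng)
        n_joint = cfg.latent * (2 if self.modalities == "both" else 1)
        self.classifier = _Classifier(n_joint, cfg.classifier_widths, rng)

    # -- batched graph-mode passes (training / bulk inference) ---------
    def encode_sil_t(self, xs: Tensor) -> tuple[Tensor, Tensor]:
        self._check_shape(xs.shape[1:], (self.config.height, self.config.width, self.config.depth), "silhouette")
        return self.sil_encoder(xs)

    def encode_acc_t(self, xa: Tensor) -> tuple[Tensor, Tensor]:
        self._check_shape(xa.shape[1:], (self.config.acc_len, self.config.acc_channels), "accelerometer")
        return self.acc_encoder(xa)

    def classify_joint_t(self, r: Tensor) -> Tensor:
        return self.classifier(r)

    @staticmethod
    def _check_shape(got, expected, name):
        if tuple(got) != tuple(expected):
            raise ValueError(f"{name} input shape mismatch: expected {expected}, got {tuple(got)}")

    # -- single-sample NumPy API ---------------------------------------
    def sil_encode(self, stack: np.ndarray) -> LatentGaussian:
        """Encode one H x W x D silhouette stack to its posterior."""
        if self.sil_encoder is None:
            raise ValueError(f"variant {self.variant} has no silhouette branch")
        x = Tensor(np.asarray(stack, dtype=np.float32)[None])
        mu, sigma = self.encode_sil_t(x)
        return LatentGaussian(mu.data[0], sigma.data[0])

    def sil_decode(self, z: np.ndarray) -> np.ndarray:
        """Decode one latent vector to an H x W x D reconstruction in [0, 1]."""
        z = np.asarray(z, dtype=np.float32)
        if z.shape != (self.config.latent,):
            raise ValueError(f"z must have length {self.config.latent}, got shape {z.shape}")
        return self.sil_decoder(Tensor(z[None])).data[0]

    def acc_encode(self, window: np.ndarray) -> LatentGaussian:
        """Encode one t_D x 3 accelerometer window to its posterior."""
        if self.acc_encoder is None:
            raise ValueError(f"variant {self.variant} has no accelerometer branch")
        x = Tensor(np.asarray(window, dtype=np.float32)[None])
        mu, sigma = self.encode_acc_t(x)
        return LatentGaussian(mu.data[0], sigma.data[0])

    def acc_decode(self, z: np.ndarray) -> np.ndarray:
        """Decode one latent vector to a t_D x 3 reconstruction."""
        z = np.asarray(z, dtype=np.float32)
        if z.shape != (self.config.latent,):
            raise ValueError(f"z must have length {self.config.latent}, got shape {z.shape}")
        return self.acc_decoder(Tensor(z[None])).data[0]

    def classify(self, gs: LatentGaussian | None, ga: LatentGaussian | None) -> Prediction:
        """Classify from the posterior means (silhouette part first)."""
        parts = []
        if self.modalities in ("both", "sil"):
            if gs is None:
                raise ValueError("silhouette latent required")
            parts.append(gs.mu)
        if self.modalities in ("both", "acc"):
            if ga is None:
                raise ValueError("accelerometer latent required")
            parts.append(ga.mu)
        r = np.concatenate(parts).astype(np.float32)
        return self.classify_vector(r)

    def classify_vector(self, r: np.ndarray) -> Prediction:
        """Classify from an already assembled joint representation."""
        n_joint = self.config.latent * (2 if self.modalities == "both" else 1)
        if r.shape != (n_joint,):
            raise ValueError(f"joint representation must have length {n_joint}, got {r.shape}")
        logit = self.classifier(Tensor(np.asarray(r, dtype=np.float32)[None])).data[0]
        return Prediction(p=_clip_p(expit(logit)))

    def forward_full(self, sample: PairedSample, seed: int = 0) -> ForwardResult:
        """One full pass: posteriors, sampled latents, reconstructions,
        and the classification consuming the posterior means."""
        if self.modalities != "both":
            raise ValueError("forward_full requires a bimodal variant")
        if sample.sil is None or sample.acc is None:
            raise ValueError("forward_full requires both modalities present")
        rng = np.random.default_rng(seed)
        gs = self.sil_encode(sample.sil.stack)
        ga = self.acc_encode(sample.acc.window)
        z_s = reparameterize(gs, rng) if self.variational else gs.mu.copy()
        z_a = reparameterize(ga, rng) if self.variational else ga.mu.copy()
        return ForwardResult(
            recon_sil=self.sil_decode(z_s),
            recon_acc=self.acc_decode(z_a),
            latent_sil=gs,
            latent_acc=ga,
            z_sil=z_s,
            z_acc=z_a,
            prediction=self.classify(gs, ga),
        )


def _clip_p(p: float) -> float:
    """Keep probabilities strictly inside (0, 1) against float saturation."""
    eps = 1e-7
    return float(min(max(p, eps), 1.0 - eps))


def save_checkpoint(model: MCPDNet, path) -> None:
    """Save weights + config + variant into a single .npz archive."""
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    meta = json.dumps({"config": asdict(model.config), "variant": model.variant})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MCPDNet:
    with np.load(path) as z:
        if "__meta__" not in z:
            raise ValueError(f"{path} is not a model checkpoint")
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_dict = meta["config"]
        for key in ("sil_filters", "acc_filters", "classifier_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = MCPDNet(ModelConfig(**cfg_dict), meta["variant"])
        n = len(model.parameters())
        model.load_state_arrays([z[f"param_{i:04d}"] for i in range(n)])
    return model
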