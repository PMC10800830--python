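"""UNETR segmentation network (2-D) and the Focal Tversky loss.

The encoder is a vision transformer: the input is cut into non-overlapping
P x P patches, linearly embedded (size K), summed with a learned positional
embedding, and passed through pre-norm transformer blocks (multi-head
self-attention + 2-layer GELU MLP). Hidden states from four intermediate
depths are reshaped to spatial grids and merged, UNET-style, into a
convolutional decoder of 3x3 conv + batch-norm + ReLU blocks and 2x2
stride-2 deconvolutions; a final 1x1 convolution emits one logit per pixel
(foreground = ring boundary).

This is the 2-D analogue of the volumetric UNETR: 2-D patches, 2-D
deconvolutions, no class token (all spatial tokens feed the decoder).
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .nn import (
    Conv2d,
    ConvBNReLU,
    ConvTranspose2x2,
    DeconvConvBNReLU,
    Linear,
    Module,
    Tensor,
    TransformerBlock,
    concat,
    no_grad,
)


def token_count(image_size: int, patch_resolution_P: int) -> int:
    """Number of transformer tokens: ``(image_size / P) ** 2``.

    With the defaults (image 256, P = 16) this is 256 tokens.
    """
    if image_size % patch_resolution_P != 0:
        raise ValueError(
            f"image size {image_size} not divisible by patch resolution "
            f"{patch_resolution_P}"
        )
    side = image_size // patch_resolution_P
    return side * side


@dataclass
class UNETRConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration (P = 16, K = 768, 12 layers,
    12 heads); a much smaller instance (e.g. ``UNETRConfig.tiny()``) trains
    in minutes on one CPU.
    """

    image_size: int = 256
    patch_resolution_P: int = 16
    embed_dim_K: int = 768
    n_transformer_layers: int = 12
    n_heads: int = 12
    mlp_hidden_dim: int | None = None  # defaults to 4 * K
    skip_layer_indices: list[int] | None = None  # defaults to {L/4, L/2, 3L/4, L}
    decoder_base_channels: int = 64
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.mlp_hidden_dim is None:
            self.mlp_hidden_dim = 4 * self.embed_dim_K
        if self.skip_layer_indices is None:
            L = self.n_transformer_layers
            self.skip_layer_indices = sorted(
                {max(1, round(L * frac / 12)) for frac in (3, 6, 9, 12)}
            )
        if self.image_size % self.patch_resolution_P:
            raise ValueError("image_size must be divisible by patch_resolution_P")
        if self.patch_resolution_P != 16:
            raise ValueError(
                "the four-stage decoder requires patch_resolution_P = 16"
            )
        if self.embed_dim_K % self.n_heads:
            raise ValueError("embed_dim_K must be divisible by n_heads")
        if len(self.skip_layer_indices) != 4:
            raise ValueError("skip_layer_indices must name 4 distinct layers")
        if sorted(self.skip_layer_indices) != list(self.skip_layer_indices):
            raise ValueError("skip_layer_indices must be sorted")
        if max(self.skip_layer_indices) > self.n_transformer_layers:
            raise ValueError("skip_layer_indices exceed the number of layers")
        if self.out_channels != 1:
            raise ValueError("single-logit output only")

    @classmethod
    def tiny(cls, image_size: int = 64) -> "UNETRConfig":
        """A CPU-friendly instance used for desk-scale experiments and tests."""
        return cls(
            image_size=image_size,
            patch_resolution_P=16,
            embed_dim_K=32,
            n_transformer_layers=4,
            n_heads=4,
            decoder_base_channels=8,
        )


@dataclass
class LossParams:
    """Focal Tversky loss parameters (alpha 0.7, beta 0.3, gamma 0.75)."""

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.75
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("gamma and epsilon must be positive")


def focal_tversky_loss(y, y_hat, params: LossParams = LossParams()):
    """Focal Tversky loss ``(1 - TI) ** gamma`` with
    ``TI = sum(y*yh) / (sum(y*yh) + a*sum(y*(1-yh)) + b*sum((1-y)*yh) + eps)``.

    ``y`` is the {0,1} ground truth; ``y_hat`` the predicted foreground
    probability. Accepts numpy arrays (returns float) or an autograd
    :class:`~ringseg.nn.Tensor` prediction (returns a Tensor for training).
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=float)
    if isinstance(y_hat, Tensor):
        if y_arr.shape != y_hat.shape:
            raise ValueError("y and y_hat shapes differ")
        yt = Tensor(y_arr)
        tp = (yt * y_hat).sum()
        fn = (yt * (1.0 - y_hat)).sum()
        fp = ((1.0 - yt) * y_hat).sum()
        ti = tp / (tp + params.alpha * fn + params.beta * fp + params.epsilon)
        return (1.0 - ti) ** params.gamma

    yh = np.asarray(y_hat, dtype=float)
    if y_arr.shape != yh.shape:
        raise ValueError(f"shape mismatch: {y_arr.shape} vs {yh.shape}")
    if not np.isin(y_arr, (0, 1)).all():
        raise ValueError("ground truth must be binary")
    if yh.size and (yh.min() < 0 or yh.max() > 1):
        raise ValueError("predictions must lie in [0, 1]")
    tp = float((y_arr * yh).sum())
    fn = float((y_arr * (1.0 - yh)).sum())
    fp = float(((1.0 - y_arr) * yh).sum())
    ti = tp / (tp + params.alpha * fn + params.beta * fp + params.epsilon)
    return float((1.0 - ti) ** params.gamma)


class UNETR(Module):
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, cfg: UNETRConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        K = cfg.embed_dim_K
        P = cfg.patch_resolution_P
        self.grid = cfg.image_size // P
        T = self.grid * self.grid
        base = cfg.decoder_base_channels

        self.patch_embed = Linear(3 * P * P, K, rng)
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02, size=(T, K)), requires_grad=True
        )
        self.blocks = [
            TransformerBlock(K, cfg.n_heads, cfg.mlp_hidden_dim, rng)
            for _ in range(cfg.n_transformer_layers)
        ]

        # skip processing chains: deepest skip gets one deconv, shallowest three
        c8, c4, c2 = base * 8, base * 4, base * 2
        self.bottleneck_up = ConvTranspose2x2(K, c8, rng)
        self.skip3_chain = [DeconvConvBNReLU(K, c8, rng)]
        self.skip2_chain = [DeconvConvBNReLU(K, c8, rng), DeconvConvBNReLU(c8, c4, rng)]
        self.skip1_chain = [
            DeconvConvBNReLU(K, c8, rng),
            DeconvConvBNReLU(c8, c4, rng),
            DeconvConvBNReLU(c4, c2, rng),
        ]
        self.image_head = [ConvBNReLU(3, base, rng), ConvBNReLU(base, base, rng)]

        self.dec3 = [ConvBNReLU(2 * c8, c8, rng), ConvBNReLU(c8, c8, rng)]
        self.up3 = ConvTranspose2x2(c8, c4, rng)
        self.dec2 = [ConvBNReLU(2 * c4, c4, rng), ConvBNReLU(c4, c4, rng)]
        self.up2 = ConvTranspose2x2(c4, c2, rng)
        self.dec1 = [ConvBNReLU(2 * c2, c2, rng), ConvBNReLU(c2, c2, rng)]
        self.up1 = ConvTranspose2x2(c2, base, rng)
        self.dec0 = [ConvBNReLU(2 * base, base, rng), ConvBNReLU(base, base, rng)]
        self.out_conv = Conv2d(base, cfg.out_channels, 1, rng)

    # -- encoder -----------------------------------------------------------
    def _tokens(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        P, g = self.cfg.patch_resolution_P, self.grid
        patches = (
            x.reshape(n, 3, g, P, g, P)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, g * g, 3 * P * P)
        )
        return self.patch_embed(patches) + self.pos_embed

    def _grid_map(self, tokens: Tensor) -> Tensor:
        n = tokens.shape[0]
        g, K = self.grid, self.cfg.embed_dim_K
        return tokens.reshape(n, g, g, K).transpose(0, 3, 1, 2)

    @staticmethod
    def _run(chain, x: Tensor) -> Tensor:
        for layer in chain:
            x = layer(x)
        return x

    def forward(self, x) -> Tensor:
        """``x``: (N, 3, H, W) reals in [0, 1] -> logits (N, 1, H, W)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h = self._tokens(x)
        hidden = {}
        for i, block in enumerate(self.blocks, start=1):
            h = block(h)
            if i in self.cfg.skip_layer_indices:
                hidden[i] = h
        i1, i2, i3, i4 = self.cfg.skip_layer_indices

        d = self.bottleneck_up(self._grid_map(hidden[i4]))
        s3 = self._run(self.skip3_chain, self._grid_map(hidden[i3]))
        d = self._run(self.dec3, concat([d, s3], axis=1))
        d = self.up3(d)
        s2 = self._run(self.skip2_chain, self._grid_map(hidden[i2]))
        d = self._run(self.dec2, concat([d, s2], axis=1))
        d = self.up2(d)
        s1 = self._run(self.skip1_chain, self._grid_map(hidden[i1]))
        d = self._run(self.dec1, concat([d, s1], axis=1))
        d = self.up1(d)
        s0 = self._run(self.image_head, x)
        d = self._run(self.dec0, concat([d, s0], axis=1))
        return self.out_conv(d)

    # -- inference helpers ---------------------------------------------------
    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Sigmoid foreground probability for (B, S, S, 3) patches in [0, 1]."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                x = np.transpose(np.asarray(patches, dtype=float), (0, 3, 1, 2))
                logits = self.forward(x)
                probs = logits.sigmoid().data[:, 0]
        finally:
            self.train(was_training)
        return probs

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_unetr(cfg: UNETRConfig, seed: int = 0) -> UNETR:
    """Construct a UNETR with weights initialized from ``seed``."""
    return UNETR(cfg, np.random.default_rng(seed))


def save_checkpoint(net: UNETR, path) -> None:
    """Save weights plus the YAML-serialized config in one ``.npz`` container."""
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        yaml.safe_dump(asdict(net.cfg)).encode(), dtype=np.uint8
    )
    buf = _io.BytesIO()
    np.savez(buf, **state)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> UNETR:
    with np.load(path) as data:
        cfg_yaml = bytes(data["__config__"]).decode()
        cfg = UNETRConfig(**yaml.safe_load(cfg_yaml))
        net = build_unetr(cfg, seed=0)
        net.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"}
        )
    return net
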