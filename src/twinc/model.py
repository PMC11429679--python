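"""The paired-sequence contact network.

Two one-hot windows pass through a shared 1D convolutional encoder that
reduces each 100 kbp (toy: 5 kbp) sequence to a compact latent of
``latent_channels x latent_positions`` (default 128 x 5).  The two latents
are combined by outer addition — ``z[c, p, q] = a[c, p] + b[c, q]`` — which
lifts the pair into a 2D interaction tensor, and a stack of dilated 2D
convolutional block pairs decodes it.  The classification head reduces to a
scalar contact score in (0, 1) via a 1x1 convolution, spatial mean and
sigmoid; the regression head emits the raw P x P block of log
observed-over-expected values.

Encoder block pairs are non-linear (conv-BN-ReLU twice) followed by linear
(max-pool, then conv-BN twice without activation); the pool factors across
pairs multiply to ``window_bp / latent_positions``.  Decoder block pairs are
the 2D analogue without pooling.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv1d,
    Conv2d,
    MaxPool1d,
    ReLU,
    Sequential,
    get_state,
    parameter_count,
    set_state,
)

F32 = np.float32

#: full-scale classification defaults: 10 encoder pairs reducing 100 kbp to
#: 5 positions, 19 decoder pairs; widths chosen so the default network lands
#: on the published ~6.5 M trainable-parameter budget.
FULL_ENCODER_CHANNELS = (32, 64, 96, 128, 128, 128, 128, 128, 128, 128)
FULL_ENCODER_POOLS = (5, 5, 5, 5, 2, 2, 2, 2, 2, 1)
FULL_DECODER_CHANNELS = (76,) * 19
FULL_DECODER_DILATIONS = (1, 2, 4, 8, 16, 32, 64, 1, 2, 4, 8, 16, 32, 64, 1, 2, 4, 8, 16)


def _toy_defaults() -> dict:
    return dict(
        window_bp=5_000,
        latent_channels=32,
        latent_positions=5,
        encoder_channels=(12, 24, 32),
        encoder_pools=(10, 10, 10),
        encoder_kernel=5,
        # wide first convolution so one filter spans a full ~10 bp site
        first_conv_kernel=11,
        decoder_channels=(32, 32),
        decoder_dilations=(1, 2),
        decoder_kernel=3,
    )


@dataclass(frozen=True)
class TwinCConfig:
    window_bp: int = 100_000
    latent_channels: int = 128
    latent_positions: int = 5
    encoder_channels: tuple[int, ...] = FULL_ENCODER_CHANNELS
    encoder_pools: tuple[int, ...] = FULL_ENCODER_POOLS
    encoder_kernel: int | tuple[int, ...] = 5
    #: optional wider kernel for the very first convolution only, so a single
    #: filter can span a complete binding site at base resolution
    first_conv_kernel: int | None = None
    decoder_channels: tuple[int, ...] = FULL_DECODER_CHANNELS
    decoder_dilations: tuple[int, ...] = FULL_DECODER_DILATIONS
    decoder_kernel: int = 3
    head: str = "classification"
    output_resolution_bp: int | None = None
    symmetrize: bool = False

    def __post_init__(self):
        if self.head not in ("classification", "regression"):
            raise ValueError(f"unknown head {self.head!r}")
        if len(self.encoder_channels) != len(self.encoder_pools):
            raise ValueError("encoder channels/pools length mismatch")
        if len(self.decoder_channels) != len(self.decoder_dilations):
            raise ValueError("decoder channels/dilations length mismatch")
        if self.encoder_channels[-1] != self.latent_channels:
            raise ValueError("last encoder width must equal latent_channels")
        prod = int(np.prod(self.encoder_pools)) * self.latent_positions
        if prod != self.window_bp:
            raise ValueError(
                f"pool factors x latent_positions = {prod} != window_bp "
                f"{self.window_bp}"
            )

    @classmethod
    def toy(cls, head: str = "classification") -> "TwinCConfig":
        return cls(head=head, **_toy_defaults())

    @classmethod
    def full_regression(cls) -> "TwinCConfig":
        """640 kbp paired inputs, 5x5 output at 128 kbp; 8 encoder pairs."""
        return cls(
            window_bp=640_000,
            encoder_channels=(32, 64, 96, 128, 128, 128, 128, 128),
            encoder_pools=(5, 5, 5, 4, 4, 4, 4, 4),
            head="regression",
            output_resolution_bp=128_000,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TwinCConfig":
        d = json.loads(text)
        for k in ("encoder_channels", "encoder_pools", "decoder_channels",
                  "decoder_dilations"):
            d[k] = tuple(d[k])
        if isinstance(d.get("encoder_kernel"), list):
            d["encoder_kernel"] = tuple(d["encoder_kernel"])
        return cls(**d)


def outer_add(embA: np.ndarray, embB: np.ndarray) -> np.ndarray:
    """out[..., c, p, q] = embA[..., c, p] + embB[..., c, q]."""
    if embA.shape != embB.shape:
        raise ValueError("outer_add requires equal shapes")
    return embA[..., :, None] + embB[..., None, :]


def analytic_parameter_count(config: TwinCConfig) -> int:
    """Closed-form trainable-parameter total for a config.

    Per conv: C_out * C_in * k (+ C_out bias); per batch norm: 2 * C.  Every
    block pair holds four convs and four batch norms; the head is a 1x1 conv
    to one channel.
    """
    total = 0
    c_in = 4
    first = True
    for c, k in zip(config.encoder_channels, _encoder_kernels(config)):
        k0 = config.first_conv_kernel if (first and config.first_conv_kernel) else k
        first = False
        total += c * c_in * k0 + c         # first conv of the pair
        total += 3 * (c * c * k + c)       # remaining three convs
        total += 4 * 2 * c                 # four batch norms
        c_in = c
    k = config.decoder_kernel
    c_in = config.latent_channels
    for c in config.decoder_channels:
        total += c * c_in * k * k + c
        total += 3 * (c * c * k * k + c)
        total += 4 * 2 * c
        c_in = c
    total += config.decoder_channels[-1] + 1   # 1x1 head conv
    return total


def _encoder_kernels(config: TwinCConfig) -> tuple[int, ...]:
    k = config.encoder_kernel
    if isinstance(k, int):
        return (k,) * len(config.encoder_channels)
    return tuple(k)


def _encoder(config: TwinCConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in = 4
    first = True
    for c, pool, k in zip(config.encoder_channels, config.encoder_pools,
                          _encoder_kernels(config)):
        k0 = config.first_conv_kernel if (first and config.first_conv_kernel) else k
        first = False
        # non-linear block at current resolution
        layers += [Conv1d(c_in, c, k0, rng=rng), BatchNorm(c), ReLU(),
                   Conv1d(c, c, k, rng=rng), BatchNorm(c), ReLU()]
        # linear block: pool first, then two conv-BN without activation
        layers += [MaxPool1d(pool),
                   Conv1d(c, c, k, rng=rng), BatchNorm(c),
                   Conv1d(c, c, k, rng=rng), BatchNorm(c)]
        c_in = c
    return Sequential(*layers)


def _decoder(config: TwinCConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in = config.latent_channels
    k = config.decoder_kernel
    for c, d in zip(config.decoder_channels, config.decoder_dilations):
        layers += [Conv2d(c_in, c, k, dilation=d, rng=rng), BatchNorm(c), ReLU(),
                   Conv2d(c, c, k, dilation=d, rng=rng), BatchNorm(c), ReLU()]
        layers += [Conv2d(c, c, k, dilation=d, rng=rng), BatchNorm(c),
                   Conv2d(c, c, k, dilation=d, rng=rng), BatchNorm(c)]
        c_in = c
    return Sequential(*layers)


class TwinCNet:
    """Realized network; see module docstring for the architecture."""

    def __init__(self, config: TwinCConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = _encoder(config, rng)
        self.decoder = _decoder(config, rng)
        self.head = Conv2d(config.decoder_channels[-1], 1, 1, rng=rng)

    # -- plumbing ----------------------------------------------------------

    def params(self):
        return (
            [("enc." + n, v, g) for n, v, g in self.encoder.params()]
            + [("dec." + n, v, g) for n, v, g in self.decoder.params()]
            + [("head." + n, v, g) for n, v, g in self.head.params()]
        )

    @property
    def parameter_count(self) -> int:
        return sum(v.size for _, v, _ in self.params())

    def make_optimizer(self, lr: float = 1e-2,
                       betas: tuple[float, float] = (0.9, 0.999)) -> Adam:
        return Adam(self.params(), lr=lr, betas=betas)

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _as_input(windows: np.ndarray) -> np.ndarray:
        """(B, L, 4) one-hot -> (B, 4, L) float32."""
        x = np.asarray(windows, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def _check_window(self, windows: np.ndarray) -> None:
        if windows.shape[-2] != self.config.window_bp:
            raise ValueError(
                f"window length {windows.shape[-2]} != config window_bp "
                f"{self.config.window_bp}"
            )

    def embed(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode (B, L, 4) windows to (B, C, P) latents."""
        self._check_window(windows)
        return self.encoder.forward(self._as_input(windows), train=train)

    def _decode(self, embA: np.ndarray, embB: np.ndarray, train: bool):
        z = outer_add(embA, embB)
        u = self.decoder.forward(z, train=train)
        v = self.head.forward(u, train=train)[:, 0]  # (B, P, P)
        return v

    def forward_pairs(self, windowsA: np.ndarray, windowsB: np.ndarray,
                      train: bool = False) -> np.ndarray:
        """Contact scores (classification) or (B, P, P) blocks (regression)."""
        self._check_window(windowsA)
        self._check_window(windowsB)
        xa, xb = self._as_input(windowsA), self._as_input(windowsB)
        B = xa.shape[0]
        h = self.encoder.forward(np.concatenate([xa, xb]), train=train)
        embA, embB = h[:B], h[B:]
        v = self._decode(embA, embB, train=train)
        if self.config.head == "regression":
            self._cache = ("regression", B, None)
            return v
        logit = v.mean(axis=(1, 2))
        score = 1.0 / (1.0 + np.exp(-logit))
        if self.config.symmetrize and not train:
            h2 = self.encoder.forward(np.concatenate([xb, xa]), train=False)
            v2 = self._decode(h2[:B], h2[B:], train=False)
            score2 = 1.0 / (1.0 + np.exp(-v2.mean(axis=(1, 2))))
            return 0.5 * (score + score2)
        self._cache = ("classification", B, score)
        return score

    def forward_logits(self, windowsA: np.ndarray, windowsB: np.ndarray,
                       train: bool = False) -> np.ndarray:
        """Pre-sigmoid contact logits; backward then takes d(loss)/d(logit).

        Up to the sigmoid the network is piecewise linear in its inputs
        (convolutions, max pools, ReLUs, inference-mode batch norm), which
        attribution methods exploit.
        """
        if self.config.head != "classification":
            raise ValueError("forward_logits requires the classification head")
        self._check_window(windowsA)
        self._check_window(windowsB)
        xa, xb = self._as_input(windowsA), self._as_input(windowsB)
        B = xa.shape[0]
        h = self.encoder.forward(np.concatenate([xa, xb]), train=train)
        v = self._decode(h[:B], h[B:], train=train)
        self._cache = ("logit", B, None)
        return v.mean(axis=(1, 2))

    def forward_pair(self, windowA: np.ndarray, windowB: np.ndarray) -> float:
        """Single-pair inference score."""
        out = self.forward_pairs(windowA[None], windowB[None], train=False)
        return float(out[0]) if self.config.head == "classification" else out[0]

    def forward_block(self, windowA: np.ndarray, windowB: np.ndarray) -> np.ndarray:
        if self.config.head != "regression":
            raise ValueError("forward_block requires the regression head")
        return self.forward_pairs(windowA[None], windowB[None])[0]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate d(loss)/d(output); returns input gradients (A, B).

        For classification `dout` is (B,) wrt the sigmoid score; for
        regression it is (B, P, P) wrt the raw block.
        """
        mode, B, score = self._cache
        P = self.config.latent_positions
        if mode in ("classification", "logit"):
            dlogit = dout * score * (1.0 - score) if mode == "classification" else dout
            dv = np.broadcast_to(
                dlogit[:, None, None] / (P * P), (B, P, P)
            ).astype(F32)
        else:
            dv = dout.astype(F32)
        du = self.head.backward(dv[:, None])
        dz = self.decoder.backward(du)
        dembA = dz.sum(axis=3)
        dembB = dz.sum(axis=2)
        dh = np.concatenate([dembA, dembB])
        dx = self.encoder.backward(dh)
        ga = dx[:B].transpose(0, 2, 1)
        gb = dx[B:].transpose(0, 2, 1)
        return ga, gb

    # -- grid prediction ---------------------------------------------------

    def predict_grid(self, store, chromA: str, chromB: str,
                     batch: int = 256) -> np.ndarray:
        """Score all window pairs of two chromosomes.

        Each locus is encoded once; the decoder then runs over all latent
        pairs, which is equivalent to pairwise forward passes but avoids
        re-encoding every window O(n) times.
        """
        if self.config.head != "classification":
            raise ValueError("predict_grid requires the classification head")
        w = self.config.window_bp
        nA = store.chrom_lengths[chromA] // w
        nB = store.chrom_lengths[chromB] // w

        def embed_chrom(chrom, n):
            wins = np.stack(
                [store.fetch_window(chrom, i * w, w).seq for i in range(n)]
            )
            return self.embed(wins, train=False)

        embA = embed_chrom(chromA, nA)
        embB = embed_chrom(chromB, nB)
        ia, ib = np.meshgrid(np.arange(nA), np.arange(nB), indexing="ij")
        ia, ib = ia.ravel(), ib.ravel()
        scores = np.empty(nA * nB, dtype=F32)
        for s in range(0, ia.size, batch):
            sl = slice(s, s + batch)
            v = self._decode(embA[ia[sl]], embB[ib[sl]], train=False)
            scores[sl] = 1.0 / (1.0 + np.exp(-v.mean(axis=(1, 2))))
        return scores.reshape(nA, nB)

    # -- persistence -------------------------------------------------------

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, part in (("enc.", self.encoder), ("dec.", self.decoder),
                             ("head.", self.head)):
            if isinstance(part, Sequential):
                for k, v in get_state(part).items():
                    out[prefix + k] = v
            else:
                for n, v, _ in part.params():
                    out[prefix + n] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        set_state(self.encoder, {k[4:]: v for k, v in state.items()
                                 if k.startswith("enc.")})
        set_state(self.decoder, {k[4:]: v for k, v in state.items()
                                 if k.startswith("dec.")})
        for n, v, _ in self.head.params():
            v[...] = state["head." + n]

    def save(self, path: str | Path) -> None:
        """Single-file archive: config JSON + weight arrays."""
        buf = BytesIO()
        np.savez(buf, **self.state())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", self.config.to_json())
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TwinCNet":
        with zipfile.ZipFile(path) as zf:
            config = TwinCConfig.from_json(zf.read("config.json").decode())
            weights = np.load(BytesIO(zf.read("weights.npz")))
            net = cls(config)
            net.load_state({k: weights[k] for k in weights.files})
        return net


def build_model(config: TwinCConfig, seed: int = 0) -> TwinCNet:
    """Instantiate a network with deterministic seed-driven initialization."""
    return TwinCNet(config, seed=seed)
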