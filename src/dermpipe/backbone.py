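"""A VGG19-layout convolutional backbone used as a deep feature extractor.

The network follows the classic 19-layer layout: 16 convolutional 3x3
layers in five blocks of {2, 2, 4, 4, 4} with widths 64/128/256/512/512,
ReLU after every convolution, 2x2 max pooling after each block, then a
fully connected head 4096 -> 512 -> n_classes with softmax.  The deep
descriptor is tapped at the first fully connected layer (4096 units,
after ReLU).

Weights are seeded-random (He initialization), which makes the tap a
deterministic nonlinear random projection of the image — no pretrained
weights are required for the pipeline to run or be tested.  A width-
scaled instance (same depth, same 4096-wide tap, conv widths divided by
an integer factor) is available for small problem sizes.

Everything is plain numpy: convolution is im2col + matmul in float32.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import DomainError

VGG19_BLOCKS: tuple[tuple[int, int], ...] = ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512))


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture description: conv blocks (n_layers, width), FC head, input size."""

    conv_blocks: tuple[tuple[int, int], ...] = VGG19_BLOCKS
    fc_widths: tuple[int, int] = (4096, 512)
    n_classes: int = 8
    input_size: int = 224

    def validate(self) -> None:
        if not self.conv_blocks or any(n < 1 or w < 1 for n, w in self.conv_blocks):
            raise DomainError("malformed conv block layout")
        if len(self.fc_widths) != 2 or any(w < 1 for w in self.fc_widths):
            raise DomainError("FC head must have two hidden widths")
        if self.n_classes < 2:
            raise DomainError("need at least two output classes")
        if self.input_size % (2 ** len(self.conv_blocks)) != 0:
            raise DomainError("input size must be divisible by the total pooling factor")

    @property
    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.conv_blocks)

    @property
    def final_grid(self) -> int:
        return self.input_size // (2 ** len(self.conv_blocks))

    @property
    def flatten_dim(self) -> int:
        return self.final_grid**2 * self.conv_blocks[-1][1]

    @property
    def tap_dim(self) -> int:
        return self.fc_widths[0]

    def scaled(self, factor: int) -> "BackboneSpec":
        """Same depth and FC head, conv widths divided by ``factor``."""
        blocks = tuple((n, max(1, w // factor)) for n, w in self.conv_blocks)
        return replace(self, conv_blocks=blocks)


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution, NHWC layout, via im2col + matmul."""
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    # (N, H, W, C, 3, 3) view over spatial windows
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = win.reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(-1, c * 9).T + b
    return out.reshape(n, h, wd, w.shape[0])


def _maxpool(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


def _maxpool_argmax(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _unpool(grad: np.ndarray, idx: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    n, h, w, c = shape
    g = np.zeros((n, h // 2, w // 2, c, 4), dtype=grad.dtype)
    np.put_along_axis(g, idx[..., None], grad[..., None], axis=-1)
    return g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)


@dataclass
class DeepDescriptor:
    """Tap-point feature vector with its provenance."""

    vector: np.ndarray  # (tap_dim,)
    provenance: dict


class Backbone:
    """Seeded-random instance of a :class:`BackboneSpec`.

    Identical (spec, seed) pairs produce identical weights and therefore
    identical descriptors.
    """

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = 3
        for n_layers, width in spec.conv_blocks:
            for _ in range(n_layers):
                std = np.sqrt(2.0 / (c_in * 9))
                self.conv_w.append(rng.normal(0, std, size=(width, c_in, 3, 3)).astype(np.float32))
                self.conv_b.append(np.zeros(width, dtype=np.float32))
                c_in = width
        dims = [spec.flatten_dim, spec.fc_widths[0], spec.fc_widths[1], spec.n_classes]
        self.fc_w = [
            rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i + 1], dims[i])).astype(np.float32)
            for i in range(3)
        ]
        self.fc_b = [np.zeros(dims[i + 1], dtype=np.float32) for i in range(3)]

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.conv_w, self.conv_b)) + sum(
            w.size + b.size for w, b in zip(self.fc_w, self.fc_b)
        )

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        s = self.spec.input_size
        if x.shape[1:] != (s, s, 3):
            raise DomainError(f"expected ({s}, {s}, 3) RGB input, got {x.shape[1:]}")
        return x / 255.0

    def forward(self, images: np.ndarray, keep_intermediates: bool = False) -> dict:
        """Run the network; returns tap, logits, probabilities (batch-first).

        With ``keep_intermediates`` the activations needed for Grad-CAM
        (last conv-block ReLU output and the pooling argmax) are kept.
        """
        x = self._prepare(images)
        li = 0
        inter: dict = {}
        n_blocks = len(self.spec.conv_blocks)
        for bi, (n_layers, _) in enumerate(self.spec.conv_blocks):
            for _ in range(n_layers):
                x = np.maximum(_conv3x3(x, self.conv_w[li], self.conv_b[li]), 0.0)
                li += 1
            if bi == n_blocks - 1:
                inter["last_conv"] = x
                x, idx = _maxpool_argmax(x)
                inter["pool_idx"] = idx
            else:
                x = _maxpool(x)
        flat = x.reshape(x.shape[0], -1)
        fc1_pre = flat @ self.fc_w[0].T + self.fc_b[0]
        fc1 = np.maximum(fc1_pre, 0.0)
        fc2_pre = fc1 @ self.fc_w[1].T + self.fc_b[1]
        fc2 = np.maximum(fc2_pre, 0.0)
        logits = fc2 @ self.fc_w[2].T + self.fc_b[2]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        out = {"tap": fc1, "logits": logits, "probs": probs}
        if keep_intermediates:
            out.update(inter)
            out["fc1"] = fc1
            out["fc2"] = fc2
        return out

    def tap(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Deep descriptors (n, tap_dim) for a batch of RGB images."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        chunks = [self.forward(x[i : i + batch_size])["tap"] for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        chunks = [self.forward(x[i : i + batch_size])["probs"] for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)


def build_backbone(spec: BackboneSpec, seed: int = 0) -> Backbone:
    """Construct a seeded-random backbone instance."""
    return Backbone(spec, seed=seed)


def extract_deep(images: np.ndarray, backbone: Backbone) -> list[DeepDescriptor]:
    """Tap-point descriptors for one image or a batch; order preserved."""
    single = np.asarray(images).ndim == 3
    vectors = backbone.tap(images)
    provenance = {"backbone": "vgg19-layout", "seed": backbone.seed, "mode": "seeded-random"}
    descs = [DeepDescriptor(vector=v, provenance=dict(provenance)) for v in vectors]
    return descs if not single else descs
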