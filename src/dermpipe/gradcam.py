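"""Grad-CAM saliency maps for the seeded backbone.

The class score (pre-softmax logit) is differentiated with respect to
the last convolutional block's ReLU output; channel weights are the
spatial means of those gradients, the weighted activation sum is
rectified, bilinearly upsampled to the input size and min-max normalized
to [0, 1].  The backward pass through the FC head and the final max
pooling is computed analytically (the network is plain numpy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import Backbone, _unpool
from .preprocess import resize_image


@dataclass
class SaliencyMap:
    heat: np.ndarray  # (H, W) in [0, 1]
    target_class: int
    degenerate: bool = False


def grad_cam(backbone: Backbone, image: np.ndarray, target_class: int) -> SaliencyMap:
    """Gradient-weighted class activation map for one RGB image."""
    out = backbone.forward(image, keep_intermediates=True)
    a = out["last_conv"]  # (1, h, w, c) post-ReLU
    idx = out["pool_idx"]

    # d logit[target] / d fc2 (through the last linear layer)
    g = backbone.fc_w[2][target_class].astype(np.float64)  # (fc2,)
    g = g * (out["fc2"][0] > 0)  # ReLU mask
    g = g @ backbone.fc_w[1]  # -> (fc1,)
    g = g * (out["fc1"][0] > 0)
    g = g @ backbone.fc_w[0]  # -> (flatten,)
    pooled_shape = (1, a.shape[1] // 2, a.shape[2] // 2, a.shape[3])
    g = g.reshape(pooled_shape)
    d_a = _unpool(g.astype(np.float32), idx, a.shape)[0]  # (h, w, c)

    alpha = d_a.mean(axis=(0, 1))  # channel weights
    cam = np.maximum((a[0] * alpha).sum(axis=-1), 0.0)

    size = backbone.spec.input_size
    if cam.max() <= 0:
        return SaliencyMap(heat=np.full((size, size), 0.5), target_class=target_class, degenerate=True)
    heat = resize_image(cam, size, size)
    heat = np.clip(heat, 0.0, None)
    heat = heat - heat.min()
    heat = heat / heat.max()
    return SaliencyMap(heat=heat, target_class=target_class, degenerate=False)
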