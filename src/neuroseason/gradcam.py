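"""Gradient-weighted class-activation mapping (Grad-CAM).

For a trained network and a target class, the channel weights are the
spatial averages of the class-score gradient with respect to a convolutional
layer's feature maps; the map is the rectified weighted sum of those feature
maps, bilinearly upsampled to the input size and normalized to [0, 1].
The class score is the pre-softmax logit.  By default the activations of the
last convolutional block (post-ReLU) are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from . import nn
from .cnn_infer import CNNClassifier
from .synthgen import NeuropilImage

__all__ = ["Heatmap", "compute_gradcam", "overlay"]

logger = logging.getLogger(__name__)


@dataclass
class Heatmap:
    """A class-activation map aligned with its source image."""

    values: np.ndarray
    source_layer: int
    target_class: int
    image_ref: NeuropilImage | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("heatmap values must be non-negative")
        vmax = self.values.max() if self.values.size else 0.0
        if vmax > 0 and not np.isclose(vmax, 1.0):
            raise ValueError("non-zero heatmap must be max-normalized")


def _resolve_model(model) -> nn.Sequential:
    if isinstance(model, CNNClassifier):
        return model.model_
    if isinstance(model, nn.Sequential):
        return model
    raise TypeError(f"unsupported model type {type(model)!r}")


def _default_layer(net: nn.Sequential) -> int:
    """Index of the activation following the last convolutional layer."""
    conv_idx = [i for i, l in enumerate(net.layers) if isinstance(l, nn.Conv2D)]
    if not conv_idx:
        raise ValueError("model has no convolutional layer")
    i = conv_idx[-1]
    if i + 1 < len(net.layers) and isinstance(net.layers[i + 1], nn.ReLU):
        return i + 1
    return i


def compute_gradcam(
    model,
    image: NeuropilImage | np.ndarray,
    target_class: int,
    layer: int | None = None,
) -> Heatmap:
    """Grad-CAM heatmap of ``image`` for ``target_class``.

    ``layer`` is an index into the network's layer list and must point at a
    convolutional layer or its ReLU; None selects the last conv block.
    The map is upsampled to the image's pixel grid and divided by its max;
    an all-zero map (constant class score) is returned unnormalized.
    """
    net = _resolve_model(model)
    if isinstance(image, NeuropilImage):
        pixels = image.pixels / 255.0
        ref = image
    else:
        pixels = np.asarray(image, dtype=np.float32)
        ref = None
    if layer is None:
        layer = _default_layer(net)
    tgt = net.layers[layer]
    prev = net.layers[layer - 1] if layer > 0 else None
    if not isinstance(tgt, (nn.Conv2D, nn.ReLU)) or (
        isinstance(tgt, nn.ReLU) and not isinstance(prev, nn.Conv2D)
    ):
        raise ValueError(f"layer {layer} is not convolutional")

    x = pixels[None, ..., None].astype(np.float32)
    acts, grads = net.activation_and_gradient(x, target_class, layer)
    a, g = acts[0], grads[0]  # (h, w, channels)
    weights = g.mean(axis=(0, 1))
    cam = np.maximum((a * weights).sum(axis=-1), 0.0)

    cam = _sk_resize(
        cam.astype(np.float64),
        pixels.shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    cam = np.maximum(cam, 0.0)
    vmax = cam.max()
    if vmax > 0:
        cam = cam / vmax
    else:
        logger.info("Grad-CAM produced an all-zero map; returned unnormalized")
    return Heatmap(values=cam, source_layer=layer, target_class=target_class,
                   image_ref=ref)


def overlay(
    heatmap: Heatmap,
    image: NeuropilImage | np.ndarray,
    alpha: float = 0.4,
    cmap: str = "jet",
) -> np.ndarray:
    """Colormapped heatmap alpha-blended over the grayscale image.

    The per-pixel blend weight is ``alpha * heatmap``, so cold regions show
    the unaltered micrograph and the hottest pixel receives the colormap's
    top colour at weight ``alpha``.  Returns a uint8 RGB array.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    pixels = image.pixels if isinstance(image, NeuropilImage) else np.asarray(image)
    if pixels.shape != heatmap.values.shape:
        raise ValueError(
            f"shape mismatch: heatmap {heatmap.values.shape} vs image {pixels.shape}"
        )
    gray = np.clip(pixels, 0, 255) / 255.0
    base = np.repeat(gray[..., None], 3, axis=-1)
    colors = colormaps[cmap](heatmap.values)[..., :3]
    a = alpha * heatmap.values[..., None]
    composite = (1.0 - a) * base + a * colors
    return np.round(composite * 255.0).astype(np.uint8)
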