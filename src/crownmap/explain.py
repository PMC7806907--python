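"""Grad-CAM, guided backpropagation, and Guided Grad-CAM attention maps.

Grad-CAM weighs a convolutional stage's feature maps by the spatial mean of
the target-class score's gradients, rectifies the weighted sum, and
upsamples it to the input patch - a coarse where-map of class evidence.
Guided backpropagation is the input gradient with every rectifier's
backward pass zeroing both negative upstream gradients and inactive
positions - a fine-grained what-map.  Their elementwise product (Guided
Grad-CAM) localises class-specific detail such as foliage edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .cnn import SmallCNN

__all__ = ["AttentionMap", "grad_cam", "guided_backprop", "guided_grad_cam",
           "render_overlay"]


@dataclass
class AttentionMap:
    """2-D attention values aligned to the input patch."""

    values: np.ndarray
    target_class: int
    layer_name: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("attention map holds non-finite values")


def grad_cam(model: SmallCNN, patch: np.ndarray, target_class: int,
             layer: str | None = None) -> AttentionMap:
    """Coarse class-activation map from the named convolutional stage."""
    layer = layer or model.last_stage
    if layer not in model.stage_of_layer:
        raise ValueError(f"model has no spatial stage named {layer!r}")
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 3:
        batch = patch[None]
    else:
        batch = patch
    model.class_score_grad(batch, target_class, capture=(layer,))
    acts = model.activation(layer)[0]        # (channels, h, w)
    grads = model.gradient(layer)[0]
    weights = grads.mean(axis=(1, 2))        # spatially averaged gradients
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    up = _sk_resize(cam, batch.shape[2:], order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return AttentionMap(np.maximum(up, 0.0), target_class, layer)


def guided_backprop(model: SmallCNN, patch: np.ndarray,
                    target_class: int) -> np.ndarray:
    """Guided input gradient of the target-class score; same shape as patch."""
    patch = np.asarray(patch, dtype=float)
    squeeze = patch.ndim == 3
    batch = patch[None] if squeeze else patch
    grad = model.class_score_grad(batch, target_class, guided=True)
    return grad[0] if squeeze else grad


def guided_grad_cam(cam: AttentionMap, gbp: np.ndarray) -> AttentionMap:
    """Elementwise product: fine-grained class-specific attention.

    The guided gradient image may carry a channel axis; it is combined with
    the 2-D coarse map by broadcasting and reduced to 2-D by summing the
    absolute channel contributions.
    """
    g = np.asarray(gbp, dtype=float)
    if g.ndim == 3:
        g = np.abs(g).sum(axis=0)
    if g.shape != cam.values.shape:
        raise ValueError(
            f"shape mismatch: cam {cam.values.shape} vs gradient {g.shape}")
    return AttentionMap(cam.values * g, cam.target_class, cam.layer_name)


def render_overlay(patch: np.ndarray, attention: AttentionMap,
                   alpha: float = 0.6) -> np.ndarray:
    """Greyscale patch composited with a heat layer; pure visualization.

    The attention is max-absolute normalized per patch; where it is zero
    the output equals the greyscale patch.  Returns (rows, cols, 3) floats
    in [0, 1].
    """
    import matplotlib as _mpl

    p = np.asarray(patch, dtype=float)
    if p.ndim == 3:
        grey = 0.299 * p[0] + 0.587 * p[1] + 0.114 * p[2]
    else:
        grey = p
    if attention.values.shape != grey.shape:
        raise ValueError("attention and patch shapes differ")
    lo, hi = grey.min(), grey.max()
    grey01 = (grey - lo) / (hi - lo) if hi > lo else np.zeros_like(grey)
    att = np.abs(attention.values)
    peak = att.max()
    heat01 = att / peak if peak > 0 else att
    heat_rgb = _mpl.colormaps["jet"](heat01)[..., :3]
    base = np.repeat(grey01[..., None], 3, axis=-1)
    return base * (1 - alpha * heat01[..., None]) + \
        heat_rgb * (alpha * heat01[..., None])
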