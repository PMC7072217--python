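"""Gradient-weighted class activation mapping for the patch classifier.

For a target class, the gradient of its (pre-softmax) score with respect to
the final convolutional feature maps is averaged spatially to give one
weight per channel; the rectified, weighted sum of the feature maps is the
coarse localization map.  It is min-max normalized per patch and bilinearly
upsampled to the patch size, so high values point at the pixels that drove
the class score — for tumor patches, the locations of recognisable cancer
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .annotations import TrainingClass
from .patch_pipeline import PATCH_SIZE, Patch, PatchClassifier

__all__ = ["CamMap", "grad_cam", "save_cam_png", "save_cam_overlay"]


class UnsupportedArchitectureError(TypeError):
    """Model exposes no convolutional feature maps to attribute to."""


@dataclass
class CamMap:
    """A per-patch localization heat map in [0, 1], upsampled to patch size.

    ``coarse`` is the map at the feature-grid resolution (also min-max
    normalized); ``heat`` is its bilinear upsample to the patch size,
    re-normalized so the maximum is exactly 1 whenever any activation
    survived the rectifier.
    """

    heat: np.ndarray
    target_class: TrainingClass
    coarse: np.ndarray | None = None
    slide_id: str = ""


def grad_cam(model: PatchClassifier, patch, target_class) -> CamMap:
    """Class activation map of one patch for the given target class."""
    target_class = TrainingClass(target_class)
    net = getattr(model, "net_", model)
    if not hasattr(net, "grad_wrt_features"):
        raise UnsupportedArchitectureError(
            "model does not expose convolutional feature maps")
    if isinstance(patch, Patch):
        pixels = patch.pixels
        slide_id = patch.slide_id
    else:
        pixels = np.asarray(patch)
        slide_id = ""
    x = pixels[None] if pixels.ndim == 3 else pixels
    if x.shape[0] != 1:
        raise ValueError("grad_cam works on a single patch")
    logits = net.forward(x, retain_features=True)
    feats = net.features_[0]                      # (h, w, C)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class.value] = 1.0          # d(score_c)/d(logits)
    dfeats = net.grad_wrt_features(dlogits)[0]    # (h, w, C)
    weights = dfeats.mean(axis=(0, 1))            # spatial mean per channel
    cam = np.maximum(feats @ weights, 0.0)        # rectified weighted sum
    heat = _sk_resize(cam, (PATCH_SIZE, PATCH_SIZE), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return CamMap(heat=_minmax(heat), target_class=target_class,
                  coarse=_minmax(cam), slide_id=slide_id)


def _minmax(cam: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; all-zero maps stay zero, flat positive maps become 1."""
    lo, hi = float(cam.min()), float(cam.max())
    if hi <= 0.0:
        return np.zeros_like(cam, dtype=np.float32)
    if hi == lo:
        return np.ones_like(cam, dtype=np.float32)
    return ((cam - lo) / (hi - lo)).astype(np.float32)


def save_cam_png(cam: CamMap, path) -> None:
    """8-bit grayscale PNG of the heat map."""
    from PIL import Image

    Image.fromarray(np.round(cam.heat * 255).astype(np.uint8), mode="L").save(path)


def save_cam_overlay(cam: CamMap, patch_pixels: np.ndarray, path,
                     alpha: float = 0.45) -> None:
    """Jet-colormap heat blended over the patch image."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import cm
    from PIL import Image

    rgb = patch_pixels.astype(np.float32)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    heat_rgb = cm.jet(cam.heat)[..., :3].astype(np.float32)
    blend = (1 - alpha) * rgb + alpha * heat_rgb
    Image.fromarray(np.round(np.clip(blend, 0, 1) * 255).astype(np.uint8)).save(path)
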