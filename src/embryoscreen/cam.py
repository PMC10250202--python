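"""Class activation maps: where in the crop the evidence for each class lies.

The final classification layer is linear in the globally pooled feature
planes, so projecting its class weights back onto the final convolutional
feature maps gives a per-class spatial evidence map:

    map_c(x, y) = sum_k w_{c,k} * f_k(x, y)

(the timestamp input's weight takes no part in the spatial projection).
All class maps of a crop are normalized jointly by a single affine
transform sending the global minimum to -1 and the global maximum to +1,
then remapped by V~ = sgn(V) * sqrt(|V|) to boost the visibility of
strongly positive/negative regions, and finally rendered to 8-bit with the
jet colormap, bilinearly upsampled to crop resolution.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .classifier import TimedCrop
from .nnet import TimedCNN

__all__ = ["compute_cams", "normalize_and_remap", "render_cam"]


def compute_cams(model: TimedCNN, crop: TimedCrop) -> np.ndarray:
    """Raw per-class maps (n_classes, h, w) at feature-map resolution."""
    if not hasattr(model, "features") or not hasattr(model, "class_weights"):
        raise TypeError(
            "model must expose final conv features and final-layer class "
            "weights (features() / class_weights)")
    x4 = model.make_input(np.asarray(crop.image, dtype=float)[None],
                          np.array([crop.tau]))
    feats = model.features(x4)[0]  # (n_features, h, w)
    w = model.class_weights  # (n_classes, n_features); tau weight excluded
    return np.tensordot(w, feats, axes=([1], [0]))


def normalize_and_remap(raw_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint [-1, +1] normalization across all classes, then sgn*sqrt remap.

    A single affine transform (shared by every class, so value ordering is
    preserved within and across classes) sends the global minimum to -1 and
    the global maximum to +1.  The remap V~ = sgn(V)*sqrt(|V|) is odd and
    monotone with fixed points {-1, 0, +1}.  If all maps are constant
    (degenerate normalization), everything maps to 0.
    """
    raw_maps = np.asarray(raw_maps, dtype=float)
    if raw_maps.size == 0:
        raise ValueError("need at least one map")
    lo, hi = raw_maps.min(), raw_maps.max()
    if hi == lo:
        z = np.zeros_like(raw_maps)
        return z, z.copy()
    normalized = -1.0 + 2.0 * (raw_maps - lo) / (hi - lo)
    remapped = np.sign(normalized) * np.sqrt(np.abs(normalized))
    return normalized, remapped


def render_cam(remapped_map: np.ndarray, crop: np.ndarray | None = None,
               alpha: float = 0.5) -> np.ndarray:
    """8-bit jet render of one remapped map, upsampled to crop size.

    Values in [-1, 1] map linearly to bytes 0..255 (round-half-up: 0 -> 128),
    are colored with the jet colormap and bilinearly upsampled.  With a
    ``crop`` given, the colormap is alpha-blended onto the grayscale crop.
    Returns an (H, W, 3) uint8 image.
    """
    import matplotlib

    m = np.asarray(remapped_map, dtype=float)
    if m.min() < -1 or m.max() > 1:
        raise ValueError("remapped map values must lie in [-1, 1]")
    bytes_ = np.floor(255.0 * (m + 1.0) / 2.0 + 0.5).astype(np.uint8)
    jet = matplotlib.colormaps["jet"]
    rgb = (jet(bytes_.astype(float) / 255.0)[..., :3] * 255).astype(np.uint8)
    if crop is not None:
        h, w = crop.shape[:2]
        up = resize(rgb.astype(float) / 255.0, (h, w), order=1,
                    anti_aliasing=False)
        gray = np.asarray(crop, dtype=float)
        if gray.ndim == 2:
            gray = np.repeat(gray[..., None], 3, axis=2)
        out = (1 - alpha) * gray + alpha * up
        return np.clip(np.round(out * 255), 0, 255).astype(np.uint8)
    return rgb
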