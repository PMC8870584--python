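"""Grad-CAM class-discriminative heat maps for the scalogram classifier.

For a class c, the gradient of the class score y^c with respect to the
activations A^k of the last max-pooling layer is global-average-pooled into
one weight per feature map,

    w^c_k = (1/S) * sum_ij d y^c / d A^k_ij       (S = map height * width),

and the weighted activation sum is rectified into the heat map

    L^c = ReLU( sum_k w^c_k A^k ).

The class score is the pre-softmax logit by default (``wrt="probability"``
differentiates through the softmax instead).  For the reference 128x128
network the target map is 16x16 (S = 256); the map is bilinearly upsampled
to the tile size and min-max scaled to [0, 1] for display (an all-zero map
stays zero; raw values are preserved alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import MaxPool2x2, Network

__all__ = ["HeatMap", "gradcam_map", "overlay", "save_heatmap", "last_pool_index"]


@dataclass
class HeatMap:
    """Grad-CAM output aligned to one input tile."""

    class_index: int
    weights: np.ndarray          # one w^c_k per feature map
    map: np.ndarray              # target-layer resolution, >= 0
    upsampled: np.ndarray        # tile resolution, min-max scaled to [0, 1]
    raw_upsampled: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.map < 0).any():
            raise ValueError("heat map must be nonnegative (post-ReLU)")


def last_pool_index(net: Network) -> int:
    """Index of the last max-pooling layer — the network's final
    non-fully-connected stage, where Grad-CAM attaches."""
    idx = [i for i, l in enumerate(net.layers) if isinstance(l, MaxPool2x2)]
    if not idx:
        raise ValueError("network contains no max-pooling layer")
    return idx[-1]


def gradcam_map(
    net: Network,
    tile: np.ndarray,
    class_index: int,
    layer_index: int | None = None,
    wrt: str = "logit",
) -> HeatMap:
    """Compute the Grad-CAM heat map of ``tile`` for ``class_index``.

    ``tile`` is (H, W) in [0, 1] (or already batched (1, C, H, W)).  The
    target layer defaults to the last max pool.
    """
    if not 0 <= class_index < net.n_classes:
        raise ValueError(
            f"class_index {class_index} out of range for {net.n_classes} classes"
        )
    x = np.asarray(tile, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None, :, :]
    elif x.ndim == 3:
        x = x[None]
    if x.shape[1:] != net.input_shape:
        raise ValueError(
            f"tile shape {x.shape[1:]} does not match network input "
            f"{net.input_shape}"
        )
    if layer_index is None:
        layer_index = last_pool_index(net)
    acts, grads, _ = net.activation_gradient(x, class_index, layer_index, wrt=wrt)
    a = acts[0]            # (K, h, w)
    g = grads[0]
    weights = g.mean(axis=(1, 2))                     # (1/S) sum_ij dY/dA
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    target_h = net.input_shape[1]
    raw_up = _bilinear_upsample(cam, target_h // cam.shape[0])
    peak = raw_up.max()
    scaled = raw_up / peak if peak > 0 else np.zeros_like(raw_up)
    return HeatMap(
        class_index=class_index,
        weights=weights,
        map=cam,
        upsampled=scaled,
        raw_upsampled=raw_up,
    )


def _bilinear_upsample(m: np.ndarray, factor: int) -> np.ndarray:
    from scipy.ndimage import zoom

    return zoom(m, factor, order=1)


def overlay(
    heatmap: HeatMap,
    tile: np.ndarray,
    out_path: str | Path | None = None,
    cmap: str = "jet",
    alpha: float = 0.4,
) -> np.ndarray:
    """Alpha-blend the upsampled heat map over the grayscale tile.

    Returns the blended (H, W, 3) uint8 image and writes it as a PNG when
    ``out_path`` is given.
    """
    from matplotlib import colormaps
    from PIL import Image

    tile = np.asarray(tile, dtype=np.float64)
    if tile.shape != heatmap.upsampled.shape:
        raise ValueError(
            f"tile shape {tile.shape} does not match heat map "
            f"{heatmap.upsampled.shape}"
        )
    colored = colormaps[cmap](heatmap.upsampled)[:, :, :3]
    gray = np.repeat(tile[:, :, None], 3, axis=2)
    blended = (1.0 - alpha) * gray + alpha * colored
    img = np.round(np.clip(blended, 0, 1) * 255).astype(np.uint8)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img, mode="RGB").save(out_path)
    return img


def save_heatmap(heatmap: HeatMap, path_prefix: str | Path,
                 provenance: dict | None = None) -> None:
    """Write the raw map as CSV plus a JSON metadata sidecar (class, per-map
    weights, optional tile provenance)."""
    import json

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".csv"), heatmap.map, fmt="%.9g",
               delimiter=",")
    meta = {
        "class_index": int(heatmap.class_index),
        "weights": heatmap.weights.tolist(),
        "map_shape": list(heatmap.map.shape),
        "provenance": provenance or {},
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
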