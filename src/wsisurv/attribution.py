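"""Tile-level attribution: gradient x feature scores, heatmaps, top tiles.

For a trained model and a bag, each tile's contribution to the patient-level
risk is summarized as the mean over feature dimensions of
``gradient * feature`` for that tile, where the gradient of the risk score
with respect to the tile's input feature vector is obtained by
backpropagation with dropout disabled ("Grad-CAM-like" score). A second
signal, the tile-level prediction score, comes from passing each tile alone
through the model and min-max normalizing over the slide. The product of the
two is the weighted importance used for heatmaps and top-tile extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from .bags import FeatureBag
from .model import MILRiskModel
from .nn import Tensor

__all__ = ["AttributionMap", "gradcam_scores", "tile_pred_scores",
           "weighted_importance", "attribute_bag", "render_heatmap", "top_tiles"]


@dataclass
class AttributionMap:
    slide_id: str
    coords: np.ndarray          # (n, 2) level-0 (x, y)
    side_px: int
    gradcam: np.ndarray         # (n,)
    tile_pred_norm: np.ndarray  # (n,) in [0, 1]
    weighted: np.ndarray        # (n,)

    def __post_init__(self):
        n = len(self.coords)
        if not (len(self.gradcam) == len(self.tile_pred_norm) == len(self.weighted) == n):
            raise ValueError("attribution vectors not aligned with coords")


def gradcam_scores(bag: FeatureBag, model: MILRiskModel) -> np.ndarray:
    """mean_d(gradient_{i,d} * feature_{i,d}) per tile, dropout disabled."""
    x = Tensor(bag.feats.astype(np.float64), requires_grad=True)
    out = model.forward_tensor(x, training=False)
    out.backward()
    if x.grad is None:
        raise RuntimeError("no gradient reached the bag input (broken graph)")
    if not np.all(np.isfinite(x.grad)):
        raise FloatingPointError("non-finite input gradient")
    return (x.grad * x.data).mean(axis=1)


def tile_pred_scores(bag: FeatureBag, model: MILRiskModel,
                     method: str = "minmax") -> np.ndarray:
    """Per-tile risk from singleton forward passes, normalized over the slide.

    ``minmax`` maps the raw range to [0, 1] (all-0.5 when the range is
    degenerate); ``softmax`` is available as an alternative normalization.
    """
    if bag.n_tiles < 1:
        raise ValueError("empty bag")
    raw = np.array([model.tile_forward(f) for f in bag.feats.astype(np.float64)])
    if method == "minmax":
        lo, hi = raw.min(), raw.max()
        if hi - lo < 1e-12:
            return np.full(raw.shape, 0.5)
        return (raw - lo) / (hi - lo)
    if method == "softmax":
        e = np.exp(raw - raw.max())
        return e / e.sum()
    raise ValueError(f"unknown normalization {method!r}")


def weighted_importance(gradcam: np.ndarray, tile_pred_norm: np.ndarray) -> np.ndarray:
    gradcam = np.asarray(gradcam, dtype=float)
    tile_pred_norm = np.asarray(tile_pred_norm, dtype=float)
    if gradcam.shape != tile_pred_norm.shape:
        raise ValueError("score vectors have mismatched lengths")
    return gradcam * tile_pred_norm


def attribute_bag(bag: FeatureBag, model: MILRiskModel, side_px: int = 224,
                  method: str = "minmax") -> AttributionMap:
    g = gradcam_scores(bag, model)
    p = tile_pred_scores(bag, model, method=method)
    return AttributionMap(slide_id=bag.slide_id, coords=bag.coords.copy(),
                          side_px=side_px, gradcam=g, tile_pred_norm=p,
                          weighted=weighted_importance(g, p))


def render_heatmap(amap: AttributionMap, thumbnail: np.ndarray,
                   downscale: float, alpha: float = 0.5,
                   cmap_name: str = "coolwarm") -> np.ndarray:
    """Paint tiles onto a slide thumbnail; returns an RGBA uint8 overlay.

    The colormap midpoint sits at weighted score 0 with a symmetric range
    (blue = protective, red = high risk). ``downscale`` is level-0 pixels per
    thumbnail pixel. Tiles falling outside the thumbnail raise.
    """
    h, w = thumbnail.shape[:2]
    vmax = float(np.max(np.abs(amap.weighted))) or 1.0
    cmap = matplotlib.colormaps[cmap_name]
    out = np.zeros((h, w, 4), dtype=np.float64)
    out[:, :, :3] = thumbnail[:, :, :3] / 255.0
    out[:, :, 3] = 1.0
    side = max(1, int(round(amap.side_px / downscale)))
    for (x, y), score in zip(amap.coords, amap.weighted):
        cx, cy = int(round(x / downscale)), int(round(y / downscale))
        if cx < 0 or cy < 0 or cx >= w or cy >= h:
            raise ValueError(f"tile at ({x}, {y}) maps outside the thumbnail")
        color = np.array(cmap(0.5 + 0.5 * score / vmax))
        x1, y1 = min(cx + side, w), min(cy + side, h)
        out[cy:y1, cx:x1, :3] = ((1 - alpha) * out[cy:y1, cx:x1, :3]
                                 + alpha * color[:3])
    return np.clip(np.round(out * 255), 0, 255).astype(np.uint8)


def top_tiles(amap: AttributionMap, k: int, direction: str = "high") -> np.ndarray:
    """Coordinates of the k most (or least) important tiles.

    Deterministic ordering: by weighted score (descending for "high",
    ascending for "low"), ties broken by (y, x).
    """
    n = len(amap.coords)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} tiles")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    sign = -1.0 if direction == "high" else 1.0
    order = sorted(range(n), key=lambda i: (sign * amap.weighted[i],
                                            amap.coords[i][1], amap.coords[i][0]))
    return np.array([amap.coords[i] for i in order[:k]])
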