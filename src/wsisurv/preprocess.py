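"""Slide tessellation, background rejection and Macenko stain normalization.

Tiles are planned on a micron-calibrated grid: the tile edge is a fixed
physical length (default 256 µm) converted to source pixels through the
slide's microns-per-pixel (mpp) value, and each tile is resized to 224x224,
giving an effective magnification of 256/224 ≈ 1.14 µm per pixel.
Background and blurry tiles are rejected by the density of Canny edges;
colors are standardized by the Macenko method (SVD plane of the optical
density cloud, percentile-extreme angles for the stain directions, and
per-stain concentration rescaling against a reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize

__all__ = [
    "SlideMeta", "TileRecord", "StainNormParams", "UnfittableTileError",
    "effective_mpp", "plan_tiles", "resize_tile", "canny_keep",
    "macenko_fit", "stain_concentrations", "normalize_tile", "read_region",
    "load_slide",
]


@dataclass(frozen=True)
class SlideMeta:
    slide_id: str
    width_px: int
    height_px: int
    mpp: float   # microns per pixel at level 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp is None or not np.isfinite(self.mpp) or self.mpp <= 0:
            raise ValueError(
                f"slide {self.slide_id!r} has no usable mpp ({self.mpp!r}); "
                "pass an explicit mpp override — no silent default is applied")


@dataclass
class TileRecord:
    x: int
    y: int
    side_px: int
    kept: bool = True
    canny_score: float = float("nan")


# Reference stain parameters a normalizer maps tiles onto: a hematoxylin-like
# direction (absorbs across red/green with a strong blue OD component) and an
# eosin-like direction dominated by green absorption, hematoxylin row first.
DEFAULT_REFERENCE_STAINS = (
    (0.56260570, 0.72008981, 0.40619373),
    (0.21005252, 0.95023759, 0.23005752),
)
DEFAULT_REFERENCE_MAXC = (1.9705, 1.0308)


@dataclass(frozen=True)
class StainNormParams:
    reference_stain_matrix: tuple = DEFAULT_REFERENCE_STAINS
    reference_max_concentrations: tuple = DEFAULT_REFERENCE_MAXC
    od_threshold: float = 0.15
    angle_percentiles: tuple = (1.0, 99.0)

    def __post_init__(self):
        m = np.asarray(self.reference_stain_matrix, dtype=float)
        if m.shape != (2, 3) or not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-3):
            raise ValueError("reference_stain_matrix must be 2x3 with unit rows")
        lo, hi = self.angle_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("angle_percentiles must satisfy 0 < low < high < 100")


class UnfittableTileError(RuntimeError):
    """Raised when a tile has too few tissue pixels or a degenerate OD cloud."""


def effective_mpp(tile_um: float = 256.0, out_px: int = 224) -> float:
    """Physical resolution of the resized tile (µm per output pixel)."""
    return tile_um / out_px


def plan_tiles(meta: SlideMeta, tile_um: float = 256.0) -> list[TileRecord]:
    """Non-overlapping grid of square tiles, origin (0,0), partial edges dropped.

    Coordinates are 0-based, half-open ``[x, x+side_px)`` at level 0.
    """
    side = round(tile_um / meta.mpp)
    if side < 1:
        raise ValueError("tile_um smaller than one source pixel")
    nx = meta.width_px // side
    ny = meta.height_px // side
    return [TileRecord(x=i * side, y=j * side, side_px=side)
            for j in range(ny) for i in range(nx)]


def resize_tile(img: np.ndarray, out_px: int = 224) -> np.ndarray:
    """Bilinear resize of a square RGB tile to out_px x out_px, 8-bit."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square RGB image, got shape {img.shape}")
    if img.shape[0] == out_px:
        return img.astype(np.uint8, copy=True)
    out = resize(img.astype(np.float64), (out_px, out_px, 3), order=1,
                 anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def canny_keep(img: np.ndarray, threshold: float = 2.0,
               hysteresis: tuple = (40.0, 100.0)) -> tuple[bool, float]:
    """Edge-density filter for background / blurry tiles.

    The grayscale tile is run through a Canny detector with the given
    hysteresis thresholds (on the 0–255 intensity scale); the score is the
    mean of the {0, 255}-coded edge map, and a tile is kept when the score
    reaches ``threshold``. A threshold of 2 therefore keeps tiles where at
    least ≈0.78% of pixels are edge pixels.
    """
    img = np.asarray(img)
    gray = rgb2gray(img) * 255.0 if img.ndim == 3 else img.astype(np.float64)
    edges = canny(gray, sigma=1.0, low_threshold=hysteresis[0],
                  high_threshold=hysteresis[1])
    score = float(edges.mean() * 255.0)
    return score >= threshold, score


# -- Macenko stain estimation -------------------------------------------------

def _optical_density(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    return -np.log10((img.astype(np.float64) + 1.0) / i0)


def stain_concentrations(img: np.ndarray, stain_matrix: np.ndarray,
                         i0: float = 255.0) -> np.ndarray:
    """Per-pixel non-negative stain concentrations (n_pixels, 2).

    Exact 2-variable non-negative least squares against the stain matrix:
    solve unconstrained normal equations, then re-solve single-stain
    projections for pixels where a component goes negative.
    """
    m = np.asarray(stain_matrix, dtype=float)          # (2, 3)
    od = _optical_density(img, i0).reshape(-1, 3)      # (n, 3)
    gram = m @ m.T                                     # (2, 2)
    rhs = od @ m.T                                     # (n, 2)
    c = rhs @ np.linalg.inv(gram).T                    # unconstrained solution
    neg = c < 0
    any_neg = neg.any(axis=1)
    if any_neg.any():
        # active-set fixups: one component clamped to zero, other projected
        for j in (0, 1):
            k = 1 - j
            sel = any_neg & neg[:, j]
            c[sel, j] = 0.0
            c[sel, k] = np.clip(od[sel] @ m[k] / (m[k] @ m[k]), 0.0, None)
        # pixels where both were negative end up at (0, 0)
        both = neg.all(axis=1)
        c[both] = 0.0
    return c


def macenko_fit(img: np.ndarray, od_threshold: float = 0.15,
                angle_percentiles: tuple = (1.0, 99.0), min_pixels: int = 50,
                i0: float = 255.0) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the 2x3 stain matrix and per-stain 99th-percentile concentrations.

    Pixels whose optical density is at or below ``od_threshold`` in any
    channel are treated as background and discarded; the remaining OD cloud
    is projected onto its top-2 principal plane, and the stain directions
    are the extreme-angle directions at ``angle_percentiles``. Rows are
    ordered hematoxylin-like first (larger blue OD component).

    Raises :class:`UnfittableTileError` when too few tissue pixels remain or
    the OD cloud is (near) rank-1, e.g. for grayscale images.
    """
    od = _optical_density(img, i0).reshape(-1, 3)
    tissue = od[~np.any(od <= od_threshold, axis=1)]
    if tissue.shape[0] < min_pixels:
        raise UnfittableTileError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}")

    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-4:
        raise UnfittableTileError("degenerate optical-density plane (rank < 2)")
    plane = evecs[:, :2]                               # (3, 2)
    # orient plane axes so projections are mostly positive
    for j in range(2):
        if (tissue @ plane[:, j]).sum() < 0:
            plane[:, j] = -plane[:, j]

    proj = tissue @ plane                              # (n, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, angle_percentiles)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    # hematoxylin-like row (larger blue OD component) first
    stains = np.vstack([v1, v2]) if v1[2] >= v2[2] else np.vstack([v2, v1])

    conc = stain_concentrations(img, stains, i0)
    max_c = np.percentile(conc, 99, axis=0)
    return stains, max_c


def normalize_tile(img: np.ndarray, fitted: tuple | None,
                   ref: StainNormParams, i0: float = 255.0) -> np.ndarray:
    """Re-render a tile through the reference stain basis.

    Concentrations w.r.t. the fitted matrix are rescaled per stain by
    ``reference_max / fitted_max`` and pushed back through the reference
    matrix. When ``fitted`` is None (unfittable tile) the image is returned
    unchanged — the caller is expected to have logged the fallback.
    """
    img = np.asarray(img)
    if fitted is None:
        return img.astype(np.uint8, copy=True)
    stains, max_c = fitted
    conc = stain_concentrations(img, stains, i0)
    ref_m = np.asarray(ref.reference_stain_matrix, dtype=float)
    ref_max = np.asarray(ref.reference_max_concentrations, dtype=float)
    scale = np.where(np.asarray(max_c) > 1e-8, ref_max / np.maximum(max_c, 1e-8), 1.0)
    od_new = (conc * scale) @ ref_m
    out = i0 * np.power(10.0, -od_new)
    return np.clip(np.round(out), 0, 255).astype(np.uint8).reshape(img.shape)


# -- thin slide reader --------------------------------------------------------

def load_slide(path, slide_id: str | None = None, mpp: float | None = None):
    """Read a single-level slide image (TIFF/PNG/JPEG) into memory.

    Returns ``(SlideMeta, pixels)``. Physical calibration must be supplied
    through ``mpp`` when the file carries none; a missing value raises.
    Pyramidal formats requiring a dedicated reader are out of scope — use
    pre-extracted feature bags for those.
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
        if mpp is None:
            res = im.info.get("resolution")
            if res and res[0] > 0:
                mpp = 10_000.0 / float(res[0])  # pixels/cm -> µm/px
    meta = SlideMeta(slide_id=slide_id or str(path), width_px=arr.shape[1],
                     height_px=arr.shape[0], mpp=mpp)
    return meta, arr


def read_region(pixels: np.ndarray, tile: TileRecord) -> np.ndarray:
    return pixels[tile.y:tile.y + tile.side_px, tile.x:tile.x + tile.side_px]
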