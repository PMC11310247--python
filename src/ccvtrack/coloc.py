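"""Fixed-image intensity metrics.

Rolling-ball background subtraction (Sternberg), thresholded Manders
overlap colocalization with Costes automatic thresholding, and the
thresholded mean-intensity readout used for live-cell dye quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball as _rolling_ball

__all__ = [
    "ColocResult",
    "rolling_ball_subtract",
    "costes_thresholds",
    "manders_overlap",
    "mean_intensity_above_threshold",
]


def rolling_ball_subtract(image: np.ndarray, radius: float = 50) -> np.ndarray:
    """Subtract a rolling-ball background (no pre-smoothing), clipped at 0.

    The background surface is a grayscale opening with a ball of the
    given radius; structures smaller than the ball survive, smooth
    background is removed.  A radius larger than the image degenerates to
    subtracting the image minimum.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    image = np.asarray(image, dtype=float)
    if radius >= max(image.shape):
        return image - float(image.min())
    bg = _rolling_ball(image, radius=radius)
    return np.clip(image - bg, 0.0, None)


@dataclass
class ColocResult:
    moc: float                  # NaN when undefined
    threshold_red: float
    threshold_green: float
    n_mask_pixels: int


def costes_thresholds(
    red: np.ndarray, green: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Costes automatic threshold pair.

    Regresses green on red, then walks the red threshold down from the
    maximum and returns the largest pair (T, a·T + b) for which the
    Pearson correlation of the below-threshold pixels drops to or below
    zero.  Falls back to the channel minima (include everything) when no
    such pair exists, e.g. for perfectly correlated channels.
    """
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    sel = np.ones(r.shape, bool) if mask is None else np.asarray(mask, bool)
    rv, gv = r[sel], g[sel]
    if rv.size < 2 or np.ptp(rv) == 0 or np.ptp(gv) == 0:
        return float(rv.min()) if rv.size else 0.0, float(gv.min()) if gv.size else 0.0
    a, b = np.polyfit(rv, gv, 1)
    for t in np.linspace(rv.max(), rv.min(), 256):
        below = (rv < t) & (gv < a * t + b)
        if below.sum() < 2:
            continue
        rb, gb = rv[below], gv[below]
        if np.ptp(rb) == 0 or np.ptp(gb) == 0:
            continue
        if np.corrcoef(rb, gb)[0, 1] <= 0:
            return float(t), float(a * t + b)
    return float(rv.min()), float(gv.min())


def manders_overlap(
    red: np.ndarray,
    green: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: tuple[float, float] | None = None,
    auto_threshold: bool = False,
) -> ColocResult:
    """Manders overlap coefficient over thresholded mask pixels.

    MOC = Σ RᵢGᵢ / sqrt(Σ Rᵢ² · Σ Gᵢ²) over mask pixels where either
    channel exceeds its threshold.  ``thresholds`` defaults to (0, 0);
    ``auto_threshold=True`` derives the pair with the Costes procedure.
    Returns MOC = NaN (undefined) when the mask is empty or neither
    channel carries signal inside it.
    """
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    if r.shape != g.shape:
        raise ValueError("channel shapes differ")
    m = np.ones(r.shape, bool) if mask is None else np.asarray(mask, bool)
    if mask is not None and m.shape != r.shape:
        raise ValueError("mask shape differs from channels")

    if thresholds is None:
        thresholds = costes_thresholds(r, g, m) if auto_threshold else (0.0, 0.0)
    tr, tg = thresholds
    sel = m & ((r > tr) | (g > tg))
    n = int(sel.sum())
    if n == 0:
        return ColocResult(float("nan"), tr, tg, 0)
    rs, gs = r[sel], g[sel]
    denom = np.sqrt(np.sum(rs**2) * np.sum(gs**2))
    if denom == 0:
        return ColocResult(float("nan"), tr, tg, n)
    return ColocResult(float(np.sum(rs * gs) / denom), float(tr), float(tg), n)


def manders_overlap_stack(
    red: np.ndarray,
    green: np.ndarray,
    mask: np.ndarray | None = None,
    mode: str = "per_slice",
    **kwargs,
) -> ColocResult:
    """MOC of a Z-stack: per-slice average (default) or pooled voxels."""
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.ndim == 2:
        return manders_overlap(red, green, mask, **kwargs)
    if mode == "pooled":
        m = None if mask is None else np.broadcast_to(mask, red.shape)
        return manders_overlap(red.reshape(-1), green.reshape(-1),
                               None if m is None else m.reshape(-1), **kwargs)
    results = [
        manders_overlap(red[z], green[z], mask, **kwargs) for z in range(red.shape[0])
    ]
    mocs = [res.moc for res in results if np.isfinite(res.moc)]
    return ColocResult(
        float(np.mean(mocs)) if mocs else float("nan"),
        float(np.mean([res.threshold_red for res in results])),
        float(np.mean([res.threshold_green for res in results])),
        int(sum(res.n_mask_pixels for res in results)),
    )


def mean_intensity_above_threshold(
    image: np.ndarray,
    threshold: float | None = None,
) -> float:
    """Mean intensity over the thresholded (cell-covered) area.

    ``threshold=None`` selects the two-class Otsu threshold; a number is
    used as a fixed cut.  Returns NaN with no passing pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if np.ptp(img) == 0:
            # constant image: everything is "cell"
            return float(img.flat[0])
        threshold = float(threshold_otsu(img))
    sel = img > threshold
    if not sel.any():
        return float("nan")
    return float(img[sel].mean())
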