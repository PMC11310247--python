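"""Sub-pixel spot detection by weighted least-squares Gaussian PSF fitting.

Candidate maxima are located on a Gaussian-smoothed copy of each frame,
then refined by fitting an isotropic 2-D Gaussian (amplitude, center,
width, local offset) to a window around each candidate.  Weights are the
inverse expected variance under Poisson statistics, floored at one.
Accepted fits must satisfy the width and amplitude gates (defaults: width
between 1 and 15 px, amplitude at least 5 a.u. above background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

__all__ = ["DetectionParams", "estimate_background", "detect_spots", "detect_movie",
           "DETECTION_COLUMNS"]

DETECTION_COLUMNS = ["frame", "x", "y", "amplitude", "sigma", "background", "residual"]


@dataclass(frozen=True)
class DetectionParams:
    """Gates and fitting controls for spot detection.

    ``intensity_threshold`` is measured above the frame background (frame
    median); ``sigma_min``/``sigma_max`` bound the accepted fitted width.
    ``candidate_gate`` selects whether the pre-filter compares the
    smoothed or the raw pixel value against the threshold: the smoothed
    gate (default) suppresses shot-noise maxima that would otherwise all
    be fitted, at the cost of attenuating peaks near the threshold; the
    fitted-amplitude gate applies in both cases.
    """

    intensity_threshold: float = 5.0
    sigma_min: float = 1.0
    sigma_max: float = 15.0
    candidate_smoothing_sigma: float = 2.0
    fit_window_halfwidth: int | None = None   # default ceil(3 * smoothing sigma)
    candidate_gate: str = "smoothed"
    merge_radius: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min < self.sigma_max:
            raise ValueError("require 0 < sigma_min < sigma_max")
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if self.candidate_gate not in ("raw", "smoothed"):
            raise ValueError("candidate_gate must be 'raw' or 'smoothed'")

    @property
    def window(self) -> int:
        if self.fit_window_halfwidth is not None:
            return int(self.fit_window_halfwidth)
        return int(math.ceil(3.0 * self.candidate_smoothing_sigma))


def estimate_background(frame: np.ndarray) -> float:
    """Median pixel intensity of the frame (robust to sparse bright spots)."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or np.all(np.isnan(frame)):
        raise ValueError("cannot estimate background of an empty or all-NaN image")
    return float(np.nanmedian(frame))


def _gauss2d(params: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    amp, x0, y0, sigma, off = params
    return off + amp * np.exp(
        -((xs - x0) ** 2 + (ys - y0) ** 2) / (2.0 * sigma**2)
    )


def _fit_spot(
    window: np.ndarray,
    x_origin: int,
    y_origin: int,
    init_sigma: float,
    background: float,
) -> tuple[np.ndarray, float] | None:
    """Weighted LS fit of one isotropic Gaussian; returns (params, residual)."""
    h, w = window.shape
    ys, xs = np.mgrid[0:h, 0:w]
    data = window.astype(float)
    # Poisson-motivated weights: 1/var with var ~= counts, floored at 1
    wgt = 1.0 / np.sqrt(np.maximum(data, 1.0))

    off0 = float(np.min(data))
    amp0 = max(float(np.max(data)) - off0, 1e-3)
    p0 = np.array([amp0, (w - 1) / 2.0, (h - 1) / 2.0, init_sigma, off0])

    def resid(p: np.ndarray) -> np.ndarray:
        return ((_gauss2d(p, xs, ys) - data) * wgt).ravel()

    def jac(p: np.ndarray) -> np.ndarray:
        amp, x0, y0, sigma, _ = p
        dx, dy = xs - x0, ys - y0
        g = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
        cols = [
            g,
            amp * g * dx / sigma**2,
            amp * g * dy / sigma**2,
            amp * g * (dx**2 + dy**2) / sigma**3,
            np.ones_like(g),
        ]
        return np.stack([(c * wgt).ravel() for c in cols], axis=1)

    try:
        res = optimize.least_squares(
            resid,
            p0,
            jac=jac,
            bounds=(
                [0.0, -1.0, -1.0, 0.2, -np.inf],
                [np.inf, w, h, 5.0 * max(w, h), np.inf],
            ),
            max_nfev=100,
        )
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    amp, x0, y0, sigma, off = res.x
    params = np.array([amp, x0 + x_origin, y0 + y_origin, sigma, off])
    residual = float(np.sqrt(np.mean(res.fun**2)))
    return params, residual


def detect_spots(
    frame: np.ndarray,
    params: DetectionParams | None = None,
    diagnostics: dict | None = None,
) -> pd.DataFrame:
    """Detect sub-pixel spots in a single frame.

    Returns a table with columns ``x, y, amplitude, sigma, background,
    residual`` (0-based pixel-center coordinates, x = column).  Fits that
    fail to converge or violate the gates are discarded; near-duplicate
    fits (< ``merge_radius`` px apart) keep the lower-residual one.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    bg = estimate_background(frame)
    hw = params.window
    smoothed = ndimage.gaussian_filter(frame, params.candidate_smoothing_sigma)
    gate_img = frame if params.candidate_gate == "raw" else smoothed

    coords = peak_local_max(
        smoothed, min_distance=max(1, int(round(params.candidate_smoothing_sigma))),
        exclude_border=False,
    )
    cands = [
        (r, c) for r, c in coords
        if gate_img[r, c] > bg + params.intensity_threshold
    ]

    diag = diagnostics if diagnostics is not None else {}
    diag.setdefault("n_candidates", 0)
    diag.setdefault("n_failed_fits", 0)
    diag["n_candidates"] += len(cands)

    h, w = frame.shape
    fits: list[tuple[float, float, float, float, float, float]] = []
    for r, c in cands:
        y0, y1 = max(0, r - hw), min(h, r + hw + 1)
        x0, x1 = max(0, c - hw), min(w, c + hw + 1)
        out = _fit_spot(frame[y0:y1, x0:x1], x0, y0,
                        params.candidate_smoothing_sigma, bg)
        if out is None:
            diag["n_failed_fits"] += 1
            continue
        (amp, fx, fy, sigma, off), residual = out
        if not (params.sigma_min <= sigma <= params.sigma_max):
            continue
        if amp < params.intensity_threshold:
            continue
        if not (x0 - 0.5 <= fx <= x1 - 0.5 and y0 - 0.5 <= fy <= y1 - 0.5):
            continue
        if not (0 <= fx <= w - 1 and 0 <= fy <= h - 1):
            continue
        fits.append((fx, fy, amp, sigma, off, residual))

    # merge near-duplicates, keeping the lower-residual fit
    fits.sort(key=lambda t: t[5])
    kept: list[tuple[float, float, float, float, float, float]] = []
    for f in fits:
        if all((f[0] - k[0]) ** 2 + (f[1] - k[1]) ** 2 >= params.merge_radius**2
               for k in kept):
            kept.append(f)

    return pd.DataFrame(
        kept, columns=["x", "y", "amplitude", "sigma", "background", "residual"]
    )


def detect_movie(
    stack: np.ndarray,
    params: DetectionParams | None = None,
    diagnostics: dict | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_spots` over every frame of a (T, H, W) stack.

    Returns the concatenated detection table with a leading ``frame``
    column; deterministic for identical input.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1:
        raise ValueError("stack must contain at least one frame")
    frames = []
    for f in range(stack.shape[0]):
        det = detect_spots(stack[f], params, diagnostics)
        det.insert(0, "frame", f)
        frames.append(det)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out.empty:
        out = pd.DataFrame(columns=DETECTION_COLUMNS)
    return out[DETECTION_COLUMNS]
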