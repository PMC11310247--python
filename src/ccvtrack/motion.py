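"""Track motion statistics: MSD, apparent diffusion constant, turning
angles, asymmetry coefficient and track length.

The mean square displacement of a track at lag ``tau`` (frames) is the
average of ``(x_{t+tau} - x_t)^2 + (y_{t+tau} - y_t)^2`` over all pairs of
observed frames exactly ``tau`` apart; for a contiguous track of N frames
this is the standard ``(1/(N - tau)) * sum_{t=1}^{N-tau}`` estimator.  For
free 2-D diffusion ``MSD(tau) = 4 D tau``, so the apparent diffusion
constant is a quarter of the slope of a line fitted through the first four
lags.

The turning angle between subsequent displacements ``v1 = p2 - p1`` and
``v2 = p3 - p2`` is ``alpha = |atan2(det(v1, v2), dot(v1, v2))|`` in
[0°, 180°]: 0° continues in the same direction, 180° is a full reversal.
The asymmetry coefficient AC is the ratio of the frequency of
near-reversal angles (180° ± 30°) to near-persistent angles (0–30°)
pooled over a field's displacements; Brownian motion gives AC ≈ 1 and
directed motion drives AC toward 0 — the lower the AC, the more
directional the transport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .link import Track

__all__ = [
    "MSDCurve",
    "Calibration",
    "FieldSummary",
    "msd",
    "fit_diffusion",
    "turning_angles",
    "asymmetry_coefficient",
    "track_length",
    "summarize_field",
    "per_track_metrics",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration: px → µm and frame → s conversion."""

    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def diffusion_to_si(self, d_px2_per_frame: float) -> float:
        """Convert D from px²/frame to µm²/s."""
        return d_px2_per_frame * self.pixel_size_um**2 / self.frame_interval_s

    def msd_to_si(self, msd_px2: float) -> float:
        return msd_px2 * self.pixel_size_um**2


@dataclass
class MSDCurve:
    """MSD(τ) per lag, with the number of displacement pairs behind each."""

    lags: np.ndarray       # frames, strictly increasing
    values: np.ndarray     # px²
    n_pairs: np.ndarray
    n_frames: int          # N: frames in the track's span

    def value_at(self, lag: int) -> float:
        idx = np.flatnonzero(self.lags == lag)
        if len(idx) == 0:
            raise KeyError(f"no displacement pairs at lag {lag}")
        return float(self.values[idx[0]])


def msd(track: Track | np.ndarray, frames: np.ndarray | None = None) -> MSDCurve:
    """Mean square displacement per lag over all observed frame pairs.

    Accepts a :class:`~ccvtrack.link.Track` or an (n, 2) position array
    with an optional explicit frame vector (defaults to 0..n-1).  Lags
    with no observed pairs (gaps) are omitted; ``n_pairs`` records the
    averaging depth per lag.
    """
    if isinstance(track, Track):
        pos = track.positions()
        f = track.frames()
    else:
        pos = np.asarray(track, dtype=float)
        f = np.arange(len(pos)) if frames is None else np.asarray(frames, dtype=int)
    if len(pos) < 2:
        raise ValueError("MSD requires at least 2 observed frames")

    span = int(f[-1] - f[0])
    sums = np.zeros(span + 1)
    counts = np.zeros(span + 1, dtype=int)
    # all-pairs accumulation; lag = frame difference
    for i in range(len(pos)):
        dtau = f[i + 1:] - f[i]
        sq = np.sum((pos[i + 1:] - pos[i]) ** 2, axis=1)
        np.add.at(sums, dtau, sq)
        np.add.at(counts, dtau, 1)
    have = np.flatnonzero(counts[1:]) + 1
    return MSDCurve(
        lags=have,
        values=sums[have] / counts[have],
        n_pairs=counts[have],
        n_frames=span + 1,
    )


def fit_diffusion(curve: MSDCurve, n_lags: int = 4) -> float:
    """Apparent diffusion constant from the early MSD slope.

    Fits an unweighted least-squares line with free intercept through
    ``(tau, MSD(tau))`` for ``tau = 1..n_lags`` and returns slope / 4
    (px²/frame).  ``through_origin`` fitting of MSD = 4 D tau is available
    via :func:`fit_diffusion_origin`.  May be negative for noisy short
    tracks; reported as-is.
    """
    sel = curve.lags <= n_lags
    if sel.sum() < n_lags:
        raise ValueError(
            f"MSD curve has {int(sel.sum())} of the first {n_lags} lags; "
            "cannot fit diffusion constant"
        )
    taus = curve.lags[sel].astype(float)
    vals = curve.values[sel]
    slope = np.polyfit(taus, vals, 1)[0]
    return float(slope) / 4.0


def fit_diffusion_origin(curve: MSDCurve, n_lags: int = 4) -> float:
    """Through-origin variant: least-squares slope of MSD = 4 D tau."""
    sel = curve.lags <= n_lags
    if sel.sum() < n_lags:
        raise ValueError("insufficient lags for diffusion fit")
    taus = curve.lags[sel].astype(float)
    vals = curve.values[sel]
    return float(np.dot(taus, vals) / np.dot(taus, taus)) / 4.0


def turning_angles(track: Track | np.ndarray, frames: np.ndarray | None = None) -> np.ndarray:
    """Angles between subsequent displacements, degrees in [0, 180].

    Only triples of *consecutive* observed frames are used (no gap inside
    a triple); zero-length displacements skip the triple.  Returns an
    empty array when fewer than three usable consecutive frames exist.
    """
    if isinstance(track, Track):
        pos = track.positions()
        f = track.frames()
    else:
        pos = np.asarray(track, dtype=float)
        f = np.arange(len(pos)) if frames is None else np.asarray(frames, dtype=int)
    if len(pos) < 3:
        return np.empty(0)
    out = []
    for i in range(len(pos) - 2):
        if f[i + 1] - f[i] != 1 or f[i + 2] - f[i + 1] != 1:
            continue
        v1 = pos[i + 1] - pos[i]
        v2 = pos[i + 2] - pos[i + 1]
        if not (np.any(v1) and np.any(v2)):
            continue
        det = v1[0] * v2[1] - v1[1] * v2[0]
        dot = float(np.dot(v1, v2))
        out.append(abs(math.degrees(math.atan2(det, dot))))
    return np.asarray(out)


def asymmetry_coefficient(
    angles: np.ndarray,
    reversal_min: float = 150.0,
    forward_max: float = 30.0,
    method: str = "tails",
) -> float:
    """Ratio of reversal-angle to persistent-angle frequencies (AC).

    ``method="tails"`` (default): AC = frac(α ≥ reversal_min) /
    frac(α ≤ forward_max), i.e. 180 ± 30° over 0–30° with the defaults.
    ``method="overlapping"`` is an alternative definition seen in the
    field, frac(α ≥ 15°) / frac(α ≤ 30°) with overlapping bins.

    Returns NaN when the denominator frequency is zero (degenerate field)
    rather than infinity.
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) == 0:
        raise ValueError("cannot compute AC of an empty angle series")
    if method == "tails":
        num = np.mean(angles >= reversal_min)
    elif method == "overlapping":
        num = np.mean(angles >= 15.0)
    else:
        raise ValueError("method must be 'tails' or 'overlapping'")
    den = np.mean(angles <= forward_max)
    if den == 0.0:
        return float("nan")
    return float(num / den)


def track_length(track: Track) -> int:
    """Number of frames in which the particle was observed (gaps excluded)."""
    return track.n_observed


@dataclass
class FieldSummary:
    """Per-field (per-movie / per-cell) aggregate of track statistics."""

    n_tracks: int
    asymmetry_coefficient: float = float("nan")
    mean_msd_at: dict[int, float] = field(default_factory=dict)
    mean_msd_at_um2: dict[int, float] = field(default_factory=dict)
    mean_track_length: float = float("nan")
    median_diffusion_px2_per_frame: float = float("nan")
    median_diffusion_um2_per_s: float = float("nan")
    n_angles: int = 0

    def to_dict(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "asymmetry_coefficient": self.asymmetry_coefficient,
            "mean_msd_at": {str(k): v for k, v in self.mean_msd_at.items()},
            "mean_msd_at_um2": {str(k): v for k, v in self.mean_msd_at_um2.items()},
            "mean_track_length": self.mean_track_length,
            "median_diffusion_px2_per_frame": self.median_diffusion_px2_per_frame,
            "median_diffusion_um2_per_s": self.median_diffusion_um2_per_s,
            "n_angles": self.n_angles,
        }


def per_track_metrics(
    tracks: list[Track],
    n_lags: int = 4,
    calibration: Calibration | None = None,
) -> pd.DataFrame:
    """Per-track table: length, D (px²/frame and µm²/s), MSD at lags 1..n_lags."""
    cal = calibration or Calibration()
    rows = []
    for tr in tracks:
        curve = msd(tr)
        try:
            d = fit_diffusion(curve, n_lags)
        except ValueError:
            d = float("nan")
        row = {
            "track_id": tr.track_id,
            "track_length": tr.n_observed,
            "D_px2_per_frame": d,
            "D_um2_per_s": cal.diffusion_to_si(d) if np.isfinite(d) else float("nan"),
        }
        for lag in range(1, n_lags + 1):
            try:
                row[f"msd_lag{lag}"] = curve.value_at(lag)
            except KeyError:
                row[f"msd_lag{lag}"] = float("nan")
        rows.append(row)
    cols = ["track_id", "track_length", "D_px2_per_frame", "D_um2_per_s"] + [
        f"msd_lag{lag}" for lag in range(1, n_lags + 1)
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_field(
    tracks: list[Track],
    calibration: Calibration | None = None,
    msd_lags: tuple[int, ...] = (1, 2, 3, 4),
    ac_kwargs: dict | None = None,
) -> FieldSummary:
    """Pool a field's tracks into the headline readouts.

    AC is computed over the pooled displacements of all tracks in the
    field (per-cell aggregation); MSD at each requested lag is averaged
    over the tracks possessing that lag.
    """
    cal = calibration or Calibration()
    if not tracks:
        return FieldSummary(n_tracks=0)
    pooled = [a for tr in tracks for a in turning_angles(tr)]
    ac = (
        asymmetry_coefficient(np.asarray(pooled), **(ac_kwargs or {}))
        if pooled
        else float("nan")
    )
    mean_msd: dict[int, float] = {}
    for lag in msd_lags:
        vals = []
        for tr in tracks:
            try:
                vals.append(msd(tr).value_at(lag))
            except (KeyError, ValueError):
                pass
        if vals:
            mean_msd[lag] = float(np.mean(vals))
    metrics = per_track_metrics(tracks, calibration=cal)
    d_med = float(np.nanmedian(metrics["D_px2_per_frame"])) if len(metrics) else float("nan")
    return FieldSummary(
        n_tracks=len(tracks),
        asymmetry_coefficient=ac,
        mean_msd_at=mean_msd,
        mean_msd_at_um2={k: cal.msd_to_si(v) for k, v in mean_msd.items()},
        mean_track_length=float(np.mean([tr.n_observed for tr in tracks])),
        median_diffusion_px2_per_frame=d_med,
        median_diffusion_um2_per_s=(
            cal.diffusion_to_si(d_med) if np.isfinite(d_med) else float("nan")
        ),
        n_angles=len(pooled),
    )
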