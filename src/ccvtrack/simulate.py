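"""Synthetic fluorescence-microscopy scenes with known ground truth.

This module generates the three kinds of data the analysis stages consume:

* time-lapse movies of diffraction-limited spots moving by Brownian and/or
  directed 2-D motion, with per-frame disappearance and blinking;
* two-channel colocalization scenes with a controllable fraction of shared
  spot positions;
* cell scenes (a fillable cell channel plus a vesicle channel) with
  controllable radial placement of vesicles inside the cell.

Time is measured in frames and space in pixels throughout; physical units
enter only through :class:`OpticsModel` calibration (``pixel_size_um``,
``frame_interval_s``).  Spots are rendered as isotropic 2-D Gaussians
evaluated at pixel centers; optional Poisson noise is applied to the
expected counts, followed by additive Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "MotionModel",
    "OpticsModel",
    "GroundTruth",
    "simulate_tracks",
    "render_movie",
    "make_coloc_pair",
    "make_cell_scene",
]


@dataclass(frozen=True)
class MotionModel:
    """Per-particle 2-D motion regime.

    Parameters
    ----------
    kind : {"stationary", "brownian", "directed"}
        Motion regime. ``directed`` superimposes a constant drift on
        (optionally zero) Brownian motion.
    D : float
        Diffusion constant in px²/frame. Brownian steps are isotropic
        Gaussian with per-axis variance ``2*D`` per frame, so the 2-D
        ensemble MSD grows as ``4*D*tau``.
    v : float
        Drift speed in px/frame (``directed`` only).
    heading : float
        Drift direction in degrees (0° = +x).
    p_off : float
        Per-frame probability of permanent disappearance.
    p_blink : float
        Per-frame probability of entering a transient dark gap; gap
        lengths are geometric with parameter ``1 - p_blink`` (so small
        ``p_blink`` gives mostly single-frame gaps).
    """

    kind: Literal["stationary", "brownian", "directed"] = "brownian"
    D: float = 0.0
    v: float = 0.0
    heading: float = 0.0
    p_off: float = 0.0
    p_blink: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stationary", "brownian", "directed"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if not (np.isfinite(self.D) and self.D >= 0):
            raise ValueError("D must be finite and >= 0")
        if not (np.isfinite(self.v) and self.v >= 0):
            raise ValueError("v must be finite and >= 0")
        for name in ("p_off", "p_blink"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class OpticsModel:
    """Rendering and calibration parameters of the simulated microscope."""

    psf_sigma: float = 2.0            # px, isotropic Gaussian PSF width
    amplitude: float = 100.0          # a.u., peak height above background
    background: float = 10.0          # a.u., constant offset
    read_noise_sigma: float = 0.0     # a.u., additive Gaussian noise
    poisson_noise: bool = False
    image_shape: tuple[int, int] = (128, 128)   # (H, W)
    pixel_size_um: float = 0.1083     # 60x objective, 6.5 um camera pixels
    frame_interval_s: float = 1.0     # 1 s between frames

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Simulator output pairing true trajectories/scenes with annotations.

    ``tracks`` is a long-format table with columns
    ``particle_id, frame, x, y, visible, in_field``: one row per particle
    per frame while the particle exists. ``visible`` is False during
    blink gaps; ``in_field`` is False when the true position left the
    image bounds (such spots are not rendered but stay in the truth).
    ``spots`` holds per-channel fixed-scene spot lists and ``cells``
    per-cell annotations, when applicable.
    """

    tracks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["particle_id", "frame", "x", "y", "visible", "in_field"]
        )
    )
    spots: dict[str, pd.DataFrame] = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def visible_spots(self, frame: int) -> pd.DataFrame:
        t = self.tracks
        return t[(t["frame"] == frame) & t["visible"] & t["in_field"]]


def _in_field(x: float, y: float, shape: tuple[int, int]) -> bool:
    h, w = shape
    return 0.0 <= x <= w - 1 and 0.0 <= y <= h - 1


def simulate_tracks(
    model: MotionModel,
    n_tracks: int,
    n_frames: int,
    shape: tuple[int, int] = (128, 128),
    seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Simulate ``n_tracks`` independent 2-D trajectories over ``n_frames``.

    Starting positions are uniform inside the field with a 4-px margin.
    Disappearance (``p_off``) is permanent once drawn; blinking
    (``p_blink``) produces missing frames with later reappearance.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = min(4.0, w / 4, h / 4)

    heading_rad = math.radians(model.heading)
    drift = (
        np.array([model.v * math.cos(heading_rad), model.v * math.sin(heading_rad)])
        if model.kind == "directed"
        else np.zeros(2)
    )
    step_sigma = math.sqrt(2.0 * model.D) if model.kind != "stationary" else 0.0

    rows: list[tuple] = []
    for pid in range(n_tracks):
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        gap_left = 0
        for f in range(n_frames):
            if f > 0:
                if step_sigma > 0:
                    dx, dy = rng.normal(0.0, step_sigma, size=2)
                else:
                    dx = dy = 0.0
                x += dx + drift[0]
                y += dy + drift[1]
                if model.p_off > 0 and rng.random() < model.p_off:
                    break
            visible = True
            if gap_left > 0:
                visible = False
                gap_left -= 1
            elif model.p_blink > 0 and f > 0 and rng.random() < model.p_blink:
                visible = False
                gap_left = int(rng.geometric(1.0 - model.p_blink)) - 1
            rows.append((pid, f, x, y, visible, _in_field(x, y, shape)))

    tracks = pd.DataFrame(
        rows, columns=["particle_id", "frame", "x", "y", "visible", "in_field"]
    )
    return GroundTruth(
        tracks=tracks,
        params={
            "motion": model.__dict__ | {"kind": model.kind},
            "n_tracks": n_tracks,
            "n_frames": n_frames,
            "shape": tuple(shape),
        },
    )


def _render_spot(frame: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Add one Gaussian spot in place, evaluated at pixel centers."""
    h, w = frame.shape
    r = int(math.ceil(5.0 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-((xs - x) ** 2) / (2.0 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2.0 * sigma**2))
    frame[y0:y1, x0:x1] += amp * np.outer(gy, gx)


def _apply_noise(movie: np.ndarray, optics: OpticsModel, rng: np.random.Generator) -> np.ndarray:
    if optics.poisson_noise:
        movie = rng.poisson(np.clip(movie, 0, None)).astype(np.float64)
    if optics.read_noise_sigma > 0:
        movie = movie + rng.normal(0.0, optics.read_noise_sigma, size=movie.shape)
    return movie


def render_movie(
    truth: GroundTruth,
    optics: OpticsModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render a ground-truth track set into a (T, H, W) float64 movie.

    Particles outside the field or in a blink gap are not rendered.
    An empty truth yields a pure-background movie.
    """
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    t = truth.tracks
    n_frames = int(t["frame"].max()) + 1 if len(t) else int(truth.params.get("n_frames", 1))
    movie = np.full((n_frames, h, w), float(optics.background))
    for f in range(n_frames):
        vis = truth.visible_spots(f)
        frame = movie[f]
        for x, y in zip(vis["x"].to_numpy(), vis["y"].to_numpy()):
            _render_spot(frame, x, y, optics.amplitude, optics.psf_sigma)
    return _apply_noise(movie, optics, rng)


def _draw_separated_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    existing: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` points pairwise (and vs existing) >= min_sep apart."""
    pts: list[tuple[float, float]] = []
    anchors = list(existing or [])
    h, w = shape
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place spots with requested separation")
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts + anchors):
            pts.append((x, y))
    return pts


def make_coloc_pair(
    n_spots: int,
    overlap_fraction: float,
    optics: OpticsModel,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two-channel scene sharing ``round(f * n_spots)`` spot positions.

    Returns ``(red, green, truth)``; non-shared spots are placed
    independently per channel with centers at least ``4 * psf_sigma``
    apart from every other spot.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    n_shared = int(round(overlap_fraction * n_spots))
    min_sep = 4.0 * optics.psf_sigma
    margin = 3.0 * optics.psf_sigma

    shared = _draw_separated_points(rng, n_shared, (h, w), min_sep, margin)
    own_r = _draw_separated_points(rng, n_spots - n_shared, (h, w), min_sep, margin, shared)
    own_g = _draw_separated_points(
        rng, n_spots - n_shared, (h, w), min_sep, margin, shared + own_r
    )

    channels = {}
    spots = {}
    for name, pts in (("red", shared + own_r), ("green", shared + own_g)):
        img = np.full((h, w), float(optics.background))
        for x, y in pts:
            _render_spot(img, x, y, optics.amplitude, optics.psf_sigma)
        channels[name] = _apply_noise(img[None], optics, rng)[0]
        spots[name] = pd.DataFrame(pts, columns=["x", "y"]).assign(
            shared=[True] * n_shared + [False] * (len(pts) - n_shared)
        )

    truth = GroundTruth(
        spots=spots,
        params={"n_spots": n_spots, "overlap_fraction": overlap_fraction,
                "n_shared": n_shared},
    )
    return channels["red"], channels["green"], truth


def make_spot_frames(
    n_frames: int,
    n_spots: int,
    optics: OpticsModel,
    seed: int | np.random.Generator = 0,
    min_sep: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Independent frames of well-separated static spots.

    A detector benchmark scene: each frame draws ``n_spots`` fresh
    positions at least ``min_sep`` (default ``4 * psf_sigma``) apart.
    Returns the rendered (T, H, W) movie and a truth whose ``tracks``
    table lists one record per rendered spot.
    """
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    sep = 4.0 * optics.psf_sigma if min_sep is None else min_sep
    margin = 3.0 * optics.psf_sigma
    movie = np.full((n_frames, h, w), float(optics.background))
    rows = []
    for f in range(n_frames):
        pts = _draw_separated_points(rng, n_spots, (h, w), sep, margin)
        for pid, (x, y) in enumerate(pts):
            _render_spot(movie[f], x, y, optics.amplitude, optics.psf_sigma)
            rows.append((pid, f, x, y, True, True))
    movie = _apply_noise(movie, optics, rng)
    tracks = pd.DataFrame(
        rows, columns=["particle_id", "frame", "x", "y", "visible", "in_field"]
    )
    return movie, GroundTruth(tracks=tracks,
                              params={"n_frames": n_frames, "n_spots": n_spots})


def match_points(
    truth_xy: np.ndarray, found_xy: np.ndarray, radius: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of found points to true points.

    Pairs are accepted in ascending-distance order within ``radius``.
    Returns (true indices, found indices, distances) of the matches —
    the basis for recall / precision / localization-error scoring.
    """
    truth_xy = np.asarray(truth_xy, float)
    found_xy = np.asarray(found_xy, float)
    if len(truth_xy) == 0 or len(found_xy) == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    d = np.sqrt(
        ((truth_xy[:, None, :] - found_xy[None, :, :]) ** 2).sum(axis=2)
    )
    ti, fi = np.nonzero(d <= radius)
    order = np.argsort(d[ti, fi], kind="stable")
    used_t: set[int] = set()
    used_f: set[int] = set()
    mt, mf, md = [], [], []
    for k in order:
        a, b = int(ti[k]), int(fi[k])
        if a in used_t or b in used_f:
            continue
        used_t.add(a)
        used_f.add(b)
        mt.append(a)
        mf.append(b)
        md.append(float(d[a, b]))
    return np.asarray(mt, int), np.asarray(mf, int), np.asarray(md)


def make_cell_scene(
    cell_radius: float,
    n_vesicles: int,
    radial_law: str = "uniform_disk",
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
    centers: list[tuple[float, float]] | None = None,
    cell_amplitude: float | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Cell + vesicle channel pair with known radial vesicle placement.

    ``radial_law`` is either ``"uniform_disk"`` (area-uniform placement,
    mean radius 2R/3) or ``"ring:<r>"`` (all vesicles at radius r).
    ``centers`` defaults to a single cell at the image center; the truth
    flags cells whose disk touches the image border.
    """
    optics = optics or OpticsModel()
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    if centers is None:
        centers = [((w - 1) / 2.0, (h - 1) / 2.0)]

    ring_r: float | None = None
    if radial_law.startswith("ring"):
        ring_r = float(radial_law.split(":", 1)[1]) if ":" in radial_law else float(
            radial_law.strip("ring()")
        )
        if ring_r >= cell_radius:
            raise ValueError("ring radius must be < cell_radius")
    elif radial_law != "uniform_disk":
        raise ValueError(f"unknown radial_law {radial_law!r}")

    cell_amp = cell_amplitude if cell_amplitude is not None else optics.amplitude / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    cell_img = np.full((h, w), float(optics.background))
    ves_img = np.full((h, w), float(optics.background))

    cell_rows = []
    ves_rows = []
    for label, (cx, cy) in enumerate(centers, start=1):
        cell_img[(xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2] += cell_amp
        touches = (
            cx - cell_radius < 0 or cx + cell_radius > w - 1
            or cy - cell_radius < 0 or cy + cell_radius > h - 1
        )
        cell_rows.append((label, cx, cy, cell_radius, touches))
        for _ in range(n_vesicles):
            if ring_r is not None:
                r = ring_r
            else:
                r = cell_radius * math.sqrt(rng.random())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            vx, vy = cx + r * math.cos(theta), cy + r * math.sin(theta)
            _render_spot(ves_img, vx, vy, optics.amplitude, optics.psf_sigma)
            ves_rows.append((label, vx, vy, r))

    cell_img = _apply_noise(cell_img[None], optics, rng)[0]
    ves_img = _apply_noise(ves_img[None], optics, rng)[0]
    truth = GroundTruth(
        spots={"vesicles": pd.DataFrame(
            ves_rows, columns=["cell_label", "x", "y", "true_distance"])},
        cells=pd.DataFrame(
            cell_rows, columns=["label", "cx", "cy", "radius", "border_touching"]),
        params={"cell_radius": cell_radius, "n_vesicles": n_vesicles,
                "radial_law": radial_law},
    )
    return cell_img, ves_img, truth
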