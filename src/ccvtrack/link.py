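"""Nearest-neighbour track linking with gap closing.

Detections are linked frame by frame: every active track is matched to
the nearest unclaimed detection within ``link_radius`` of its last
observed position, conflicts resolved globally per frame by ascending
pair distance (ties broken by lower track id, then lower detection row
index).  Unmatched detections seed new tracks; a track missing from up
to ``max_gap`` consecutive frames stays eligible and is closed after
that.  Tracks observed in fewer than ``min_length`` frames are dropped.

Defaults follow the tracking settings used for clathrin-coated-vesicle
movies: 3 px search radius, 5-frame maximum gap, 5-frame minimum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as _opt

__all__ = ["LinkParams", "Track", "link_tracks", "track_table", "TRACK_COLUMNS"]

TRACK_COLUMNS = ["track_id", "frame", "x", "y", "amplitude"]


@dataclass(frozen=True)
class LinkParams:
    link_radius: float = 3.0     # px, max step between linked detections
    max_gap: int = 5             # frames a track may go unobserved
    min_length: int = 5          # minimum observed frames to keep a track
    scale_radius_with_gap: bool = False   # radius *= sqrt(gap+1) when bridging
    assignment: str = "greedy"   # "greedy" (nearest-neighbour) or "optimal"

    def __post_init__(self) -> None:
        if self.link_radius <= 0:
            raise ValueError("link_radius must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.assignment not in ("greedy", "optimal"):
            raise ValueError("assignment must be 'greedy' or 'optimal'")


@dataclass
class Track:
    """An identity-linked, frame-ordered sequence of detections."""

    track_id: int
    points: pd.DataFrame   # columns frame, x, y, amplitude; frames increasing

    @property
    def n_observed(self) -> int:
        return len(self.points)

    @property
    def span(self) -> int:
        f = self.points["frame"]
        return int(f.iloc[-1] - f.iloc[0] + 1)

    def positions(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)

    def frames(self) -> np.ndarray:
        return self.points["frame"].to_numpy(dtype=int)


class _ActiveTrack:
    __slots__ = ("track_id", "rows", "last_frame", "last_xy")

    def __init__(self, track_id: int, frame: int, row: tuple):
        self.track_id = track_id
        self.rows = [row]
        self.last_frame = frame
        self.last_xy = (row[1], row[2])

    def add(self, frame: int, row: tuple) -> None:
        self.rows.append(row)
        self.last_frame = frame
        self.last_xy = (row[1], row[2])


def link_tracks(
    detections: pd.DataFrame,
    params: LinkParams | None = None,
) -> list[Track]:
    """Link a per-frame detection table into :class:`Track` objects.

    ``detections`` needs columns ``frame, x, y`` (``amplitude`` optional,
    defaulting to NaN).  Returns tracks passing the minimum-length cut,
    ordered by track id (seeding order).
    """
    params = params or LinkParams()
    if detections is None or len(detections) == 0:
        return []
    det = detections.copy()
    if "amplitude" not in det.columns:
        det["amplitude"] = np.nan
    det = det.sort_values("frame", kind="stable").reset_index(drop=True)

    active: list[_ActiveTrack] = []
    closed: list[_ActiveTrack] = []
    next_id = 0

    for frame, grp in det.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks whose gap budget is spent
        still = []
        for tr in active:
            if frame - tr.last_frame - 1 > params.max_gap:
                closed.append(tr)
            else:
                still.append(tr)
        active = still

        xs = grp["x"].to_numpy(dtype=float)
        ys = grp["y"].to_numpy(dtype=float)
        amps = grp["amplitude"].to_numpy(dtype=float)
        n_det = len(grp)

        pairs: list[tuple[float, int, int]] = []  # (distance, track idx, det idx)
        for ti, tr in enumerate(active):
            gap = frame - tr.last_frame - 1
            radius = params.link_radius
            if params.scale_radius_with_gap and gap > 0:
                radius *= math.sqrt(gap + 1)
            dx = xs - tr.last_xy[0]
            dy = ys - tr.last_xy[1]
            d = np.hypot(dx, dy)
            for di in np.flatnonzero(d <= radius):
                pairs.append((float(d[di]), ti, int(di)))

        track_claimed = [False] * len(active)
        det_claimed = [False] * n_det
        if params.assignment == "optimal" and pairs:
            cost = np.full((len(active), n_det), 1e9)
            for d, ti, di in pairs:
                cost[ti, di] = d
            ri, ci = _opt.linear_sum_assignment(cost)
            matches = [(ti, di) for ti, di in zip(ri, ci) if cost[ti, di] < 1e9]
        else:
            # greedy nearest-neighbour: ascending distance, deterministic ties
            pairs.sort(key=lambda p: (p[0], active[p[1]].track_id, p[2]))
            matches = []
            for d, ti, di in pairs:
                if not track_claimed[ti] and not det_claimed[di]:
                    matches.append((ti, di))
                    track_claimed[ti] = True
                    det_claimed[di] = True

        for ti, di in matches:
            track_claimed[ti] = True
            det_claimed[di] = True
            active[ti].add(frame, (frame, float(xs[di]), float(ys[di]), float(amps[di])))
        for di in range(n_det):
            if not det_claimed[di]:
                tr = _ActiveTrack(
                    next_id, frame,
                    (frame, float(xs[di]), float(ys[di]), float(amps[di])),
                )
                next_id += 1
                active.append(tr)

    closed.extend(active)
    closed.sort(key=lambda tr: tr.track_id)
    out = []
    for tr in closed:
        if len(tr.rows) < params.min_length:
            continue
        pts = pd.DataFrame(tr.rows, columns=["frame", "x", "y", "amplitude"])
        out.append(Track(track_id=tr.track_id, points=pts))
    return out


def track_table(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a long-format table (track_id, frame, x, y, amplitude)."""
    if not tracks:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    rows = []
    for tr in tracks:
        p = tr.points.copy()
        p.insert(0, "track_id", tr.track_id)
        rows.append(p)
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a long-format table."""
    if table is None or len(table) == 0:
        return []
    out = []
    for tid, grp in table.groupby("track_id", sort=True):
        pts = grp.sort_values("frame")[["frame", "x", "y", "amplitude"]].reset_index(
            drop=True
        )
        out.append(Track(track_id=int(tid), points=pts))
    return out
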