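"""Frame-to-frame linking of detections into cell tracks.

Flow is unidirectional and the sample dilute, so a gated greedy
nearest-neighbor linker is sufficient: a candidate link must advance
downstream by a displacement consistent with the expected velocity range,
stay within a lateral gate, and — once a track has a velocity history —
stay consistent with its own previous step.  Candidate links are resolved
globally per frame pair in order of increasing cost (primarily the
downstream advance, with a lateral penalty), one successor per detection.

Each accepted track carries an ordinary-least-squares velocity fit over
its whole span (which averages pixel-quantization noise) and the mean
normalized lateral position |y/W| measured from the channel centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Detection
from .errors import ConfigurationError, RejectedInputError
from .geometry import ChannelGeometry


@dataclass
class CellTrack:
    """A linked sequence of detections of one cell."""

    track_id: int
    detections: list[Detection]
    velocity_mm_s: float | None = None
    velocity_fit_residual_px: float | None = None
    mean_abs_yW: float | None = None

    @property
    def n_frames(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class LinkingParams:
    expected_velocity_range: tuple[float, float] = (0.1, 10.0)  # mm/s
    gate_y_px: float = 8.0
    min_track_length: int = 3
    step_margin_lo: float = 0.8  # fraction of slowest expected step
    step_margin_hi: float = 1.08  # fraction of fastest expected step
    consistency_frac: float = 0.35  # allowed step change for established tracks


def link_tracks(
    detections_per_frame: list[list[Detection]],
    geometry: ChannelGeometry,
    frame_rate_hz: float,
    params: LinkingParams = LinkingParams(),
) -> list[CellTrack]:
    """Greedy gated nearest-neighbor linking; drops tracks below minimum length."""
    if frame_rate_hz <= 0:
        raise ConfigurationError("frame_rate_hz must be positive")
    v_lo, v_hi = params.expected_velocity_range
    px_per_mm_s = 1000.0 / geometry.pixel_size_um / frame_rate_hz
    step_lo = max(0.5, v_lo * px_per_mm_s * params.step_margin_lo - 1.0)
    step_hi = v_hi * px_per_mm_s * params.step_margin_hi + 2.0

    open_tracks: list[list[Detection]] = []
    closed: list[list[Detection]] = []

    for t, dets in enumerate(detections_per_frame):
        # candidate (track, detection) pairs with gating
        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(open_tracks):
            tail = tr[-1]
            if tail.frame_index != t - 1:
                continue
            last_step = (
                tr[-1].centroid_x_px - tr[-2].centroid_x_px if len(tr) >= 2 else None
            )
            for di, d in enumerate(dets):
                dx = d.centroid_x_px - tail.centroid_x_px
                dy = abs(d.centroid_y_px - tail.centroid_y_px)
                if not (step_lo <= dx <= step_hi) or dy > params.gate_y_px:
                    continue
                if last_step is not None and abs(dx - last_step) > max(
                    params.consistency_frac * last_step, 4.0
                ):
                    continue
                pairs.append((dx + 4.0 * dy, ti, di))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for _, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            open_tracks[ti].append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        # close stalled tracks, open new ones for unmatched detections
        still_open: list[list[Detection]] = []
        for tr in open_tracks:
            if tr[-1].frame_index >= t - 1:
                still_open.append(tr)
            else:
                closed.append(tr)
        open_tracks = still_open
        for di, d in enumerate(dets):
            if di not in used_dets:
                open_tracks.append([d])
    closed.extend(open_tracks)

    tracks = [
        CellTrack(track_id=i, detections=tr)
        for i, tr in enumerate(
            tr for tr in closed if len(tr) >= params.min_track_length
        )
    ]
    return tracks


def estimate_velocity(
    track: CellTrack, frame_rate_hz: float, pixel_size_um: float
) -> float:
    """OLS velocity of a track in mm/s; stores the fit residual on the track."""
    if track.n_frames < 3:
        raise RejectedInputError("velocity fit needs >= 3 detections")
    t = np.array([d.frame_index for d in track.detections], dtype=float)
    x = np.array([d.centroid_x_px for d in track.detections], dtype=float)
    if np.ptp(t) == 0:
        raise RejectedInputError("degenerate time values in track")
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    track.velocity_fit_residual_px = float(np.sqrt(np.mean(resid**2)))
    v = slope * frame_rate_hz * pixel_size_um / 1000.0  # px/frame -> mm/s
    track.velocity_mm_s = float(v)
    return track.velocity_mm_s


def normalized_lateral_position(
    track: CellTrack, geometry: ChannelGeometry
) -> float:
    """Mean |y/W| of a track, measured from the channel centerline.

    Detections whose centroid falls outside the channel interior are flagged
    (dropped from the mean); a track with no valid detection is rejected.
    """
    first, last = geometry.channel_span_px
    vals = []
    for d in track.detections:
        if not (first <= d.centroid_y_px <= last - 1):
            continue
        vals.append(geometry.abs_y_over_w(d.centroid_y_px))
    if not vals:
        raise RejectedInputError("no detection inside the channel span")
    track.mean_abs_yW = float(np.mean(vals))
    return track.mean_abs_yW


def build_tracks(
    detections_per_frame: list[list[Detection]],
    geometry: ChannelGeometry,
    frame_rate_hz: float,
    params: LinkingParams = LinkingParams(),
) -> list[CellTrack]:
    """Link detections and attach velocity and |y/W| to each accepted track.

    Tracks with non-positive fitted velocity are dropped (flow is
    unidirectional).
    """
    tracks = link_tracks(detections_per_frame, geometry, frame_rate_hz, params)
    accepted = []
    for tr in tracks:
        try:
            v = estimate_velocity(tr, frame_rate_hz, geometry.pixel_size_um)
            normalized_lateral_position(tr, geometry)
        except RejectedInputError:
            continue
        if v > 0:
            accepted.append(tr)
    for i, tr in enumerate(accepted):
        tr.track_id = i
    return accepted


def tracks_table(tracks: list[CellTrack]):
    """Tracks as a tidy DataFrame (track_id, velocity, |y/W|, length, residual)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "track_id": [t.track_id for t in tracks],
            "velocity_mm_s": [t.velocity_mm_s for t in tracks],
            "mean_abs_yW": [t.mean_abs_yW for t in tracks],
            "n_frames": [t.n_frames for t in tracks],
            "fit_residual_px": [t.velocity_fit_residual_px for t in tracks],
        }
    )
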