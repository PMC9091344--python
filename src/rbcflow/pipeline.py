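"""End-to-end orchestration: frames → detections → tracks → labels → report.

``analyze_sample`` turns classified tracks into a :class:`SampleReport`
(lateral distributions per velocity bin, phase diagram, transition
velocity, shape ratio, non-slipper ratio, and — when a control reference
is supplied — the deviation score).  ``pipeline_run`` runs the whole chain
on a frame stack, logging per-stage counts so every "cells analyzed"
number is a reproducible artifact of the run.
"""

from __future__ import annotations

import logging

import numpy as np

from . import stats
from .classify import ShapeClassifier, classify_tracks
from .detect import DetectionParams, detect_sequence, extract_crop
from .errors import DegenerateDataError, RejectedInputError
from .geometry import ChannelGeometry
from .io import SampleReport
from .track import CellTrack, LinkingParams, build_tracks
from .shapes import ShapeClass

logger = logging.getLogger("rbcflow")

MAX_CROPS_PER_TRACK = 5


def track_crops(
    tracks: list[CellTrack],
    frames: np.ndarray,
    background: np.ndarray,
    crop_px: int = 88,
    max_crops: int = MAX_CROPS_PER_TRACK,
) -> dict[int, list[np.ndarray]]:
    """Background-subtracted crops for up to ``max_crops`` central detections
    of each track (central frames are least affected by entry/exit)."""
    out: dict[int, list[np.ndarray]] = {}
    for tr in tracks:
        n = tr.n_frames
        order = np.argsort(np.abs(np.arange(n) - (n - 1) / 2.0))[:max_crops]
        crops = []
        for i in sorted(order):
            d = tr.detections[i]
            diff = background - frames[d.frame_index].astype(np.float64)
            crops.append(
                extract_crop(diff, (d.centroid_y_px, d.centroid_x_px), crop_px)
            )
        out[tr.track_id] = crops
    return out


def analyze_sample(
    labels,
    velocities,
    abs_yw,
    sample_id: str = "sample",
    condition: str = "control",
    reference: dict | None = None,
    shape_ratio_range: tuple[float, float] = (1.0, 10.0),
) -> SampleReport:
    """Compute every summary statistic from classified tracks.

    ``labels``, ``velocities`` and ``abs_yw`` are aligned per-track arrays.
    Undefined statistics become ``None`` in the report, never zero.
    """
    labels = [ShapeClass(l) for l in labels]
    velocities = np.asarray(velocities, dtype=float)
    abs_yw = np.asarray(abs_yw, dtype=float)
    report = SampleReport(
        sample_id=sample_id, condition=condition, n_cells=len(labels)
    )
    if len(labels) == 0:
        return report

    dists = stats.binned_lateral_pdfs(velocities, abs_yw)
    report.distributions = [
        {
            "velocity_bin": list(b),
            "n_cells": d.n_cells,
            "bandwidth": d.bandwidth,
            "hist_edges": d.hist_edges.tolist(),
            "hist_counts": d.hist_counts.tolist(),
            "grid": d.grid.tolist(),
            "pdf": d.pdf.tolist(),
        }
        for b, d in sorted(dists.items())
    ]

    diagram = stats.phase_diagram(labels, velocities)
    report.phase_diagram = {
        "edges": diagram.edges.tolist(),
        "classes": [c.value for c in stats.CLASS_ORDER],
        "fractions": [
            None if np.isnan(row).all() else row.tolist()
            for row in diagram.fractions
        ],
        "n_per_bin": diagram.n_per_bin.tolist(),
    }
    report.transition_velocity = stats.transition_velocity(diagram)

    try:
        report.shape_ratio = stats.shape_ratio(
            labels, velocities, velocity_range=shape_ratio_range
        )
    except DegenerateDataError:
        report.shape_ratio = None
    try:
        report.nonslipper_ratio = stats.nonslipper_ratio(labels, velocities)
    except DegenerateDataError:
        report.nonslipper_ratio = None
    if reference is not None:
        try:
            report.deviation_score = stats.deviation_score(dists, reference)
        except DegenerateDataError:
            report.deviation_score = None
    return report


def pipeline_run(
    frames: np.ndarray,
    geometry: ChannelGeometry,
    frame_rate_hz: float,
    model: ShapeClassifier,
    detection: DetectionParams = DetectionParams(),
    linking: LinkingParams = LinkingParams(),
    sample_id: str = "sample",
    condition: str = "control",
    reference: dict | None = None,
) -> SampleReport:
    """Full deterministic analysis of one frame stack.

    Raises the failing stage's error unchanged; stage counts accumulated so
    far are logged with the stage name.
    """
    counts: dict[str, int] = {"frames": int(frames.shape[0])}
    stage = "detect"
    try:
        per_frame, background = detect_sequence(frames, detection)
        counts["detections"] = int(sum(len(d) for d in per_frame))
        logger.info("detect: %d detections in %d frames", counts["detections"], counts["frames"])

        stage = "track"
        tracks = build_tracks(per_frame, geometry, frame_rate_hz, linking)
        counts["tracks"] = len(tracks)
        logger.info("track: %d accepted tracks", counts["tracks"])

        stage = "classify"
        if tracks:
            crops = track_crops(tracks, frames, background, detection.crop_px)
            classified = classify_tracks(model, crops)
            labels = [c.predicted for c in classified]
        else:
            labels = []
        counts["classified"] = len(labels)

        stage = "analyze"
        report = analyze_sample(
            labels,
            [t.velocity_mm_s for t in tracks],
            [t.mean_abs_yW for t in tracks],
            sample_id=sample_id,
            condition=condition,
            reference=reference,
        )
        report.stage_counts = counts
        report.metadata = {
            "frame_rate_hz": frame_rate_hz,
            "geometry": geometry.to_dict(),
        }
        return report
    except Exception:
        logger.error("pipeline failed at stage %r with counts %s", stage, counts)
        raise
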