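"""Scoring pipeline output against synthetic ground truth.

Used by the test suite and the reproduction script to measure detection
recall/precision, centroid error, velocity error, lateral-position error,
and track purity on generator output.  Recall is evaluated on ground-truth
observations where the cell is fully inside the field of view (partial
cells at the image border are discarded by design); precision is evaluated
against all ground-truth observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import Detection
from .geometry import ChannelGeometry
from .synth import GroundTruth
from .track import CellTrack


def detection_fidelity(
    per_frame: list[list[Detection]],
    truth: GroundTruth,
    radius_px: float = 2.0,
) -> dict:
    """Recall, precision and centroid error of per-frame detections."""
    obs = truth.observations
    by_frame = {f: g for f, g in obs.groupby("frame")}
    n_gt = 0
    n_hit = 0
    n_det = 0
    n_matched_det = 0
    errors: list[float] = []
    for t, dets in enumerate(per_frame):
        g = by_frame.get(t)
        gx = g.x_px.to_numpy() if g is not None else np.empty(0)
        gy = g.y_px.to_numpy() if g is not None else np.empty(0)
        full = g.fully_visible.to_numpy() if g is not None else np.empty(0, bool)
        n_gt += int(full.sum())
        hit = np.zeros(len(gx), dtype=bool)
        for d in dets:
            n_det += 1
            if len(gx) == 0:
                continue
            dist = np.hypot(gx - d.centroid_x_px, gy - d.centroid_y_px)
            j = int(np.argmin(dist))
            if dist[j] <= radius_px:
                n_matched_det += 1
                hit[j] = True
                if full[j]:
                    errors.append(float(dist[j]))
        n_hit += int((hit & full).sum())
    return {
        "recall": n_hit / n_gt if n_gt else float("nan"),
        "precision": n_matched_det / n_det if n_det else float("nan"),
        "mean_centroid_error_px": float(np.mean(errors)) if errors else float("nan"),
        "n_ground_truth": n_gt,
        "n_detections": n_det,
    }


def match_tracks(
    tracks: list[CellTrack],
    truth: GroundTruth,
    geometry: ChannelGeometry,
    radius_px: float = 2.0,
) -> pd.DataFrame:
    """Assign each track to a ground-truth cell and score its estimates.

    A track is *pure* when every one of its detections matches an
    observation of the same cell.  The true lateral position compared
    against is the mean |y/W| of the cell's fully visible observations
    (what an ideal tracker would average).
    """
    obs = truth.observations
    by_frame = {f: g for f, g in obs.groupby("frame")}
    cells = truth.cells.set_index("cell_id")
    fv = obs[obs.fully_visible]
    true_yw = {
        cid: float(np.abs(g.y_px - geometry.centerline_row).mean() / geometry.width_px)
        for cid, g in fv.groupby("cell_id")
    }
    rows = []
    for tr in tracks:
        ids = []
        for d in tr.detections:
            g = by_frame.get(d.frame_index)
            if g is None or len(g) == 0:
                ids.append(-1)
                continue
            dist = np.hypot(
                g.x_px.to_numpy() - d.centroid_x_px,
                g.y_px.to_numpy() - d.centroid_y_px,
            )
            j = int(np.argmin(dist))
            ids.append(int(g.cell_id.iloc[j]) if dist[j] <= radius_px else -1)
        uniq = set(ids)
        pure = len(uniq) == 1 and -1 not in uniq
        cid = max(uniq - {-1}, default=-1)
        row = {
            "track_id": tr.track_id,
            "cell_id": cid,
            "pure": pure,
            "n_frames": tr.n_frames,
            "velocity_mm_s": tr.velocity_mm_s,
            "mean_abs_yW": tr.mean_abs_yW,
        }
        if cid >= 0:
            cell = cells.loc[cid]
            row["true_velocity_mm_s"] = float(cell.true_velocity_mm_s)
            row["true_class"] = cell.true_class
            row["velocity_rel_error"] = abs(
                tr.velocity_mm_s - cell.true_velocity_mm_s
            ) / cell.true_velocity_mm_s
            if cid in true_yw:
                row["true_mean_abs_yW"] = true_yw[cid]
                row["yW_abs_error"] = abs(tr.mean_abs_yW - true_yw[cid])
        rows.append(row)
    return pd.DataFrame(rows)


def tracking_summary(matched: pd.DataFrame, truth: GroundTruth) -> dict:
    """Aggregate track-level fidelity numbers."""
    return {
        "n_tracks": len(matched),
        "n_cells": len(truth.cells),
        "all_pure": bool(matched.pure.all()) if len(matched) else True,
        "velocity_mare": float(matched.velocity_rel_error.mean()),
        "yW_mae": float(matched.yW_abs_error.mean()),
    }
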