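"""Generate a synthetic capillary sequence and recover every cell.

Builds a 40-cell healthy-control video (dark cells streaming through a
bright 11 µm channel), runs background estimation, segmentation and
tracking, and scores the result against the generator's ground truth.
"""

from rbcflow.detect import detect_sequence
from rbcflow.evaluate import detection_fidelity, match_tracks, tracking_summary
from rbcflow.geometry import ChannelGeometry
from rbcflow.synth import generate_sequence, get_preset
from rbcflow.track import build_tracks

geometry = ChannelGeometry()  # 8 x 11 um channel, 0.1375 um/px, W = 80 px
config = get_preset("control", cells_per_sequence=40, seed=1)

frames, truth = generate_sequence(geometry, config)
per_frame, background = detect_sequence(frames)
tracks = build_tracks(per_frame, geometry, config.frame_rate_hz)

fid = detection_fidelity(per_frame, truth)
summary = tracking_summary(match_tracks(tracks, truth, geometry), truth)

print(f"frames: {frames.shape[0]}, ground-truth cells: {len(truth.cells)}")
print(f"detection recall {fid['recall']:.3f}, precision {fid['precision']:.3f}, "
      f"centroid error {fid['mean_centroid_error_px']:.3f} px")
print(f"tracks: {summary['n_tracks']} (pure: {summary['all_pure']})")
print(f"velocity mean |rel. error| {summary['velocity_mare']:.4f}, "
      f"|y/W| mean abs. error {summary['yW_mae']:.4f}")
# recall/precision ~1 and sub-0.01 |y/W| error mean the tracker recovers the
# per-cell velocity and lateral equilibrium position essentially losslessly.
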