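"""Ground-truthed synthetic capillary-flow video generator.

The generator realizes the statistical structure the analysis pipeline
assumes, with every quantity recorded as ground truth:

* cell velocities drawn uniformly from a configurable range inside the
  device's 0.1–10 mm/s operating envelope;
* a velocity-dependent shape mixture — croissants dominate at low
  velocity and slippers take over above a crossover velocity (default
  6 mm/s) following a logistic curve, with an optional admixture of
  pathological classes drawn uniformly from the five non-healthy shapes;
* lateral equilibrium positions — croissants and pathological shapes
  flow on the channel centerline with Gaussian jitter, slippers at an
  off-centered position (default ``|y/W| = 0.125``) with random sign;
* cells streamed through the field of view at their true velocity, as
  dark silhouettes on a brighter channel background between darker
  walls, with additive Gaussian sensor noise.

Cells are kept well separated (a guaranteed minimum edge-to-edge gap at
all times, including when a fast cell follows a slow one) so tracking is
unambiguous in the default sparse regime.  Everything is reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RejectedInputError
from .geometry import ChannelGeometry
from .shapes import (
    BACKGROUND_LEVEL,
    CELL_LEVEL,
    WALL_LEVEL,
    CLASS_ORDER,
    HEALTHY_CLASSES,
    PATHOLOGICAL_CLASSES,
    ShapeClass,
    mask_centroid,
    silhouette_alpha,
)

VELOCITY_ENVELOPE = (0.1, 10.0)  # device operating range, mm/s


@dataclass(frozen=True)
class FlowPopulationConfig:
    """Statistical description of one synthetic sample.

    Velocities are in mm/s, lateral offsets in ``|y/W|`` units, noise in
    8-bit grey levels.  ``crossover_steepness`` is the logistic rate in
    1/(mm/s): P(slipper | v) = logistic((v - crossover) * steepness).
    """

    velocity_range: tuple[float, float] = (0.5, 10.0)
    croissant_to_slipper_crossover: float = 6.0
    crossover_steepness: float = 1.0
    fraction_pathological: float = 0.0
    slipper_offset_mean: float = 0.125
    slipper_offset_sd: float = 0.02
    centered_jitter_sd: float = 0.02
    cells_per_sequence: int = 200
    noise_sd: float = 4.0
    frame_rate_hz: float = 400.0
    cell_scale_um: float = 8.0
    orientation_jitter_deg: float = 6.0
    min_gap_px: float = 150.0
    mean_gap_px: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.velocity_range
        if not (VELOCITY_ENVELOPE[0] <= lo <= hi <= VELOCITY_ENVELOPE[1]):
            raise ConfigurationError(
                f"velocity_range {self.velocity_range} outside the "
                f"{VELOCITY_ENVELOPE} mm/s operating envelope"
            )
        if not (0.0 < self.slipper_offset_mean < 0.5):
            raise ConfigurationError("slipper_offset_mean must lie in (0, 0.5)")
        if min(self.slipper_offset_sd, self.centered_jitter_sd, self.noise_sd) < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not (0.0 <= self.fraction_pathological <= 1.0):
            raise ConfigurationError("fraction_pathological must lie in [0, 1]")
        if self.cells_per_sequence < 1:
            raise ConfigurationError("cells_per_sequence must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["velocity_range"] = list(self.velocity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FlowPopulationConfig":
        d = dict(d)
        d["velocity_range"] = tuple(d["velocity_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-cell and per-observation truth records for one generated sequence.

    ``cells`` has one row per rendered cell (id, class, velocity, signed and
    absolute lateral offset, entry frame); ``observations`` one row per
    cell-frame with the sub-pixel centroid of the rendered silhouette and a
    flag marking frames where the cell is fully inside the field of view.
    """

    cells: pd.DataFrame
    observations: pd.DataFrame

    def write(self, cells_path, observations_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.observations.to_csv(observations_path, index=False)

    @classmethod
    def read(cls, cells_path, observations_path) -> "GroundTruth":
        return cls(
            cells=pd.read_csv(cells_path),
            observations=pd.read_csv(observations_path),
        )


def slipper_probability(velocity: float | np.ndarray, config: FlowPopulationConfig):
    """P(slipper | velocity) under the logistic crossover model."""
    z = (np.asarray(velocity, dtype=float) - config.croissant_to_slipper_crossover)
    z = z * config.crossover_steepness
    return 1.0 / (1.0 + np.exp(-z))


def mean_slipper_probability(
    config: FlowPopulationConfig, velocity_range: tuple[float, float] | None = None
) -> float:
    """Exact mean of P(slipper | v) for v uniform on ``velocity_range``.

    Uses the closed-form integral of the logistic,
    ∫ σ(k(v−c)) dv = ln(1 + exp(k(v−c))) / k.
    """
    lo, hi = velocity_range if velocity_range is not None else config.velocity_range
    if hi == lo:
        return float(slipper_probability(lo, config))
    k = config.crossover_steepness
    c = config.croissant_to_slipper_crossover
    antider = lambda v: np.logaddexp(0.0, k * (v - c)) / k
    return float((antider(hi) - antider(lo)) / (hi - lo))


def sample_shape_class(
    velocity: float, config: FlowPopulationConfig, rng: np.random.Generator
) -> ShapeClass:
    """Draw one shape class for a cell at the given velocity.

    With probability ``fraction_pathological`` a pathological class is drawn
    uniformly from the five non-healthy shapes; otherwise the cell is a
    croissant or slipper according to the logistic crossover model.
    """
    lo, hi = config.velocity_range
    if not (lo <= velocity <= hi):
        raise RejectedInputError(
            f"velocity {velocity} mm/s outside configured range {config.velocity_range}"
        )
    if rng.random() < config.fraction_pathological:
        return PATHOLOGICAL_CLASSES[rng.integers(len(PATHOLOGICAL_CLASSES))]
    p = float(slipper_probability(velocity, config))
    return ShapeClass.SLIPPER if rng.random() < p else ShapeClass.CROISSANT


def sample_tracks(
    config: FlowPopulationConfig,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sample per-cell truth (velocity, class, lateral offset) without rendering.

    This is the statistical core that :func:`generate_sequence` realizes as
    video; it is also useful on its own for fast Monte-Carlo studies of the
    downstream statistics with perfect labels.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    n = config.cells_per_sequence if n is None else int(n)
    lo, hi = config.velocity_range

    v = rng.uniform(lo, hi, n)
    is_path = rng.random(n) < config.fraction_pathological
    path_idx = rng.integers(0, len(PATHOLOGICAL_CLASSES), n)
    is_slipper = (rng.random(n) < slipper_probability(v, config)) & ~is_path

    # offsets: slippers sit off-center with random sign, everything else on
    # the centerline with jitter; both clipped so cells stay in the channel
    slip_mag = np.clip(
        rng.normal(config.slipper_offset_mean, config.slipper_offset_sd, n),
        0.05,
        0.25,
    )
    slip_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    jitter_bound = 3.0 * config.centered_jitter_sd
    centered = np.clip(
        rng.normal(0.0, config.centered_jitter_sd, n) if config.centered_jitter_sd > 0
        else np.zeros(n),
        -jitter_bound,
        jitter_bound,
    )
    y_frac = np.where(is_slipper, slip_mag * slip_sign, centered)

    orientation = rng.normal(0.0, config.orientation_jitter_deg, n)
    # slipper asymmetry faces the nearer wall
    orientation = orientation + np.where(is_slipper & (y_frac < 0), 180.0, 0.0)

    classes = np.where(
        is_path,
        np.array([c.value for c in PATHOLOGICAL_CLASSES])[path_idx],
        np.where(is_slipper, ShapeClass.SLIPPER.value, ShapeClass.CROISSANT.value),
    )
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "true_class": classes,
            "true_velocity_mm_s": v,
            "y_frac": y_frac,
            "true_offset_yW": np.abs(y_frac),
            "orientation_deg": orientation,
        }
    )


def empty_channel_image(geometry: ChannelGeometry) -> np.ndarray:
    """Noise-free image of the cell-free channel (walls dark, interior bright)."""
    rows, cols = geometry.fov_px
    img = np.full((rows, cols), WALL_LEVEL, dtype=float)
    first, last = geometry.channel_span_px
    img[first:last, :] = BACKGROUND_LEVEL
    return img


def _step_px_per_frame(velocity_mm_s: float, geometry: ChannelGeometry, frame_rate_hz: float) -> float:
    return velocity_mm_s * 1000.0 / geometry.pixel_size_um / frame_rate_hz


def generate_sequence(
    geometry: ChannelGeometry,
    config: FlowPopulationConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a full synthetic sequence and its ground truth.

    Returns an 8-bit frame stack of shape ``(n_frames, rows, cols)`` and a
    :class:`GroundTruth`.  Deterministic given (geometry, config): the same
    inputs produce byte-identical frames and records.
    """
    rows_fov, cols_fov = geometry.fov_px
    cell_diameter_px = config.cell_scale_um / geometry.pixel_size_um
    if cols_fov < cell_diameter_px or geometry.width_px < cell_diameter_px * 0.6:
        raise ConfigurationError(
            "field of view / channel narrower than the cell diameter "
            f"({cell_diameter_px:.0f} px)"
        )

    rng = np.random.default_rng(config.seed)
    cells = sample_tracks(config, rng=rng)

    # pre-render each cell's silhouette geometry once to get its intrinsic
    # center-of-mass offset and extent (orientation is fixed per cell)
    alphas0 = []
    for _, cell in cells.iterrows():
        a = silhouette_alpha(
            ShapeClass(cell.true_class),
            orientation_deg=cell.orientation_deg,
            scale_um=config.cell_scale_um,
            pixel_size_um=geometry.pixel_size_um,
            supersample=2,
            recenter=False,
        )
        alphas0.append(a)
    patch = alphas0[0].shape[0]
    center = (patch - 1) / 2.0
    intrinsic = [mask_centroid(a) for a in alphas0]
    half_extent_x = []
    for a in alphas0:
        cols_any = np.flatnonzero(a.sum(axis=0) > 0)
        half_extent_x.append((cols_any[-1] - cols_any[0] + 1) / 2.0)

    steps = [
        _step_px_per_frame(v, geometry, config.frame_rate_hz)
        for v in cells.true_velocity_mm_s
    ]

    # entry scheduling: guarantee an edge-to-edge gap >= min_gap_px at all
    # times, including when a faster cell follows a slower one
    entries: list[float] = []
    for i in range(len(cells)):
        if i == 0:
            entries.append(0.0)
            continue
        gap_edge = config.min_gap_px + rng.exponential(config.mean_gap_px)
        G = gap_edge + half_extent_x[i] + half_extent_x[i - 1]
        s_prev, s_cur = steps[i - 1], steps[i]
        travel_prev = cols_fov + 2 * half_extent_x[i - 1]
        if s_cur <= s_prev:
            d_entry = (G + half_extent_x[i - 1] - half_extent_x[i]) / s_prev
        else:
            d_entry = (
                G
                + half_extent_x[i - 1]
                - half_extent_x[i]
                + (s_cur - s_prev) * travel_prev / s_prev
            ) / s_cur
        entries.append(entries[i - 1] + math.ceil(max(d_entry, 1.0)))
    entry_frames = [int(e) for e in entries]
    exit_frames = [
        entry_frames[i]
        + int(math.ceil((cols_fov + 2 * half_extent_x[i]) / steps[i]))
        for i in range(len(cells))
    ]
    n_frames = max(exit_frames) + 1

    cells = cells.assign(entry_frame=entry_frames)

    background = empty_channel_image(geometry)
    frames = np.empty((n_frames, rows_fov, cols_fov), dtype=np.uint8)
    obs_records: list[dict] = []

    first_active = 0
    for t in range(n_frames):
        canvas = background.copy()
        while first_active < len(cells) and exit_frames[first_active] < t:
            first_active += 1
        i = first_active
        while i < len(cells) and entry_frames[i] <= t:
            if t <= exit_frames[i]:
                cx = -half_extent_x[i] + steps[i] * (t - entry_frames[i])
                cy = geometry.centerline_row + cells.y_frac.iloc[i] * geometry.width_px
                r0 = int(round(cy)) - patch // 2
                c0 = int(round(cx)) - patch // 2
                dy = cy - (r0 + center) - (intrinsic[i][0] - center)
                dx = cx - (c0 + center) - (intrinsic[i][1] - center)
                alpha = silhouette_alpha(
                    ShapeClass(cells.true_class.iloc[i]),
                    orientation_deg=cells.orientation_deg.iloc[i],
                    scale_um=config.cell_scale_um,
                    pixel_size_um=geometry.pixel_size_um,
                    subpixel=(dy, dx),
                    supersample=2,
                    recenter=False,
                )
                rr0, rr1 = max(r0, 0), min(r0 + patch, rows_fov)
                cc0, cc1 = max(c0, 0), min(c0 + patch, cols_fov)
                if rr1 > rr0 and cc1 > cc0:
                    sub = alpha[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
                    if sub.sum() > 0:
                        canvas[rr0:rr1, cc0:cc1] -= (BACKGROUND_LEVEL - CELL_LEVEL) * sub
                        my, mx = mask_centroid(sub)
                        col_cover = alpha.sum(axis=0)
                        cols_any = np.flatnonzero(col_cover > 0)
                        col_lo = c0 + cols_any[0]
                        col_hi = c0 + cols_any[-1]
                        fully = (
                            col_lo >= 1
                            and col_hi <= cols_fov - 2
                            and cols_any[0] > 0
                            and cols_any[-1] < patch - 1
                        )
                        obs_records.append(
                            {
                                "cell_id": int(cells.cell_id.iloc[i]),
                                "frame": t,
                                "x_px": cc0 + mx,
                                "y_px": rr0 + my,
                                "fully_visible": bool(fully),
                            }
                        )
            i += 1
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
        frames[t] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    observations = pd.DataFrame(
        obs_records, columns=["cell_id", "frame", "x_px", "y_px", "fully_visible"]
    )
    return frames, GroundTruth(cells=cells, observations=observations)


def make_labeled_crops(
    n_per_class: int,
    seed: int = 0,
    pixel_size_um: float = 0.1375,
    patch_px: int = 88,
    scale_um: float = 8.0,
    scale_jitter_um: float = 0.8,
    orientation_jitter_deg: float = 12.0,
    noise_sd: float = 4.0,
) -> tuple[np.ndarray, list[ShapeClass]]:
    """Balanced labeled crop set over the 7 classes for classifier training.

    Each crop gets a random orientation, sub-pixel offset, scale jitter and
    additive Gaussian noise.  Returns ``(crops, labels)`` with crops of shape
    ``(7 * n_per_class, patch_px, patch_px)`` on the 8-bit grey scale, in
    class-major order.
    """
    if n_per_class < 1:
        raise RejectedInputError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    crops = np.empty((7 * n_per_class, patch_px, patch_px), dtype=np.float32)
    labels: list[ShapeClass] = []
    k = 0
    for shape in CLASS_ORDER:
        for _ in range(n_per_class):
            # cells sit near either wall: both 180°-rotated poses occur in flow
            pose = 180.0 if rng.random() < 0.5 else 0.0
            alpha = silhouette_alpha(
                shape,
                orientation_deg=pose + float(rng.normal(0.0, orientation_jitter_deg)),
                scale_um=float(
                    scale_um + rng.uniform(-scale_jitter_um, scale_jitter_um)
                ),
                pixel_size_um=pixel_size_um,
                patch_px=patch_px,
                subpixel=(float(rng.uniform(-0.5, 0.5)), float(rng.uniform(-0.5, 0.5))),
                supersample=2,
            )
            img = BACKGROUND_LEVEL - (BACKGROUND_LEVEL - CELL_LEVEL) * alpha
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, img.shape)
            crops[k] = np.clip(img, 0, 255)
            labels.append(shape)
            k += 1
    return crops, labels


# ---------------------------------------------------------------------------
# presets: the study conditions for each cohort-like synthetic sample
# ---------------------------------------------------------------------------

_PRESETS: dict[str, dict] = {
    # healthy donor: pure croissant/slipper mixture
    "control": {"fraction_pathological": 0.0},
    # neuroacanthocytosis-like: a large admixture of centered pathological
    # shapes (acanthocytes among them) that never become slippers
    "nas": {"fraction_pathological": 0.40},
    # hemodiafiltration: elevated pathological fraction before treatment,
    # higher still immediately after
    "hdf-pre": {"fraction_pathological": 0.15},
    "hdf-post": {"fraction_pathological": 0.35},
}


def storage_fraction_for_ratio(
    normalized_ratio: float,
    config: FlowPopulationConfig,
    velocity_range: tuple[float, float] = (8.0, 10.0),
) -> float:
    """Pathological fraction that yields a target normalized non-slipper ratio.

    The fresh-control non-slipper/slipper ratio over the high-velocity window
    is R0 = (1 − s̄)/s̄ with s̄ the mean slipper probability.  A pathological
    (centered) admixture f rescales the slipper share to (1 − f)·s̄, giving
    ratio R = (1 − (1 − f)·s̄)/((1 − f)·s̄).  Solving R = normalized_ratio · R0
    for f gives the value returned here.
    """
    if normalized_ratio < 1.0:
        raise ConfigurationError("normalized storage ratio cannot be below 1 (fresh)")
    s_bar = mean_slipper_probability(config, velocity_range)
    r0 = (1.0 - s_bar) / s_bar
    target = normalized_ratio * r0
    f = 1.0 - 1.0 / (s_bar * (1.0 + target))
    return float(np.clip(f, 0.0, 0.95))


def get_preset(
    name: str,
    cells_per_sequence: int | None = None,
    seed: int | None = None,
    week: int | None = None,
    storage_slope: float = 0.25,
    **overrides,
) -> FlowPopulationConfig:
    """Build a :class:`FlowPopulationConfig` for a named study condition.

    Recognized names: ``control``, ``nas``, ``hdf-pre``, ``hdf-post`` and
    ``storage-week-N`` (or ``storage-week`` plus ``week=N``).  The storage
    preset restricts velocities to the 8–10 mm/s window and raises the
    centered (non-slipper) fraction linearly with storage week with the
    given slope on the normalized non-slipper ratio.
    """
    name = name.lower()
    if name.startswith("storage-week"):
        tail = name[len("storage-week") :].lstrip("-")
        if tail:
            week = int(tail)
        if week is None:
            raise ConfigurationError("storage preset needs a week number")
        base_kv = dict(overrides)
        base_kv.setdefault("velocity_range", (8.0, 10.0))
        base = FlowPopulationConfig(**base_kv)
        frac = storage_fraction_for_ratio(1.0 + storage_slope * week, base)
        kv: dict = {
            "velocity_range": base.velocity_range,
            "fraction_pathological": frac,
        }
    elif name in _PRESETS:
        kv = dict(_PRESETS[name])
    else:
        raise ConfigurationError(
            f"unknown preset {name!r}; expected one of "
            f"{sorted(_PRESETS)} or storage-week-N"
        )
    kv.update(overrides)
    if cells_per_sequence is not None:
        kv["cells_per_sequence"] = int(cells_per_sequence)
    if seed is not None:
        kv["seed"] = int(seed)
    return FlowPopulationConfig(**kv)
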