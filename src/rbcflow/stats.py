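"""Distributions, phase diagrams, and clinical summary statistics.

From classified tracks this module computes:

* per-velocity-bin distributions of the normalized lateral position
  ``|y/W|`` (histogram + boundary-reflected Gaussian kernel density);
* the shape phase diagram — per-bin class frequencies versus velocity —
  and the croissant→slipper transition velocity read off it;
* the deviation score of a sample from a healthy-control reference
  (mean per-bin L1 distance between densities over 1–10 mm/s);
* the shape ratio (pathological/healthy counts in a velocity window) and
  the storage non-slipper/slipper ratio over 8–10 mm/s;
* storage-lesion trends: linear fits of the normalized non-slipper ratio
  over storage weeks, a cross-donor threshold at a reference week, and
  each donor's threshold-crossing week;
* one-way ANOVA with Tukey-HSD multiple comparison for group contrasts.

Velocity bins are half-open ``(lo, hi]`` of width 1 mm/s over (0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    EmptyBinError,
    RejectedInputError,
    UndefinedRatioError,
    UndefinedScoreError,
)
from .shapes import CLASS_ORDER, HEALTHY_CLASSES, PATHOLOGICAL_CLASSES, ShapeClass

# fixed grids shared by every density in a run
YW_GRID = np.linspace(0.0, 0.5, 251)
HIST_EDGES = np.arange(0.0, 0.5 + 1e-9, 0.02)
VELOCITY_EDGES = np.arange(0.0, 10.0 + 1e-9, 1.0)
BANDWIDTH_FLOOR = 0.01


def velocity_bin_index(v: np.ndarray, edges: np.ndarray = VELOCITY_EDGES) -> np.ndarray:
    """Half-open (lo, hi] bin index for each velocity; -1 when out of range."""
    v = np.asarray(v, dtype=float)
    idx = np.searchsorted(edges, v, side="left") - 1
    idx[(v <= edges[0]) | (v > edges[-1])] = -1
    return idx


@dataclass
class LateralDistribution:
    """Histogram and smoothed unit-integral pdf of |y/W| for one velocity bin."""

    velocity_bin: tuple[float, float]
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    grid: np.ndarray
    pdf: np.ndarray
    n_cells: int
    bandwidth: float

    def mode(self, min_yw: float = 0.0) -> float:
        """Location of the pdf maximum, optionally restricted to |y/W| > min_yw."""
        sel = self.grid >= min_yw
        return float(self.grid[sel][np.argmax(self.pdf[sel])])


def _reflected_kde(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE with reflection at the domain boundaries 0 and 0.5."""
    pts = np.concatenate([values, -values, 1.0 - values])  # reflect at 0 and 0.5
    d = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * d**2).sum(axis=1) / (
        len(values) * bandwidth * np.sqrt(2 * np.pi)
    )
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, floored at 0.01 |y/W| units."""
    n = len(values)
    std = np.std(values, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25])) if n > 1 else 0.0
    spread = min(std, iqr / 1.34) if iqr > 0 else std
    bw = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    return max(bw, BANDWIDTH_FLOOR)


def lateral_pdf(
    abs_yw: np.ndarray,
    velocity_bin: tuple[float, float] = (0.0, 10.0),
    grid: np.ndarray = YW_GRID,
    bandwidth: float | None = None,
) -> LateralDistribution:
    """Distribution of |y/W| values for the tracks of one velocity bin."""
    values = np.asarray(abs_yw, dtype=float)
    if values.size == 0:
        raise EmptyBinError(f"no tracks in velocity bin {velocity_bin}")
    if ((values < 0) | (values > 0.5)).any():
        raise RejectedInputError("|y/W| values must lie in [0, 0.5]")
    bw = bandwidth if bandwidth is not None else silverman_bandwidth(values)
    counts, _ = np.histogram(values, bins=HIST_EDGES)
    return LateralDistribution(
        velocity_bin=tuple(velocity_bin),
        hist_edges=HIST_EDGES.copy(),
        hist_counts=counts,
        grid=np.asarray(grid),
        pdf=_reflected_kde(values, np.asarray(grid), bw),
        n_cells=int(values.size),
        bandwidth=float(bw),
    )


def binned_lateral_pdfs(
    velocities: np.ndarray,
    abs_yw: np.ndarray,
    edges: np.ndarray = VELOCITY_EDGES,
) -> dict[tuple[float, float], LateralDistribution]:
    """One LateralDistribution per populated velocity bin."""
    velocities = np.asarray(velocities, float)
    abs_yw = np.asarray(abs_yw, float)
    idx = velocity_bin_index(velocities, edges)
    out: dict[tuple[float, float], LateralDistribution] = {}
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            vbin = (float(edges[b]), float(edges[b + 1]))
            out[vbin] = lateral_pdf(abs_yw[sel], vbin)
    return out


def distributions_from_records(
    records: list[dict],
) -> dict[tuple[float, float], LateralDistribution]:
    """Rebuild per-bin distributions from their serialized report form."""
    out = {}
    for rec in records:
        b = tuple(rec["velocity_bin"])
        out[b] = LateralDistribution(
            velocity_bin=b,
            hist_edges=np.asarray(rec["hist_edges"]),
            hist_counts=np.asarray(rec["hist_counts"]),
            grid=np.asarray(rec["grid"]),
            pdf=np.asarray(rec["pdf"]),
            n_cells=int(rec["n_cells"]),
            bandwidth=float(rec["bandwidth"]),
        )
    return out


def control_reference(
    control_distributions: list[dict[tuple[float, float], LateralDistribution]],
) -> dict[tuple[float, float], np.ndarray]:
    """Per-bin pointwise mean of control pdfs, renormalized to unit integral.

    Bins with no control data are simply absent from the reference (and are
    skipped by :func:`deviation_score`).
    """
    if not control_distributions:
        raise RejectedInputError("need at least one control sample")
    bins = sorted({b for dists in control_distributions for b in dists})
    ref: dict[tuple[float, float], np.ndarray] = {}
    for b in bins:
        pdfs = [d[b].pdf for d in control_distributions if b in d]
        grid = next(d[b].grid for d in control_distributions if b in d)
        mean = np.mean(pdfs, axis=0)
        ref[b] = mean / np.trapezoid(mean, grid)
    return ref


def deviation_score(
    sample: dict[tuple[float, float], LateralDistribution],
    reference: dict[tuple[float, float], np.ndarray],
    velocity_range: tuple[float, float] = (1.0, 10.0),
    grid: np.ndarray = YW_GRID,
) -> float:
    """Deviation of a sample's |y/W| densities from the control reference.

    Per shared bin the unsigned area between the two pdfs (L1 distance,
    range [0, 2]); the score is the mean over populated bins inside the
    velocity range, so samples missing bins remain comparable.
    """
    lo, hi = velocity_range
    per_bin = []
    for b, dist in sample.items():
        if b not in reference:
            continue
        if b[1] <= lo or b[0] >= hi:
            continue
        per_bin.append(np.trapezoid(np.abs(dist.pdf - reference[b]), grid))
    if not per_bin:
        raise UndefinedScoreError(
            "sample and reference share no populated bins in the velocity range"
        )
    return float(np.mean(per_bin))


def shape_ratio(
    labels,
    velocities,
    numerator: tuple[ShapeClass, ...] = PATHOLOGICAL_CLASSES,
    denominator: tuple[ShapeClass, ...] = HEALTHY_CLASSES,
    velocity_range: tuple[float, float] = (1.0, 10.0),
) -> float:
    """Count ratio of two class sets within a velocity window, e.g. the
    pathological/healthy shape ratio."""
    labels = np.asarray([ShapeClass(l).value for l in labels])
    v = np.asarray(velocities, dtype=float)
    lo, hi = velocity_range
    sel = (v > lo) & (v <= hi)
    num_set = {c.value for c in numerator}
    den_set = {c.value for c in denominator}
    n_num = int(np.isin(labels[sel], list(num_set)).sum())
    n_den = int(np.isin(labels[sel], list(den_set)).sum())
    if n_den == 0:
        raise UndefinedRatioError(
            f"no denominator-class cells in velocity range {velocity_range}"
        )
    return n_num / n_den


def nonslipper_ratio(
    labels, velocities, velocity_range: tuple[float, float] = (8.0, 10.0)
) -> float:
    """Ratio of non-slipper to slipper cells in the high-velocity window."""
    non_slipper = tuple(c for c in CLASS_ORDER if c is not ShapeClass.SLIPPER)
    return shape_ratio(
        labels,
        velocities,
        numerator=non_slipper,
        denominator=(ShapeClass.SLIPPER,),
        velocity_range=velocity_range,
    )


@dataclass
class PhaseDiagram:
    """Per-velocity-bin frequency of each of the seven shape classes."""

    edges: np.ndarray
    fractions: np.ndarray  # (n_bins, 7); NaN rows for empty bins
    n_per_bin: np.ndarray

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def fraction_of(self, shape: ShapeClass) -> np.ndarray:
        return self.fractions[:, CLASS_ORDER.index(shape)]


def phase_diagram(
    labels, velocities, edges: np.ndarray = VELOCITY_EDGES
) -> PhaseDiagram:
    """Shape-class frequencies as a function of cell velocity.

    Empty bins are flagged with ``n = 0`` and NaN fractions, never zero-filled.
    """
    labels = [ShapeClass(l) for l in labels]
    if len(labels) == 0:
        raise RejectedInputError("phase diagram needs at least one classified cell")
    idx = velocity_bin_index(np.asarray(velocities, float), edges)
    n_bins = len(edges) - 1
    fractions = np.full((n_bins, len(CLASS_ORDER)), np.nan)
    n_per_bin = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = np.flatnonzero(idx == b)
        n_per_bin[b] = sel.size
        if sel.size:
            counts = np.zeros(len(CLASS_ORDER))
            for i in sel:
                counts[CLASS_ORDER.index(labels[i])] += 1
            fractions[b] = counts / sel.size
    return PhaseDiagram(edges=np.asarray(edges, float), fractions=fractions, n_per_bin=n_per_bin)


def transition_velocity(diagram: PhaseDiagram) -> float | None:
    """Croissant→slipper crossover velocity read off the phase diagram.

    Midpoint of the first bin (scanning upward) where the slipper fraction
    exceeds the croissant fraction and stays higher in every subsequent
    populated bin; ``None`` if no such bin exists.
    """
    slip = diagram.fraction_of(ShapeClass.SLIPPER)
    croi = diagram.fraction_of(ShapeClass.CROISSANT)
    mids = diagram.bin_midpoints
    populated = diagram.n_per_bin > 0
    for b in range(len(mids)):
        if not populated[b]:
            continue
        later = populated.copy()
        later[: b] = False
        if np.all(slip[later] > croi[later]):
            return float(mids[b])
    return None


@dataclass
class StorageSeries:
    """A donor's normalized non-slipper ratio over storage weeks with its fit."""

    weeks: np.ndarray
    normalized_ratio: np.ndarray
    slope: float
    intercept: float
    threshold: float | None = None
    crossing_week: float | None = None

    def fitted(self, week) -> np.ndarray:
        return self.slope * np.asarray(week, float) + self.intercept


def fit_storage_series(weeks, ratios, normalizer: float) -> StorageSeries:
    """OLS line through (week, ratio / fresh-control normalizer)."""
    weeks = np.asarray(weeks, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if weeks.size < 2:
        raise RejectedInputError("storage trend needs >= 2 time points")
    if np.any(np.diff(weeks) <= 0):
        raise RejectedInputError("weeks must be strictly increasing")
    if normalizer <= 0:
        raise RejectedInputError("fresh-control normalizer must be positive")
    norm = ratios / normalizer
    slope, intercept = np.polyfit(weeks, norm, 1)
    return StorageSeries(
        weeks=weeks, normalized_ratio=norm, slope=float(slope), intercept=float(intercept)
    )


def storage_threshold(
    series: list[StorageSeries], reference_week: float = 7.0
) -> float:
    """Mean of all donors' fitted values at the reference (expiry) week."""
    if not series:
        raise RejectedInputError("need at least one donor series")
    return float(np.mean([s.fitted(reference_week) for s in series]))


def storage_trend(
    weeks,
    ratios,
    normalizer: float,
    threshold: float,
    horizon_weeks: float = 4.0,
) -> StorageSeries:
    """Fit one donor's storage series and solve its threshold-crossing week.

    The crossing week satisfies ``fit(week) = threshold`` exactly; it is
    ``None`` when the fit never reaches the threshold within the observed
    span plus ``horizon_weeks``.
    """
    s = fit_storage_series(weeks, ratios, normalizer)
    s.threshold = float(threshold)
    if s.slope > 0:
        wx = (threshold - s.intercept) / s.slope
        if wx <= s.weeks[-1] + horizon_weeks:
            s.crossing_week = float(wx)
    elif s.intercept >= threshold:  # starts above a non-rising fit
        s.crossing_week = float(s.weeks[0])
    return s


def storage_trend_panel(
    donor_series: dict[str, tuple[np.ndarray, np.ndarray]],
    normalizer: float,
    reference_week: float = 7.0,
) -> dict[str, StorageSeries]:
    """Fit all donors, set the shared expiry threshold, solve all crossings."""
    fits = {
        name: fit_storage_series(w, r, normalizer)
        for name, (w, r) in donor_series.items()
    }
    thr = storage_threshold(list(fits.values()), reference_week)
    return {
        name: storage_trend(w, r, normalizer, thr)
        for name, (w, r) in donor_series.items()
    }


def compare_groups(groups: dict[str, np.ndarray], alpha=(0.05, 0.01)) -> dict:
    """One-way ANOVA with Tukey-HSD pairwise multiple comparison.

    Returns the F statistic, its p-value, and per-pair adjusted p-values
    with significance stars (* p<0.05, ** p<0.01, ns otherwise).
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    if len(values) < 2 or any(v.size < 2 for v in values):
        raise RejectedInputError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(v) == 0 for v in values):
        raise DegenerateDataError("zero within-group variance in every group")
    f_stat, p_value = sps.f_oneway(*values)
    tukey = sps.tukey_hsd(*values)
    pairs = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            stars = "**" if p < alpha[1] else "*" if p < alpha[0] else "ns"
            pairs[(names[i], names[j])] = {"p_adj": p, "stars": stars}
    return {"F": float(f_stat), "p": float(p_value), "pairs": pairs}
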