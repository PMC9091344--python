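"""Optional plots: |y/W| density overlays, phase diagrams, storage trends.

Each function draws onto a fresh figure and, given ``path``, saves and
closes it — convenient both interactively and from scripts.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .shapes import CLASS_ORDER
from .stats import LateralDistribution, PhaseDiagram, StorageSeries


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_lateral_pdfs(
    distributions: dict[tuple[float, float], LateralDistribution],
    reference: dict[tuple[float, float], np.ndarray] | None = None,
    path=None,
):
    """Per-velocity-bin |y/W| densities, optionally against a control reference."""
    bins = sorted(distributions)
    fig, axes = plt.subplots(
        len(bins), 1, figsize=(5, 1.6 * len(bins)), sharex=True, squeeze=False
    )
    for ax, b in zip(axes[:, 0], bins):
        d = distributions[b]
        ax.fill_between(d.grid, d.pdf, alpha=0.4, label="sample")
        if reference is not None and b in reference:
            ax.plot(d.grid, reference[b], "k-", lw=1, label="control reference")
        ax.set_ylabel(f"({b[0]:g},{b[1]:g}]\nn={d.n_cells}")
    axes[-1, 0].set_xlabel("|y/W|")
    axes[0, 0].legend(fontsize=8)
    return _finish(fig, path)


def plot_phase_diagram(diagram: PhaseDiagram, path=None):
    """Stacked per-bin shape-class frequencies versus velocity."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    mids = diagram.bin_midpoints
    bottom = np.zeros(len(mids))
    width = np.diff(diagram.edges)
    for i, cls in enumerate(CLASS_ORDER):
        frac = np.nan_to_num(diagram.fractions[:, i])
        ax.bar(mids, frac, width=width * 0.9, bottom=bottom, label=cls.value)
        bottom += frac
    ax.set_xlabel("velocity (mm/s)")
    ax.set_ylabel("shape frequency")
    ax.legend(fontsize=7, ncol=2)
    return _finish(fig, path)


def plot_storage_trends(panel: dict[str, StorageSeries], path=None):
    """Normalized non-slipper ratios, linear fits, and the expiry threshold."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for name, s in panel.items():
        ax.plot(s.weeks, s.normalized_ratio, "o", ms=4)
        wgrid = np.linspace(s.weeks[0], s.weeks[-1], 50)
        ax.plot(wgrid, s.fitted(wgrid), "-", lw=1, label=name)
    thr = next(iter(panel.values())).threshold
    if thr is not None:
        ax.axhline(thr, color="b", ls="--", lw=1, label="expiry threshold")
    ax.set_xlabel("storage week")
    ax.set_ylabel("normalized non-slipper/slipper ratio")
    ax.legend(fontsize=8)
    return _finish(fig, path)
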