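"""The seven red-blood-cell shape classes and a parametric silhouette renderer.

In confined capillary flow healthy RBCs adopt two dominant morphologies:
the axisymmetric *croissant* (bullet/parachute) that flows on the channel
centerline, and the asymmetric *slipper* with an off-centered equilibrium
position.  Pathological samples additionally show spiculated acanthocytes,
echinocytes, near-spherical cells, multilobed cells, and a catch-all class
of irregular/elongated shapes.  The renderer draws each class as a dark
grey-level silhouette on a brighter background — the appearance of a cell
in a bright-field capillary image — from simple implicit geometry.

All silhouettes are defined in unit coordinates ``(u, v) = (x, y)/R`` with
``R = scale_um/2`` the nominal cell radius; ``u`` points downstream.  The
numeric shape parameters below (lobe counts, spicule counts, aspect
ratios) are package constants, chosen so the classes are visually and
morphometrically separable at the default 0.1375 µm/px scale.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .errors import RejectedInputError


class ShapeClass(str, Enum):
    """The seven shape classes. Healthy flow shapes first, then pathological."""

    CROISSANT = "croissant"
    SLIPPER = "slipper"
    ACANTHOCYTE = "acanthocyte"
    ECHINOCYTE = "echinocyte"
    SPHERE = "sphere"
    MULTILOBE = "multilobe"
    OTHER = "other"

    @property
    def is_healthy(self) -> bool:
        return self in HEALTHY_CLASSES


#: Fixed partition used by every downstream ratio.
HEALTHY_CLASSES = (ShapeClass.CROISSANT, ShapeClass.SLIPPER)
PATHOLOGICAL_CLASSES = (
    ShapeClass.ACANTHOCYTE,
    ShapeClass.ECHINOCYTE,
    ShapeClass.SPHERE,
    ShapeClass.MULTILOBE,
    ShapeClass.OTHER,
)
CLASS_ORDER = tuple(ShapeClass)

# default grey levels of the synthetic bright-field image (8 bit)
BACKGROUND_LEVEL = 200.0
CELL_LEVEL = 90.0
WALL_LEVEL = 120.0


def _inside(shape: ShapeClass, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Boolean membership of points (u, v) in the unit-scale silhouette."""
    if shape is ShapeClass.CROISSANT:
        # ellipse with a circular bite taken out of the upstream face,
        # mirror-symmetric about the flow axis (v -> -v)
        body = (u / 1.0) ** 2 + (v / 0.78) ** 2 <= 1.0
        bite = (u + 0.55) ** 2 + v**2 <= 0.62**2
        return body & ~bite
    if shape is ShapeClass.SLIPPER:
        # flatter ellipse with the bite displaced off-axis: asymmetric
        body = (u / 1.05) ** 2 + (v / 0.62) ** 2 <= 1.0
        bite = (u + 0.45) ** 2 + (v - 0.38) ** 2 <= 0.55**2
        return body & ~bite
    if shape is ShapeClass.SPHERE:
        return u**2 + v**2 <= 0.72**2
    if shape is ShapeClass.ACANTHOCYTE:
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        spike = np.maximum(np.cos(3.5 * theta), 0.0) ** 6
        return rho <= 0.55 * (1.0 + 0.55 * spike)
    if shape is ShapeClass.ECHINOCYTE:
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        return rho <= 0.62 * (1.0 + 0.13 * np.cos(14.0 * theta))
    if shape is ShapeClass.MULTILOBE:
        out = u**2 + v**2 <= 0.34**2
        for ang in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
            cu, cv = 0.40 * np.cos(ang), 0.40 * np.sin(ang)
            out = out | ((u - cu) ** 2 + (v - cv) ** 2 <= 0.42**2)
        return out
    if shape is ShapeClass.OTHER:
        # elongated, slightly bent rod
        vv = v - 0.28 * u**2
        return (u / 1.1) ** 2 + (vv / 0.34) ** 2 <= 1.0
    raise RejectedInputError(f"unknown shape class {shape!r}")


def silhouette_alpha(
    shape: ShapeClass,
    orientation_deg: float = 0.0,
    scale_um: float = 8.0,
    pixel_size_um: float = 0.1375,
    patch_px: int | None = None,
    subpixel: tuple[float, float] = (0.0, 0.0),
    supersample: int = 3,
    recenter: bool = True,
) -> np.ndarray:
    """Anti-aliased coverage map of a cell silhouette.

    Returns a ``(patch_px, patch_px)`` float array in [0, 1]: the fraction of
    each pixel covered by the silhouette, estimated on a ``supersample``²
    sub-grid.  With ``recenter`` (default) the silhouette's center of mass is
    placed at the patch center plus ``subpixel = (dy, dx)``, so the nominal
    placement coordinate of a cell *is* its center of mass regardless of the
    asymmetry of the shape.
    """
    if pixel_size_um <= 0:
        raise RejectedInputError("pixel_size_um must be positive")
    if scale_um <= 0:
        raise RejectedInputError("scale_um must be positive")
    radius_px = 0.5 * scale_um / pixel_size_um
    if patch_px is None:
        patch_px = int(np.ceil(2.9 * radius_px))
    center = (patch_px - 1) / 2.0

    theta = np.deg2rad(orientation_deg)
    ct, st = np.cos(theta), np.sin(theta)

    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    base = np.arange(patch_px, dtype=float)
    # supersampled coordinates along one axis, shape (patch_px*ss,)
    coords = (base[:, None] + offs[None, :]).ravel()

    def render(cy: float, cx: float) -> np.ndarray:
        y = coords - cy
        x = coords - cx
        X, Y = np.meshgrid(x, y)  # X columns, Y rows
        # rotate image coords into shape frame
        u = (ct * X + st * Y) / radius_px
        v = (-st * X + ct * Y) / radius_px
        m = _inside(shape, u, v).astype(float)
        m = m.reshape(patch_px, supersample, patch_px, supersample)
        return m.mean(axis=(1, 3))

    cy, cx = center + subpixel[0], center + subpixel[1]
    alpha = render(cy, cx)
    if recenter:
        total = alpha.sum()
        if total <= 0:
            raise RejectedInputError(
                f"{shape} renders empty at scale {scale_um} µm / {pixel_size_um} µm/px"
            )
        rows = np.arange(patch_px)
        my = (alpha.sum(axis=1) * rows).sum() / total
        mx = (alpha.sum(axis=0) * rows).sum() / total
        alpha = render(cy - (my - cy), cx - (mx - cx))
    return alpha


def render_cell(
    shape: ShapeClass,
    orientation_deg: float = 0.0,
    scale_um: float = 8.0,
    pixel_size_um: float = 0.1375,
    patch_px: int | None = None,
    subpixel: tuple[float, float] = (0.0, 0.0),
    foreground: float = CELL_LEVEL,
    background: float = BACKGROUND_LEVEL,
    supersample: int = 3,
) -> np.ndarray:
    """Render one cell as a grey-level patch: dark silhouette on light background.

    The patch is noise free; callers add sensor noise.  Values are floats on
    the 8-bit grey scale (0–255).
    """
    alpha = silhouette_alpha(
        shape,
        orientation_deg=orientation_deg,
        scale_um=scale_um,
        pixel_size_um=pixel_size_um,
        patch_px=patch_px,
        subpixel=subpixel,
        supersample=supersample,
    )
    return background - (background - foreground) * alpha


def mask_centroid(alpha: np.ndarray) -> tuple[float, float]:
    """Center of mass (row, col) of a coverage map."""
    total = alpha.sum()
    rows = np.arange(alpha.shape[0])
    cols = np.arange(alpha.shape[1])
    return (
        float((alpha.sum(axis=1) * rows).sum() / total),
        float((alpha.sum(axis=0) * cols).sum() / total),
    )
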