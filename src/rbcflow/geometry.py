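"""Channel geometry and the pixel/micron coordinate conventions.

Coordinates follow the imaging convention used throughout the package:
frames are 2-D arrays indexed ``[row, column]``; flow runs along the
columns (the x axis, ``flow_axis='x'``), and the lateral direction across
the channel is the row axis (y).  The channel interior occupies a
contiguous band of rows; everything outside that band images the channel
walls.  The normalized lateral position ``|y/W|`` is measured from the
channel centerline and runs from 0 (centerline) to 0.5 (wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical dimensions of the capillary channel and the optical scale.

    Parameters
    ----------
    height_um:
        Channel height along the optical (z) axis, metadata only.
    width_um:
        Channel width W across the flow, the normalizer of ``|y/W|``.
    length_mm:
        Total channel length, metadata only.
    pixel_size_um:
        Microns per pixel of the camera image.
    flow_axis:
        Which image axis carries the flow; only ``'x'`` (columns) is used.
    channel_span_px:
        ``(first, last)`` rows of the channel interior; the interior rows are
        ``first .. last-1`` so ``last - first`` is the channel width in pixels.
    fov_px:
        Field of view as ``(rows, columns)``.
    """

    height_um: float = 8.0
    width_um: float = 11.0
    length_mm: float = 40.0
    pixel_size_um: float = 0.1375
    flow_axis: str = "x"
    channel_span_px: tuple[int, int] = (10, 90)
    fov_px: tuple[int, int] = (100, 800)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.flow_axis != "x":
            raise ConfigurationError("only flow_axis='x' (columns) is supported")
        first, last = self.channel_span_px
        if not (0 <= first < last <= self.fov_px[0]):
            raise ConfigurationError(
                f"channel_span_px {self.channel_span_px} does not fit the "
                f"{self.fov_px[0]}-row field of view"
            )
        if abs(self.width_px - self.width_um / self.pixel_size_um) > 1.0:
            raise ConfigurationError(
                "channel_span_px spans "
                f"{self.width_px} px but width_um/pixel_size_um = "
                f"{self.width_um / self.pixel_size_um:.2f} px (must agree within 1 px)"
            )

    @property
    def width_px(self) -> float:
        """Channel width W in pixels."""
        first, last = self.channel_span_px
        return float(last - first)

    @property
    def centerline_row(self) -> float:
        """Sub-pixel row coordinate of the channel centerline."""
        first, last = self.channel_span_px
        return (first + last) / 2.0 - 0.5

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um

    def abs_y_over_w(self, row: float) -> float:
        """Normalized lateral position |y/W| of a sub-pixel row coordinate."""
        return abs(row - self.centerline_row) / self.width_px

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_span_px"] = list(self.channel_span_px)
        d["fov_px"] = list(self.fov_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        d = dict(d)
        d["channel_span_px"] = tuple(d["channel_span_px"])
        d["fov_px"] = tuple(d["fov_px"])
        return cls(**d)
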