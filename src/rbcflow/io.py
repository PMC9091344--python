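"""On-disk formats: frame sequences, metadata sidecars, reports, run configs.

Frames travel as multi-page TIFF stacks or directories of zero-padded
numbered PNG/TIFF frames, always with a JSON metadata sidecar carrying the
physical constants that must never be silently defaulted: ``frame_rate_hz``
and ``pixel_size_um`` (``channel_span_px`` may be omitted and calibrated
from the background).  Reports and configs are JSON with a
``schema_version`` field; undefined statistics round-trip as explicit
nulls, never as zero.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml

from .errors import ConfigurationError, FormatError
from .geometry import ChannelGeometry
from .synth import FlowPopulationConfig

REPORT_SCHEMA_VERSION = 1
CONFIG_SCHEMA_VERSION = 1

REQUIRED_METADATA = ("frame_rate_hz", "pixel_size_um")


def write_sequence(frames: np.ndarray, path, metadata: dict, fmt: str = "tiff") -> Path:
    """Write a frame stack plus its JSON metadata sidecar.

    ``fmt='tiff'`` writes ``frames.tif`` (multi-page) under ``path``;
    ``fmt='png'`` writes zero-padded numbered PNGs.  Returns the sequence
    path (the TIFF file or the directory).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        seq_path = path / "frames.tif"
        tifffile.imwrite(seq_path, frames, photometric="minisblack")
    elif fmt == "png":
        seq_path = path
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
    else:
        raise ConfigurationError(f"unknown sequence format {fmt!r}")
    (path / "meta.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return seq_path


def _read_metadata(meta_path: Path) -> dict:
    if not meta_path.exists():
        raise ConfigurationError(f"metadata sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise ConfigurationError(f"metadata is missing required field {key!r}")
    return meta


def read_sequence(path, meta_path=None) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF or a numbered frame directory with its metadata.

    Raises an explicit error naming missing metadata fields, listing gaps in
    frame numbering, and rejecting inconsistent frame shapes.
    """
    path = Path(path)
    if path.is_file():
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        meta = _read_metadata(
            Path(meta_path) if meta_path else path.parent / "meta.json"
        )
        return frames, meta
    if not path.is_dir():
        raise FormatError(f"{path} is neither a TIFF file nor a frame directory")
    tif = path / "frames.tif"
    if tif.exists():
        return read_sequence(tif, meta_path or path / "meta.json")
    pattern = re.compile(r"frame_(\d+)\.(png|tif|tiff)$")
    numbered = sorted(
        (int(m.group(1)), p)
        for p in path.iterdir()
        if (m := pattern.match(p.name))
    )
    if not numbered:
        raise FormatError(f"no numbered frames found in {path}")
    indices = [n for n, _ in numbered]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise FormatError(f"gap in frame numbering; missing indices {missing}")
    frames = [iio.imread(p) for _, p in numbered]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")
    meta = _read_metadata(Path(meta_path) if meta_path else path / "meta.json")
    return np.stack(frames), meta


# ---------------------------------------------------------------------------
# sample reports
# ---------------------------------------------------------------------------


@dataclass
class SampleReport:
    """All per-sample outputs: distributions, phase diagram, summary scalars.

    Undefined statistics (e.g. a ratio with zero denominator) are ``None``
    and serialize as JSON null.
    """

    sample_id: str
    condition: str
    n_cells: int
    deviation_score: float | None = None
    shape_ratio: float | None = None
    nonslipper_ratio: float | None = None
    transition_velocity: float | None = None
    distributions: list[dict] = field(default_factory=list)
    phase_diagram: dict | None = None
    stage_counts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = REPORT_SCHEMA_VERSION
        return d


def write_report(report: SampleReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def read_report(path) -> SampleReport:
    """Lossless JSON round-trip; unknown extra keys warn and are preserved."""
    d = json.loads(Path(path).read_text())
    version = d.pop("schema_version", None)
    if version != REPORT_SCHEMA_VERSION:
        raise FormatError(
            f"report schema version {version!r} unsupported "
            f"(expected {REPORT_SCHEMA_VERSION})"
        )
    known = set(SampleReport.__dataclass_fields__)
    unknown = {k: d.pop(k) for k in list(d) if k not in known}
    if unknown:
        warnings.warn(f"report has unknown keys {sorted(unknown)}; preserved in extra")
        d.setdefault("extra", {}).update(unknown)
    return SampleReport(**d)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable round-trip to JSON."""

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    population: FlowPopulationConfig = field(default_factory=FlowPopulationConfig)
    detection: dict = field(default_factory=dict)
    classifier_path: str | None = None
    sample_id: str = "sample"
    condition: str = "control"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "geometry": self.geometry.to_dict(),
            "population": self.population.to_dict(),
            "detection": dict(self.detection),
            "classifier_path": self.classifier_path,
            "sample_id": self.sample_id,
            "condition": self.condition,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        """Serialize to JSON, or YAML when the suffix is .yaml/.yml."""
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("schema_version", None)
        if version != CONFIG_SCHEMA_VERSION:
            raise FormatError(f"config schema version {version!r} unsupported")
        return cls(
            geometry=ChannelGeometry.from_dict(d["geometry"]),
            population=FlowPopulationConfig.from_dict(d["population"]),
            detection=d.get("detection", {}),
            classifier_path=d.get("classifier_path"),
            sample_id=d.get("sample_id", "sample"),
            condition=d.get("condition", "control"),
            seed=d.get("seed", 0),
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))
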