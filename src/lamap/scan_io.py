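"""On-disk artifacts: scan-line tables, 8-bit grayscale exports, ROI label maps.

Scan-line dialect
-----------------
Delimited text (comma-separated), one row per acquisition cycle, mandatory
header.  Columns: ``run_id, line_index, cycle_index`` followed by one raw
intensity column per m/z channel named ``<Element><mass>`` (``C13``, ``Mn55``,
``Fe57``, ``Cu63`` ...).  Two isotope columns of the same element may coexist.
Acquisition metadata (scan speed, cycle time, spot diameter, line spacing,
carbon channel) lives in a ``<file>.meta`` key-value sidecar.

Images are single-channel TIFF: 8-bit for grayscale exports, 16-bit for ROI
label maps, 32-bit float for calibrated concentration maps.  Every image
carries a ``<file>.meta`` sidecar with its stretch range and pixel geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateRangeError,
    FormatError,
)

logger = logging.getLogger("lamap")

GLASS_LABEL = 0
GLASS_NAME = "glass"
ENTIRE_SECTION = "entire_section"


# ---------------------------------------------------------------------------
# scan lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionMeta:
    """Geometry of a raster acquisition.

    scan_speed in μm s⁻¹, cycle_time in s, spot_diameter and line_spacing
    in μm.  The along-track pixel pitch is ``scan_speed * cycle_time``; the
    between-line pitch is ``line_spacing`` (ablation spot plus residual).
    """

    scan_speed: float = 70.0
    cycle_time: float = 0.341
    spot_diameter: float = 60.0
    line_spacing: float = 90.0

    def __post_init__(self) -> None:
        for name in ("scan_speed", "cycle_time", "spot_diameter", "line_spacing"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be > 0")


@dataclass
class ScanLineSet:
    """Ordered ablation lines of one run.

    ``lines[i]`` is an ``(n_cycles, n_channels)`` float array of raw ion
    intensities (counts) for line ``i``, column order given by ``channels``.
    Exactly one channel is flagged as the carbon reference.
    """

    run_id: str
    lines: list[np.ndarray]
    channels: list[str]
    carbon_channel: str
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        if not self.lines:
            raise FormatError("a ScanLineSet needs at least one line")
        n_ch = len(self.channels)
        if len(set(self.channels)) != n_ch:
            raise FormatError("duplicate channel names")
        if self.carbon_channel not in self.channels:
            raise FormatError(
                f"carbon reference channel {self.carbon_channel!r} not among channels"
            )
        for i, line in enumerate(self.lines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != n_ch or arr.shape[0] < 1:
                raise FormatError(f"line {i} is not (n_cycles ≥ 1, {n_ch}) shaped")
            if np.any(arr < 0):
                raise FormatError(f"line {i} contains negative intensities")
            self.lines[i] = arr

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not present") from None


def _meta_path(path: Path | str) -> Path:
    return Path(str(path) + ".meta")


def write_sidecar(path: Path | str, entries: Mapping[str, object]) -> None:
    lines = [f"{k}={v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: Path | str) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing sidecar {path}")
    out: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        if "=" not in raw:
            raise FormatError(f"malformed sidecar line {raw!r} in {path}")
        k, v = raw.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_scanlines(scan: ScanLineSet, path: Path | str) -> None:
    """Write a run as delimited text plus a key-value metadata sidecar."""
    path = Path(path)
    frames = []
    for li, line in enumerate(scan.lines):
        df = pd.DataFrame(line, columns=scan.channels)
        df.insert(0, "cycle_index", np.arange(line.shape[0]))
        df.insert(0, "line_index", li)
        df.insert(0, "run_id", scan.run_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    write_sidecar(
        _meta_path(path),
        {
            "carbon_channel": scan.carbon_channel,
            "scan_speed": scan.meta.scan_speed,
            "cycle_time": scan.meta.cycle_time,
            "spot_diameter": scan.meta.spot_diameter,
            "line_spacing": scan.meta.line_spacing,
        },
    )


def read_scanlines(path: Path | str) -> ScanLineSet:
    """Read a scan-line table; ragged lines are permitted but logged."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such scan-line file: {path}")
    df = pd.read_csv(path)
    required = ("run_id", "line_index", "cycle_index")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    channels = [c for c in df.columns if c not in required]
    if not channels:
        raise FormatError(f"{path}: no intensity channels")
    side = read_sidecar(_meta_path(path))
    carbon = side.get("carbon_channel", "")
    if carbon not in channels:
        raise FormatError(
            f"{path}: no channel marked as carbon reference (sidecar says {carbon!r})"
        )
    meta = AcquisitionMeta(
        scan_speed=float(side.get("scan_speed", 70.0)),
        cycle_time=float(side.get("cycle_time", 0.341)),
        spot_diameter=float(side.get("spot_diameter", 60.0)),
        line_spacing=float(side.get("line_spacing", 90.0)),
    )
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise FormatError(f"{path}: expected one run_id, found {len(run_ids)}")
    lines: list[np.ndarray] = []
    lengths = set()
    for li in sorted(df["line_index"].unique()):
        block = df[df["line_index"] == li].sort_values("cycle_index")
        lines.append(block[channels].to_numpy(dtype=float))
        lengths.add(len(block))
    if len(lengths) > 1:
        logger.warning("%s: ragged cycle counts across lines: %s", path, sorted(lengths))
    return ScanLineSet(
        run_id=str(run_ids[0]),
        lines=lines,
        channels=channels,
        carbon_channel=carbon,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# 8-bit grayscale export / import
# ---------------------------------------------------------------------------

@dataclass
class Gray8Image:
    """8-bit grayscale image plus the affine stretch that produced it.

    ``min_counts`` maps to gray 0 and ``max_counts`` to gray 255; the sidecar
    preserves both so the raw-intensity scale can be reconstructed.
    """

    data: np.ndarray  # uint8, 2-D
    channel: str
    max_counts: float
    min_counts: float
    pixel_size_x: float = 1.0
    pixel_size_y: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.dtype != np.uint8:
            raise FormatError("Gray8Image.data must be a 2-D uint8 array")
        if not self.max_counts > self.min_counts:
            raise DegenerateRangeError("max_counts must exceed min_counts")


def export_gray8(
    values: np.ndarray,
    channel: str = "",
    stretch: tuple[float, float] | None = None,
    pixel_size_x: float = 1.0,
    pixel_size_y: float = 1.0,
) -> Gray8Image:
    """Quantize a raw-intensity grid to 8 bits.

    gray = round(255 * (value - min) / (max - min)), clipped to [0, 255].
    ``stretch`` fixes (min_counts, max_counts); by default the image's own
    finite min/max are used.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise FormatError("export_gray8 requires finite intensities")
    if stretch is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = float(stretch[0]), float(stretch[1])
    if not hi > lo:
        raise DegenerateRangeError(f"degenerate stretch range [{lo}, {hi}]")
    gray = np.clip(np.round(255.0 * (values - lo) / (hi - lo)), 0, 255).astype(np.uint8)
    return Gray8Image(
        data=gray,
        channel=channel,
        max_counts=hi,
        min_counts=lo,
        pixel_size_x=pixel_size_x,
        pixel_size_y=pixel_size_y,
    )


def import_gray8(image: Gray8Image) -> np.ndarray:
    """Invert the affine stretch: value = min + gray/255 * (max - min).

    Exact up to quantization: at most half an LSB of the stored range,
    i.e. (max_counts - min_counts) / 510 per pixel.
    """
    span = image.max_counts - image.min_counts
    return image.min_counts + image.data.astype(float) / 255.0 * span


def write_gray8(image: Gray8Image, path: Path | str) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.data)
    write_sidecar(
        _meta_path(path),
        {
            "channel": image.channel,
            "max_counts": repr(image.max_counts),
            "min_counts": repr(image.min_counts),
            "pixel_size_x": repr(image.pixel_size_x),
            "pixel_size_y": repr(image.pixel_size_y),
        },
    )


def read_gray8(path: Path | str) -> Gray8Image:
    path = Path(path)
    data = tifffile.imread(path)
    if data.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit TIFF, got {data.dtype}")
    side = read_sidecar(_meta_path(path))
    return Gray8Image(
        data=data,
        channel=side.get("channel", ""),
        max_counts=float(side["max_counts"]),
        min_counts=float(side["min_counts"]),
        pixel_size_x=float(side.get("pixel_size_x", 1.0)),
        pixel_size_y=float(side.get("pixel_size_y", 1.0)),
    )


# ---------------------------------------------------------------------------
# float-32 concentration maps
# ---------------------------------------------------------------------------

def write_float_image(
    values: np.ndarray, path: Path | str, channel: str = "", units: str = "",
    pixel_size_x: float = 1.0, pixel_size_y: float = 1.0,
) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    write_sidecar(
        _meta_path(path),
        {
            "channel": channel,
            "units": units,
            "pixel_size_x": repr(pixel_size_x),
            "pixel_size_y": repr(pixel_size_y),
        },
    )


def read_float_image(path: Path | str) -> tuple[np.ndarray, dict[str, str]]:
    data = tifffile.imread(Path(path)).astype(float)
    return data, read_sidecar(_meta_path(path))


# ---------------------------------------------------------------------------
# ROI label maps
# ---------------------------------------------------------------------------

@dataclass
class RoiMaskSet:
    """Region label map aligned to an image grid.

    Label 0 is reserved for the glass background; ``entire_section`` denotes
    the union of all nonzero labels and is always available as a region name.
    """

    labels: np.ndarray  # 2-D integer label map
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label map must be 2-D")
        present = set(np.unique(self.labels).tolist())
        if GLASS_LABEL not in present:
            raise FormatError("label map has no glass background (label 0)")
        self.names = dict(self.names)
        self.names.setdefault(GLASS_LABEL, GLASS_NAME)
        unmapped = sorted(present - set(self.names))
        if unmapped:
            raise FormatError(f"labels without names: {unmapped}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def glass_mask(self) -> np.ndarray:
        return self.labels == GLASS_LABEL

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != GLASS_LABEL

    def region_names(self) -> list[str]:
        return [n for l, n in sorted(self.names.items()) if l != GLASS_LABEL]

    def region_mask(self, region: str) -> np.ndarray:
        if region == ENTIRE_SECTION:
            return self.tissue_mask
        if region == GLASS_NAME:
            return self.glass_mask
        for label, name in self.names.items():
            if name == region:
                return self.labels == label
        raise FormatError(f"unknown region {region!r}")


def write_label_map(mask: RoiMaskSet, path: Path | str) -> None:
    path = Path(path)
    labels = mask.labels
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("labels outside uint16 range")
    tifffile.imwrite(path, labels.astype(np.uint16))
    write_sidecar(_meta_path(path), {str(k): v for k, v in sorted(mask.names.items())})


def read_roi_labels(
    path: Path | str,
    name_table: Mapping[int, str] | None = None,
    expected_shape: tuple[int, int] | None = None,
) -> RoiMaskSet:
    """Read a 16-bit label TIFF; names come from ``name_table`` or the sidecar."""
    path = Path(path)
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise FormatError(f"{path}: label map must be single-channel 2-D")
    if expected_shape is not None and tuple(labels.shape) != tuple(expected_shape):
        raise AlignmentError(
            f"{path}: label map {labels.shape} does not match image {expected_shape}"
        )
    if name_table is None:
        side = read_sidecar(_meta_path(path))
        name_table = {int(k): v for k, v in side.items()}
    present = set(np.unique(labels).tolist())
    unmapped = sorted(present - set(name_table))
    if unmapped:
        logger.warning("%s: unmapped labels %s", path, unmapped)
    return RoiMaskSet(labels=labels.astype(np.int64), names=dict(name_table))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: Path | str) -> dict:
    """Load a structured pipeline configuration (YAML mapping)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg
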