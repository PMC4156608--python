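"""Scan lines → aligned per-channel images; drift correction; ¹³C normalization.

Pixel convention: row = ablation line index, column = acquisition cycle index,
both 0-based; physical x of a column is measured at the cycle start.  The
along-track pixel pitch is scan_speed × cycle_time (stored unrounded, 23.87 μm
for the default 70 μm s⁻¹ × 0.341 s acquisition, displayed as 24 μm) and the
between-line pitch is the line spacing (ablation spot + residual, 90 μm).
Ragged lines are right-padded with NaN sentinels, which every downstream
readout excludes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    AlignmentError,
    DriftEstimationError,
    FormatError,
    LamapError,
    NormalizationError,
)
from .scan_io import ScanLineSet

logger = logging.getLogger("lamap")

UNITS_COUNTS = "counts"
UNITS_NORMALIZED = "normalized"
UNITS_UGG = "ug/g"


@dataclass
class ElementImageStack:
    """Per-channel 2-D grids sharing one pixel geometry.

    ``data`` is (n_channels, n_lines, n_cols); NaN marks padded (sentinel)
    pixels of ragged lines.  ``units`` tracks the processing state of every
    channel (counts → normalized → μg g⁻¹).
    """

    data: np.ndarray
    channels: list[str]
    carbon_channel: str
    pixel_size_x: float
    pixel_size_y: float
    units: dict[str, str]
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise FormatError("stack must be (n_channels, n_lines, n_cols)")
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise FormatError("pixel sizes must be positive")
        missing = set(self.channels) - set(self.units)
        if missing:
            raise FormatError(f"channels without a units flag: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not in stack") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def metal_channels(self) -> list[str]:
        return [c for c in self.channels if c != self.carbon_channel]

    def display_pixel_size(self) -> tuple[int, int]:
        """Pixel pitch rounded to whole μm for display (e.g. 23.87 → 24)."""
        return (round(self.pixel_size_x), round(self.pixel_size_y))

    def copy(self) -> "ElementImageStack":
        return ElementImageStack(
            data=self.data.copy(),
            channels=list(self.channels),
            carbon_channel=self.carbon_channel,
            pixel_size_x=self.pixel_size_x,
            pixel_size_y=self.pixel_size_y,
            units=dict(self.units),
            history=list(self.history),
        )


def rasterize(scan: ScanLineSet) -> ElementImageStack:
    """Arrange cycles on the acquisition grid: pixel (r, c) of channel k is
    the intensity of cycle c in line r; shorter lines are NaN-padded."""
    if scan.n_lines == 0:
        raise LamapError("cannot rasterize an empty scan")
    n_ch = len(scan.channels)
    n_cols = max(line.shape[0] for line in scan.lines)
    data = np.full((n_ch, scan.n_lines, n_cols), np.nan)
    for r, line in enumerate(scan.lines):
        data[:, r, : line.shape[0]] = line.T
    return ElementImageStack(
        data=data,
        channels=list(scan.channels),
        carbon_channel=scan.carbon_channel,
        pixel_size_x=scan.meta.scan_speed * scan.meta.cycle_time,
        pixel_size_y=scan.meta.line_spacing,
        units={c: UNITS_COUNTS for c in scan.channels},
        history=[f"rasterize(run_id={scan.run_id})"],
    )


@dataclass
class DriftModel:
    """Linear multiplicative per-line sensitivity drift.

    ``factors[0] = 1`` at the standard-adjacent end; ``endpoint_factor`` is
    the fitted level at the far end divided by the level at the near end.
    ``necessary`` is False when the endpoint factor sits within the
    no-correction tolerance of 1 (default ±2%).
    """

    endpoint_factor: float
    factors: np.ndarray
    necessary: bool
    reference_channel: str
    tolerance: float = 0.02

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise DriftEstimationError("drift factors must be strictly positive")
        if abs(self.factors[0] - 1.0) > 1e-12:
            raise DriftEstimationError("factor at the standard-adjacent end must be 1")


def estimate_drift(
    stack: ElementImageStack,
    reference: str | None = None,
    tissue_mask: np.ndarray | None = None,
    tolerance: float = 0.02,
) -> DriftModel:
    """Fit the per-line level of a reference channel linearly in line index.

    The per-line level is the median over tissue pixels (or the whole line if
    no mask is given) — robust against region edges.  Factors are the fitted
    line normalized to its value at line 0.
    """
    if stack.n_lines < 3:
        raise DriftEstimationError("need at least 3 lines to estimate drift")
    reference = reference or stack.carbon_channel
    image = stack.get(reference)
    if tissue_mask is not None:
        if tissue_mask.shape != image.shape:
            raise AlignmentError("tissue mask does not match the stack grid")
        image = np.where(tissue_mask, image, np.nan)
    with warnings.catch_warnings():
        # glass-only lines have no tissue pixels; their NaN level is excluded below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        levels = np.nanmedian(image, axis=1)
    idx = np.arange(stack.n_lines, dtype=float)
    ok = np.isfinite(levels)
    if ok.sum() < 3:
        raise DriftEstimationError("fewer than 3 lines with usable reference signal")
    slope, intercept = np.polyfit(idx[ok], levels[ok], 1)
    fitted = intercept + slope * idx
    if fitted[0] <= 0:
        raise DriftEstimationError("non-positive fitted level at the drift anchor")
    factors = fitted / fitted[0]
    endpoint = float(factors[-1])
    necessary = abs(endpoint - 1.0) > tolerance
    if not necessary:
        logger.info("drift correction unnecessary (endpoint factor %.4f)", endpoint)
    return DriftModel(
        endpoint_factor=endpoint,
        factors=factors,
        necessary=necessary,
        reference_channel=reference,
        tolerance=tolerance,
    )


def apply_drift(stack: ElementImageStack, model: DriftModel) -> ElementImageStack:
    """Divide every line by its drift factor (all channels drift together)."""
    if len(model.factors) != stack.n_lines:
        raise AlignmentError(
            f"drift model has {len(model.factors)} lines, stack has {stack.n_lines}"
        )
    out = stack.copy()
    out.data = out.data / model.factors[None, :, None]
    out.history.append(
        f"apply_drift(endpoint={model.endpoint_factor:.6g}, ref={model.reference_channel})"
    )
    return out


def net_carbon_level(
    stack: ElementImageStack, glass_mask: np.ndarray | None = None
) -> float:
    """Average net ¹³C intensity of a section (slice-thickness surrogate).

    The net level is the separation of the tissue and glass modes of the
    carbon histogram: a 256-bin histogram is split at the Otsu threshold;
    each mode is the most populated bin on its side and contributes the mean
    of its member pixels.  With an explicit ``glass_mask`` the histogram step
    is bypassed and plain tissue/glass means are used instead.
    """
    carbon = stack.get(stack.carbon_channel)
    values = carbon[np.isfinite(carbon)]
    if values.size == 0:
        raise NormalizationError("carbon channel has no usable pixels")
    if glass_mask is not None:
        if glass_mask.shape != carbon.shape:
            raise AlignmentError("glass mask does not match the stack grid")
        finite = np.isfinite(carbon)
        glass_vals = carbon[glass_mask & finite]
        tissue_vals = carbon[~glass_mask & finite]
        if glass_vals.size == 0 or tissue_vals.size == 0:
            raise NormalizationError("glass mask leaves an empty tissue or glass set")
        glass_level = float(glass_vals.mean())
        tissue_level = float(tissue_vals.mean())
    else:
        glass_level, tissue_level = _histogram_modes(values)
    net = tissue_level - glass_level
    if net <= 0:
        raise NormalizationError(
            f"non-positive net carbon level ({net:.4g}); tissue/glass not separated"
        )
    return net


def carbon_normalize(
    stack: ElementImageStack, glass_mask: np.ndarray | None = None
) -> ElementImageStack:
    """Divide metal channels by the average net ¹³C intensity.

    See :func:`net_carbon_level` for how the net level is determined; the
    applied scalar is logged and recorded in the stack history.
    """
    net = net_carbon_level(stack, glass_mask=glass_mask)
    logger.info("carbon normalization: net 13C level %.6g", net)
    out = stack.copy()
    for channel in out.metal_channels():
        out.data[out.channel_index(channel)] /= net
        out.units[channel] = UNITS_NORMALIZED
    out.history.append(f"carbon_normalize(net={net:.6g})")
    return out


def _histogram_modes(values: np.ndarray) -> tuple[float, float]:
    """Glass and tissue levels from the 256-bin carbon histogram."""
    if np.ptp(values) == 0:
        raise NormalizationError("constant carbon image: unimodal histogram")
    counts, edges = np.histogram(values, bins=256)
    try:
        threshold = threshold_otsu(values)
    except ValueError as exc:  # pragma: no cover - ptp==0 already handled
        raise NormalizationError(f"cannot threshold carbon histogram: {exc}") from exc
    centers = 0.5 * (edges[:-1] + edges[1:])
    below = centers <= threshold
    above = ~below
    if counts[below].sum() == 0 or counts[above].sum() == 0:
        raise NormalizationError("carbon histogram has no glass/tissue separation")

    def mode_mean(side: np.ndarray) -> float:
        masked = np.where(side, counts, -1)
        b = int(np.argmax(masked))
        lo, hi = edges[b], edges[b + 1]
        inside = (values >= lo) & (values <= hi if b == 255 else values < hi)
        return float(values[inside].mean())

    glass_level = mode_mean(below)
    tissue_level = mode_mean(above)
    return glass_level, tissue_level
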