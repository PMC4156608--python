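"""Matrix-matched calibration: counts → μg g⁻¹ wet weight.

The raw-count pathway is primary: concentration = (counts − background)/slope,
with the slope fitted by ordinary least squares of per-level mean counts on
the known standard concentrations and the background taken from the fitted
intercept (standards include a blank) or, failing that, from the sample's own
glass ROI.

The historical 8-bit pathway is also provided:

    concentration = (max_counts − min_counts) × (gray − background_gray)
                    / (255 × slope)

where gray values are the affine 8-bit quantization of raw counts and
``background_gray`` is the mean gray over the glass ROI.  Both pathways agree
within the propagated half-LSB quantization bound,
(max_counts − min_counts)/(510 × slope), on every pixel.

Isotope pairs (Cu63/Cu65, ...) are calibrated independently and never
averaged; comparing their concentration maps is a validation check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CalibrationError, DegenerateRangeError, DomainError, RankError
from .phantom import StandardScan, channel_element
from .reconstruct import UNITS_UGG, ElementImageStack
from .scan_io import Gray8Image

logger = logging.getLogger("lamap")


@dataclass
class CalibrationCurve:
    """Per-channel linear counts-vs-concentration calibration."""

    channel: str
    slope: float  # counts per μg g⁻¹
    intercept: float  # background counts
    levels: pd.DataFrame  # concentration, mean_counts, sd_counts, n_cycles
    r_squared: float
    residual_sd: float
    slope_se: float = float("nan")
    curve_id: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"{self.channel}: non-positive fitted slope {self.slope:.4g} "
                "(corrupt standards?)"
            )
        if self.intercept < 0:
            logger.warning(
                "%s: negative fitted background %.4g clamped to 0",
                self.channel, self.intercept,
            )
            self.intercept = 0.0


def fit_slope(
    levels: pd.DataFrame | list[tuple[float, float]],
    channel: str = "",
    curve_id: str = "",
) -> CalibrationCurve:
    """OLS line of per-level mean counts on known concentration.

    ``levels`` rows carry (concentration, mean_counts) and optionally
    sd_counts / n_cycles.  Needs ≥ 2 distinct concentrations.
    """
    if not isinstance(levels, pd.DataFrame):
        levels = pd.DataFrame(levels, columns=["concentration", "mean_counts"])
    levels = levels.copy()
    for col in ("sd_counts", "n_cycles"):
        if col not in levels.columns:
            levels[col] = np.nan
    conc = levels["concentration"].to_numpy(dtype=float)
    counts = levels["mean_counts"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 2:
        raise RankError(
            f"{channel or 'calibration'}: standards have identical concentrations"
        )
    res = sps.linregress(conc, counts)
    fitted = res.intercept + res.slope * conc
    resid = counts - fitted
    dof = max(len(conc) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return CalibrationCurve(
        channel=channel,
        slope=float(res.slope),
        intercept=float(res.intercept),
        levels=levels,
        r_squared=float(res.rvalue**2) if len(conc) > 2 else 1.0 - _ss_ratio(resid, counts),
        residual_sd=residual_sd,
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else float("nan"),
        curve_id=curve_id,
    )


def _ss_ratio(resid: np.ndarray, counts: np.ndarray) -> float:
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    return float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0


def standards_to_levels(standards: list[StandardScan], channel: str) -> pd.DataFrame:
    """Collapse simulated/measured standard blocks to per-level summary counts."""
    element = channel_element(channel)
    rows = []
    for std in standards:
        idx = std.scan.channel_index(channel)
        values = np.concatenate([line[:, idx] for line in std.scan.lines])
        rows.append(
            {
                "concentration": float(std.concentrations.get(element, 0.0)),
                "mean_counts": float(values.mean()),
                "sd_counts": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "n_cycles": int(values.size),
            }
        )
    return pd.DataFrame(rows)


def fit_curves(
    standards: list[StandardScan],
    channels: list[str] | None = None,
    curve_id: str = "",
) -> dict[str, CalibrationCurve]:
    """Fit one calibration curve per metal channel from standard scans."""
    if not standards:
        raise CalibrationError("no standard scans supplied")
    scan = standards[0].scan
    if channels is None:
        channels = [c for c in scan.channels if c != scan.carbon_channel]
    return {
        ch: fit_slope(standards_to_levels(standards, ch), channel=ch, curve_id=curve_id)
        for ch in channels
    }


def concentration_from_counts(
    counts: np.ndarray | float, curve: CalibrationCurve
) -> np.ndarray | float:
    """(counts − background) / slope, clamped at 0 (clamp count is logged)."""
    arr = np.asarray(counts, dtype=float)
    conc = (arr - curve.intercept) / curve.slope
    clamped = int(np.sum(conc < 0))
    if clamped:
        logger.info("%s: clamped %d negative pixels to 0", curve.channel, clamped)
    conc = np.maximum(conc, 0.0)
    if np.isscalar(counts):
        return float(conc)
    return conc


def concentration_from_gray(
    gray: np.ndarray | float,
    background_gray: float,
    max_counts: float,
    min_counts: float,
    slope: float,
) -> np.ndarray | float:
    """8-bit pathway: (max − min) × (gray − background_gray) / (255 × slope)."""
    if not max_counts > min_counts:
        raise DegenerateRangeError("max_counts must exceed min_counts")
    if slope <= 0:
        raise DomainError("slope must be positive")
    g = np.asarray(gray, dtype=float)
    if np.any(g < 0) or np.any(g > 255) or not 0 <= background_gray <= 255:
        raise DomainError("gray values must lie in [0, 255]")
    conc = (max_counts - min_counts) * (g - background_gray) / (255.0 * slope)
    conc = np.maximum(conc, 0.0)
    if np.isscalar(gray):
        return float(conc)
    return conc


def gray_pathway(
    image: Gray8Image, glass_mask: np.ndarray, curve: CalibrationCurve
) -> np.ndarray:
    """Calibrate an 8-bit export; background_gray = mean gray over the glass ROI."""
    background_gray = float(image.data[glass_mask].mean())
    return concentration_from_gray(
        image.data, background_gray, image.max_counts, image.min_counts, curve.slope
    )


def calibrate_stack(
    stack: ElementImageStack,
    curves: dict[str, CalibrationCurve],
    glass_mask: np.ndarray | None = None,
    channels: list[str] | None = None,
) -> ElementImageStack:
    """Convert metal channels of a counts stack to μg g⁻¹ wet weight.

    Each channel must have a curve fitted from its own run's standard.  The
    background is the fitted intercept; when a curve was fitted without a
    blank (zero-concentration level) the sample's own glass-ROI mean is used
    instead, which requires ``glass_mask``.
    """
    if channels is None:
        channels = stack.metal_channels()
    out = stack.copy()
    for channel in channels:
        if channel not in curves:
            raise CalibrationError(f"no calibration curve for channel {channel!r}")
        curve = curves[channel]
        idx = out.channel_index(channel)
        if out.units[channel] == UNITS_UGG:
            raise CalibrationError(f"{channel}: channel is already calibrated")
        background = curve.intercept
        has_blank = bool(np.any(curve.levels["concentration"].to_numpy() == 0.0))
        if not has_blank:
            if glass_mask is None:
                raise CalibrationError(
                    f"{channel}: standards have no blank and no glass mask was given"
                )
            pix = out.data[idx][glass_mask & np.isfinite(out.data[idx])]
            background = float(pix.mean())
        conc = (out.data[idx] - background) / curve.slope
        clamped = int(np.nansum(conc < 0))
        if clamped:
            logger.info("%s: clamped %d negative pixels to 0", channel, clamped)
        out.data[idx] = np.where(np.isfinite(conc), np.maximum(conc, 0.0), np.nan)
        out.units[channel] = UNITS_UGG
        out.history.append(f"calibrate({channel}, curve={curve.curve_id or 'anon'})")
    return out


def write_curve(curve: CalibrationCurve, path) -> None:
    """Serialize a curve as key-value text with its standard-level table."""
    from pathlib import Path

    lines = [
        f"channel={curve.channel}",
        f"slope={curve.slope!r}",
        f"intercept={curve.intercept!r}",
        f"r_squared={curve.r_squared!r}",
        f"residual_sd={curve.residual_sd!r}",
        f"slope_se={curve.slope_se!r}",
        f"curve_id={curve.curve_id}",
        "levels:",
    ]
    for row in curve.levels.itertuples():
        lines.append(
            f"  {row.concentration!r} {row.mean_counts!r} "
            f"{row.sd_counts!r} {row.n_cycles!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path) -> CalibrationCurve:
    from pathlib import Path

    fields: dict[str, str] = {}
    level_rows = []
    in_levels = False
    for raw in Path(path).read_text().splitlines():
        if raw.strip() == "levels:":
            in_levels = True
            continue
        if in_levels:
            parts = raw.split()
            if len(parts) == 4:
                level_rows.append(
                    {
                        "concentration": float(parts[0]),
                        "mean_counts": float(parts[1]),
                        "sd_counts": float(parts[2]),
                        "n_cycles": float(parts[3]),
                    }
                )
            continue
        if "=" in raw:
            k, v = raw.split("=", 1)
            fields[k.strip()] = v.strip()
    return CalibrationCurve(
        channel=fields["channel"],
        slope=float(fields["slope"]),
        intercept=float(fields["intercept"]),
        levels=pd.DataFrame(level_rows),
        r_squared=float(fields["r_squared"]),
        residual_sd=float(fields["residual_sd"]),
        slope_se=float(fields["slope_se"]),
        curve_id=fields.get("curve_id", ""),
    )


def isotope_pair_report(
    stack: ElementImageStack, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Compare independently calibrated isotope maps of the same element.

    Reports mean concentrations and their relative difference per pair; maps
    are never averaged.
    """
    if pairs is None:
        by_element: dict[str, list[str]] = {}
        for ch in stack.metal_channels():
            if stack.units.get(ch) == UNITS_UGG:
                by_element.setdefault(channel_element(ch), []).append(ch)
        pairs = [tuple(chs[:2]) for chs in by_element.values() if len(chs) >= 2]
    rows = []
    for a, b in pairs:
        ma = float(np.nanmean(stack.get(a)))
        mb = float(np.nanmean(stack.get(b)))
        denom = 0.5 * (ma + mb)
        rows.append(
            {
                "channel_a": a,
                "channel_b": b,
                "mean_a": ma,
                "mean_b": mb,
                "relative_difference": (ma - mb) / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
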