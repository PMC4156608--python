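"""ROI readout of calibrated images into per-animal regional concentrations.

Readout is the arithmetic mean over the non-sentinel pixels carrying a region
label.  Each hemisphere of an animal is acquired, calibrated and read out
independently; the per-animal value of a region is the unweighted mean of its
two hemisphere means (bi-hemispheric average).  ``entire_section`` always
denotes the union of all non-glass labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CompletenessError,
    EmptyRoiError,
    PairingError,
)
from .phantom import channel_element
from .scan_io import ENTIRE_SECTION, RoiMaskSet

logger = logging.getLogger("lamap")


@dataclass
class RegionMeasurement:
    """Mean concentration of one region in one hemisphere image.

    ``sd`` is the sample SD across the region's pixels (ddof=1; 0 for a
    single-pixel region).
    """

    region: str
    channel: str
    mean: float
    sd: float
    n_pixels: int
    element: str = ""
    animal: str = ""
    group: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise EmptyRoiError(f"region {self.region!r} has no pixels")
        if not self.element and self.channel:
            self.element = channel_element(self.channel)


def region_mean(
    image: np.ndarray,
    mask: RoiMaskSet,
    region: str,
    channel: str = "",
    animal: str = "",
    group: str = "",
    hemisphere: str = "",
) -> RegionMeasurement:
    """Arithmetic mean over the region's non-sentinel (finite) pixels."""
    image = np.asarray(image, dtype=float)
    if image.shape != mask.shape:
        raise AlignmentError(
            f"image {image.shape} does not align with mask {mask.shape}"
        )
    sel = mask.region_mask(region) & np.isfinite(image)
    values = image[sel]
    if values.size == 0:
        raise EmptyRoiError(f"region {region!r} has no usable pixels")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RegionMeasurement(
        region=region,
        channel=channel,
        mean=float(values.mean()),
        sd=sd,
        n_pixels=int(values.size),
        animal=animal,
        group=group,
        hemisphere=hemisphere,
    )


def measure_regions(
    stack,
    mask: RoiMaskSet,
    channels: list[str] | None = None,
    regions: list[str] | None = None,
    animal: str = "",
    group: str = "",
    hemisphere: str = "",
    include_entire_section: bool = True,
) -> pd.DataFrame:
    """Tidy per-(region × channel) readout of one calibrated hemisphere stack."""
    if channels is None:
        channels = stack.metal_channels()
    if regions is None:
        regions = mask.region_names()
        if include_entire_section and ENTIRE_SECTION not in regions:
            regions = regions + [ENTIRE_SECTION]
    rows = []
    for channel in channels:
        image = stack.get(channel)
        for region in regions:
            m = region_mean(
                image, mask, region, channel=channel,
                animal=animal, group=group, hemisphere=hemisphere,
            )
            rows.append(
                {
                    "animal": m.animal, "group": m.group, "hemisphere": m.hemisphere,
                    "region": m.region, "channel": m.channel, "element": m.element,
                    "mean": m.mean, "sd": m.sd, "n_pixels": m.n_pixels,
                }
            )
    return pd.DataFrame(rows)


def bihemispheric_average(
    left: RegionMeasurement, right: RegionMeasurement
) -> RegionMeasurement:
    """Unweighted mean of the two hemisphere means of one animal/region/channel."""
    for attr in ("animal", "region", "channel"):
        if getattr(left, attr) != getattr(right, attr):
            raise PairingError(
                f"hemisphere measurements differ in {attr}: "
                f"{getattr(left, attr)!r} vs {getattr(right, attr)!r}"
            )
    return RegionMeasurement(
        region=left.region,
        channel=left.channel,
        mean=0.5 * (left.mean + right.mean),
        sd=0.5 * (left.sd + right.sd),
        n_pixels=left.n_pixels + right.n_pixels,
        animal=left.animal,
        group=left.group,
        hemisphere="LR",
    )


def combine_hemispheres(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse the tidy per-hemisphere table to per-animal values.

    Animals with a single measured hemisphere contribute that hemisphere's
    value (logged) rather than silently shrinking the group.
    """
    keys = ["animal", "group", "region", "channel", "element"]
    rows = []
    for key, block in measurements.groupby(keys, sort=True):
        n_hemi = block["hemisphere"].nunique()
        if n_hemi == 1:
            logger.warning(
                "animal %s region %s channel %s: single hemisphere only", *key[:1], key[2], key[3]
            )
        rows.append(dict(zip(keys, key)) | {"value": float(block["mean"].mean())})
    return pd.DataFrame(rows)


def assemble_cohort(
    per_animal: pd.DataFrame, manifest: pd.DataFrame
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Group per-animal values into control/WD vectors per (region, channel).

    The manifest (animal, group) defines cohort membership; an animal listed
    there with no measurements is a completeness error.  Vectors are ordered
    by sorted animal id, so shuffled input yields identical output.
    """
    manifest = manifest[["animal", "group"]].drop_duplicates()
    measured = set(per_animal["animal"].unique())
    missing = sorted(set(manifest["animal"]) - measured)
    if missing:
        raise CompletenessError(f"manifest animals without measurements: {missing}")
    group_of = dict(zip(manifest["animal"], manifest["group"]))
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (region, channel), block in per_animal.groupby(["region", "channel"], sort=True):
        block = block.sort_values("animal")
        vectors: dict[str, np.ndarray] = {}
        for group in sorted(manifest["group"].unique()):
            sel = block[block["animal"].map(group_of) == group]
            vectors[group] = sel["value"].to_numpy(dtype=float)
        out[(str(region), str(channel))] = vectors
    return out
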