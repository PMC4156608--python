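"""Synthetic phantoms, cohorts and raw scan-line simulation.

The forward instrument model is deliberately minimal but invertible by the
analysis chain:

* expected counts per cycle = slope × (spot-averaged concentration over the
  ablation spot's travel) + background,
* optional Poisson counting noise,
* a multiplicative per-line drift factor, linear in line index, anchored at
  1 on the standard-adjacent end,
* a ¹³C channel carrying a two-level tissue/glass intensity as a slice
  thickness surrogate.

Spot smearing is a one-dimensional moving average along the travel (x)
direction over the spot diameter; with the default 90 μm line spacing and
60 μm spot there is no between-line overlap, so lines are independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import (
    AlignmentError,
    FormatError,
    LamapError,
    LayoutError,
    ParameterError,
    RankError,
    ResolutionError,
)
from .scan_io import GLASS_LABEL, GLASS_NAME, AcquisitionMeta, RoiMaskSet, ScanLineSet

# ---------------------------------------------------------------------------
# channel table: 28 m/z channels including the ¹³C reference and two isotopes
# per element where available (Fe56/Fe57, Cu63/Cu65, Zn64/Zn66).
# ---------------------------------------------------------------------------

DEFAULT_CHANNELS: tuple[str, ...] = (
    "C13", "Na23", "Mg24", "Al27", "P31", "S34", "K39", "Ca44",
    "Ti48", "V51", "Cr52", "Mn55", "Fe56", "Fe57", "Co59", "Ni60",
    "Cu63", "Cu65", "Zn64", "Zn66", "Ga69", "Se77", "Rb85", "Sr88",
    "Mo95", "Cd111", "Gd157", "Pb208",
)

CARBON_CHANNEL = "C13"

# Per-element primary isotope used for numeric results; the secondary isotope
# maps are kept for validation, never averaged in.
PRIMARY_ISOTOPE = {"Fe": "Fe57", "Cu": "Cu63", "Zn": "Zn64", "Mn": "Mn55"}

# sensitivities in counts per μg g⁻¹ per cycle and backgrounds in counts;
# values are of realistic quadrupole magnitude (e.g. high Fe56 background
# from the ArO⁺ interference, low-abundance Fe57).
DEFAULT_SENSITIVITY: dict[str, float] = {
    "Na23": 40.0, "Mg24": 100.0, "Al27": 100.0, "P31": 15.0, "S34": 20.0,
    "K39": 30.0, "Ca44": 50.0, "Ti48": 100.0, "V51": 300.0, "Cr52": 300.0,
    "Mn55": 3000.0, "Fe56": 700.0, "Fe57": 80.0, "Co59": 1000.0, "Ni60": 300.0,
    "Cu63": 800.0, "Cu65": 360.0, "Zn64": 350.0, "Zn66": 200.0, "Ga69": 500.0,
    "Se77": 30.0, "Rb85": 800.0, "Sr88": 1000.0, "Mo95": 400.0, "Cd111": 300.0,
    "Gd157": 1000.0, "Pb208": 800.0,
}

DEFAULT_BACKGROUND: dict[str, float] = {
    "Na23": 200.0, "Mg24": 50.0, "Al27": 80.0, "P31": 100.0, "S34": 150.0,
    "K39": 300.0, "Ca44": 120.0, "Ti48": 30.0, "V51": 10.0, "Cr52": 40.0,
    "Mn55": 30.0, "Fe56": 500.0, "Fe57": 60.0, "Co59": 10.0, "Ni60": 25.0,
    "Cu63": 40.0, "Cu65": 25.0, "Zn64": 60.0, "Zn66": 35.0, "Ga69": 10.0,
    "Se77": 20.0, "Rb85": 10.0, "Sr88": 10.0, "Mo95": 10.0, "Cd111": 10.0,
    "Gd157": 5.0, "Pb208": 15.0,
}

_ELEMENT_RE = re.compile(r"^([A-Z][a-z]?)(\d+)$")


def channel_element(channel: str) -> str:
    """``'Cu63' -> 'Cu'``; the element symbol of an ``<Element><mass>`` channel."""
    m = _ELEMENT_RE.match(channel)
    if m is None:
        raise FormatError(f"channel name {channel!r} is not <Element><mass>")
    return m.group(1)


def derive_seed(master: int, *keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(master), *(int(k) for k in keys)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phantom:
    """Region-labeled ground-truth geometry on the acquisition pixel grid."""

    label_map: np.ndarray
    region_names: dict[int, str]
    pixel_size_x: float
    pixel_size_y: float

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if lm.ndim != 2 or lm.size < 1:
            raise LayoutError("label map must be a non-empty 2-D grid")
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise LayoutError("pixel sizes must be positive")
        present = set(np.unique(lm).tolist()) - {GLASS_LABEL}
        missing = present - set(self.region_names)
        if missing:
            raise LayoutError(f"labels without names: {sorted(missing)}")
        object.__setattr__(self, "label_map", lm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def regions(self) -> list[str]:
        present = set(np.unique(self.label_map).tolist()) - {GLASS_LABEL}
        return [self.region_names[l] for l in sorted(present)]

    def label_of(self, region: str) -> int:
        for label, name in self.region_names.items():
            if name == region:
                return label
        raise LayoutError(f"unknown region {region!r}")

    def roi_mask(self) -> RoiMaskSet:
        names = {GLASS_LABEL: GLASS_NAME, **self.region_names}
        return RoiMaskSet(labels=self.label_map.copy(), names=names)


# (name, row0, row1, col0, col1), half-open pixel rectangles on glass.
RegionRect = tuple[str, int, int, int, int]


def build_phantom(
    layout: Sequence[RegionRect],
    shape: tuple[int, int],
    pixel_size_x: float = 70.0 * 0.341,
    pixel_size_y: float = 90.0,
) -> Phantom:
    """Rasterize a rectangle layout into a labeled phantom.

    Regions must be non-overlapping and leave a glass border around the map;
    labels are assigned 1..n in layout order.  Deterministic for a fixed
    layout.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise LayoutError("phantom shape must be at least 1×1")
    lm = np.zeros((rows, cols), dtype=np.int64)
    names: dict[int, str] = {}
    for label, (name, r0, r1, c0, c1) in enumerate(layout, start=1):
        r0c, r1c = max(r0, 0), min(r1, rows)
        c0c, c1c = max(c0, 0), min(c1, cols)
        if r0c >= r1c or c0c >= c1c:
            raise ResolutionError(f"region {name!r} has zero pixels at this resolution")
        block = lm[r0c:r1c, c0c:c1c]
        if np.any(block != GLASS_LABEL):
            raise LayoutError(f"region {name!r} overlaps an earlier region")
        block[:] = label
        names[label] = name
    border = np.concatenate([lm[0, :], lm[-1, :], lm[:, 0], lm[:, -1]])
    if np.any(border != GLASS_LABEL):
        raise LayoutError("layout must leave a glass background border")
    return Phantom(lm, names, pixel_size_x, pixel_size_y)


def default_layout() -> tuple[tuple[int, int], list[RegionRect]]:
    """Scaled-down mouse-brain layout with all 20 reference regions.

    48 lines × 100 cycles (≈ 4.3 × 2.4 mm at the 90 × 23.87 μm pitch); row
    bands separate anatomical groups, glass gaps ≥ 4 columns (≈ 95 μm) keep
    the 60 μm spot from smearing across neighbouring regions.
    """
    rects: list[RegionRect] = [
        ("cortex", 3, 10, 3, 97),
        ("corpus_callosum", 10, 13, 3, 97),
        ("lateral_ventricles", 14, 18, 3, 32),
        ("third_ventricle", 14, 18, 36, 65),
        ("fourth_ventricle", 14, 18, 69, 97),
        ("colliculus_superior", 19, 23, 3, 48),
        ("colliculus_inferior", 19, 23, 52, 97),
        ("cerebellum_cu_rich", 24, 29, 3, 33),
        ("cerebellum_cu_poor", 24, 29, 37, 66),
        ("cerebellar_white_matter", 24, 29, 70, 97),
        ("moleculare", 30, 36, 3, 20),
        ("granulare", 30, 36, 24, 41),
        ("multiforme", 30, 36, 45, 62),
        ("oriens", 30, 36, 66, 78),
        ("ca3", 30, 36, 82, 97),
        ("ca1_2", 37, 43, 3, 20),
        ("radiatum", 37, 43, 24, 41),
        ("lacunosum_moleculare", 37, 43, 45, 62),
        ("subiculum", 37, 43, 66, 78),
        ("praesubiculum", 37, 43, 82, 97),
    ]
    return (48, 100), rects


def default_phantom() -> Phantom:
    shape, rects = default_layout()
    return build_phantom(rects, shape)


# ---------------------------------------------------------------------------
# cohort parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Per (group, region, element) mean/SD concentrations plus group sizes."""

    table: pd.DataFrame  # columns: group, region, element, mean, sd
    n_control: int = reference.CONTROL_N
    n_wd: int = reference.WD_N

    def __post_init__(self) -> None:
        cols = {"group", "region", "element", "mean", "sd"}
        if not cols.issubset(self.table.columns):
            raise ParameterError(f"params table needs columns {sorted(cols)}")
        if (self.table["mean"] < 0).any() or (self.table["sd"] < 0).any():
            raise ParameterError("means and SDs must be non-negative")
        if self.n_control < 2 or self.n_wd < 2:
            raise ParameterError("group sizes must be at least 2")
        self._index = {
            (r.group, r.region, r.element): (float(r.mean), float(r.sd))
            for r in self.table.itertuples()
        }

    def lookup(self, group: str, region: str, element: str) -> tuple[float, float]:
        try:
            return self._index[(group, region, element)]
        except KeyError:
            raise ParameterError(
                f"no parameters for ({group!r}, {region!r}, {element!r})"
            ) from None

    def elements(self) -> list[str]:
        return sorted(self.table["element"].unique())


def default_group_params(fill_periventricular: bool = True) -> GroupParams:
    """The reference cohort table as simulator parameters.

    ``fill_periventricular`` substitutes entire-section Fe/Zn/Mn values for
    the periventricular cells that were reported for Cu only, so every
    phantom region × element is parameterized.
    """
    rows = []
    for region, per_elem in reference.REGION_PARAMS.items():
        for element in reference.ELEMENTS:
            if element in per_elem:
                cells = per_elem[element]
            elif fill_periventricular and region in reference.PERIVENTRICULAR_REGIONS:
                cells = reference.ENTIRE_SECTION_PARAMS[element]
            else:
                continue
            for group in reference.GROUPS:
                mean, sd = cells[group]
                rows.append(
                    {"group": group, "region": region, "element": element,
                     "mean": mean, "sd": sd}
                )
    return GroupParams(pd.DataFrame(rows))


@dataclass
class TruthTable:
    """Per-animal ground-truth concentrations (simulator bookkeeping).

    Both hemispheres of an animal share the same true values; they differ
    downstream only through independent runs, standards, noise and drift.
    """

    table: pd.DataFrame  # animal, group, hemisphere, region, element, concentration
    seed: int

    def __post_init__(self) -> None:
        cols = {"animal", "group", "hemisphere", "region", "element", "concentration"}
        if not cols.issubset(self.table.columns):
            raise ParameterError(f"truth table needs columns {sorted(cols)}")
        if (self.table["concentration"] < 0).any():
            raise ParameterError("negative true concentration")

    def animals(self) -> list[str]:
        return sorted(self.table["animal"].unique())

    def group_of(self, animal: str) -> str:
        g = self.table.loc[self.table["animal"] == animal, "group"].unique()
        return str(g[0])

    def animal_slice(self, animal: str, hemisphere: str) -> dict[str, dict[str, float]]:
        """region -> element -> true concentration for one run."""
        sel = self.table[
            (self.table["animal"] == animal) & (self.table["hemisphere"] == hemisphere)
        ]
        out: dict[str, dict[str, float]] = {}
        for row in sel.itertuples():
            out.setdefault(row.region, {})[row.element] = float(row.concentration)
        return out

    def value(self, animal: str, region: str, element: str) -> float:
        sel = self.table[
            (self.table["animal"] == animal)
            & (self.table["region"] == region)
            & (self.table["element"] == element)
        ]
        return float(sel["concentration"].iloc[0])


def sample_cohort(
    params: GroupParams,
    phantom: Phantom,
    seed: int,
    elements: Sequence[str] | None = None,
) -> TruthTable:
    """Draw per-animal regional truths from the group mean ± SD.

    Draws are independent across animals, regions and elements, normal with
    the group's mean and SD and truncated at zero; both hemispheres of an
    animal share one draw.  Fully reproducible from ``seed``.
    """
    if elements is None:
        elements = params.elements()
    regions = phantom.regions()
    # fail fast on incomplete parameterization
    for group in reference.GROUPS:
        for region in regions:
            for element in elements:
                params.lookup(group, region, element)
    rng = np.random.default_rng(seed)
    animals = [("control", f"C{i + 1:02d}") for i in range(params.n_control)]
    animals += [("wd", f"W{i + 1:02d}") for i in range(params.n_wd)]
    rows = []
    for group, animal in animals:
        for region in regions:
            for element in elements:
                mean, sd = params.lookup(group, region, element)
                value = max(0.0, float(rng.normal(mean, sd)))
                for hemisphere in ("L", "R"):
                    rows.append(
                        {"animal": animal, "group": group, "hemisphere": hemisphere,
                         "region": region, "element": element, "concentration": value}
                    )
    return TruthTable(pd.DataFrame(rows), seed=seed)


# ---------------------------------------------------------------------------
# instrument model
# ---------------------------------------------------------------------------

@dataclass
class InstrumentModel:
    """Linear counts-vs-concentration response with noise and drift.

    ``sensitivity`` (counts per μg g⁻¹ per cycle) and ``background`` (counts)
    are per metal channel; the carbon channel instead emits
    ``carbon_tissue_level`` over tissue and ``carbon_glass_level`` over glass.
    ``drift_endpoint_factor`` is the multiplicative factor reached at the line
    farthest from the standard (1.0 = no drift).
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    carbon_channel: str = CARBON_CHANNEL
    sensitivity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    background: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    noise_model: str = "poisson"
    drift_endpoint_factor: float = 1.0
    spot_diameter: float = 60.0
    scan_speed: float = 70.0
    cycle_time: float = 0.341
    line_spacing: float = 90.0
    carbon_tissue_level: float = 50_000.0
    carbon_glass_level: float = 2_000.0

    def __post_init__(self) -> None:
        if self.carbon_channel not in self.channels:
            raise ParameterError("carbon channel must be among channels")
        if self.noise_model not in ("poisson", "none"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")
        if self.drift_endpoint_factor <= 0:
            raise ParameterError("drift endpoint factor must be positive")
        if self.spot_diameter < self.pixel_size_x:
            raise ParameterError("spot diameter must cover at least one x pixel")
        for ch in self.channels:
            if ch == self.carbon_channel:
                continue
            if self.sensitivity.get(ch, 0.0) <= 0:
                raise ParameterError(f"sensitivity for {ch} must be > 0")
            if self.background.get(ch, -1.0) < 0:
                raise ParameterError(f"background for {ch} must be ≥ 0")

    @property
    def pixel_size_x(self) -> float:
        return self.scan_speed * self.cycle_time

    @property
    def pixel_size_y(self) -> float:
        return self.line_spacing

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            scan_speed=self.scan_speed,
            cycle_time=self.cycle_time,
            spot_diameter=self.spot_diameter,
            line_spacing=self.line_spacing,
        )


def reduced_instrument(**overrides) -> InstrumentModel:
    """A lean instrument carrying only the carbon reference and the four
    primary metal isotopes; statistically equivalent for those channels."""
    channels = (CARBON_CHANNEL, "Mn55", "Fe57", "Cu63", "Zn64")
    return InstrumentModel(channels=channels, **overrides)


def drift_factors(n_lines: int, endpoint_factor: float) -> np.ndarray:
    """Per-line multiplicative drift, linear from 1.0 to the endpoint factor."""
    if n_lines < 1:
        raise ParameterError("need at least one line")
    if n_lines == 1:
        return np.ones(1)
    return 1.0 + (endpoint_factor - 1.0) * np.arange(n_lines) / (n_lines - 1)


def spot_average(profile: np.ndarray, spot_diameter: float, pixel_size_x: float) -> np.ndarray:
    """Exact moving average of a piecewise-constant row profile over the spot.

    ``profile`` is (n_rows, n_cols); each pixel holds the value on
    [c·p, (c+1)·p).  The returned pixel value is the mean of the profile over
    the window of width ``spot_diameter`` centered on the pixel center,
    clipped to the scanned domain (the average renormalizes to the covered
    width at the domain edges).
    """
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    n_rows, n_cols = profile.shape
    p = float(pixel_size_x)
    width = n_cols * p
    cum = np.zeros((n_rows, n_cols + 1))
    np.cumsum(profile * p, axis=1, out=cum[:, 1:])

    def integral_to(x: np.ndarray) -> np.ndarray:
        k = np.clip((x // p).astype(int), 0, n_cols - 1)
        frac = x - k * p
        return cum[:, k] + profile[:, k] * frac

    centers = (np.arange(n_cols) + 0.5) * p
    a = np.clip(centers - spot_diameter / 2.0, 0.0, width)
    b = np.clip(centers + spot_diameter / 2.0, 0.0, width)
    return (integral_to(b) - integral_to(a)) / (b - a)


def _element_maps(
    phantom: Phantom, truth: Mapping[str, Mapping[str, float]]
) -> dict[str, np.ndarray]:
    """Per-element concentration maps from region truths; missing region → error."""
    lm = phantom.label_map
    regions = phantom.regions()
    elements: set[str] = set()
    for region in regions:
        if region not in truth:
            raise ParameterError(f"no truth values for phantom region {region!r}")
        elements.update(truth[region])
    maps: dict[str, np.ndarray] = {}
    max_label = int(lm.max())
    for element in elements:
        lut = np.zeros(max_label + 1)
        for region in regions:
            conc = truth[region].get(element)
            if conc is None:
                raise ParameterError(f"region {region!r} lacks element {element!r}")
            lut[phantom.label_of(region)] = conc
        maps[element] = lut[lm]
    return maps


def simulate_scan(
    phantom: Phantom,
    truth: Mapping[str, Mapping[str, float]],
    instrument: InstrumentModel,
    seed: int,
    run_id: str = "run",
) -> ScanLineSet:
    """Forward-simulate one animal-hemisphere run over the phantom.

    One ablation line per label-map row (line pitch = line spacing); cycle
    ``c`` of line ``r`` samples the spot-averaged concentration at pixel
    (r, c), maps it through the linear response, adds Poisson noise if
    enabled and applies the line's drift factor.
    """
    lm = phantom.label_map
    if lm.size == 0:
        raise LamapError("empty phantom")
    if abs(phantom.pixel_size_x - instrument.pixel_size_x) > 1e-9 or abs(
        phantom.pixel_size_y - instrument.pixel_size_y
    ) > 1e-9:
        raise AlignmentError(
            "phantom pixel geometry does not match the instrument raster"
        )
    n_lines, n_cols = lm.shape
    rng = np.random.default_rng(seed)
    factors = drift_factors(n_lines, instrument.drift_endpoint_factor)
    conc_maps = _element_maps(phantom, truth)
    carbon_map = np.where(
        lm != GLASS_LABEL, instrument.carbon_tissue_level, instrument.carbon_glass_level
    ).astype(float)

    cube = np.empty((n_lines, n_cols, len(instrument.channels)))
    for ci, channel in enumerate(instrument.channels):
        if channel == instrument.carbon_channel:
            expected = spot_average(
                carbon_map, instrument.spot_diameter, instrument.pixel_size_x
            )
        else:
            element = channel_element(channel)
            conc = conc_maps.get(element)
            if conc is None:
                # carrier-free channel: background only
                expected = np.full(lm.shape, instrument.background[channel])
            else:
                smeared = spot_average(
                    conc, instrument.spot_diameter, instrument.pixel_size_x
                )
                expected = (
                    instrument.sensitivity[channel] * smeared
                    + instrument.background[channel]
                )
        if instrument.noise_model == "poisson":
            counts = rng.poisson(expected).astype(float)
        else:
            counts = np.asarray(expected, dtype=float)
        cube[:, :, ci] = counts * factors[:, None]

    return ScanLineSet(
        run_id=run_id,
        lines=[cube[r] for r in range(n_lines)],
        channels=list(instrument.channels),
        carbon_channel=instrument.carbon_channel,
        meta=instrument.meta(),
    )


# ---------------------------------------------------------------------------
# calibration standards
# ---------------------------------------------------------------------------

@dataclass
class StandardLevel:
    """One homogeneous standard block at known per-element concentrations."""

    concentrations: dict[str, float]  # element symbol -> μg g⁻¹ (absent = 0)
    n_lines: int = 2

    def concentration(self, element: str) -> float:
        return float(self.concentrations.get(element, 0.0))


@dataclass
class StandardSpec:
    """Matrix-matched standard series: a blank plus levels spanning the tissue range."""

    levels: list[StandardLevel]
    cycles_per_line: int = 60

    def __post_init__(self) -> None:
        if not self.levels:
            raise RankError("a standard series needs at least one level")
        for lvl in self.levels:
            if any(c < 0 for c in lvl.concentrations.values()):
                raise RankError("standard concentrations must be non-negative")

    def elements(self) -> list[str]:
        out: set[str] = set()
        for lvl in self.levels:
            out.update(lvl.concentrations)
        return sorted(out)

    def validate_for(self, elements: Iterable[str]) -> None:
        for element in elements:
            values = {lvl.concentration(element) for lvl in self.levels}
            if len(values) < 2:
                raise RankError(
                    f"standards give {len(values)} distinct level(s) for {element}; need ≥ 2"
                )


# Default levels span the tissue ranges: blank + a mid and a high level.
_STANDARD_MID = {
    "Fe": 10.0, "Cu": 10.0, "Zn": 15.0, "Mn": 0.3, "Na": 400.0, "P": 1000.0,
    "Mg": 50.0, "Al": 5.0, "S": 500.0, "K": 200.0, "Ca": 50.0, "Ti": 1.0,
    "V": 0.5, "Cr": 1.0, "Co": 0.5, "Ni": 1.0, "Ga": 0.5, "Se": 0.5,
    "Rb": 2.0, "Sr": 1.0, "Mo": 0.5, "Cd": 0.2, "Gd": 0.1, "Pb": 0.5,
}
_STANDARD_HIGH = {
    "Fe": 30.0, "Cu": 80.0, "Zn": 60.0, "Mn": 1.2, "Na": 1000.0, "P": 3000.0,
    "Mg": 200.0, "Al": 20.0, "S": 2000.0, "K": 800.0, "Ca": 200.0, "Ti": 5.0,
    "V": 2.0, "Cr": 4.0, "Co": 2.0, "Ni": 5.0, "Ga": 2.0, "Se": 2.0,
    "Rb": 8.0, "Sr": 4.0, "Mo": 2.0, "Cd": 1.0, "Gd": 0.5, "Pb": 2.0,
}


def default_standard_spec() -> StandardSpec:
    return StandardSpec(
        levels=[
            StandardLevel(concentrations={}),
            StandardLevel(concentrations=dict(_STANDARD_MID)),
            StandardLevel(concentrations=dict(_STANDARD_HIGH)),
        ]
    )


@dataclass
class StandardScan:
    """Simulated standard block tagged with its known concentrations."""

    concentrations: dict[str, float]  # element -> μg g⁻¹
    scan: ScanLineSet


def simulate_standards(
    spec: StandardSpec,
    instrument: InstrumentModel,
    seed: int,
    run_id: str = "std",
) -> list[StandardScan]:
    """Simulate one homogeneous block per standard level.

    Standards follow the same linear response and noise model; they are
    acquired as compact blocks adjacent to the drift anchor, so their drift
    factor is 1.
    """
    metal_elements = {
        channel_element(ch)
        for ch in instrument.channels
        if ch != instrument.carbon_channel
    }
    rng = np.random.default_rng(seed)
    out: list[StandardScan] = []
    for li, level in enumerate(spec.levels):
        shape = (level.n_lines, spec.cycles_per_line)
        cube = np.empty((*shape, len(instrument.channels)))
        for ci, channel in enumerate(instrument.channels):
            if channel == instrument.carbon_channel:
                expected = np.full(shape, instrument.carbon_tissue_level)
            else:
                element = channel_element(channel)
                expected = np.full(
                    shape,
                    instrument.sensitivity[channel] * level.concentration(element)
                    + instrument.background[channel],
                )
            if instrument.noise_model == "poisson":
                cube[:, :, ci] = rng.poisson(expected).astype(float)
            else:
                cube[:, :, ci] = expected
        scan = ScanLineSet(
            run_id=f"{run_id}-L{li}",
            lines=[cube[r] for r in range(shape[0])],
            channels=list(instrument.channels),
            carbon_channel=instrument.carbon_channel,
            meta=instrument.meta(),
        )
        out.append(StandardScan(concentrations={e: level.concentration(e) for e in metal_elements}, scan=scan))
    return out
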