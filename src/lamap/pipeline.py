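"""End-to-end orchestration: simulate → reconstruct → calibrate → quantify → stats.

Two entry points:

* :func:`analyze_cohort` — in-memory pipeline for simulation studies
  (parameter recovery, power checks); nothing touches disk.
* :func:`run_pipeline` — the CLI-facing staged run on a config mapping;
  every stage persists its artifacts in the run directory (scan-line tables,
  truth table, ROI label map, calibration curves, concentration images,
  measurement tables, the cohort report and a reproducibility manifest), so
  each stage can be re-run and inspected in isolation.

Determinism: one master seed; per-run seeds are derived from it with
:func:`lamap.phantom.derive_seed`, so rerunning a config reproduces every
numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    CalibrationCurve,
    calibrate_stack,
    fit_slope,
    standards_to_levels,
    write_curve,
)
from .errors import ConfigError, LamapError
from .phantom import (
    GroupParams,
    InstrumentModel,
    Phantom,
    PRIMARY_ISOTOPE,
    StandardScan,
    StandardSpec,
    TruthTable,
    default_group_params,
    default_phantom,
    default_standard_spec,
    derive_seed,
    reduced_instrument,
    sample_cohort,
    simulate_scan,
    simulate_standards,
)
from .quantify import assemble_cohort, combine_hemispheres, measure_regions
from .reconstruct import (
    DriftModel,
    ElementImageStack,
    apply_drift,
    carbon_normalize,
    estimate_drift,
    net_carbon_level,
    rasterize,
)
from .scan_io import (
    RoiMaskSet,
    ScanLineSet,
    load_config,
    read_scanlines,
    write_float_image,
    write_label_map,
    write_scanlines,
)
from .stats import ALPHA_DEFAULT, build_report, format_report

logger = logging.getLogger("lamap")

DRIFT_MODES = ("auto", "on", "off")
CORRECTIONS = ("bonferroni", "holm-standard", "holm-literal")
DEFAULT_REPORT_CHANNELS = tuple(PRIMARY_ISOTOPE[e] for e in ("Fe", "Cu", "Zn", "Mn"))


# ---------------------------------------------------------------------------
# simulation of a cohort of runs
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    """One animal-hemisphere acquisition with its own standard series."""

    animal: str
    group: str
    hemisphere: str
    run_id: str
    seed: int
    standard_seed: int
    scan: ScanLineSet
    standards: list[StandardScan]
    thickness: float = 1.0


def _thickness_instrument(instrument: InstrumentModel, thickness: float) -> InstrumentModel:
    """Scale ablated-mass-proportional terms by a per-section thickness factor."""
    if thickness == 1.0:
        return instrument
    return dataclasses.replace(
        instrument,
        sensitivity={k: v * thickness for k, v in instrument.sensitivity.items()},
        carbon_tissue_level=instrument.carbon_tissue_level * thickness,
    )


def simulate_cohort_runs(
    params: GroupParams,
    phantom: Phantom,
    instrument: InstrumentModel,
    standard_spec: StandardSpec,
    master_seed: int,
    groups: tuple[str, ...] | None = None,
    thickness_cv: float = 0.0,
) -> tuple[TruthTable, list[SimulatedRun]]:
    """Draw a cohort truth table and simulate every hemisphere run.

    Each hemisphere is an independent run with its own seed and its own
    standard series; both hemispheres of an animal share the true values.
    ``thickness_cv`` adds per-section slice-thickness variation (CV of a
    normal factor around 1), scaling metal sensitivity and the ¹³C level.
    """
    truth = sample_cohort(params, phantom, derive_seed(master_seed, 0))
    runs: list[SimulatedRun] = []
    for ai, animal in enumerate(truth.animals()):
        group = truth.group_of(animal)
        if groups is not None and group not in groups:
            continue
        for hi, hemisphere in enumerate(("L", "R")):
            seed = derive_seed(master_seed, 1, ai, hi)
            std_seed = derive_seed(master_seed, 2, ai, hi)
            thickness = 1.0
            if thickness_cv > 0:
                t_rng = np.random.default_rng(derive_seed(master_seed, 3, ai, hi))
                thickness = max(0.2, float(t_rng.normal(1.0, thickness_cv)))
            run_instrument = _thickness_instrument(instrument, thickness)
            run_id = f"{animal}-{hemisphere}"
            scan = simulate_scan(
                phantom, truth.animal_slice(animal, hemisphere),
                run_instrument, seed, run_id=run_id,
            )
            standards = simulate_standards(
                standard_spec, instrument, std_seed, run_id=f"std-{run_id}"
            )
            runs.append(
                SimulatedRun(
                    animal=animal, group=group, hemisphere=hemisphere,
                    run_id=run_id, seed=seed, standard_seed=std_seed,
                    scan=scan, standards=standards, thickness=thickness,
                )
            )
    return truth, runs


# ---------------------------------------------------------------------------
# per-run processing
# ---------------------------------------------------------------------------

def reconstruct_run(
    scan: ScanLineSet,
    tissue_mask: np.ndarray | None = None,
    drift_mode: str = "auto",
    normalize: bool = False,
    reference: str | None = None,
    drift_tolerance: float = 0.02,
) -> tuple[ElementImageStack, DriftModel | None, float | None]:
    """Rasterize one run, drift-correct per the chosen mode, optionally
    ¹³C-normalize.  Returns (stack, drift model or None, net ¹³C or None)."""
    if drift_mode not in DRIFT_MODES:
        raise ConfigError(f"unknown drift mode {drift_mode!r}")
    stack = rasterize(scan)
    model: DriftModel | None = None
    if drift_mode != "off":
        model = estimate_drift(
            stack, reference=reference, tissue_mask=tissue_mask,
            tolerance=drift_tolerance,
        )
        if drift_mode == "on" or model.necessary:
            stack = apply_drift(stack, model)
    net = None
    if normalize:
        net = net_carbon_level(stack)
        stack = carbon_normalize(stack)
    return stack, model, net


def fit_run_curves(
    standards: list[StandardScan],
    channels: list[str],
    curve_id: str = "",
    normalize_net: float | None = None,
) -> dict[str, CalibrationCurve]:
    """Per-channel calibration curves from a run's own standard series.

    With ``normalize_net`` the level counts are divided by the standard's
    net ¹³C (its block mean, a pure-tissue matrix), mirroring a normalized
    sample so the calibrated scale stays μg g⁻¹.
    """
    curves: dict[str, CalibrationCurve] = {}
    for channel in channels:
        levels = standards_to_levels(standards, channel)
        if normalize_net is not None:
            levels = levels.assign(
                mean_counts=levels["mean_counts"] / normalize_net,
                sd_counts=levels["sd_counts"] / normalize_net,
            )
        curves[channel] = fit_slope(levels, channel=channel, curve_id=curve_id)
    return curves


def standard_net_carbon(standards: list[StandardScan]) -> float:
    """Mean ¹³C intensity over all standard blocks (no glass inside a block)."""
    scan = standards[0].scan
    idx = scan.channel_index(scan.carbon_channel)
    values = np.concatenate(
        [line[:, idx] for std in standards for line in std.scan.lines]
    )
    return float(values.mean())


def process_run(
    run: SimulatedRun,
    mask: RoiMaskSet,
    channels: list[str] | None = None,
    drift_mode: str = "auto",
    normalize: bool = False,
    reference: str | None = None,
    drift_tolerance: float = 0.02,
) -> tuple[ElementImageStack, DriftModel | None, dict[str, CalibrationCurve]]:
    """Reconstruct and calibrate one simulated run against its own standard."""
    stack, model, _net = reconstruct_run(
        run.scan, tissue_mask=mask.tissue_mask, drift_mode=drift_mode,
        normalize=normalize, reference=reference, drift_tolerance=drift_tolerance,
    )
    if channels is None:
        channels = stack.metal_channels()
    std_net = standard_net_carbon(run.standards) if normalize else None
    curves = fit_run_curves(
        run.standards, channels, curve_id=f"std-{run.run_id}", normalize_net=std_net
    )
    calibrated = calibrate_stack(stack, curves, glass_mask=mask.glass_mask, channels=channels)
    return calibrated, model, curves


# ---------------------------------------------------------------------------
# in-memory cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    truth: TruthTable
    manifest: pd.DataFrame
    measurements: pd.DataFrame
    per_animal: pd.DataFrame
    report: pd.DataFrame


def analyze_cohort(
    master_seed: int,
    params: GroupParams | None = None,
    phantom: Phantom | None = None,
    instrument: InstrumentModel | None = None,
    standard_spec: StandardSpec | None = None,
    channels: list[str] | None = None,
    groups: tuple[str, ...] | None = None,
    drift_mode: str = "auto",
    normalize: bool = False,
    thickness_cv: float = 0.0,
    alpha: float = ALPHA_DEFAULT,
    holm_mode: str = "standard",
    family_size: int | None = None,
    build_stats: bool = True,
) -> CohortResult:
    """Simulate a cohort and run the full pipeline on it, in memory.

    Defaults reproduce the study conditions: the reference group parameters
    (8 control vs 9 WD animals), the 28-channel instrument with Poisson noise,
    a blank + two-level standard series per run, and readout of the four
    primary metal isotopes over all regions plus the entire section.
    """
    params = params or default_group_params()
    phantom = phantom or default_phantom()
    instrument = instrument or InstrumentModel()
    standard_spec = standard_spec or default_standard_spec()
    if channels is None:
        channels = [c for c in DEFAULT_REPORT_CHANNELS if c in instrument.channels]
    mask = phantom.roi_mask()
    truth, runs = simulate_cohort_runs(
        params, phantom, instrument, standard_spec, master_seed,
        groups=groups, thickness_cv=thickness_cv,
    )
    frames = []
    manifest_rows = []
    for run in runs:
        calibrated, model, _curves = process_run(
            run, mask, channels=channels, drift_mode=drift_mode, normalize=normalize
        )
        frames.append(
            measure_regions(
                calibrated, mask, channels=channels,
                animal=run.animal, group=run.group, hemisphere=run.hemisphere,
            )
        )
        manifest_rows.append(
            {
                "animal": run.animal, "group": run.group,
                "hemisphere": run.hemisphere, "run_id": run.run_id,
                "seed": run.seed, "standard_seed": run.standard_seed,
                "thickness": run.thickness,
                "drift_endpoint": model.endpoint_factor if model else float("nan"),
            }
        )
    measurements = pd.concat(frames, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    per_animal = combine_hemispheres(measurements)
    report = pd.DataFrame()
    if build_stats and manifest["group"].nunique() >= 2:
        cohort = assemble_cohort(per_animal, manifest)
        report = build_report(
            cohort, alpha=alpha, holm_mode=holm_mode, family_size=family_size
        )
    return CohortResult(
        truth=truth, manifest=manifest, measurements=measurements,
        per_animal=per_animal, report=report,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def validate_config(config: dict) -> dict:
    """Merge a config mapping with defaults; reject invalid values before work."""
    cfg = {
        "seed": 1,
        "phantom": "default",
        "instrument": {},
        "standards": "default",
        "cohort": {},
        "processing": {},
    }
    for key, value in (config or {}).items():
        if key not in cfg and key != "output_dir":
            raise ConfigError(f"unknown config key {key!r}")
        cfg[key] = value
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    inst = {"channels": "full", "noise_model": "poisson", "drift_endpoint_factor": 1.0}
    inst.update(cfg["instrument"] or {})
    if inst["channels"] not in ("full", "reduced"):
        raise ConfigError("instrument.channels must be 'full' or 'reduced'")
    if inst["noise_model"] not in ("poisson", "none"):
        raise ConfigError("instrument.noise_model must be 'poisson' or 'none'")
    cohort = {"n_control": 8, "n_wd": 9, "groups": None, "thickness_cv": 0.0}
    cohort.update(cfg["cohort"] or {})
    proc = {
        "drift": "auto",
        "normalize": False,
        "reference": None,
        "correction": "holm-standard",
        "alpha": ALPHA_DEFAULT,
        "family": None,
        "channels": list(DEFAULT_REPORT_CHANNELS),
    }
    proc.update(cfg["processing"] or {})
    if proc["drift"] not in DRIFT_MODES:
        raise ConfigError(f"processing.drift must be one of {DRIFT_MODES}")
    if proc["correction"] not in CORRECTIONS:
        raise ConfigError(f"processing.correction must be one of {CORRECTIONS}")
    if not 0 < float(proc["alpha"]) < 1:
        raise ConfigError("processing.alpha must lie in (0, 1)")
    cfg["instrument"] = inst
    cfg["cohort"] = cohort
    cfg["processing"] = proc
    return cfg


def _build_objects(cfg: dict) -> tuple[GroupParams, Phantom, InstrumentModel, StandardSpec]:
    params = default_group_params()
    params.n_control = int(cfg["cohort"]["n_control"])
    params.n_wd = int(cfg["cohort"]["n_wd"])
    phantom = default_phantom()
    inst_cfg = dict(cfg["instrument"])
    kind = inst_cfg.pop("channels")
    if kind == "reduced":
        instrument = reduced_instrument(**inst_cfg)
    else:
        instrument = InstrumentModel(**inst_cfg)
    return params, phantom, instrument, default_standard_spec()


# ---------------------------------------------------------------------------
# staged, on-disk pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run every stage on a config, persisting all artifacts.

    Returns the run directory.  A stage failure aborts with the failing stage
    named; artifacts of completed stages are preserved.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    outdir = Path(output_dir or cfg.get("output_dir") or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        stage_simulate(cfg, outdir)
        stage = "reconstruct+calibrate+quantify"
        _stage_process(cfg, outdir)
        stage = "stats"
        stage_stats(
            outdir,
            correction=cfg["processing"]["correction"],
            alpha=float(cfg["processing"]["alpha"]),
            family=cfg["processing"]["family"],
        )
    except LamapError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "lamap_version": __version__,
        "config": _jsonable(cfg),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def stage_simulate(cfg: dict, outdir: Path) -> None:
    """Simulate the cohort: scan-line files, standards, truth, labels, manifest."""
    params, phantom, instrument, spec = _build_objects(cfg)
    truth, runs = simulate_cohort_runs(
        params, phantom, instrument, spec, int(cfg["seed"]),
        groups=tuple(cfg["cohort"]["groups"]) if cfg["cohort"]["groups"] else None,
        thickness_cv=float(cfg["cohort"]["thickness_cv"]),
    )
    scans_dir = outdir / "scans"
    scans_dir.mkdir(parents=True, exist_ok=True)
    std_rows = []
    manifest_rows = []
    for run in runs:
        scan_path = scans_dir / f"{run.run_id}.csv"
        write_scanlines(run.scan, scan_path)
        for li, std in enumerate(run.standards):
            std_path = scans_dir / f"{run.run_id}-std{li}.csv"
            write_scanlines(std.scan, std_path)
            std_rows.append(
                {"run_id": run.run_id, "level": li, "path": std_path.name}
                | {f"conc_{e}": c for e, c in sorted(std.concentrations.items())}
            )
        manifest_rows.append(
            {
                "animal": run.animal, "group": run.group,
                "hemisphere": run.hemisphere, "run_id": run.run_id,
                "scan": scan_path.name, "seed": run.seed,
                "standard_seed": run.standard_seed, "thickness": run.thickness,
            }
        )
    truth.table.to_csv(outdir / "truth.csv", index=False)
    write_label_map(phantom.roi_mask(), outdir / "roi_labels.tif")
    pd.DataFrame(manifest_rows).to_csv(outdir / "cohort_manifest.csv", index=False)
    pd.DataFrame(std_rows).to_csv(outdir / "standards_manifest.csv", index=False)


def _load_run_standards(outdir: Path, run_id: str) -> list[StandardScan]:
    table = pd.read_csv(outdir / "standards_manifest.csv")
    block = table[table["run_id"] == run_id].sort_values("level")
    out = []
    for row in block.itertuples():
        scan = read_scanlines(outdir / "scans" / row.path)
        conc = {
            c.removeprefix("conc_"): float(getattr(row, c))
            for c in table.columns if c.startswith("conc_")
        }
        out.append(StandardScan(concentrations=conc, scan=scan))
    return out


def _stage_process(cfg: dict, outdir: Path) -> None:
    """Reconstruct, calibrate and quantify every run from the on-disk artifacts."""
    from .scan_io import read_roi_labels

    proc = cfg["processing"]
    manifest = pd.read_csv(outdir / "cohort_manifest.csv")
    mask = read_roi_labels(outdir / "roi_labels.tif")
    channels = list(proc["channels"])
    images_dir = outdir / "images"
    curves_dir = outdir / "curves"
    images_dir.mkdir(exist_ok=True)
    curves_dir.mkdir(exist_ok=True)
    frames = []
    for row in manifest.itertuples():
        scan = read_scanlines(outdir / "scans" / row.scan)
        standards = _load_run_standards(outdir, row.run_id)
        stack, model, _net = reconstruct_run(
            scan, tissue_mask=mask.tissue_mask,
            drift_mode=proc["drift"], normalize=bool(proc["normalize"]),
            reference=proc["reference"],
        )
        std_net = standard_net_carbon(standards) if proc["normalize"] else None
        curves = fit_run_curves(
            standards, channels, curve_id=f"std-{row.run_id}", normalize_net=std_net
        )
        calibrated = calibrate_stack(stack, curves, glass_mask=mask.glass_mask, channels=channels)
        for ch in channels:
            write_curve(curves[ch], curves_dir / f"{row.run_id}_{ch}.txt")
            write_float_image(
                calibrated.get(ch), images_dir / f"{row.run_id}_{ch}.tif",
                channel=ch, units=calibrated.units[ch],
                pixel_size_x=calibrated.pixel_size_x,
                pixel_size_y=calibrated.pixel_size_y,
            )
        frames.append(
            measure_regions(
                calibrated, mask, channels=channels,
                animal=row.animal, group=row.group, hemisphere=row.hemisphere,
            )
        )
    measurements = pd.concat(frames, ignore_index=True)
    measurements.to_csv(outdir / "measurements.csv", index=False)
    combine_hemispheres(measurements).to_csv(outdir / "per_animal.csv", index=False)


def stage_stats(
    outdir: Path,
    correction: str = "holm-standard",
    alpha: float = ALPHA_DEFAULT,
    family: int | None = None,
) -> pd.DataFrame:
    """Group statistics on the per-animal table; writes report.csv/report.txt."""
    if correction not in CORRECTIONS:
        raise ConfigError(f"unknown correction {correction!r}")
    per_animal = pd.read_csv(outdir / "per_animal.csv")
    manifest = pd.read_csv(outdir / "cohort_manifest.csv")
    cohort = assemble_cohort(per_animal, manifest)
    holm_mode = "literal" if correction == "holm-literal" else "standard"
    report = build_report(
        cohort, alpha=alpha, holm_mode=holm_mode, family_size=family
    )
    report.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.txt").write_text(format_report(report) + "\n")
    return report
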