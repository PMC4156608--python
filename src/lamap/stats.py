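"""Group comparison statistics for regional element concentrations.

Heteroscedastic (Welch) two-sample t-tests with Welch–Satterthwaite degrees
of freedom, two-sided p-values; percent change and fold factors vs the
control group; the classical Bonferroni threshold α/(regions × elements); and
two step-down variants of the Holm procedure:

* ``standard`` — the usual Holm step-down: the i-th smallest p is compared
  to α/(m − i + 1), stopping at the first failure;
* ``literal`` — thresholds α/1, α/2, α/3, ... down the sorted list, i.e. the
  published description of the procedure taken at face value (it starts at α
  rather than α/m).  Which mode produced a flag is always recorded.

Percent changes round half-away-from-zero to integer percent and fold
factors to one decimal for reporting; unrounded values are what the report
stores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CompletenessError, DomainError, SampleSizeError

ALPHA_DEFAULT = 0.05

HOLM_MODES = ("standard", "literal")


@dataclass
class TestResult:
    """One region × element group comparison."""

    t: float
    df: float
    p: float
    region: str = ""
    element: str = ""
    percent_change: float = float("nan")
    fold_factor: float = float("nan")
    significant_bonferroni: bool | None = None
    significant_holm: bool | None = None


def _welch_core(
    mean_a: float, var_a: float, n_a: int, mean_b: float, var_b: float, n_b: int
) -> tuple[float, float, float]:
    """Welch t, Welch–Satterthwaite df and two-sided p from summary moments."""
    if n_a < 2 or n_b < 2:
        raise SampleSizeError("each group needs at least 2 values")
    sa, sb = var_a / n_a, var_b / n_b
    se2 = sa + sb
    if se2 == 0.0:
        # zero variance in both groups
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        return math.inf, float(n_a + n_b - 2), float(np.nextafter(0.0, 1.0))
    t = (mean_a - mean_b) / math.sqrt(se2)
    df = se2**2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), max(p, float(np.nextafter(0.0, 1.0)))


def welch_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Heteroscedastic two-sample t-test on raw value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("non-finite values in test input")
    t, df, p = _welch_core(
        float(a.mean()), float(a.var(ddof=1)), a.size,
        float(b.mean()), float(b.var(ddof=1)), b.size,
    )
    return TestResult(t=t, df=df, p=p)


def welch_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TestResult:
    """The same test from printed mean/SD/n summaries."""
    if sd_a < 0 or sd_b < 0:
        raise DomainError("SDs must be non-negative")
    t, df, p = _welch_core(mean_a, sd_a**2, n_a, mean_b, sd_b**2, n_b)
    return TestResult(t=t, df=df, p=p)


def percent_change(control_mean: float, wd_mean: float) -> float:
    """100 × (WD − control)/control; unrounded (report rounds to integer %)."""
    if control_mean <= 0:
        raise DomainError("percent change needs a positive control mean")
    return 100.0 * (wd_mean - control_mean) / control_mean


def round_percent(value: float) -> int:
    """Round half away from zero to integer percent (table convention)."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def fold_factor(control_mean: float, wd_mean: float, direction: str = "auto") -> float:
    """Decrease factor control/WD or increase factor WD/control (unrounded)."""
    if control_mean <= 0 or wd_mean <= 0:
        raise DomainError("fold factor needs positive means")
    if direction == "auto":
        direction = "decrease" if wd_mean < control_mean else "increase"
    if direction == "decrease":
        return control_mean / wd_mean
    if direction == "increase":
        return wd_mean / control_mean
    raise DomainError(f"unknown direction {direction!r}")


def round_fold(value: float) -> float:
    """One-decimal, half away from zero (table convention for fold factors)."""
    return math.floor(abs(value) * 10.0 + 0.5) / 10.0 * (1 if value >= 0 else -1)


def bonferroni_threshold(
    n_regions: int, n_elements: int = 1, alpha: float = ALPHA_DEFAULT
) -> float:
    """α divided by the size of the region × element family (unrounded)."""
    if n_regions < 1 or n_elements < 1:
        raise DomainError("family counts must be ≥ 1")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    return alpha / (n_regions * n_elements)


def round_one_significant(value: float) -> float:
    """Round to one significant figure, the convention for reported thresholds."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    scaled = value / 10**exponent
    return round(scaled) * 10.0**exponent


@dataclass
class HolmResult:
    flags: np.ndarray  # bool, in input order
    mode: str
    alpha: float


def holm_adjust(
    pvalues: np.ndarray, alpha: float = ALPHA_DEFAULT, mode: str = "standard"
) -> HolmResult:
    """Step-down multiple-testing flags in the order of the input p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value set")
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    if mode not in HOLM_MODES:
        raise DomainError(f"unknown Holm mode {mode!r}; choose from {HOLM_MODES}")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0 = smallest p
        if mode == "standard":
            threshold = alpha / (m - rank)
        else:
            threshold = alpha / (rank + 1)
        if p[idx] <= threshold:
            flags[idx] = True
        else:
            break  # step-down: everything larger also fails
    return HolmResult(flags=flags, mode=mode, alpha=alpha)


def bonferroni_flags(pvalues: np.ndarray, alpha: float, m: int | None = None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    return p <= alpha / m


def build_report(
    cohort: dict[tuple[str, str], dict[str, np.ndarray]],
    alpha: float = ALPHA_DEFAULT,
    holm_mode: str = "standard",
    family_size: int | None = None,
    control_group: str = "control",
    wd_group: str = "wd",
) -> pd.DataFrame:
    """Cohort table: one row per (region, channel) with means ± SD, % change,
    Welch p and multiple-testing flags.

    ``family_size`` defaults to the number of rows (region × channel tests
    actually performed); pass an explicit family to mirror a fixed design.
    """
    rows = []
    for (region, channel), vectors in sorted(cohort.items()):
        a = np.asarray(vectors.get(control_group, ()), dtype=float)
        b = np.asarray(vectors.get(wd_group, ()), dtype=float)
        if a.size == 0 or b.size == 0:
            raise CompletenessError(
                f"({region}, {channel}): empty {control_group if a.size == 0 else wd_group} group"
            )
        res = welch_test(a, b)
        ctrl_mean = float(a.mean())
        wd_mean = float(b.mean())
        rows.append(
            {
                "region": region,
                "channel": channel,
                "control_mean": ctrl_mean,
                "control_sd": float(a.std(ddof=1)),
                "wd_mean": wd_mean,
                "wd_sd": float(b.std(ddof=1)),
                "n_control": int(a.size),
                "n_wd": int(b.size),
                "percent_change": percent_change(ctrl_mean, wd_mean)
                if ctrl_mean > 0 else np.nan,
                "fold_factor": fold_factor(ctrl_mean, wd_mean)
                if ctrl_mean > 0 and wd_mean > 0 else np.nan,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(table)
    table["significant_bonferroni"] = bonferroni_flags(table["p"].to_numpy(), alpha, m)
    holm = holm_adjust(table["p"].to_numpy(), alpha=alpha, mode=holm_mode)
    table["significant_holm"] = holm.flags
    table.attrs["alpha"] = alpha
    table.attrs["holm_mode"] = holm.mode
    table.attrs["family_size"] = m
    table.attrs["bonferroni_threshold"] = alpha / m
    return table


def _fmt_value(x: float) -> str:
    """Table precision: 2 decimals below 1 (Mn-level), 1 decimal below 20, else integer."""
    if x < 1.0:
        return f"{x:.2f}"
    if x < 20.0:
        return f"{x:.1f}"
    return f"{x:.0f}"


def _fmt_p(p: float) -> str:
    if p < 1e-5:
        return f"{p:.1e}"
    return f"{p:.4g}"


def format_report(table: pd.DataFrame, show_change_alpha: float = 0.05) -> str:
    """Human-readable cohort table mirroring the published layout.

    Percent change is shown only for rows below ``show_change_alpha``
    (blank cells mean "not significant", the convention adopted here).
    """
    lines = [
        f"{'region':<24}{'channel':<8}{'control':>14}{'WD':>14}"
        f"{'% change':>10}{'p':>10}{'Bonf':>6}{'Holm':>6}"
    ]
    for row in table.itertuples():
        ctrl = f"{_fmt_value(row.control_mean)} ± {_fmt_value(row.control_sd)}"
        wd = f"{_fmt_value(row.wd_mean)} ± {_fmt_value(row.wd_sd)}"
        change = (
            f"{round_percent(row.percent_change):+d}%"
            if np.isfinite(row.percent_change) and row.p <= show_change_alpha
            else ""
        )
        lines.append(
            f"{row.region:<24}{row.channel:<8}{ctrl:>14}{wd:>14}"
            f"{change:>10}{_fmt_p(row.p):>10}"
            f"{'*' if row.significant_bonferroni else '':>6}"
            f"{'*' if row.significant_holm else '':>6}"
        )
    return "\n".join(lines)
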