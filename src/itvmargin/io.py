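"""Cohort CSV schema, run configuration and the analysis pipeline.

The cohort lives in a tidy CSV with one row per (patient, fraction, axis):

    patient_id, fraction, axis, applied_shift_mm, clipbox_correction_mm, amplitude_mm

All lengths are millimetres. The pipeline ties the stages together:
simulate (or read) a cohort, difference each fraction against fraction 1,
decompose the population errors, and evaluate the margin recipes. Outputs
are deterministic for a fixed (config, seed) pair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .axes import AXES, AXIS_INDEX
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
    UndefinedStatisticError,
)
from .margins import MarginTable, margin_table
from .metrics import (
    BASELINE_SIGNS,
    FractionRecord,
    delta_table,
    exceedance_frequency,
)
from .stats import (
    PopulationError,
    baseline_amplitude_correlation,
    combine_components,
    normality_check,
    paired_direction_test,
    pooled_summary,
    population_error,
)
from .synthetic import CohortConfig, simulate_cohort

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "analyze_records",
    "run_pipeline",
]

logger = logging.getLogger("itvmargin")

COHORT_COLUMNS = [
    "patient_id",
    "fraction",
    "axis",
    "applied_shift_mm",
    "clipbox_correction_mm",
    "amplitude_mm",
]

_NUMERIC_COLUMNS = ["applied_shift_mm", "clipbox_correction_mm", "amplitude_mm"]


def write_cohort(records: Sequence[FractionRecord], path) -> None:
    """Write fraction records to the tidy cohort CSV."""
    rows = []
    for rec in records:
        for j, axis in enumerate(AXES):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "fraction": rec.fraction,
                    "axis": axis,
                    "applied_shift_mm": rec.applied_shift_mm[j],
                    "clipbox_correction_mm": rec.clipbox_correction_mm[j],
                    "amplitude_mm": rec.amplitude_mm[j],
                }
            )
    # %.17g + float_precision="round_trip" on read makes the CSV lossless
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> list[FractionRecord]:
    """Read and validate a cohort CSV into fraction records.

    The result is independent of row order. Schema violations (missing
    column, non-numeric cell, duplicate or incomplete (patient, fraction)
    axis triples) raise :class:`SchemaError` naming the offending row;
    row numbers count the header as line 1.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}; expected {COHORT_COLUMNS}")
    for col in _NUMERIC_COLUMNS + ["fraction"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise SchemaError(f"non-numeric value in column '{col}' at row {bad[0] + 2}")
        df[col] = coerced
    if not np.all(np.isfinite(df[_NUMERIC_COLUMNS].to_numpy())):
        raise SchemaError("non-finite numeric value in cohort table")
    bad_axis = df.index[~df["axis"].isin(AXES)]
    if len(bad_axis):
        raise SchemaError(f"unknown axis '{df.loc[bad_axis[0], 'axis']}' at row {bad_axis[0] + 2}")
    dup = df.duplicated(subset=["patient_id", "fraction", "axis"])
    if dup.any():
        row = df.index[dup][0]
        key = tuple(df.loc[row, ["patient_id", "fraction", "axis"]])
        raise SchemaError(f"duplicate (patient, fraction, axis) {key} at row {row + 2}")

    records = []
    for (pid, frac), grp in df.groupby(["patient_id", "fraction"], sort=True):
        if set(grp["axis"]) != set(AXES):
            raise SchemaError(f"patient {pid} fraction {int(frac)}: expected axes {AXES}, got {sorted(grp['axis'])}")
        grp = grp.set_index("axis")
        vec = lambda col: np.array([grp.loc[a, col] for a in AXES])
        records.append(
            FractionRecord(
                patient_id=str(pid),
                fraction=int(frac),
                applied_shift_mm=vec("applied_shift_mm"),
                clipbox_correction_mm=vec("clipbox_correction_mm"),
                amplitude_mm=vec("amplitude_mm"),
            )
        )
    records.sort(key=lambda r: (r.patient_id, r.fraction))
    return records


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``simulate`` (generate a cohort and analyze it), ``analyze``
    (read ``cohort_path``) or ``full`` (simulate, write the cohort, analyze).
    """

    mode: str = "full"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None
    out_dir: str = "itvmargin_out"
    baseline_sign: str = "first_minus_later"
    exceedance_thresholds_mm: tuple[float, ...] = (2.0, 5.0)
    margin_component: str = "combined"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise InvalidParameterError(f"mode must be simulate|analyze|full; got {self.mode}")
        if self.baseline_sign not in BASELINE_SIGNS:
            raise InvalidParameterError(f"baseline_sign must be one of {BASELINE_SIGNS}")
        if self.margin_component not in ("combined", "baseline", "amplitude"):
            raise InvalidParameterError("margin_component must be combined|baseline|amplitude")
        thr = tuple(float(t) for t in self.exceedance_thresholds_mm)
        if any(t <= 0 for t in thr) or list(thr) != sorted(thr):
            raise InvalidParameterError("exceedance thresholds must be positive and sorted")
        object.__setattr__(self, "exceedance_thresholds_mm", thr)
        if self.mode == "analyze" and not self.cohort_path:
            raise InvalidParameterError("analyze mode requires cohort_path")

    @classmethod
    def from_json(cls, path, seed: int | None = None) -> "RunConfig":
        """Load a run configuration from a JSON file; ``seed`` overrides the cohort seed."""
        with open(path) as fh:
            data = json.load(fh)
        cohort_kwargs = data.pop("cohort", {})
        if seed is not None:
            cohort_kwargs["seed"] = int(seed)
        cfg = cls(cohort=CohortConfig(**cohort_kwargs), **data)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d["cohort"].items()}
        return d


def _series_dict(values) -> dict:
    return {axis: float(values[j]) for j, axis in enumerate(AXES)}


def _test_dict(res) -> dict:
    d = {"statistic": res.statistic, "pvalue": res.pvalue, "n": res.n, "label": res.label}
    if res.normal is not None or "normality" in res.label:
        d["normal"] = res.normal
    return d


def analyze_records(
    records: Sequence[FractionRecord],
    *,
    baseline_sign: str = "first_minus_later",
    exceedance_thresholds_mm: Sequence[float] = (2.0, 5.0),
    margin_component: str = "combined",
) -> tuple[pd.DataFrame, dict, MarginTable]:
    """Run the full analysis on fraction records.

    Returns the tidy delta table, a JSON-ready summary dictionary holding
    every reported number, and the margin table object.
    """
    deltas = delta_table(records, baseline_sign=baseline_sign)
    n_patients = deltas["patient_id"].nunique()

    components: dict[str, dict] = {}
    errors: dict[str, PopulationError] = {}
    for component in ("baseline", "amplitude"):
        err = population_error(deltas, component)
        errors[component] = err
        pooled = pooled_summary(deltas, component)
        exceed = []
        for thr in exceedance_thresholds_mm:
            exceed.append(exceedance_frequency(deltas, thr, component).to_dict(orient="records"))
        normality = {axis: _test_dict(normality_check(deltas, component, axis)) for axis in AXES}
        direction_tests = {}
        for axis_a, axis_b in (("SI", "LR"), ("SI", "AP")):
            try:
                direction_tests[f"{axis_a}_vs_{axis_b}"] = _test_dict(
                    paired_direction_test(deltas, component, axis_a, axis_b)
                )
            except InsufficientDataError:
                direction_tests[f"{axis_a}_vs_{axis_b}"] = None
        components[component] = {
            "systematic_mm": _series_dict(err.systematic_mm),
            "random_mm": _series_dict(err.random_mm),
            "pooled": {
                row["axis"]: {k: row[k] for k in ("n", "mean_mm", "sd_mm", "min_mm", "max_mm")}
                for row in pooled.to_dict(orient="records")
            },
            "exceedance": [item for sub in exceed for item in sub],
            "normality": normality,
            "direction_tests": direction_tests,
        }

    correlations = {}
    for axis in AXES:
        try:
            correlations[axis] = _test_dict(baseline_amplitude_correlation(deltas, axis))
        except (UndefinedStatisticError, InsufficientDataError):
            correlations[axis] = None

    combined = combine_components(errors["baseline"], errors["amplitude"])
    margin_input = {"combined": combined, "baseline": errors["baseline"], "amplitude": errors["amplitude"]}[
        margin_component
    ]
    table = margin_table(margin_input)

    summary = {
        "n_patients": int(n_patients),
        "n_records": len(records),
        "n_delta_rows": int(len(deltas) // 3),
        "baseline_sign": baseline_sign,
        "components": components,
        "combined": {
            "systematic_mm": _series_dict(combined.systematic_mm),
            "random_mm": _series_dict(combined.random_mm),
        },
        "correlation_baseline_amplitude": correlations,
        "margin_component": margin_component,
        "margins": {
            row.recipe: {
                "formula": row.formula,
                "assumption": row.assumption,
                "raw_mm": _series_dict(row.raw_mm),
                "display_mm": _series_dict(row.display_mm),
                "floored": {axis: bool(row.floored[j]) for j, axis in enumerate(AXES)},
            }
            for row in table.rows
        },
    }
    return deltas, summary, table


def _format_report(summary: dict) -> str:
    """Render the summary as a human-readable text report."""
    lines = []
    lines.append("Inter-fraction tumor motion analysis")
    lines.append("=" * 60)
    lines.append(
        f"patients: {summary['n_patients']}   fraction records: {summary['n_records']}   "
        f"delta rows: {summary['n_delta_rows']}"
    )
    for component in ("baseline", "amplitude"):
        comp = summary["components"][component]
        lines.append("")
        lines.append(f"{component} deltas (mm, vs fraction 1)")
        lines.append("-" * 60)
        lines.append(f"{'axis':<5}{'mean±SD':>16}{'range':>20}{'Σ':>8}{'σ':>8}")
        for axis in AXES:
            p = comp["pooled"][axis]
            lines.append(
                f"{axis:<5}{p['mean_mm']:>8.1f} ± {p['sd_mm']:<5.1f}"
                f"{p['min_mm']:>9.1f} to {p['max_mm']:<7.1f}"
                f"{comp['systematic_mm'][axis]:>8.1f}{comp['random_mm'][axis]:>8.1f}"
            )
        for row in comp["exceedance"]:
            lines.append(
                f"  |delta| >= {row['threshold_mm']:.0f} mm on {row['axis']}: "
                f"{row['n_exceed']}/{row['n_total']} = {100 * row['proportion']:.2f}%"
            )
    lines.append("")
    lines.append("baseline-amplitude correlation")
    for axis, res in summary["correlation_baseline_amplitude"].items():
        if res is None:
            lines.append(f"  {axis}: not evaluable")
        else:
            lines.append(f"  {axis}: r = {res['statistic']:.3f} (p = {res['pvalue']:.3f}, n = {res['n']})")
    lines.append("")
    lines.append(f"ITV margins (mm) from the {summary['margin_component']} component")
    lines.append("-" * 60)
    lines.append(f"{'recipe':<13}{'LR':>6}{'SI':>6}{'AP':>6}  formula")
    for name, row in summary["margins"].items():
        d = row["display_mm"]
        flag = " (floored)" if any(row["floored"].values()) else ""
        lines.append(f"{name:<13}{d['LR']:>6.1f}{d['SI']:>6.1f}{d['AP']:>6.1f}  {row['formula']}{flag}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline and write all outputs to ``cfg.out_dir``.

    Outputs: ``cohort.csv`` (when simulated), ``deltas.csv``, ``margins.csv``,
    ``report.txt`` and ``summary.json``. The summary records the seed and a
    hash of the configuration; identical (config, seed) runs produce
    byte-identical files. All results are computed before anything is
    written, so a failing stage leaves no partial output.
    """
    stage = "configuration"
    try:
        cfg_dict = cfg.to_dict()
        cfg_dict.pop("out_dir")  # analysis content must not depend on where it is written
        cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
        logger.info("run config hash %s (seed %s)", cfg_hash, cfg.cohort.seed)

        stage = "cohort"
        if cfg.mode == "analyze":
            records = read_cohort(cfg.cohort_path)
            simulated = False
        else:
            records = simulate_cohort(cfg.cohort)
            simulated = True
        logger.info("%s cohort: %d fraction records", "simulated" if simulated else "loaded", len(records))

        stage = "analysis"
        deltas, summary, table = analyze_records(
            records,
            baseline_sign=cfg.baseline_sign,
            exceedance_thresholds_mm=cfg.exceedance_thresholds_mm,
            margin_component=cfg.margin_component,
        )
        summary["seed"] = int(cfg.cohort.seed) if simulated else None
        summary["config_hash"] = cfg_hash
        summary["config"] = cfg_dict

        stage = "output"
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if simulated:
            write_cohort(records, out / "cohort.csv")
        deltas.to_csv(out / "deltas.csv", index=False)
        table.to_frame().to_csv(out / "margins.csv", index=False)
        (out / "report.txt").write_text(_format_report(summary))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        logger.info("wrote outputs to %s", out)
        return summary
    except Exception as exc:
        logger.error("pipeline failed in stage '%s': %s", stage, exc)
        if hasattr(exc, "add_note"):
            exc.add_note(f"pipeline stage: {stage}")
        raise
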