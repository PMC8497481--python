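"""Population error decomposition and hypothesis tests.

Following the standard radiotherapy error taxonomy, the population
systematic error Sigma on an axis is the standard deviation, across
patients, of each patient's mean inter-fraction delta, and the population
random error sigma is the root mean square of the per-patient delta SDs.
Sample statistics use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .axes import AXES, as_vec3
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from .metrics import _component_column

__all__ = [
    "PopulationError",
    "TestResult",
    "patient_summaries",
    "systematic_error",
    "random_error",
    "population_error",
    "combine_components",
    "pooled_summary",
    "paired_direction_test",
    "baseline_amplitude_correlation",
    "normality_check",
]


@dataclass(frozen=True)
class PopulationError:
    """Per-axis systematic (Sigma) and random (sigma) error of one component, mm."""

    component: str
    systematic_mm: np.ndarray
    random_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "systematic_mm", as_vec3(self.systematic_mm, "systematic_mm", nonnegative=True))
        object.__setattr__(self, "random_mm", as_vec3(self.random_mm, "random_mm", nonnegative=True))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``normal`` is populated only by the normality check: True/False for the
    decision at alpha = 0.05, None when the test is not evaluable
    (e.g. constant input).
    """

    statistic: float
    pvalue: float
    label: str
    n: int
    normal: bool | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0 <= self.pvalue <= 1:
            raise InvalidParameterError(f"p-value out of [0, 1]: {self.pvalue}")


def patient_summaries(deltas: pd.DataFrame, component: str = "baseline", ddof: int = 1) -> pd.DataFrame:
    """Per-patient, per-axis mean and SD of the inter-fraction deltas.

    ``ddof=1`` (sample SD) is the default; a patient with a single delta row
    then has no defined SD and raises, unless ``ddof=0`` is requested.
    """
    col = _component_column(component)
    if deltas.empty:
        raise InsufficientDataError("no delta rows")
    rows = []
    for (pid, axis), grp in deltas.groupby(["patient_id", "axis"], sort=True):
        vals = grp[col].to_numpy()
        if vals.size <= ddof:
            raise InsufficientDataError(
                f"patient {pid}: {vals.size} delta row(s) cannot support SD with ddof={ddof}"
            )
        rows.append(
            {
                "patient_id": pid,
                "axis": axis,
                "component": component,
                "n": int(vals.size),
                "mean_mm": float(vals.mean()),
                "sd_mm": float(vals.std(ddof=ddof)),
            }
        )
    return pd.DataFrame(rows)


def systematic_error(summaries: pd.DataFrame) -> pd.Series:
    """Sigma per axis: SD across patients of the per-patient mean deltas."""
    out = {}
    for axis in AXES:
        means = summaries.loc[summaries["axis"] == axis, "mean_mm"].to_numpy()
        if means.size < 2:
            raise InsufficientDataError(f"axis {axis}: need >= 2 patients for Sigma; got {means.size}")
        out[axis] = float(means.std(ddof=1))
    return pd.Series(out, name="systematic_mm")


def random_error(summaries: pd.DataFrame) -> pd.Series:
    """sigma per axis: root mean square across patients of the per-patient SDs."""
    out = {}
    for axis in AXES:
        sds = summaries.loc[summaries["axis"] == axis, "sd_mm"].to_numpy()
        if sds.size < 1:
            raise InsufficientDataError(f"axis {axis}: no patients")
        out[axis] = float(np.sqrt(np.mean(sds**2)))
    return pd.Series(out, name="random_mm")


def population_error(deltas: pd.DataFrame, component: str = "baseline", ddof: int = 1) -> PopulationError:
    """Sigma/sigma decomposition of one component from the tidy delta table."""
    summ = patient_summaries(deltas, component, ddof=ddof)
    sig = systematic_error(summ)
    rnd = random_error(summ)
    return PopulationError(
        component=component,
        systematic_mm=sig[list(AXES)].to_numpy(),
        random_mm=rnd[list(AXES)].to_numpy(),
    )


def combine_components(base: PopulationError, amp: PopulationError) -> PopulationError:
    """Combine two independent error components in quadrature, per axis."""
    return PopulationError(
        component="combined",
        systematic_mm=np.sqrt(base.systematic_mm**2 + amp.systematic_mm**2),
        random_mm=np.sqrt(base.random_mm**2 + amp.random_mm**2),
    )


def pooled_summary(deltas: pd.DataFrame, component: str = "baseline") -> pd.DataFrame:
    """Pooled mean, SD, range and count of the deltas per axis (all rows)."""
    col = _component_column(component)
    if deltas.empty:
        raise InsufficientDataError("no delta rows")
    rows = []
    for axis in AXES:
        vals = deltas.loc[deltas["axis"] == axis, col].to_numpy()
        if vals.size < 2:
            raise InsufficientDataError(f"axis {axis}: need >= 2 delta rows for a pooled SD")
        rows.append(
            {
                "axis": axis,
                "component": component,
                "n": int(vals.size),
                "mean_mm": float(vals.mean()),
                "sd_mm": float(vals.std(ddof=1)),
                "min_mm": float(vals.min()),
                "max_mm": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def _axis_values(deltas: pd.DataFrame, component: str, axis: str) -> pd.DataFrame:
    col = _component_column(component)
    if axis not in AXES:
        raise InvalidParameterError(f"axis must be one of {AXES}; got {axis}")
    sub = deltas.loc[deltas["axis"] == axis, ["patient_id", "fraction", col]]
    return sub.rename(columns={col: "value"})


def paired_direction_test(
    deltas: pd.DataFrame,
    component: str = "baseline",
    axis_a: str = "SI",
    axis_b: str = "AP",
    absolute: bool = True,
) -> TestResult:
    """Paired t-test comparing delta magnitudes between two axes.

    Rows are paired by (patient, fraction). By default the test operates on
    absolute deltas, the scale on which "larger motion in one direction" is
    meaningful; ``absolute=False`` tests the signed deltas.
    """
    a = _axis_values(deltas, component, axis_a).set_index(["patient_id", "fraction"])["value"]
    b = _axis_values(deltas, component, axis_b).set_index(["patient_id", "fraction"])["value"]
    paired = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(paired) < 2:
        raise InsufficientDataError(f"need >= 2 paired rows; got {len(paired)}")
    x = paired["a"].to_numpy()
    y = paired["b"].to_numpy()
    if absolute:
        x, y = np.abs(x), np.abs(y)
    label = f"{component} |delta| {axis_a} vs {axis_b}" if absolute else f"{component} delta {axis_a} vs {axis_b}"
    diffs = x - y
    if np.all(diffs == 0):
        return TestResult(statistic=0.0, pvalue=1.0, label=label, n=len(paired))
    t, p = sps.ttest_rel(x, y)
    return TestResult(statistic=float(t), pvalue=float(p), label=label, n=len(paired))


def baseline_amplitude_correlation(deltas: pd.DataFrame, axis: str = "SI") -> TestResult:
    """Pearson correlation between baseline and amplitude deltas on one axis."""
    if axis not in AXES:
        raise InvalidParameterError(f"axis must be one of {AXES}; got {axis}")
    sub = deltas.loc[deltas["axis"] == axis, ["baseline_delta_mm", "amplitude_delta_mm"]].dropna()
    if len(sub) < 3:
        raise InsufficientDataError(f"need >= 3 paired rows; got {len(sub)}")
    x = sub["baseline_delta_mm"].to_numpy()
    y = sub["amplitude_delta_mm"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError(f"axis {axis}: zero variance makes Pearson r undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), pvalue=float(p), label=f"baseline vs amplitude delta, {axis}", n=len(sub))


def normality_check(deltas: pd.DataFrame, component: str = "baseline", axis: str = "SI", alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality test of the pooled deltas on one axis.

    Constant input is reported as not evaluable (``normal=None``) rather
    than raising, so a degenerate cohort still produces a full report.
    """
    vals = _axis_values(deltas, component, axis)["value"].to_numpy()
    if vals.size < 3:
        raise InsufficientDataError(f"need >= 3 rows for Shapiro-Wilk; got {vals.size}")
    label = f"{component} delta normality, {axis}"
    if np.ptp(vals) == 0:
        return TestResult(statistic=float("nan"), pvalue=float("nan"), label=label, n=int(vals.size), normal=None)
    w, p = sps.shapiro(vals)
    return TestResult(statistic=float(w), pvalue=float(p), label=label, n=int(vals.size), normal=bool(p >= alpha))
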