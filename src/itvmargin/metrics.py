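"""Per-fraction motion records and inter-fraction delta computation.

The baseline shift of a fraction is the applied table shift minus the
bony-anatomy (clipbox) setup correction: the residual displacement of the
tumor relative to bone. Inter-fraction deltas are referenced to fraction 1;
the baseline delta follows the reference-minus-fraction convention by
default (a flag flips it), the amplitude delta is fraction-minus-reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .axes import AXES, as_vec3
from .exceptions import (
    InvalidParameterError,
    MissingReferenceError,
    UndefinedStatisticError,
)

__all__ = [
    "FractionRecord",
    "InterFractionDelta",
    "baseline_shift",
    "interfraction_deltas",
    "interfraction_baseline_deltas",
    "interfraction_amplitude_deltas",
    "delta_table",
    "exceedance_frequency",
]

BASELINE_SIGNS = ("first_minus_later", "later_minus_first")


@dataclass(frozen=True)
class FractionRecord:
    """Measured vectors of one treatment fraction (mm, LR/SI/AP order)."""

    patient_id: str
    fraction: int
    applied_shift_mm: np.ndarray
    clipbox_correction_mm: np.ndarray
    amplitude_mm: np.ndarray

    def __post_init__(self) -> None:
        if int(self.fraction) != self.fraction or self.fraction < 1:
            raise InvalidParameterError(f"fraction must be an integer >= 1; got {self.fraction}")
        object.__setattr__(self, "fraction", int(self.fraction))
        object.__setattr__(self, "applied_shift_mm", as_vec3(self.applied_shift_mm, "applied_shift_mm"))
        object.__setattr__(self, "clipbox_correction_mm", as_vec3(self.clipbox_correction_mm, "clipbox_correction_mm"))
        object.__setattr__(self, "amplitude_mm", as_vec3(self.amplitude_mm, "amplitude_mm", nonnegative=True))


@dataclass(frozen=True)
class InterFractionDelta:
    """Baseline and amplitude deltas of one fraction relative to fraction 1."""

    patient_id: str
    fraction: int
    baseline_delta_mm: np.ndarray
    amplitude_delta_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.fraction < 2:
            raise InvalidParameterError("delta rows exist only for fractions >= 2")
        object.__setattr__(self, "baseline_delta_mm", as_vec3(self.baseline_delta_mm, "baseline_delta_mm"))
        object.__setattr__(self, "amplitude_delta_mm", as_vec3(self.amplitude_delta_mm, "amplitude_delta_mm"))


def baseline_shift(rec: FractionRecord) -> np.ndarray:
    """Applied table shift minus clipbox setup correction, per axis (mm)."""
    return rec.applied_shift_mm - rec.clipbox_correction_mm


def _group_by_patient(records: Iterable[FractionRecord]) -> dict[str, list[FractionRecord]]:
    groups: dict[str, list[FractionRecord]] = {}
    for rec in records:
        groups.setdefault(rec.patient_id, []).append(rec)
    for pid, recs in groups.items():
        recs.sort(key=lambda r: r.fraction)
        fracs = [r.fraction for r in recs]
        if fracs[0] != 1:
            raise MissingReferenceError(f"patient {pid}: fraction 1 (reference) is missing")
        if fracs != list(range(1, len(fracs) + 1)):
            raise InvalidParameterError(f"patient {pid}: fractions must be consecutive from 1; got {fracs}")
    return groups


def interfraction_deltas(
    records: Iterable[FractionRecord],
    *,
    baseline_sign: str = "first_minus_later",
) -> list[InterFractionDelta]:
    """Compute per-patient deltas of every fraction >= 2 against fraction 1.

    ``baseline_sign`` selects the baseline convention: ``"first_minus_later"``
    (default) reports ``shift_1 - shift_k``, ``"later_minus_first"`` the
    negative. The amplitude delta is always ``amplitude_k - amplitude_1``.
    """
    if baseline_sign not in BASELINE_SIGNS:
        raise InvalidParameterError(f"baseline_sign must be one of {BASELINE_SIGNS}")
    sgn = 1.0 if baseline_sign == "first_minus_later" else -1.0
    out: list[InterFractionDelta] = []
    for pid, recs in _group_by_patient(records).items():
        ref_shift = baseline_shift(recs[0])
        ref_amp = recs[0].amplitude_mm
        for rec in recs[1:]:
            out.append(
                InterFractionDelta(
                    patient_id=pid,
                    fraction=rec.fraction,
                    baseline_delta_mm=sgn * (ref_shift - baseline_shift(rec)),
                    amplitude_delta_mm=rec.amplitude_mm - ref_amp,
                )
            )
    return out


def interfraction_baseline_deltas(records, *, baseline_sign="first_minus_later") -> pd.DataFrame:
    """Baseline deltas as a wide table (one row per patient/fraction, axis columns)."""
    rows = interfraction_deltas(records, baseline_sign=baseline_sign)
    return pd.DataFrame(
        [{"patient_id": d.patient_id, "fraction": d.fraction,
          **dict(zip(AXES, d.baseline_delta_mm))} for d in rows]
    )


def interfraction_amplitude_deltas(records) -> pd.DataFrame:
    """Amplitude deltas as a wide table (one row per patient/fraction, axis columns)."""
    rows = interfraction_deltas(records)
    return pd.DataFrame(
        [{"patient_id": d.patient_id, "fraction": d.fraction,
          **dict(zip(AXES, d.amplitude_delta_mm))} for d in rows]
    )


def delta_table(
    records: Iterable[FractionRecord],
    *,
    baseline_sign: str = "first_minus_later",
) -> pd.DataFrame:
    """Tidy delta table: patient_id, fraction, axis, baseline_delta_mm, amplitude_delta_mm."""
    rows = interfraction_deltas(records, baseline_sign=baseline_sign)
    data = []
    for d in rows:
        for j, axis in enumerate(AXES):
            data.append(
                {
                    "patient_id": d.patient_id,
                    "fraction": d.fraction,
                    "axis": axis,
                    "baseline_delta_mm": d.baseline_delta_mm[j],
                    "amplitude_delta_mm": d.amplitude_delta_mm[j],
                }
            )
    return pd.DataFrame(data, columns=["patient_id", "fraction", "axis", "baseline_delta_mm", "amplitude_delta_mm"])


def exceedance_frequency(
    deltas: pd.DataFrame,
    threshold: float,
    component: str = "baseline",
) -> pd.DataFrame:
    """Fraction of delta rows with ``|delta| >= threshold`` per axis.

    The denominator is the number of delta rows pooled over the cohort
    (fractions >= 2 only) and is reported explicitly in the output.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    col = _component_column(component)
    if deltas.empty:
        raise UndefinedStatisticError("no delta rows: exceedance proportion undefined")
    out = []
    for axis in AXES:
        vals = deltas.loc[deltas["axis"] == axis, col].to_numpy()
        if vals.size == 0:
            raise UndefinedStatisticError(f"no delta rows on axis {axis}")
        n_exceed = int(np.sum(np.abs(vals) >= threshold))
        out.append(
            {
                "axis": axis,
                "component": component,
                "threshold_mm": float(threshold),
                "n_exceed": n_exceed,
                "n_total": int(vals.size),
                "proportion": n_exceed / vals.size,
            }
        )
    return pd.DataFrame(out)


def _component_column(component: str) -> str:
    if component not in ("baseline", "amplitude"):
        raise InvalidParameterError("component must be 'baseline' or 'amplitude'")
    return f"{component}_delta_mm"
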