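"""ITV margin recipes mapping population errors (Sigma, sigma) to margins.

Four closed-form recipes from the treatment-margin literature are provided.
Writing S for the systematic error Sigma and r for the random error sigma
(both mm):

    stroom        2 S + 0.7 r
    vanherk       2.5 S + 0.7 r
    parker        S + sqrt(r^2 + S^2)
    vanherk_tcp   sqrt(2.7^2 S^2 + 1.6^2 r^2) - 2.8 mm   (floored at 0)

Each carries the statistical coverage assumption under which it was derived.
Margins are computed from the combined baseline (+) amplitude component by
default; displayed values are rounded half-up to 0.1 mm while raw values
are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .axes import AXES
from .exceptions import InvalidParameterError
from .stats import PopulationError

__all__ = [
    "MarginRow",
    "MarginTable",
    "RECIPES",
    "margin_stroom",
    "margin_vanherk",
    "margin_parker",
    "margin_vanherk_tcp",
    "margin_table",
    "round_half_up",
]


def _check(sigma_sys, sigma_rand):
    s = np.asarray(sigma_sys, dtype=float)
    r = np.asarray(sigma_rand, dtype=float)
    if np.any(s < 0) or np.any(r < 0):
        raise InvalidParameterError("Sigma and sigma must be >= 0")
    return s, r


def _ret(value, scalar):
    return float(value) if scalar else value


def margin_stroom(sigma_sys, sigma_rand):
    """Stroom recipe: 2 Sigma + 0.7 sigma (mm)."""
    scalar = np.ndim(sigma_sys) == 0 and np.ndim(sigma_rand) == 0
    s, r = _check(sigma_sys, sigma_rand)
    return _ret(2.0 * s + 0.7 * r, scalar)


def margin_vanherk(sigma_sys, sigma_rand):
    """van Herk recipe: 2.5 Sigma + 0.7 sigma (mm)."""
    scalar = np.ndim(sigma_sys) == 0 and np.ndim(sigma_rand) == 0
    s, r = _check(sigma_sys, sigma_rand)
    return _ret(2.5 * s + 0.7 * r, scalar)


def margin_parker(sigma_sys, sigma_rand):
    """Parker recipe: Sigma + sqrt(sigma^2 + Sigma^2) (mm)."""
    scalar = np.ndim(sigma_sys) == 0 and np.ndim(sigma_rand) == 0
    s, r = _check(sigma_sys, sigma_rand)
    return _ret(s + np.hypot(r, s), scalar)


def margin_vanherk_tcp(sigma_sys, sigma_rand, floor: bool = True):
    """van Herk TCP-loss recipe: sqrt(2.7^2 Sigma^2 + 1.6^2 sigma^2) - 2.8 mm.

    The subtraction can turn negative for small errors; with ``floor=True``
    (default) the result is clamped at 0. ``floor=False`` returns the raw
    value.
    """
    scalar = np.ndim(sigma_sys) == 0 and np.ndim(sigma_rand) == 0
    s, r = _check(sigma_sys, sigma_rand)
    raw = np.hypot(2.7 * s, 1.6 * r) - 2.8
    return _ret(np.maximum(raw, 0.0) if floor else raw, scalar)


# name -> (callable(S, r) -> raw margin, formula string, coverage assumption)
RECIPES = {
    "stroom": (
        lambda s, r: margin_stroom(s, r),
        "2Σ + 0.7σ",
        "95% absorbed dose to on average 99% of the CTV",
    ),
    "vanherk": (
        lambda s, r: margin_vanherk(s, r),
        "2.5Σ + 0.7σ",
        "minimum CTV dose 95% for 90% of patients",
    ),
    "parker": (
        lambda s, r: margin_parker(s, r),
        "Σ + sqrt(σ² + Σ²)",
        "95% minimum dose and 100% dose to 95% of the volume",
    ),
    "vanherk_tcp": (
        lambda s, r: margin_vanherk_tcp(s, r, floor=False),
        "sqrt(2.7²Σ² + 1.6²σ²) − 2.8 mm",
        "at most 1% TCP loss from geometric error (Monte Carlo)",
    ),
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero upward (2.45 -> 2.5), as printed margin tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MarginRow:
    """One recipe's margins: raw and display (0.1 mm) values per axis."""

    recipe: str
    formula: str
    assumption: str
    raw_mm: np.ndarray  # (3,) possibly negative for vanherk_tcp
    display_mm: np.ndarray  # (3,) floored then rounded to 0.1 mm
    floored: np.ndarray  # (3,) bool: True where the raw value was negative


@dataclass(frozen=True)
class MarginTable:
    """All recipes by all axes, computed from one PopulationError."""

    component: str
    rows: tuple[MarginRow, ...]

    def __getitem__(self, recipe: str) -> MarginRow:
        for row in self.rows:
            if row.recipe == recipe:
                return row
        raise KeyError(recipe)

    def to_frame(self) -> pd.DataFrame:
        data = []
        for row in self.rows:
            entry = {"recipe": row.recipe, "formula": row.formula, "assumption": row.assumption}
            for j, axis in enumerate(AXES):
                entry[f"{axis}_mm"] = row.display_mm[j]
                entry[f"{axis}_raw_mm"] = row.raw_mm[j]
            data.append(entry)
        return pd.DataFrame(data)


def margin_table(errors: PopulationError) -> MarginTable:
    """Evaluate all four recipes on the per-axis (Sigma, sigma) of ``errors``."""
    rows = []
    for name, (fn, formula, assumption) in RECIPES.items():
        raw = np.asarray(fn(errors.systematic_mm, errors.random_mm), dtype=float)
        floored = raw < 0
        display = np.array([round_half_up(v) for v in np.maximum(raw, 0.0)])
        rows.append(
            MarginRow(
                recipe=name,
                formula=formula,
                assumption=assumption,
                raw_mm=raw,
                display_mm=display,
                floored=floored,
            )
        )
    return MarginTable(component=errors.component, rows=tuple(rows))
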