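"""Patient coordinate axes.

Every vector quantity in the package is a length-3 array ordered
left-right (LR), superior-inferior (SI), anterior-posterior (AP).
Positive values point toward patient left, superior and anterior.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .exceptions import InvalidParameterError


class MotionAxis(str, Enum):
    """Patient axis labels, in the canonical vector order."""

    LR = "LR"
    SI = "SI"
    AP = "AP"


AXES: tuple[str, str, str] = tuple(a.value for a in MotionAxis)  # type: ignore[assignment]
AXIS_INDEX: dict[str, int] = {a: i for i, a in enumerate(AXES)}


def as_vec3(value, name: str = "value", nonnegative: bool = False) -> np.ndarray:
    """Coerce ``value`` to a finite float array of shape (3,) in LR/SI/AP order.

    Scalars are broadcast to all three axes.
    """
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise InvalidParameterError(f"{name} must be a 3-vector (LR, SI, AP); got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must be finite; got {arr}")
    if nonnegative and np.any(arr < 0):
        raise InvalidParameterError(f"{name} must be non-negative per axis; got {arr}")
    return arr
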