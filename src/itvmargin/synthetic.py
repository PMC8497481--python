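"""Synthetic respiratory-motion cohorts and 4DCBCT acquisition emulation.

This module provides two layers of simulation:

1. A trajectory layer: an even-power-cosine breathing trace
   ``z(t) = z0 - b * cos^(2n)(pi * t / tau + phi)`` sampled by a slow-rotation
   cone-beam acquisition and sorted retrospectively into respiratory phase
   bins, from which a peak-to-peak amplitude and an ITV extent are measured.
   The even power reproduces the long end-exhale dwell of quiet breathing.

2. A cohort layer: per-patient systematic offsets plus per-fraction random
   deviations of the inter-fraction baseline-shift and amplitude deltas,
   drawn per axis with an optional baseline-amplitude correlation, and
   packed into :class:`~itvmargin.metrics.FractionRecord` objects so that
   the metrics module recovers exactly the deltas that were drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .axes import AXES, AXIS_INDEX, as_vec3
from .exceptions import InsufficientCyclesError, InvalidParameterError
from .metrics import FractionRecord

__all__ = [
    "BreathingTraceParams",
    "AcquisitionConfig",
    "CohortConfig",
    "PhasePositions",
    "AcquisitionSamples",
    "breathing_trace",
    "simulate_acquisition",
    "phase_bin",
    "peak_to_peak",
    "itv_extent",
    "simulate_cohort",
]


@dataclass(frozen=True)
class BreathingTraceParams:
    """Parameters of the even-power-cosine breathing trace.

    Parameters
    ----------
    period_s
        Mean breathing period tau in seconds (> 0).
    amplitude_mm
        Peak-to-peak excursion ``b`` per axis in mm (the trace spans
        ``[z0 - b, z0]`` on each axis).
    exponent
        Half-power ``n`` (>= 1); the trace uses ``cos^(2n)``. Larger values
        lengthen the end-exhale dwell.
    phase_rad
        Phase offset ``phi`` in radians.
    baseline_mm
        End-exhale baseline position ``z0`` per axis in mm.
    period_jitter
        Fractional standard deviation of the cycle-to-cycle period
        (0 disables jitter).
    seed
        Seed for the per-cycle period draws; the trace is deterministic
        given the parameters.
    """

    period_s: float = 4.0
    amplitude_mm: np.ndarray = (2.0, 10.0, 5.0)
    exponent: int = 2
    phase_rad: float = 0.0
    baseline_mm: np.ndarray = (0.0, 0.0, 0.0)
    period_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise InvalidParameterError(f"period_s must be > 0; got {self.period_s}")
        if int(self.exponent) != self.exponent or self.exponent < 1:
            raise InvalidParameterError(f"exponent must be an integer >= 1; got {self.exponent}")
        if self.period_jitter < 0:
            raise InvalidParameterError("period_jitter must be >= 0")
        object.__setattr__(self, "amplitude_mm", as_vec3(self.amplitude_mm, "amplitude_mm", nonnegative=True))
        object.__setattr__(self, "baseline_mm", as_vec3(self.baseline_mm, "baseline_mm"))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Slow-rotation cone-beam acquisition geometry.

    Defaults emulate a 200 degree arc at 3 deg/s with 975 projections,
    sorted into 10 respiratory phase bins.
    """

    arc_deg: float = 200.0
    gantry_speed_deg_s: float = 3.0
    n_projections: int = 975
    n_phase_bins: int = 10

    def __post_init__(self) -> None:
        if not self.arc_deg > 0:
            raise InvalidParameterError("arc_deg must be > 0")
        if not self.gantry_speed_deg_s > 0:
            raise InvalidParameterError("gantry_speed_deg_s must be > 0")
        if self.n_projections < 2:
            raise InvalidParameterError("n_projections must be >= 2")
        if self.n_phase_bins < 2:
            raise InvalidParameterError("n_phase_bins must be >= 2")

    @property
    def duration_s(self) -> float:
        """Scan duration: arc length divided by gantry speed."""
        return self.arc_deg / self.gantry_speed_deg_s


@dataclass(frozen=True)
class AcquisitionSamples:
    """Timestamped tumor positions seen by the projections."""

    t: np.ndarray  # (N,) seconds
    positions: np.ndarray  # (N, 3) mm, LR/SI/AP


@dataclass(frozen=True)
class PhasePositions:
    """Mean tumor position per respiratory phase bin, shape (n_bins, 3) mm."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidParameterError("positions must have shape (n_bins, 3)")
        if not np.all(np.isfinite(pos)):
            raise InvalidParameterError("phase-bin positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_bins(self) -> int:
        return self.positions.shape[0]


def _cycle_coordinate(params: BreathingTraceParams, t: np.ndarray) -> np.ndarray:
    """Map times to a continuous cycle index (1.0 per breathing cycle)."""
    if params.period_jitter == 0:
        return t / params.period_s
    rng = np.random.default_rng(params.seed)
    t_max = float(t.max(initial=0.0))
    # jittered periods, truncated at 3 SD so they stay positive
    n_cycles = max(4, math.ceil(t_max / (params.period_s * (1 - 3 * min(params.period_jitter, 0.3)))) + 2)
    xi = np.clip(rng.standard_normal(n_cycles), -3.0, 3.0)
    periods = params.period_s * (1.0 + params.period_jitter * xi)
    periods = np.maximum(periods, 0.1 * params.period_s)
    while periods.sum() <= t_max:
        xi = np.clip(rng.standard_normal(n_cycles), -3.0, 3.0)
        periods = np.concatenate([periods, np.maximum(params.period_s * (1.0 + params.period_jitter * xi), 0.1 * params.period_s)])
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(periods) - 1)
    return idx + (t - edges[idx]) / periods[idx]


def breathing_trace(params: BreathingTraceParams, t) -> np.ndarray:
    """Evaluate the breathing trace at time(s) ``t`` (seconds, >= 0).

    Returns positions in mm: shape (3,) for scalar ``t``, else (len(t), 3).
    """
    scalar = np.ndim(t) == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0) or not np.all(np.isfinite(tt)):
        raise InvalidParameterError("t must be finite and >= 0")
    u = _cycle_coordinate(params, tt)
    # cos^(2n) has period pi in its argument, i.e. one breathing cycle per unit u
    shape = np.cos(np.pi * u + params.phase_rad) ** (2 * int(params.exponent))
    pos = params.baseline_mm[None, :] - params.amplitude_mm[None, :] * shape[:, None]
    return pos[0] if scalar else pos


def simulate_acquisition(params: BreathingTraceParams, acq: AcquisitionConfig | None = None) -> AcquisitionSamples:
    """Sample the trace at uniform projection timestamps over the scan arc."""
    acq = acq or AcquisitionConfig()
    t = np.linspace(0.0, acq.duration_s, acq.n_projections)
    return AcquisitionSamples(t=t, positions=breathing_trace(params, t))


def phase_bin(samples: AcquisitionSamples, acq: AcquisitionConfig | None = None) -> PhasePositions:
    """Retrospectively sort projection samples into respiratory phase bins.

    The SI component of the trajectory serves as the respiratory surrogate
    (standing in for diaphragm tracking). Phase 0 is the end-exhale peak;
    between successive peaks the phase advances linearly; samples before the
    first or after the last detected peak are phased by extrapolating the
    adjacent cycle. Bins are half-open ``[i/n, (i+1)/n)`` and the per-bin
    position is the mean of its member samples on each axis.
    """
    acq = acq or AcquisitionConfig()
    si = samples.positions[:, AXIS_INDEX["SI"]]
    span = float(si.max() - si.min())
    if span <= 0:
        raise InsufficientCyclesError("constant SI surrogate: no breathing peaks detectable")
    peaks, _ = find_peaks(si, prominence=0.25 * span)
    if len(peaks) < 2:
        raise InsufficientCyclesError(f"need >= 2 surrogate peaks to assign phases; found {len(peaks)}")
    tp = samples.t[peaks]
    k = np.arange(len(tp), dtype=float)
    cont = np.interp(samples.t, tp, k)
    before = samples.t < tp[0]
    after = samples.t > tp[-1]
    cont[before] = (samples.t[before] - tp[0]) / (tp[1] - tp[0])
    cont[after] = k[-1] + (samples.t[after] - tp[-1]) / (tp[-1] - tp[-2])
    phase = np.mod(cont, 1.0)
    nb = acq.n_phase_bins
    bins = np.minimum((phase * nb).astype(int), nb - 1)
    counts = np.bincount(bins, minlength=nb)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise InsufficientCyclesError(f"phase bins {empty} received no samples; trace covers too few cycles")
    positions = np.empty((nb, 3))
    for i in range(nb):
        positions[i] = samples.positions[bins == i].mean(axis=0)
    return PhasePositions(positions)


def peak_to_peak(phases: PhasePositions) -> np.ndarray:
    """Per-axis peak-to-peak range (max minus min) over the phase-bin positions, mm."""
    return phases.positions.max(axis=0) - phases.positions.min(axis=0)


def itv_extent(gtv_interval, phases: PhasePositions) -> np.ndarray:
    """Bounding interval of the union of the GTV translated to each phase position.

    Parameters
    ----------
    gtv_interval
        Array-like of shape (3, 2): per-axis ``[lo, hi]`` of the GTV in mm.
    phases
        Phase-bin positions used as translation offsets.

    Returns
    -------
    (3, 2) array: per-axis ITV interval. Its length equals the GTV length
    plus the peak-to-peak motion on that axis.
    """
    gtv = np.asarray(gtv_interval, dtype=float)
    if gtv.shape != (3, 2):
        raise InvalidParameterError(f"gtv_interval must have shape (3, 2); got {gtv.shape}")
    if np.any(gtv[:, 0] > gtv[:, 1]):
        raise InvalidParameterError("gtv_interval must satisfy lo <= hi per axis")
    lo = gtv[:, 0] + phases.positions.min(axis=0)
    hi = gtv[:, 1] + phases.positions.max(axis=0)
    return np.column_stack([lo, hi])


# ---------------------------------------------------------------------------
# cohort layer
# ---------------------------------------------------------------------------

def _vec3_field(values):
    return field(default_factory=lambda: np.array(values, dtype=float))


@dataclass(frozen=True)
class CohortConfig:
    """Generative model of an inter-fraction motion cohort.

    Per axis and per component (baseline shift, amplitude), the inter-fraction
    delta of patient ``p`` at fraction ``k >= 2`` is

        d_pk = m_p + e_pk,   m_p ~ N(mu, Sigma^2),   e_pk ~ N(0, sigma^2)

    where ``Sigma`` is the population systematic SD and ``sigma`` the random
    SD. On each axis the baseline and amplitude draws may be correlated:
    ``rho`` is the target correlation of the pooled (systematic + random)
    delta pairs, and is distributed over both hierarchy levels so the pooled
    sample correlation converges to it.

    Defaults encode a 19-patient, 5-fraction lower-lobe lung SABR cohort:
    pooled delta means and the published systematic/random decomposition per
    axis, with SI and AP baseline-amplitude correlations.
    """

    n_patients: int = 19
    n_fractions: int = 5
    baseline_mean: np.ndarray = _vec3_field((-0.0, 0.9, 0.1))
    baseline_systematic: np.ndarray = _vec3_field((0.6, 0.5, 1.0))
    baseline_random: np.ndarray = _vec3_field((0.7, 0.6, 0.4))
    amplitude_mean: np.ndarray = _vec3_field((-0.2, 0.4, -0.4))
    amplitude_systematic: np.ndarray = _vec3_field((0.9, 1.2, 1.6))
    amplitude_random: np.ndarray = _vec3_field((0.9, 1.2, 0.8))
    rho: np.ndarray = _vec3_field((0.0, 0.353, -0.227))
    reference_amplitude_mean: np.ndarray = _vec3_field((2.0, 10.0, 5.0))
    reference_amplitude_sd: np.ndarray = _vec3_field((1.0, 3.0, 2.0))
    reference_baseline_sd: float = 1.0
    setup_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidParameterError("n_patients must be >= 1")
        if self.n_fractions < 2:
            raise InvalidParameterError("n_fractions must be >= 2")
        for name in (
            "baseline_mean", "baseline_systematic", "baseline_random",
            "amplitude_mean", "amplitude_systematic", "amplitude_random",
            "rho", "reference_amplitude_mean", "reference_amplitude_sd",
        ):
            nonneg = name not in ("baseline_mean", "amplitude_mean", "rho")
            object.__setattr__(self, name, as_vec3(getattr(self, name), name, nonnegative=nonneg))
        if np.any(np.abs(self.rho) > 1):
            raise InvalidParameterError("|rho| must be <= 1 per axis")
        if self.reference_baseline_sd < 0 or self.setup_sd < 0:
            raise InvalidParameterError("reference_baseline_sd and setup_sd must be >= 0")

    @classmethod
    def from_pooled(
        cls,
        baseline_mean=(-0.0, 0.9, 0.1),
        baseline_sd=(1.3, 2.3, 1.5),
        amplitude_mean=(-0.2, 0.4, -0.4),
        amplitude_sd=(1.4, 2.9, 2.0),
        systematic_fraction: float = 0.5,
        **kwargs,
    ) -> "CohortConfig":
        """Build a config from pooled delta means and SDs per axis.

        The pooled variance ``SD^2`` is split into systematic and random
        parts as ``Sigma^2 = f * SD^2`` and ``sigma^2 = (1 - f) * SD^2``
        with ``f = systematic_fraction``.
        """
        if not 0 <= systematic_fraction <= 1:
            raise InvalidParameterError("systematic_fraction must be in [0, 1]")
        b_sd = as_vec3(baseline_sd, "baseline_sd", nonnegative=True)
        a_sd = as_vec3(amplitude_sd, "amplitude_sd", nonnegative=True)
        f = systematic_fraction
        return cls(
            baseline_mean=baseline_mean,
            baseline_systematic=np.sqrt(f) * b_sd,
            baseline_random=np.sqrt(1 - f) * b_sd,
            amplitude_mean=amplitude_mean,
            amplitude_systematic=np.sqrt(f) * a_sd,
            amplitude_random=np.sqrt(1 - f) * a_sd,
            **kwargs,
        )

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def _correlated_pair(rng, mean_x, mean_y, sd_x, sd_y, rho, size):
    """Draw (x, y) ~ bivariate normal with the given marginals and correlation."""
    z1 = rng.standard_normal(size)
    z2 = rng.standard_normal(size)
    x = mean_x + sd_x * z1
    y = mean_y + sd_y * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return x, y


def _level_correlation(rho, sb, rb, sa, ra) -> float:
    """Correlation to apply at both hierarchy levels so the pooled pairs have correlation rho."""
    pooled = math.sqrt((sb * sb + rb * rb) * (sa * sa + ra * ra))
    if pooled == 0:
        return 0.0
    denom = sb * sa + rb * ra
    if denom == 0:
        if rho != 0:
            raise InvalidParameterError("rho must be 0 when no common variance level exists between components")
        return 0.0
    level = rho * pooled / denom
    if abs(level) > 1:
        raise InvalidParameterError(
            f"rho={rho} is not attainable with this systematic/random split (would need level correlation {level:.3f})"
        )
    return level


def simulate_cohort(cfg: CohortConfig) -> list[FractionRecord]:
    """Draw a full cohort of fraction records; bit-reproducible for a fixed seed.

    Fraction 1 carries the reference baseline shift and amplitude for each
    patient; fraction ``k >= 2`` is constructed so that the metrics module,
    using the reference-minus-fraction baseline convention and the
    fraction-minus-reference amplitude convention, recovers exactly the
    deltas drawn from the hierarchical model. Amplitudes are floored at 0 mm
    (physically non-negative); at default reference amplitudes the floor is
    hit on well under 1% of records.
    """
    rng = np.random.default_rng(cfg.seed)
    P, F = cfg.n_patients, cfg.n_fractions
    nd = F - 1

    d_base = np.empty((P, nd, 3))
    d_amp = np.empty((P, nd, 3))
    for j in range(3):
        level = _level_correlation(
            cfg.rho[j],
            cfg.baseline_systematic[j], cfg.baseline_random[j],
            cfg.amplitude_systematic[j], cfg.amplitude_random[j],
        )
        m_b, m_a = _correlated_pair(
            rng, cfg.baseline_mean[j], cfg.amplitude_mean[j],
            cfg.baseline_systematic[j], cfg.amplitude_systematic[j], level, P,
        )
        e_b, e_a = _correlated_pair(
            rng, 0.0, 0.0, cfg.baseline_random[j], cfg.amplitude_random[j], level, (P, nd),
        )
        d_base[:, :, j] = m_b[:, None] + e_b
        d_amp[:, :, j] = m_a[:, None] + e_a

    base1 = rng.normal(0.0, cfg.reference_baseline_sd, size=(P, 3))
    clipbox = rng.normal(0.0, cfg.setup_sd, size=(P, F, 3))
    amp1 = np.maximum(rng.normal(cfg.reference_amplitude_mean, cfg.reference_amplitude_sd, size=(P, 3)), 0.0)

    width = max(2, len(str(P)))
    records: list[FractionRecord] = []
    for p in range(P):
        pid = f"P{p + 1:0{width}d}"
        for kfrac in range(1, F + 1):
            if kfrac == 1:
                baseline = base1[p]
                amplitude = amp1[p]
            else:
                # delta convention: baseline_1 - baseline_k; amplitude_k - amplitude_1
                baseline = base1[p] - d_base[p, kfrac - 2]
                amplitude = np.maximum(amp1[p] + d_amp[p, kfrac - 2], 0.0)
            cb = clipbox[p, kfrac - 1]
            records.append(
                FractionRecord(
                    patient_id=pid,
                    fraction=kfrac,
                    applied_shift_mm=cb + baseline,
                    clipbox_correction_mm=cb,
                    amplitude_mm=amplitude,
                )
            )
    return records
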