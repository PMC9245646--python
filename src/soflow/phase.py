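"""SO-phase machinery: Hilbert phase, phase-grid resampling, peak extraction.

Each SO's quantifier time series is re-expressed on a fixed phase grid so
that pre- and post-trough flow peaks align across events regardless of
exact wave timing. The instantaneous phase of the 2-s, 0.1-4 Hz epoch
around the trough is taken from the analytic signal of the *negated*
trace (so the trough is the analytic-signal peak), unwrapped, and shifted
so the trough sample has phase exactly 0. Quantifier values at the
sliding-window centers are then linearly interpolated onto a grid from
-pi to pi in steps of pi/64 (129 points), restricted to the largest
interval around the trough where the phase increases monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

#: Fixed phase grid: -pi..pi, step pi/64.
PHASE_STEP = np.pi / 64
PHASE_GRID = np.linspace(-np.pi, np.pi, 129)
#: Grid indices of the five canonical phases {-pi, -pi/2, 0, pi/2, pi}.
CANONICAL_PHASE_INDEX = {"-pi": 0, "-pi/2": 32, "0": 64, "pi/2": 96, "pi": 128}


class EventSkipped(ValueError):
    """Raised when an SO cannot contribute a phase series (caller logs & skips)."""


@dataclass
class PhaseSeries:
    """Quantifier values on the fixed phase grid; NaN marks uncovered points."""

    values: np.ndarray                   # (129,)
    grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())
    counts: np.ndarray | None = None     # per-point number of contributing SOs
    subject: str = ""
    so_channel: str = ""
    source: str = ""
    sink: str = "ALL"


@dataclass
class PeakRecord:
    """Pre/post-trough peaks of a subject-level phase series."""

    subject: str
    so_channel: str
    source: str
    sink: str
    prepeak_value: float
    prepeak_phase: float
    postpeak_value: float
    postpeak_phase: float
    trough_value: float
    phase_values: dict[str, float] = field(default_factory=dict)
    cluster: str | None = None
    coupled: bool | None = None


def so_phase(filtered_epoch: np.ndarray, taper: bool = True) -> np.ndarray:
    """Unwrapped instantaneous phase of a 2-s SO epoch; 0 at the trough.

    The epoch is the 0.1-4 Hz trace from 1 s before to 1 s after the
    trough (trough at the center sample). The trace is negated so the
    trough maps onto the analytic-signal peak; a cosine taper on the outer
    10% limits Hilbert edge artifacts (on by default).
    """
    x = -np.asarray(filtered_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be one channel")
    if np.std(x) == 0:
        raise ValueError("zero-variance epoch has no phase")
    if taper:
        x = x * scipy.signal.windows.tukey(x.size, alpha=0.2)
    analytic = scipy.signal.hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    center = x.size // 2
    return phase - phase[center]


def monotonic_valid_range(phase: np.ndarray) -> tuple[int, int]:
    """Largest strictly increasing run containing the trough, within [-pi, pi].

    Returns inclusive sample indices (lo, hi). Raises :class:`EventSkipped`
    when fewer than 3 samples remain.
    """
    phase = np.asarray(phase, dtype=float)
    center = phase.size // 2
    d = np.diff(phase)
    lo = center
    while lo > 0 and d[lo - 1] > 0:
        lo -= 1
    hi = center
    while hi < phase.size - 1 and d[hi] > 0:
        hi += 1
    # clip to [-pi, pi], keeping one bracketing sample past each bound so
    # interpolation can reach the -pi and pi grid endpoints
    while lo < center and phase[lo + 1] < -np.pi:
        lo += 1
    while hi > center and phase[hi - 1] > np.pi:
        hi -= 1
    if hi - lo + 1 < 3:
        raise EventSkipped("monotonic phase range shorter than 3 samples")
    return lo, hi


def resample_to_phase(values: np.ndarray, center_phases: np.ndarray,
                      valid: np.ndarray | None = None, **meta) -> PhaseSeries:
    """Interpolate one SO's quantifier series onto the fixed phase grid.

    ``center_phases`` gives the phase at each sliding-window center;
    ``valid`` flags the centers inside the monotonic range. Grid points
    outside the covered phase span are NaN. Raises :class:`EventSkipped`
    with fewer than 2 valid pairs.
    """
    values = np.asarray(values, dtype=float)
    center_phases = np.asarray(center_phases, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    ph = center_phases[valid]
    va = values[valid]
    if ph.size < 2:
        raise EventSkipped("fewer than 2 valid (phase, value) pairs")
    order = np.argsort(ph)
    ph, va = ph[order], va[order]
    out = np.full(PHASE_GRID.size, np.nan)
    inside = (PHASE_GRID >= ph[0]) & (PHASE_GRID <= ph[-1])
    out[inside] = np.interp(PHASE_GRID[inside], ph, va)
    return PhaseSeries(values=out, **meta)


def average_phase_series(series: list[PhaseSeries], **meta) -> PhaseSeries:
    """Pointwise available-case mean over per-SO series (NaNs ignored)."""
    if not series:
        raise ValueError("empty group: no phase series to average")
    stack = np.vstack([s.values for s in series])
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(stack, axis=0) /
                        np.maximum(counts, 1), np.nan)
    return PhaseSeries(values=mean, counts=counts, **meta)


def extract_peaks(series: PhaseSeries) -> PeakRecord:
    """Pre/post-trough maxima and the five canonical phase values.

    The prepeak is the maximum over grid points in (-pi, 0), the postpeak
    over (0, pi); ties resolve to the earliest grid point. Raises when the
    series is undefined at phase 0 or over either half-range.
    """
    v = series.values
    i0 = CANONICAL_PHASE_INDEX["0"]
    if np.isnan(v[i0]):
        raise ValueError("phase series undefined at phase 0")
    pre = slice(1, i0)
    post = slice(i0 + 1, PHASE_GRID.size - 1)
    for name, sl in (("pre", pre), ("post", post)):
        if np.all(np.isnan(v[sl])):
            raise ValueError(f"phase series undefined over the {name} half-range")
    pre_idx = 1 + int(np.nanargmax(v[pre]))
    post_idx = i0 + 1 + int(np.nanargmax(v[post]))
    phase_values = {name: float(v[idx])
                    for name, idx in CANONICAL_PHASE_INDEX.items()}
    return PeakRecord(
        subject=series.subject, so_channel=series.so_channel,
        source=series.source, sink=series.sink,
        prepeak_value=float(v[pre_idx]), prepeak_phase=float(PHASE_GRID[pre_idx]),
        postpeak_value=float(v[post_idx]), postpeak_phase=float(PHASE_GRID[post_idx]),
        trough_value=float(v[i0]), phase_values=phase_values,
    )
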