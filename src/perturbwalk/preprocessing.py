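"""Zero-phase low-pass filtering and numerical differentiation of marker data.

Marker trajectories are smoothed with a low-pass Butterworth filter applied
forward and backward (zero phase lag; the two passes double the effective
order), then differentiated to obtain velocities for the extrapolated
centre of mass.  Differentiation is always done on the filtered positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["FilterSpec", "butterworth_zero_phase", "differentiate"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter specification.

    cutoff : Hz, must lie below the Nyquist frequency of the series.
    order : order of a single pass; the forward-backward application
        doubles the effective order.
    zero_phase : apply forward-backward (no phase lag).  Single-pass
        causal filtering is available mainly for diagnostics.
    """

    cutoff: float = 12.0
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def butterworth_zero_phase(
    series: np.ndarray, spec: FilterSpec | None = None, rate: float = 100.0
) -> np.ndarray:
    """Filter ``series`` (sampled at ``rate`` Hz) with a zero-phase Butterworth.

    Output length equals input length.  Edge transients are suppressed by
    reflective padding of three filter lengths before the forward-backward
    pass.
    """
    spec = spec or FilterSpec()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("expected a 1-D series")
    nyquist = rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    b, a = butter(spec.order, spec.cutoff / nyquist)
    padlen = 3 * max(len(a), len(b))
    if series.size <= padlen:
        raise ValueError(
            f"series of length {series.size} too short to filter (needs > {padlen})"
        )
    if not spec.zero_phase:
        from scipy.signal import lfilter

        return lfilter(b, a, series)
    return filtfilt(b, a, series, padtype="even", padlen=padlen)


def differentiate(series: np.ndarray, rate: float) -> np.ndarray:
    """First time derivative: central differences inside, one-sided at ends.

    Length is preserved; units are input units per second.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / rate)
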