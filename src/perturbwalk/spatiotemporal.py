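"""Spatiotemporal step parameters and their variability.

Step time is the interval between consecutive contralateral touchdowns;
step length the AP distance between the leading and trailing hallux at the
leading foot's touchdown (instantaneous marker positions — no belt
integration by default); step width the absolute mediolateral hallux
separation at touchdown; double support time the overlap of the two stance
intervals bounding the step.  Variability is summarized as the coefficient
of variation, 100 * SD / mean (sample SD, n-1 denominator).

Only the hallux markers are available as foot markers in the reduced
six-marker set, so they define both length and width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import GaitEvents

__all__ = [
    "StepRecord",
    "step_parameters",
    "coefficient_of_variation",
    "summarize_steps",
]


@dataclass(frozen=True)
class StepRecord:
    """One step, indexed by the leading foot's touchdown."""

    touchdown_time: float
    side: str  # leading foot
    step_time: float
    step_length: float
    step_width: float
    double_support_time: float


def _toeoff_after(events: GaitEvents, t: float, side: str) -> float | None:
    times = events.to_times(side)
    later = times[times > t]
    return float(later[0]) if later.size else None


def step_parameters(
    events: GaitEvents,
    markers_or_session,
    belt_correction: bool = False,
) -> list:
    """Per-step spatiotemporal parameters from events and hallux positions.

    ``markers_or_session`` is either a MarkerSession or a (time, markers)
    pair with markers already filtered.  With ``belt_correction`` the belt
    displacement of the trailing foot over the step is added to the step
    length (off by default).
    """
    if hasattr(markers_or_session, "markers"):
        session = markers_or_session
        time, markers = session.time, session.markers
    else:
        session = None
        time, markers = markers_or_session
    td = sorted(events.touchdowns)
    if len(td) < 3:
        raise ValueError("need at least 3 touchdowns")
    for (t0, s0), (t1, s1) in zip(td, td[1:]):
        if s0 == s1:
            raise ValueError(
                f"touchdowns do not alternate at {t0:.3f}/{t1:.3f} s"
            )
    hallux = {"L": markers["LHLX"], "R": markers["RHLX"]}
    records = []
    for (t_prev, s_prev), (t_lead, s_lead) in zip(td, td[1:]):
        x_lead = np.interp(t_lead, time, hallux[s_lead][:, 0])
        x_trail = np.interp(t_lead, time, hallux[s_prev][:, 0])
        y_lead = np.interp(t_lead, time, hallux[s_lead][:, 1])
        y_trail = np.interp(t_lead, time, hallux[s_prev][:, 1])
        length = x_lead - x_trail
        if belt_correction:
            if session is None:
                raise ValueError("belt correction needs a MarkerSession")
            tt = np.linspace(t_prev, t_lead, 32)
            length += float(np.trapezoid(session.belt_at(tt, s_prev), tt))
        toe_trail = _toeoff_after(events, t_prev, s_prev)
        ds = max(0.0, toe_trail - t_lead) if toe_trail is not None else np.nan
        records.append(
            StepRecord(
                touchdown_time=float(t_lead),
                side=s_lead,
                step_time=float(t_lead - t_prev),
                step_length=float(length),
                step_width=float(abs(y_lead - y_trail)),
                double_support_time=float(ds),
            )
        )
    return records


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD / mean.  Errors on n < 2 or zero mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean; CV undefined")
    return float(100.0 * v.std(ddof=1) / mean)


def summarize_steps(records, trial_label: str = "", speed: float = np.nan) -> pd.DataFrame:
    """Tidy per-trial summary: mean and CV of each step parameter."""
    df = pd.DataFrame(
        {
            "step_time": [r.step_time for r in records],
            "step_length": [r.step_length for r in records],
            "step_width": [r.step_width for r in records],
            "double_support_time": [r.double_support_time for r in records],
        }
    )
    rows = []
    for param in df.columns:
        vals = df[param].dropna().to_numpy()
        rows.append(
            {
                "trial": trial_label,
                "speed": speed,
                "parameter": param,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "cv_percent": coefficient_of_variation(vals)
                if vals.size >= 2 and np.mean(vals) != 0
                else np.nan,
                "n_steps": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
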