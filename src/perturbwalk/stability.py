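"""Extrapolated centre of mass and anteroposterior margin of stability.

The margin of stability (MoS) treats the walker as an inverted pendulum of
length ``l``: the extrapolated centre of mass

    XCoM(t) = x_com(t) + v_com(t) / omega0,      omega0 = sqrt(g / l)

must stay behind the anterior boundary of the base of support for the
configuration to be passively recoverable.  Here the CoM is proxied by a
weighted mean of the sacrum, mid-trochanter and C7 markers (reduced
six-marker model), the anterior BoS boundary by the leading hallux, and the
anteroposterior MoS at each touchdown is

    MoS = x_hallux_lead(td) - XCoM_ap(td).

On a treadmill the base of support translates with the belt, so the CoM
velocity entering XCoM is belt-relative by default: the lab-frame derivative
plus the instantaneous belt speed of the stance side.

The stability-normalized walking speed is the speed at which the mean MoS of
the final steps of a trial equals a target (0.05 m by default), solved from
a quadratic fit of mean MoS against trial speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvents
from .preprocessing import FilterSpec, butterworth_zero_phase, differentiate

__all__ = [
    "ComState",
    "MosSeries",
    "StabilitySpeedCurve",
    "StabilitySpeedModel",
    "StabilitySpeedResults",
    "com_proxy",
    "pendulum_length",
    "xcom",
    "stance_side_codes",
    "mos_at_touchdowns",
    "mean_mos_final_steps",
    "solve_normalized_speed",
    "compute_mos_series",
]

G = 9.81
DEFAULT_COM_WEIGHTS = (0.5, 0.3, 0.2)  # sacrum, mid-trochanter, C7


@dataclass
class ComState:
    """Pendulum state for the XCoM construct."""

    position: np.ndarray  # (n, 3) CoM proxy, lab frame
    velocity_ap: np.ndarray  # belt-relative anteroposterior velocity, m/s
    l: float  # pendulum length, m
    g: float = G

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"pendulum length must be positive, got {self.l}")

    @property
    def omega0(self) -> float:
        return float(np.sqrt(self.g / self.l))


@dataclass
class MosSeries:
    """Per-step anteroposterior MoS at touchdown."""

    touchdown_times: np.ndarray
    sides: list
    mos_ap: np.ndarray  # metres; positive = XCoM behind the anterior BoS edge
    trial_label: str = ""

    def __len__(self) -> int:
        return len(self.touchdown_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "touchdown_time": self.touchdown_times,
                "side": self.sides,
                "mos_ap": self.mos_ap,
            }
        )


def com_proxy(markers, weights=DEFAULT_COM_WEIGHTS) -> np.ndarray:
    """CoM proxy: weighted mean of sacrum, mid-trochanter and C7 positions.

    ``markers`` maps labels to (n, 3) arrays (already filtered).  Weights must
    be a convex combination (sum to 1).
    """
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be 3 values summing to 1")
    for lab in ("SACR", "LTRO", "RTRO", "C7"):
        if lab not in markers:
            raise ValueError(f"missing marker {lab} for CoM proxy")
    mid_tro = 0.5 * (markers["LTRO"] + markers["RTRO"])
    return w[0] * markers["SACR"] + w[1] * mid_tro + w[2] * markers["C7"]


def pendulum_length(com: np.ndarray, markers) -> float:
    """Mean vertical CoM height above the lowest hallux sample over the trial."""
    floor = min(markers["LHLX"][:, 2].min(), markers["RHLX"][:, 2].min())
    l = float(np.mean(com[:, 2]) - floor)
    if l <= 0:
        raise ValueError(f"non-positive pendulum length {l}")
    return l


def xcom(com_ap: np.ndarray, velocity_ap: np.ndarray, omega0: float) -> np.ndarray:
    """Extrapolated centre of mass: XCoM = x + v / omega0."""
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    return np.asarray(com_ap, float) + np.asarray(velocity_ap, float) / omega0


def stance_side_codes(time: np.ndarray, events: GaitEvents) -> np.ndarray:
    """Side of the most recent touchdown at each sample ('L'/'R' array).

    Samples before the first touchdown inherit the side opposite to it (that
    foot is still in stance there).
    """
    td = sorted(events.touchdowns)
    if not td:
        raise ValueError("no touchdowns")
    td_times = np.array([t for t, _ in td])
    td_sides = np.array([s for _, s in td])
    idx = np.searchsorted(td_times, time, side="right") - 1
    out = np.empty(len(time), dtype="<U1")
    first_opposite = "L" if td_sides[0] == "R" else "R"
    out[idx < 0] = first_opposite
    valid = idx >= 0
    out[valid] = td_sides[idx[valid]]
    return out


def mos_at_touchdowns(
    time: np.ndarray,
    com_ap: np.ndarray,
    com_vel_lab: np.ndarray,
    markers,
    events: GaitEvents,
    omega0: float,
    session=None,
    belt_relative: bool = True,
    trial_label: str = "",
) -> MosSeries:
    """Anteroposterior MoS at each touchdown.

    MoS = (leading hallux AP) - XCoM_ap, both evaluated at the touchdown
    instant.  The belt-relative CoM velocity uses the belt speed of the
    landing foot's side, looked up per event (never interpolated across the
    stance-side switch).
    """
    if not events.touchdowns:
        raise ValueError("no touchdown events")
    t0, t1 = time[0], time[-1]
    times, sides, mos = [], [], []
    for t, side in sorted(events.touchdowns):
        if not (t0 <= t <= t1):
            raise ValueError(f"event at {t:.3f} s outside series support")
        hallux = markers["LHLX" if side == "L" else "RHLX"][:, 0]
        bos = np.interp(t, time, hallux)
        v = np.interp(t, time, com_vel_lab)
        if belt_relative:
            if session is None:
                raise ValueError("belt_relative MoS needs the session for belt speeds")
            v = v + float(session.belt_at(t, side))
        xc = np.interp(t, time, com_ap) + v / omega0
        times.append(t)
        sides.append(side)
        mos.append(bos - xc)
    return MosSeries(
        touchdown_times=np.array(times),
        sides=sides,
        mos_ap=np.array(mos),
        trial_label=trial_label,
    )


def mean_mos_final_steps(mos: MosSeries, n_steps: int = 10) -> float:
    """Arithmetic mean of the last ``n_steps`` MoS values of a trial."""
    if len(mos) < n_steps:
        raise ValueError(f"need >= {n_steps} steps, have {len(mos)}")
    return float(np.mean(mos.mos_ap[-n_steps:]))


def compute_mos_series(
    session,
    forces=None,
    events: GaitEvents | None = None,
    filter_spec: FilterSpec | None = None,
    weights=DEFAULT_COM_WEIGHTS,
    belt_relative: bool = True,
    l_override: float | None = None,
    g: float = G,
) -> MosSeries:
    """Full pipeline: filter markers, detect events, compute per-step MoS."""
    from .events import detect_events_force, detect_events_marker

    spec = filter_spec or FilterSpec()
    rate = session.sampling_rate_markers
    filt = {
        lab: np.column_stack(
            [butterworth_zero_phase(arr[:, j], spec, rate) for j in range(3)]
        )
        for lab, arr in session.markers.items()
    }
    if events is None:
        if forces is not None:
            events = detect_events_force(forces, rate=session.sampling_rate_forces)
        else:
            events = detect_events_marker(session, spec)
    com = com_proxy(filt, weights)
    l = l_override if l_override is not None else pendulum_length(com, filt)
    omega0 = float(np.sqrt(g / l))
    vel_lab = differentiate(com[:, 0], rate)
    return mos_at_touchdowns(
        session.time,
        com[:, 0],
        vel_lab,
        filt,
        events,
        omega0,
        session=session,
        belt_relative=belt_relative,
        trial_label=session.trial_label,
    )


# ---------------------------------------------------------------------------
# Stability-normalized walking speed


@dataclass
class StabilitySpeedCurve:
    """Per-participant mean MoS vs speed and the solved normalized speed."""

    speeds: np.ndarray
    mean_mos: np.ndarray
    fit_coeffs: np.ndarray  # highest power first
    normalized_speed: float
    target_mos: float = 0.05
    extrapolated: bool = False
    method: str = "quadratic"

    @property
    def reported_speed(self) -> float:
        """Normalized speed to the 0.01 m/s resolution used for reporting."""
        return round(self.normalized_speed, 2)


class StabilitySpeedModel:
    """Quadratic model of mean MoS against walking speed.

    Fit with least squares; ``fit()`` returns a results object carrying the
    solved stability-normalized speed (the in-range root of the fitted curve
    at the target MoS on its decreasing branch), falling back to a linear fit
    flagged as extrapolated when the quadratic has no usable in-range root.
    """

    def __init__(self, speeds, mean_mos, target_mos: float = 0.05):
        self.speeds = np.asarray(speeds, dtype=float)
        self.mean_mos = np.asarray(mean_mos, dtype=float)
        self.target_mos = float(target_mos)
        if self.speeds.size < 3:
            raise ValueError("need at least 3 speed points")
        if np.any(np.diff(self.speeds) <= 0):
            raise ValueError("speeds must be strictly increasing")
        if np.ptp(self.mean_mos) < 1e-12:
            raise ValueError("mean MoS is constant across speeds; cannot solve")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, speed: str = "speed", mos: str = "mean_mos", **kw
    ) -> "StabilitySpeedModel":
        d = df.sort_values(speed)
        return cls(d[speed].to_numpy(), d[mos].to_numpy(), **kw)

    def _solve_quadratic(self, coeffs) -> float | None:
        a, b, c = coeffs
        if abs(a) < 1e-10 * max(abs(b), 1e-12):
            return None
        disc = b * b - 4 * a * (c - self.target_mos)
        if disc < 0:
            return None
        roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1.0, -1.0)]
        lo, hi = self.speeds[0], self.speeds[-1]
        usable = [
            r for r in roots if 2 * a * r + b < 0 and lo - 1e-9 <= r <= hi + 1e-9
        ]
        if not usable:
            return None
        return float(min(usable, key=lambda r: abs(r - 0.5 * (lo + hi))))

    def fit(self) -> "StabilitySpeedResults":
        lo, hi = self.speeds[0], self.speeds[-1]
        quad = np.polyfit(self.speeds, self.mean_mos, 2)
        root = self._solve_quadratic(quad)
        if root is not None:
            curve = StabilitySpeedCurve(
                self.speeds, self.mean_mos, quad, root, self.target_mos,
                extrapolated=False, method="quadratic",
            )
            return StabilitySpeedResults(self, curve)
        lin = np.polyfit(self.speeds, self.mean_mos, 1)
        slope, intercept = lin
        if slope >= 0:
            raise ValueError(
                "no in-range decreasing quadratic root and the linear trend is "
                "non-decreasing; cannot solve for the target MoS"
            )
        v = float((self.target_mos - intercept) / slope)
        curve = StabilitySpeedCurve(
            self.speeds, self.mean_mos, lin, v, self.target_mos,
            extrapolated=not (lo - 1e-9 <= v <= hi + 1e-9), method="linear",
        )
        return StabilitySpeedResults(self, curve)


class StabilitySpeedResults:
    """Fitted MoS-vs-speed curve plus the solved normalized speed."""

    def __init__(self, model: StabilitySpeedModel, curve: StabilitySpeedCurve):
        self.model = model
        self.curve = curve

    @property
    def normalized_speed(self) -> float:
        return self.curve.normalized_speed

    @property
    def fit_coeffs(self) -> np.ndarray:
        return self.curve.fit_coeffs

    @property
    def residuals(self) -> np.ndarray:
        return self.model.mean_mos - np.polyval(
            self.curve.fit_coeffs, self.model.speeds
        )

    def predict(self, speeds) -> np.ndarray:
        return np.polyval(self.curve.fit_coeffs, np.asarray(speeds, float))

    def summary(self) -> str:
        c = self.curve
        lines = [
            "Stability-normalized walking speed",
            "----------------------------------",
            f"fit: {c.method} over {c.speeds[0]:.2f}-{c.speeds[-1]:.2f} m/s "
            f"({len(c.speeds)} speeds)",
            f"coefficients (highest power first): "
            + ", ".join(f"{v:+.5f}" for v in c.fit_coeffs),
            f"target MoS: {c.target_mos:.3f} m",
            f"normalized speed: {c.reported_speed:.2f} m/s"
            + (" [extrapolated]" if c.extrapolated else ""),
            f"max |residual|: {np.max(np.abs(self.residuals)):.4f} m",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c.speeds, c.mean_mos, "o", label="mean MoS (final steps)")
        vv = np.linspace(min(c.speeds[0], c.normalized_speed),
                         max(c.speeds[-1], c.normalized_speed), 200)
        ax.plot(vv, np.polyval(c.fit_coeffs, vv), "-", label=f"{c.method} fit")
        ax.axhline(c.target_mos, ls=":", color="grey")
        ax.axvline(c.normalized_speed, ls="--", color="k",
                   label=f"normalized speed {c.reported_speed:.2f} m/s")
        ax.set_xlabel("walking speed (m/s)")
        ax.set_ylabel("mean anteroposterior MoS (m)")
        ax.legend()
        return ax


def solve_normalized_speed(points, target_mos: float = 0.05) -> StabilitySpeedCurve:
    """Solve the stability-normalized speed from (speed, mean MoS) pairs."""
    pts = sorted(points)
    speeds = [p[0] for p in pts]
    mos = [p[1] for p in pts]
    return StabilitySpeedModel(speeds, mos, target_mos).fit().curve
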