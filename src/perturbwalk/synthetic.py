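"""Synthetic treadmill gait with ground truth for every pipeline stage.

The generator emulates periodic treadmill walking over 0.4-1.8 m/s with
lognormal step-to-step variability, a configurable monotone MoS-vs-speed
relationship, and belt-acceleration perturbations whose MoS response decays
geometrically over recovery steps with configurable across-perturbation
adaptation.  Everything downstream needs is emitted with exact ground
truth: marker trajectories (100 Hz), dual-belt vertical forces and belt
speed commands (1000 Hz), touchdown/toe-off events, per-step MoS, and
perturbation onsets.

Construction (inverse design):

* Foot trajectories.  During stance the hallux is advected backward at the
  belt speed (with a short C2 landing blend and a catch-up phase that keeps
  the mean advection per step exactly equal to the belt displacement, so
  realized step lengths match the configured ones).  Swing is a quintic
  with matched boundary velocities, giving hallux AP extrema at the events.

* CoM trajectory.  A smooth target XCoM path c(t) is drawn through the
  per-touchdown constraints c(td) = x_hallux_lead(td) - MoS_truth, and the
  CoM AP position is obtained by integrating the pendulum relation
  x' = omega0 (c - x) - v_belt.  The downstream computation
  XCoM = x + (x' + v_belt)/omega0 then reproduces c(t) identically, so the
  pipeline's MoS equals the configured truth at every touchdown (up to
  numerical differentiation and filtering, well below a millimetre for
  noiseless sessions).

* Forces.  Smoothed trapezoids per stance scaled to body weight, sufficient
  for threshold-based event detection within a few milliseconds of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .events import GaitEvents
from .io import ForceRecord, MarkerSession
from .perturbation import PerturbationSpec, belt_profile, count_recovery_steps, LabeledPerturbation
from .stability import MosSeries

__all__ = [
    "GaitModelParams",
    "PerturbationResponseParams",
    "PerturbationSchedule",
    "SyntheticSession",
    "generate_unperturbed_trial",
    "generate_perturbation_session",
    "response_deviations",
    "simulate_mos_table",
    "simulate_recovery_counts",
]

log = logging.getLogger(__name__)

G = 9.81
DT = 1e-3  # master grid (s); markers decimated to 100 Hz
MARKER_DECIM = 10
CADENCE_EXPONENT = 0.5  # step time scales as (reference speed / speed)^0.5
LANDING_BLEND = 0.04  # s, C2 velocity blend after touchdown
CATCHUP = 0.24  # s, stance catch-up phase repaying the blend deficit
FORCE_RISE = 0.04  # s, half-cosine loading/unloading of the GRF trapezoid
STEP_REVERSION = 0.15  # per-step pull of foot placement toward the anchor


def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


@dataclass(frozen=True)
class GaitModelParams:
    """Generator configuration for one synthetic participant.

    ``mos_speed_coeffs`` (highest power first, for numpy polyval) define the
    true mean MoS as a function of belt speed; the default quadratic is
    monotone decreasing over 0.4-1.8 m/s and crosses the 0.05 m target near
    1.35 m/s.  ``step_time_mean`` and ``step_length_mean`` describe walking
    at ``walking_speed``; other trial speeds rescale cadence with a square
    root law and keep step length consistent with the belt displacement.
    """

    walking_speed: float = 1.3  # m/s, reference speed of the step parameters
    step_time_mean: float = 0.5  # s
    step_time_cv: float = 0.03
    step_length_mean: float = 0.65  # m
    step_length_cv: float = 0.04
    step_width_mean: float = 0.10  # m
    step_width_cv: float = 0.08
    double_support_fraction: float = 0.14  # of stride, per-step overlap
    leg_length: float = 1.0  # m, pendulum (CoM) height
    mos_speed_coeffs: tuple = (0.02, -0.16, 0.23)
    mos_step_sd: float = 0.008  # m, step-to-step MoS noise
    marker_noise_sd: float = 0.001  # m, additive Gaussian marker noise
    body_mass: float = 75.0  # kg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_time_mean <= 0:
            raise ValueError("step_time_mean must be positive")
        if not (0 < self.double_support_fraction < 0.5):
            raise ValueError("double_support_fraction must lie in (0, 0.5)")
        for name in ("step_time_cv", "step_length_cv", "step_width_cv",
                     "mos_step_sd", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.leg_length <= 0:
            raise ValueError("leg_length must be positive")
        if self.true_mos(0.4) <= self.true_mos(1.8):
            raise ValueError(
                "mos_speed_coeffs must give MoS decreasing from 0.4 to 1.8 m/s"
            )

    def true_mos(self, speed: float) -> float:
        """Configured mean MoS at a belt speed (the ground-truth curve)."""
        return float(np.polyval(self.mos_speed_coeffs, speed))

    def noiseless(self, **overrides) -> "GaitModelParams":
        """Copy with all stochastic components switched off."""
        kw = dict(
            step_time_cv=0.0, step_length_cv=0.0, step_width_cv=0.0,
            mos_step_sd=0.0, marker_noise_sd=0.0,
        )
        kw.update(overrides)
        return replace(self, **kw)

    def step_time_at(self, speed: float) -> float:
        return self.step_time_mean * (self.walking_speed / speed) ** CADENCE_EXPONENT

    def step_length_at(self, speed: float) -> float:
        # treadmill stationarity: mean step length equals belt travel per step
        return speed * self.step_time_at(speed)


@dataclass(frozen=True)
class PerturbationResponseParams:
    """Stochastic law of the post-perturbation MoS response.

    Perturbation k (1-based) displaces the Post-step MoS from baseline by
    ``initial_mos_deviation * (1 - adaptation_rate)**(k-1)``; the deviation
    holds for ``delay_steps`` steps after Post1 and then decays
    geometrically with ``recovery_rate`` per step, with ``response_sd`` of
    step-to-step noise superimposed.
    """

    initial_mos_deviation: float = -0.15  # m, signed Post1 deviation
    recovery_rate: float = 0.8  # per-step geometric decay factor
    adaptation_rate: float = 0.25  # per-repetition multiplicative reduction
    response_sd: float = 0.02  # m
    delay_steps: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.recovery_rate < 1):
            raise ValueError("recovery_rate must lie in (0, 1)")
        if not (0 <= self.adaptation_rate <= 1):
            raise ValueError("adaptation_rate must lie in [0, 1]")
        if self.response_sd < 0 or self.delay_steps < 0:
            raise ValueError("response_sd and delay_steps must be >= 0")

    @classmethod
    def non_faller(cls) -> "PerturbationResponseParams":
        """Adapting profile: consistent responses, clear adaptation."""
        return cls()

    @classmethod
    def faller(cls) -> "PerturbationResponseParams":
        """Falls-history profile: delayed, variable, barely adapting."""
        return cls(adaptation_rate=0.05, response_sd=0.03, delay_steps=1)


def response_deviations(
    resp: PerturbationResponseParams, pert_index: int, n_steps: int = 8
) -> np.ndarray:
    """Noise-free truth deviations at Post1..Post``n_steps`` of perturbation k."""
    d_k = resp.initial_mos_deviation * (1.0 - resp.adaptation_rate) ** (pert_index - 1)
    m = np.arange(1, n_steps + 1)
    expo = np.maximum(0, m - 1 - resp.delay_steps)
    return d_k * resp.recovery_rate ** expo


@dataclass(frozen=True)
class PerturbationSchedule:
    """Nominal protocol: sides and inter-perturbation gaps.

    Default side order is R, then eight L, then R.  Actual onsets snap to
    the first qualifying swing at or after each nominal time.
    """

    sides: tuple = ("R",) + ("L",) * 8 + ("R",)
    gaps: tuple = (60.0,) * 9  # s, between consecutive nominal onsets
    lead_in: float = 180.0  # s of unperturbed walking before the first onset
    acceleration: float = 3.0  # m/s^2
    speed_factor: float = 1.8

    def __post_init__(self) -> None:
        if len(self.sides) != len(self.gaps) + 1:
            raise ValueError("need exactly one more side than gaps")
        if any(s not in ("L", "R") for s in self.sides):
            raise ValueError("sides must be 'L' or 'R'")
        if self.lead_in < 15:
            raise ValueError("lead_in must allow a pre-perturbation baseline")

    @property
    def n_perturbations(self) -> int:
        return len(self.sides)

    @property
    def nominal_onsets(self) -> np.ndarray:
        return self.lead_in + np.concatenate([[0.0], np.cumsum(self.gaps)])

    @classmethod
    def standard(
        cls, seed: int = 0, lead_in: float = 180.0, gap_range=(31.5, 88.5)
    ) -> "PerturbationSchedule":
        """The ten-perturbation protocol with unannounced 30-90 s gaps."""
        rng = np.random.default_rng(seed)
        gaps = tuple(rng.uniform(*gap_range, size=9))
        return cls(gaps=gaps, lead_in=lead_in)

    def spec(self, k: int) -> PerturbationSpec:
        return PerturbationSpec(
            side=self.sides[k], index=k + 1,
            acceleration=self.acceleration, speed_factor=self.speed_factor,
        )


@dataclass
class SyntheticSession:
    """A generated trial plus its ground truth."""

    markers: MarkerSession
    forces: ForceRecord
    truth_events: GaitEvents
    truth_mos: MosSeries
    truth_pert_times: list
    truth_pert_sides: list
    truth_steps: pd.DataFrame
    group_label: str = "NoFalls"
    params: GaitModelParams | None = None
    response: PerturbationResponseParams | None = None
    schedule: PerturbationSchedule | None = None

    def validate(self) -> None:
        self.truth_events.validate()
        t = np.asarray(self.truth_pert_times)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("perturbation onsets not strictly increasing")
            gaps = np.diff(t)
            if t.size > 1 and (np.any(gaps < 30.0) or np.any(gaps > 90.0)):
                raise ValueError("perturbation gaps outside 30-90 s")

    def save(self, path) -> None:
        from .io import write_session

        truth = {
            "touchdowns": [[t, s] for t, s in self.truth_events.touchdowns],
            "toeoffs": [[t, s] for t, s in self.truth_events.toeoffs],
            "mos": {
                "times": self.truth_mos.touchdown_times.tolist(),
                "sides": list(self.truth_mos.sides),
                "values": self.truth_mos.mos_ap.tolist(),
            },
            "pert_times": list(map(float, self.truth_pert_times)),
            "pert_sides": list(self.truth_pert_sides),
            "group": self.group_label,
        }
        write_session(self.markers, path, forces=self.forces, truth=truth)


# ---------------------------------------------------------------------------
# Core generator


class _FootState:
    __slots__ = ("toe_time", "toe_pos", "toe_vel", "y", "last_td", "last_pos")

    def __init__(self):
        self.toe_time = None
        self.toe_pos = None
        self.toe_vel = None
        self.y = 0.0
        self.last_td = None
        self.last_pos = None


def _quintic(s, x0, w0, x1):
    """Quintic on s in [0,1]: p(0)=x0, p'(0)=w0, p''(0)=0, p(1)=x1, p'(1)=p''(1)=0."""
    A = x1 - x0 - w0
    B = -w0
    # [1 1 1; 3 4 5; 6 12 20] [a3 a4 a5]^T = [A B 0]^T
    a3 = 10.0 * A - 4.0 * B
    a4 = -15.0 * A + 7.0 * B
    a5 = 6.0 * A - 3.0 * B
    return x0 + w0 * s + s ** 3 * (a3 + s * (a4 + s * a5))


def _stance_phi(s: np.ndarray, stance_dur: float) -> np.ndarray:
    """Advection velocity factor over stance-relative time s.

    Half-cosine rise over the landing blend, then a catch-up bump whose
    excess integral repays the blend deficit so mean advection matches the
    belt displacement exactly.
    """
    tau = min(LANDING_BLEND, 0.4 * stance_dur)
    tau2 = min(CATCHUP, max(0.05, stance_dur - tau - 0.05))
    c = tau / tau2  # excess factor: integral of c*sin^2 over tau2 = tau/2
    phi = np.ones_like(s)
    m0 = s < tau
    phi[m0] = 0.5 * (1.0 - np.cos(np.pi * s[m0] / tau))
    m1 = (s >= tau) & (s < tau + tau2)
    phi[m1] = 1.0 + c * np.sin(np.pi * (s[m1] - tau) / tau2) ** 2
    return phi


def _generate(
    params: GaitModelParams,
    speed: float,
    duration: float,
    resp: PerturbationResponseParams | None = None,
    schedule: PerturbationSchedule | None = None,
    group_label: str = "NoFalls",
) -> SyntheticSession:
    if not (0.2 <= speed <= 2.5):
        raise ValueError(f"speed {speed} m/s outside the supported 0.2-2.5 range")
    if duration < 10.0:
        raise ValueError(f"duration {duration} s too short (need >= 10 s)")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration / DT))
    t = np.arange(n) * DT
    t_end = t[-1]

    T_v = params.step_time_at(speed)
    L_v = params.step_length_at(speed)
    ds_frac = params.double_support_fraction

    # --- step timing (two fictitious lead-in touchdowns at indices 0, 1) ---
    n_max = int(duration / T_v * 1.4) + 12
    T_draw = _lognormal(rng, T_v, params.step_time_cv, n_max)
    first_real = max(1.0, 2.4 * T_v)
    t_start = max(0.05, first_real - T_draw[0] - T_draw[1])
    td = t_start + np.concatenate([[0.0], np.cumsum(T_draw)])
    keep = td < duration - 0.05
    td = td[keep]
    n_td = len(td)
    if n_td < 6:
        raise ValueError("duration too short for the configured cadence")
    sides = np.array(["R" if j % 2 == 0 else "L" for j in range(n_td)])

    # double support after each touchdown, from the local stride
    D = np.empty(n_td)
    for j in range(n_td):
        lo = td[j - 1] if j >= 1 else td[j] - T_v
        hi = td[j + 1] if j + 1 < n_td else td[j] + T_v
        D[j] = ds_frac * (hi - lo)
    toe = np.full(n_td, np.nan)  # toe-off of the foot landing at td[j]
    for j in range(n_td):
        toe[j] = (td[j + 1] + D[j + 1]) if j + 1 < n_td else td[j] + T_v + D[j]

    W = _lognormal(rng, params.step_width_mean, params.step_width_cv, n_td)
    L_draw = _lognormal(rng, L_v, params.step_length_cv, n_td)
    mos_base = np.full(n_td, params.true_mos(speed))
    if params.mos_step_sd > 0:
        mos_base += rng.normal(0.0, params.mos_step_sd, n_td)

    # --- belt speed commands (mutated in the step loop by perturbations) ---
    belt = {"L": np.full(n, float(speed)), "R": np.full(n, float(speed))}

    # --- foot trajectories, built segment by segment ---
    foot_x = {"L": np.zeros(n), "R": np.zeros(n)}
    foot_y = {"L": np.zeros(n), "R": np.zeros(n)}
    foot_z = {"L": np.zeros(n), "R": np.zeros(n)}
    state = {"L": _FootState(), "R": _FootState()}
    x_td = np.empty(n_td)
    realized_len = np.full(n_td, np.nan)
    swing_h = 0.05  # m, hallux lift during swing

    pert_ptr = 0
    nominal = schedule.nominal_onsets if schedule is not None else np.array([])
    pert_onsets: list = []
    pert_sides: list = []
    pert_post1: list = []  # touchdown index of Post1 per perturbation

    def fill_stance(side: str, j: int) -> None:
        """Advect foot from its touchdown through toe-off (or session end)."""
        t0, t1 = td[j], min(toe[j], t_end)
        i0, i1 = int(np.ceil(t0 / DT)), int(np.floor(t1 / DT)) + 1
        i1 = min(i1, n)
        if i1 <= i0:
            return
        ts = t[i0:i1]
        stance_dur = toe[j] - td[j]
        phi = _stance_phi(ts - t0, stance_dur)
        vel = -belt[side][i0:i1] * phi
        # trapezoid from the exact touchdown instant (velocity is 0 at t0)
        x = np.empty(len(ts))
        x[0] = x_td[j] + (ts[0] - t0) * 0.5 * vel[0]
        if len(ts) > 1:
            x[1:] = x[0] + np.cumsum(0.5 * (vel[1:] + vel[:-1]) * DT)
        foot_x[side][i0:i1] = x
        foot_y[side][i0:i1] = state[side].y
        foot_z[side][i0:i1] = 0.0
        st = state[side]
        st.toe_time = toe[j]
        if toe[j] <= t_end:
            st.toe_pos = float(np.interp(toe[j], ts, x)) if len(ts) > 1 else x[0]
            st.toe_vel = float(-belt[side][min(i1 - 1, n - 1)])
        # hold stance to session end after the final toe-off of this foot
        if j + 2 >= n_td and i1 < n:
            vel_tail = -belt[side][i1 - 1: n]
            tail = x[-1] + np.cumsum(0.5 * (vel_tail[1:] + vel_tail[:-1]) * DT)
            foot_x[side][i1:n] = tail
            foot_y[side][i1:n] = state[side].y
        st.last_td = td[j]
        st.last_pos = x_td[j]

    def fill_swing(side: str, j: int, y_new: float) -> None:
        """Quintic swing from the previous toe-off to touchdown j."""
        st = state[side]
        t0, x0, w0 = st.toe_time, st.toe_pos, st.toe_vel
        t1 = td[j]
        i0, i1 = int(np.ceil(t0 / DT)), int(np.floor(t1 / DT)) + 1
        i1 = min(i1, n)
        if i1 <= i0:
            return
        s = (t[i0:i1] - t0) / (t1 - t0)
        foot_x[side][i0:i1] = _quintic(s, x0, w0 * (t1 - t0), x_td[j])
        smooth = s * s * (3.0 - 2.0 * s)
        foot_y[side][i0:i1] = st.y + (y_new - st.y) * smooth
        foot_z[side][i0:i1] = swing_h * np.sin(np.pi * s) ** 2
        st.y = y_new

    # initial segment: both feet in stance from t = 0 through their first toe-off
    for j in (0, 1):
        side = sides[j]
        x_td[j] = (L_v / 2.0 if j == 1 else 0.0)
        y0 = (W[j] / 2.0 if side == "L" else -W[j] / 2.0)
        state[side].y = y0
        # back-advect from the (fictitious) touchdown to t = 0
        t1 = min(toe[j], t_end)
        i1 = int(np.floor(t1 / DT)) + 1
        ts = t[:i1]
        vel = -belt[side][:i1]
        disp = np.concatenate([[0.0], np.cumsum(0.5 * (vel[1:] + vel[:-1]) * DT)])
        disp_at_td = np.interp(td[j], ts, disp)
        foot_x[side][:i1] = x_td[j] + disp - disp_at_td
        foot_y[side][:i1] = y0
        st = state[side]
        st.toe_time = toe[j]
        st.toe_pos = float(x_td[j] + np.interp(toe[j], ts, disp) - disp_at_td)
        st.toe_vel = float(-belt[side][min(i1 - 1, n - 1)])
        st.last_td = td[j]
        st.last_pos = x_td[j]

    anchor_mid = (x_td[0] + x_td[1]) / 2.0
    for j in range(2, n_td):
        side = sides[j]
        other = "L" if side == "R" else "R"
        # trailing-foot position at this touchdown (other foot is in stance)
        i_at = min(int(td[j] / DT), n - 2)
        frac = td[j] / DT - i_at
        x_trail = (1 - frac) * foot_x[other][i_at] + frac * foot_x[other][i_at + 1]
        raw = x_trail + L_draw[j]
        mid = (raw + x_trail) / 2.0
        x_td[j] = raw - STEP_REVERSION * (mid - anchor_mid)
        realized_len[j] = x_td[j] - x_trail
        y_new = W[j] / 2.0 if side == "L" else -W[j] / 2.0
        fill_swing(side, j, y_new)
        # scheduled perturbation during this swing?
        if (
            schedule is not None
            and pert_ptr < schedule.n_perturbations
            and schedule.sides[pert_ptr] == side
            and nominal[pert_ptr] <= td[j]
        ):
            t_lo = max(state[side].toe_time, nominal[pert_ptr])
            i_lo = int(np.ceil(t_lo / DT))
            i_hi = int(np.floor(td[j] / DT))
            if i_hi > i_lo:
                d = foot_x[side][i_lo:i_hi] - foot_x[other][i_lo:i_hi]
                cross = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
                if cross.size:
                    i_c = i_lo + cross[0]
                    frac = -d[cross[0]] / (d[cross[0] + 1] - d[cross[0]])
                    onset = t[i_c] + frac * DT
                    spec = schedule.spec(pert_ptr)
                    i_on = int(np.ceil(onset / DT))
                    ramp = (spec.speed_factor - 1.0) * speed / spec.acceleration
                    i_off = min(n, int(np.ceil((toe[j] + ramp + 0.2) / DT)))
                    belt[side][i_on:i_off] = belt_profile(
                        spec, speed, onset, toe[j], t[i_on:i_off]
                    )
                    pert_onsets.append(float(onset))
                    pert_sides.append(side)
                    pert_post1.append(j)
                    pert_ptr += 1
        fill_stance(side, j)

    if schedule is not None and pert_ptr < schedule.n_perturbations:
        raise ValueError(
            f"only {pert_ptr}/{schedule.n_perturbations} perturbations fit in "
            f"{duration:.0f} s; extend the session"
        )

    # --- truth MoS with perturbation-response deviations ---
    mos_truth = mos_base.copy()
    if resp is not None and pert_onsets:
        for k, p1 in enumerate(pert_post1, start=1):
            nxt = pert_post1[k] if k < len(pert_post1) else n_td
            horizon = min(n_td, nxt, p1 + max(12, resp.delay_steps + 10))
            n_aff = horizon - p1
            if n_aff <= 0:
                continue
            dev = response_deviations(resp, k, n_aff)
            if resp.response_sd > 0:
                dev = dev + rng.normal(0.0, resp.response_sd, n_aff)
            mos_truth[p1:horizon] += dev

    # --- inverse-designed CoM: XCoM target path through the MoS constraints ---
    knots_t = np.concatenate([[0.0], td[2:], [t_end + DT]])
    knots_c = np.concatenate(
        [[x_td[2] - mos_truth[2]], x_td[2:] - mos_truth[2:],
         [x_td[-1] - mos_truth[-1]]]
    )
    c = PchipInterpolator(knots_t, knots_c)(t)

    side_idx = np.searchsorted(td, t, side="right") - 1
    side_idx = np.clip(side_idx, 0, n_td - 1)
    is_left = sides[side_idx] == "L"
    v_stance = np.where(is_left, belt["L"], belt["R"])
    # When the belts differ (perturbations), the side switch at touchdown
    # would put a velocity jump into the CoM ODE that the downstream
    # filtered derivative cannot resolve at the event instant.  Blend the
    # stance-side speed over the last ~100 ms of swing so it reaches the
    # landing side's belt speed exactly at touchdown (C0, matching the
    # per-event belt lookup downstream).
    beta = min(0.12, 0.4 * T_v)
    for j in range(2, n_td):
        new, old = sides[j], sides[j - 1]
        i0 = max(0, int(np.ceil((td[j] - beta) / DT)))
        i1 = min(n, int(np.floor(td[j] / DT)) + 1)
        if i1 <= i0:
            continue
        seg_new = belt[new][i0:i1]
        seg_old = belt[old][i0:i1]
        if np.allclose(seg_new, seg_old):
            continue
        w = 0.5 * (1.0 - np.cos(np.pi * (t[i0:i1] - (td[j] - beta)) / beta))
        v_stance[i0:i1] = (1.0 - w) * seg_old + w * seg_new

    omega0 = np.sqrt(G / params.leg_length)
    alpha = np.exp(-omega0 * DT)
    u = c - v_stance / omega0
    um = 0.5 * (u[:-1] + u[1:])
    x0 = u[0]
    zi = np.array([alpha * x0])
    y_out, _ = lfilter([1.0 - alpha], [1.0, -alpha], um, zi=zi)
    x_com = np.concatenate([[x0], y_out])

    # --- assemble markers at 100 Hz ---
    sl = slice(None, None, MARKER_DECIM)
    t100 = t[sl]
    zu = params.leg_length / 1.06
    z_sacr, z_tro, z_c7 = 1.00 * zu, 0.90 * zu, 1.45 * zu
    xc = x_com[sl]
    nn = len(t100)

    def col(x, y, z):
        return np.column_stack(
            [np.broadcast_to(x, nn).copy(), np.full(nn, y), np.full(nn, z)]
        )

    markers = {
        "SACR": col(xc - 0.02, 0.0, z_sacr),
        "LTRO": col(xc + 0.02, +0.12, z_tro),
        "RTRO": col(xc + 0.02, -0.12, z_tro),
        "C7": col(xc + 0.02, 0.0, z_c7),
        "LHLX": np.column_stack([foot_x["L"][sl], foot_y["L"][sl], foot_z["L"][sl]]),
        "RHLX": np.column_stack([foot_x["R"][sl], foot_y["R"][sl], foot_z["R"][sl]]),
    }
    if params.marker_noise_sd > 0:
        for arr in markers.values():
            arr += rng.normal(0.0, params.marker_noise_sd, arr.shape)

    session = MarkerSession(
        time=t100,
        markers=markers,
        belt_speed_left=belt["L"],
        belt_speed_right=belt["R"],
        sampling_rate_markers=1.0 / (DT * MARKER_DECIM),
        sampling_rate_forces=1.0 / DT,
        trial_label=f"synthetic_v{speed:.2f}",
    )

    # --- forces: smoothed trapezoids per stance ---
    bw = params.body_mass * G
    forces = {"L": np.zeros(n), "R": np.zeros(n)}
    for j in range(n_td):
        side = sides[j]
        t0 = td[j] if j >= 2 else -1.0  # initial contacts are loaded from t=0
        t1 = toe[j]
        i0 = max(0, int(np.floor(t0 / DT)))
        i1 = min(n, int(np.ceil(t1 / DT)) + 1)
        if i1 <= i0:
            continue
        ts = t[i0:i1]
        rise = np.clip((ts - t0) / FORCE_RISE, 0.0, 1.0)
        fall = np.clip((t1 - ts) / FORCE_RISE, 0.0, 1.0)
        load = (0.5 - 0.5 * np.cos(np.pi * rise)) * (0.5 - 0.5 * np.cos(np.pi * fall))
        forces[side][i0:i1] = np.maximum(forces[side][i0:i1], bw * load)
    force_rec = ForceRecord(time=t.copy(), left=forces["L"], right=forces["R"],
                            rate=1.0 / DT)

    # --- truth containers (real steps only) ---
    ev = GaitEvents(
        touchdowns=[(float(td[j]), str(sides[j])) for j in range(2, n_td)],
        toeoffs=sorted(
            (float(toe[j]), str(sides[j])) for j in range(n_td) if toe[j] <= t_end
        ),
    )
    truth_mos = MosSeries(
        touchdown_times=td[2:].copy(),
        sides=[str(s) for s in sides[2:]],
        mos_ap=mos_truth[2:].copy(),
        trial_label=session.trial_label,
    )
    post1_of = {p1: k + 1 for k, p1 in enumerate(pert_post1)}
    steps = pd.DataFrame(
        {
            "touchdown_time": td[2:],
            "side": sides[2:],
            "step_time": np.diff(td)[1:],
            "step_length": realized_len[2:],
            "step_width": 0.5 * (W[2:] + W[1:-1]),
            "double_support_time": D[2:],
            "mos_truth": mos_truth[2:],
            "post1_of": [post1_of.get(j, 0) for j in range(2, n_td)],
        }
    )
    out = SyntheticSession(
        markers=session,
        forces=force_rec,
        truth_events=ev,
        truth_mos=truth_mos,
        truth_pert_times=pert_onsets,
        truth_pert_sides=pert_sides,
        truth_steps=steps,
        group_label=group_label,
        params=params,
        response=resp,
        schedule=schedule,
    )
    return out


def generate_unperturbed_trial(
    params: GaitModelParams, speed: float, duration: float = 60.0
) -> SyntheticSession:
    """Steady treadmill walking at one belt speed with ground truth."""
    return _generate(params, speed, duration)


def generate_perturbation_session(
    params: GaitModelParams,
    resp: PerturbationResponseParams,
    schedule: PerturbationSchedule | None = None,
    speed: float | None = None,
    group_label: str = "NoFalls",
) -> SyntheticSession:
    """Perturbation protocol: lead-in walking plus belt accelerations.

    ``speed`` defaults to the participant's reference walking speed (the
    protocol walks everyone at their stability-normalized speed; pass it
    here).  Session length is derived from the schedule plus a tail long
    enough for the Post1-8 steps of the final perturbation.
    """
    schedule = schedule or PerturbationSchedule.standard(params.seed)
    v = params.walking_speed if speed is None else speed
    duration = float(schedule.nominal_onsets[-1] + 25.0)
    return _generate(
        params, v, duration, resp=resp, schedule=schedule, group_label=group_label
    )


# ---------------------------------------------------------------------------
# Step-level cohort simulators (same response law, no marker synthesis)


def simulate_mos_table(
    n_falls: int,
    n_nofalls: int,
    resp_falls: PerturbationResponseParams,
    resp_nofalls: PerturbationResponseParams,
    pert_index: int = 1,
    base_mos: float = 0.055,
    between_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Long Base/Pre/Post1-8 MoS table for a two-group cohort.

    Draws each participant's baseline level (between-participant SD
    ``between_sd``), then applies the group's response law at perturbation
    ``pert_index``: Base is the mean of ten baseline steps, Pre one step,
    Post1-8 baseline plus the truth deviations plus response noise.  This is
    the same stochastic law the full marker-level generator embeds, at the
    step level.
    """
    rng = np.random.default_rng(seed)
    rows = []
    step_names = ["Base", "Pre"] + [f"Post{m}" for m in range(1, 9)]
    for group, n_g, resp in (
        ("Falls", n_falls, resp_falls),
        ("NoFalls", n_nofalls, resp_nofalls),
    ):
        dev = response_deviations(resp, pert_index, 8)
        for i in range(n_g):
            pid = f"{group}_{i:02d}"
            b = base_mos + rng.normal(0.0, between_sd)
            sd = resp.response_sd
            vals = [b + rng.normal(0.0, sd) / np.sqrt(10.0)]  # Base: mean of 10
            vals.append(b + rng.normal(0.0, sd))  # Pre
            vals.extend(b + dev + rng.normal(0.0, sd, 8))  # Post1-8
            for name, v in zip(step_names, vals):
                rows.append(
                    {"participant": pid, "group": group, "step": name, "mos": v}
                )
    return pd.DataFrame(rows)


def simulate_recovery_counts(
    n_participants: int,
    resp: PerturbationResponseParams,
    pert_indices: Sequence[int] = (1, 2, 9),
    tolerance: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery-step counts per participant x perturbation from the response law.

    Base is estimated (as in the pipeline) from ten noisy baseline steps;
    the Post1-8 curve is the truth deviation plus response noise; counts use
    the backward-scan rule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        for k in pert_indices:
            b = 0.055
            base_est = float(np.mean(b + rng.normal(0.0, resp.response_sd, 10)))
            post = b + response_deviations(resp, k, 8)
            if resp.response_sd > 0:
                post = post + rng.normal(0.0, resp.response_sd, 8)
            lp = LabeledPerturbation(
                onset_time=0.0, base_mos=base_est, pre_mos=b, post_mos=post,
                index=k,
            )
            rows.append(
                {
                    "participant": f"p{i:02d}",
                    "perturbation": k,
                    "recovery_steps": count_recovery_steps(lp, tolerance),
                }
            )
    return pd.DataFrame(rows)
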