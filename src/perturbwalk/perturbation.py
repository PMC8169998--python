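"""Belt perturbation profiles, trigger detection, step labeling, recovery counting.

The perturbation is a unilateral belt acceleration (3 m/s^2 by default) to a
ceiling of 180% of the baseline speed.  It is triggered when the hallux of
the to-be-perturbed limb passes the opposite hallux in the sagittal plane
(mid-swing), held until toe-off of the perturbed limb, then symmetrically
decelerated back to baseline.

Steps around each perturbation are labeled relative to its onset:

    Base   mean MoS of the 11th..2nd-last step before onset (10 steps)
    Pre    the final step before onset
    Post1-8  the first eight recovery steps after onset

and the number of recovery steps is 8 minus the length of the consecutive
run of post steps, counted backward from Post8, whose MoS lies within a
tolerance band (0.05 m) around Base.  A later out-of-band step therefore
invalidates earlier in-band steps; if Post8 itself is out of band the count
is 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stability import MosSeries

__all__ = [
    "PerturbationSpec",
    "LabeledPerturbation",
    "trigger_time",
    "belt_profile",
    "label_steps",
    "label_all",
    "count_recovery_steps",
    "labeled_to_frame",
]

RECOVERY_TOLERANCE = 0.05  # m, band around Base
N_POST = 8


@dataclass(frozen=True)
class PerturbationSpec:
    """One belt acceleration perturbation."""

    side: str  # 'L' or 'R'
    index: int = 1  # 1..10 within the protocol
    acceleration: float = 3.0  # m/s^2
    speed_factor: float = 1.8  # peak speed as a multiple of baseline

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.acceleration <= 0:
            raise ValueError("acceleration must be positive")
        if self.speed_factor <= 1:
            raise ValueError("speed_factor must exceed 1")


@dataclass
class LabeledPerturbation:
    """MoS of the Base/Pre/Post1-8 steps around one perturbation onset."""

    onset_time: float
    base_mos: float
    pre_mos: float
    post_mos: np.ndarray  # Post1..Post8
    side: str = ""
    index: int = 0
    recovery_steps: int = -1  # filled by count_recovery_steps

    def __post_init__(self) -> None:
        self.post_mos = np.asarray(self.post_mos, dtype=float)
        if self.post_mos.size != N_POST:
            raise ValueError(f"need exactly {N_POST} post values")


def trigger_time(session, side: str, search_window) -> float:
    """First instant in ``search_window`` where the perturbed-side hallux
    passes the opposite hallux in the AP direction (negative-to-positive
    crossing of their difference)."""
    t_lo, t_hi = search_window
    time = session.time
    if t_lo < time[0] or t_hi > time[-1]:
        raise ValueError("search window outside session support")
    pert = session.markers["LHLX" if side == "L" else "RHLX"][:, 0]
    opp = session.markers["RHLX" if side == "L" else "LHLX"][:, 0]
    diff = pert - opp
    mask = (time >= t_lo) & (time <= t_hi)
    idx = np.flatnonzero(mask)
    d = diff[idx]
    crossings = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
    if crossings.size == 0:
        raise ValueError(
            f"no hallux crossing of side {side} in window "
            f"[{t_lo:.2f}, {t_hi:.2f}] s"
        )
    i = idx[crossings[0]]
    t0, t1 = time[i], time[i + 1]
    d0, d1 = diff[i], diff[i + 1]
    frac = 0.0 if d1 == d0 else -d0 / (d1 - d0)
    return float(t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0))


def belt_profile(
    spec: PerturbationSpec,
    v0: float,
    t_trigger: float,
    t_toeoff: float,
    t: np.ndarray,
) -> np.ndarray:
    """Belt speed of the perturbed side evaluated at times ``t``.

    Ramp from ``v0`` at the configured acceleration, capped at
    ``speed_factor * v0``, held until toe-off, then symmetric deceleration
    back to ``v0``.
    """
    if v0 <= 0:
        raise ValueError("baseline speed must be positive")
    if t_toeoff <= t_trigger:
        raise ValueError("toe-off must follow the trigger")
    t = np.asarray(t, dtype=float)
    a = spec.acceleration
    vmax = spec.speed_factor * v0
    up = v0 + a * np.clip(t - t_trigger, 0.0, None)
    v_at_toeoff = min(vmax, v0 + a * (t_toeoff - t_trigger))
    down = v_at_toeoff - a * np.clip(t - t_toeoff, 0.0, None)
    v = np.where(t < t_toeoff, np.minimum(up, vmax), np.maximum(down, v0))
    v[t < t_trigger] = v0
    return v


def label_steps(mos: MosSeries, onset_time: float, n_base: int = 10) -> LabeledPerturbation:
    """Label the steps of ``mos`` around one perturbation onset.

    A touchdown exactly at the onset counts as Post1.  Requires at least
    ``n_base + 1`` steps before and 8 after the onset.
    """
    t = mos.touchdown_times
    pre_idx = np.flatnonzero(t < onset_time)
    post_idx = np.flatnonzero(t >= onset_time)
    if pre_idx.size < n_base + 1:
        raise ValueError(
            f"only {pre_idx.size} steps before onset; need {n_base + 1} "
            f"(10 baseline + 1 pre)"
        )
    if post_idx.size < N_POST:
        raise ValueError(
            f"only {post_idx.size} steps after onset; need {N_POST}"
        )
    base_block = mos.mos_ap[pre_idx[-(n_base + 1):-1]]
    lp = LabeledPerturbation(
        onset_time=onset_time,
        base_mos=float(np.mean(base_block)),
        pre_mos=float(mos.mos_ap[pre_idx[-1]]),
        post_mos=mos.mos_ap[post_idx[:N_POST]].copy(),
    )
    lp.recovery_steps = count_recovery_steps(lp)
    return lp


def count_recovery_steps(
    labeled: LabeledPerturbation, tolerance: float = RECOVERY_TOLERANCE
) -> int:
    """Recovery-step count via backward scan from Post8.

    k = length of the consecutive run of post steps, ending at Post8, with
    |post - Base| <= tolerance; the count is 8 - k (8 if Post8 itself is out
    of band).
    """
    post = np.asarray(labeled.post_mos, dtype=float)
    if post.size != N_POST or not np.all(np.isfinite(post)):
        raise ValueError("need 8 finite post values")
    in_band = np.abs(post - labeled.base_mos) <= tolerance
    k = 0
    for ok in in_band[::-1]:
        if not ok:
            break
        k += 1
    return N_POST - k


def label_all(
    mos: MosSeries,
    onsets,
    sides=None,
    tolerance: float = RECOVERY_TOLERANCE,
) -> list:
    """Label every perturbation of a session; returns LabeledPerturbation list."""
    out = []
    for k, onset in enumerate(onsets, start=1):
        lp = label_steps(mos, float(onset))
        lp.index = k
        if sides is not None:
            lp.side = sides[k - 1]
        lp.recovery_steps = count_recovery_steps(lp, tolerance)
        out.append(lp)
    return out


def labeled_to_frame(labeled, participant: str = "") -> pd.DataFrame:
    """Tidy one-row-per-perturbation table (base, pre, post1-8, recovery)."""
    rows = []
    for lp in labeled:
        row = {
            "participant": participant,
            "perturbation": lp.index,
            "side": lp.side,
            "onset_time": lp.onset_time,
            "base": lp.base_mos,
            "pre": lp.pre_mos,
            "recovery_steps": lp.recovery_steps,
        }
        for m in range(N_POST):
            row[f"post{m + 1}"] = lp.post_mos[m]
        rows.append(row)
    return pd.DataFrame(rows)
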