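"""Trigger detection, belt profiles, step labeling and recovery counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from perturbwalk import (
    LabeledPerturbation,
    PerturbationSpec,
    belt_profile,
    count_recovery_steps,
    label_all,
    label_steps,
    trigger_time,
)
from perturbwalk.io import REQUIRED_MARKERS, MarkerSession
from perturbwalk.stability import MosSeries


def _crossing_session(t_cross=5.0, rate=100.0, n=1000):
    time = np.arange(n) / rate
    markers = {m: np.zeros((n, 3)) for m in REQUIRED_MARKERS}
    markers["RHLX"][:, 0] = 0.1 * (time - t_cross)  # crosses zero at t_cross
    markers["LHLX"][:, 0] = 0.0
    return MarkerSession(
        time=time,
        markers=markers,
        belt_speed_left=np.full(n, 1.0),
        belt_speed_right=np.full(n, 1.0),
        sampling_rate_forces=rate,
    )


def test_trigger_constructed_crossing():
    s = _crossing_session(5.0)
    t = trigger_time(s, "R", (4.0, 6.0))
    assert t == pytest.approx(5.0, abs=0.011)  # within one frame


def test_trigger_no_crossing_errors():
    s = _crossing_session(5.0)
    s.markers["RHLX"][:, 0] = -1.0  # always behind
    with pytest.raises(ValueError, match="no hallux crossing"):
        trigger_time(s, "R", (4.0, 6.0))


def test_trigger_matches_generator_onsets(noiseless_pert_session):
    s = noiseless_pert_session
    for onset, side in zip(s.truth_pert_times, s.truth_pert_sides):
        t = trigger_time(s.markers, side, (onset - 1.0, onset + 0.5))
        assert abs(t - onset) < 0.020


def test_belt_profile_ramp_kinematics():
    spec = PerturbationSpec(side="R", acceleration=3.0, speed_factor=1.8)
    t = np.arange(0.0, 3.0, 1e-3)
    v = belt_profile(spec, 1.0, 0.5, 1.5, t)
    assert v.max() == pytest.approx(1.8, abs=1e-9)
    # peak reached after 0.8 / 3 s of ramp
    t_peak = t[np.argmax(v >= 1.8 - 1e-12)]
    assert t_peak - 0.5 == pytest.approx(0.8 / 3.0, abs=2e-3)
    # slope of the ramp is the configured acceleration
    ramp = (t > 0.52) & (t < 0.7)
    slope = np.polyfit(t[ramp], v[ramp], 1)[0]
    assert slope == pytest.approx(3.0, rel=1e-6)
    # symmetric deceleration back to baseline after toe-off
    assert v[-1] == pytest.approx(1.0)


def test_belt_profile_degenerate_cap():
    spec = PerturbationSpec(side="L", speed_factor=1.0 + 1e-9)
    t = np.linspace(0, 2, 500)
    v = belt_profile(spec, 1.2, 0.5, 1.0, t)
    assert np.allclose(v, 1.2, atol=1e-6)


def test_belt_profile_peak_ratio_over_random_baselines():
    spec = PerturbationSpec(side="L")
    rng = np.random.default_rng(0)
    t = np.arange(0, 4, 1e-3)
    for v0 in rng.uniform(0.8, 1.6, 20):
        v = belt_profile(spec, v0, 0.5, 2.0, t)  # stance longer than ramp
        assert v.max() / v0 == pytest.approx(1.8, abs=1e-9)
    # short stance: cap not reached, ratio stays below 1.8
    v = belt_profile(spec, 1.0, 0.5, 0.6, t)
    assert v.max() / 1.0 < 1.8


def test_belt_profile_rejects_bad_ordering():
    with pytest.raises(ValueError):
        belt_profile(PerturbationSpec(side="L"), 1.0, 2.0, 1.0, np.arange(3.0))


# --- labeling ---


def _mos_series(values, t0=0.0, dt=0.5):
    n = len(values)
    return MosSeries(
        touchdown_times=t0 + dt * np.arange(n),
        sides=["L", "R"] * (n // 2 + 1),
        mos_ap=np.asarray(values, float),
    )


def test_label_constant_baseline():
    mos = _mos_series([0.07] * 12 + [0.0] * 8)
    lp = label_steps(mos, onset_time=5.9)
    assert lp.base_mos == pytest.approx(0.07)
    assert lp.pre_mos == pytest.approx(0.07)


def test_label_indexing_against_hand_count():
    # 12 pre steps valued 1..12 (steps -12..-1), 8 post steps
    mos = _mos_series(list(range(1, 13)) + [99] * 8)
    lp = label_steps(mos, onset_time=5.9)  # onset between steps 12 and 13
    assert lp.base_mos == pytest.approx(np.mean(np.arange(2, 12)))  # 6.5
    assert lp.pre_mos == pytest.approx(12.0)
    assert np.allclose(lp.post_mos, 99.0)


def test_touchdown_at_onset_counts_as_post1():
    mos = _mos_series(list(range(1, 13)) + [50] + [99] * 7)
    lp = label_steps(mos, onset_time=6.0)  # exactly at step 13's touchdown
    assert lp.post_mos[0] == pytest.approx(50.0)
    assert lp.pre_mos == pytest.approx(12.0)


def test_label_insufficient_steps_errors():
    mos = _mos_series([0.1] * 10)
    with pytest.raises(ValueError, match="before onset"):
        label_steps(mos, onset_time=4.9)
    mos2 = _mos_series([0.1] * 15)
    with pytest.raises(ValueError, match="after onset"):
        label_steps(mos2, onset_time=6.4)


def test_labeled_posts_match_generator_truth(noiseless_pert_session, pert_session_mos):
    s = noiseless_pert_session
    labeled = label_all(pert_session_mos, s.truth_pert_times, sides=s.truth_pert_sides)
    base = s.params.true_mos(s.params.walking_speed)
    from perturbwalk import response_deviations

    for k, lp in enumerate(labeled, start=1):
        truth = base + response_deviations(s.response, k, 8)
        assert np.allclose(lp.post_mos, truth, atol=0.005)


# --- recovery counting ---


def _labeled(post, base=0.0):
    return LabeledPerturbation(onset_time=0.0, base_mos=base, pre_mos=base, post_mos=post)


def _brute_force_count(post, base, tol):
    """Independent oracle: scan backward from Post8 by explicit iteration."""
    k = 0
    for value in reversed(list(post)):
        if abs(value - base) <= tol:
            k += 1
        else:
            break
    return 8 - k


def test_all_in_band_is_zero():
    assert count_recovery_steps(_labeled([0.01] * 8)) == 0


def test_partial_recovery_count():
    post = [0.2, 0.2, 0.2, 0.2, 0.0, 0.0, 0.0, 0.0]
    assert count_recovery_steps(_labeled(post)) == 4


def test_post8_out_of_band_forces_eight():
    post = [0.0] * 7 + [0.2]
    assert count_recovery_steps(_labeled(post)) == 8


def test_recovery_counts_equal_brute_force_scan():
    rng = np.random.default_rng(42)
    for _ in range(2000):
        base = rng.normal(0.05, 0.02)
        post = base + rng.normal(0.0, 0.08, 8)
        lp = _labeled(post, base)
        assert count_recovery_steps(lp) == _brute_force_count(post, base, 0.05)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    post=hst.lists(hst.floats(-0.3, 0.3), min_size=8, max_size=8),
    tol_lo=hst.floats(0.01, 0.05),
    tol_extra=hst.floats(0.0, 0.1),
)
def test_recovery_count_monotone_in_tolerance(post, tol_lo, tol_extra):
    lp = _labeled(post)
    wide = count_recovery_steps(lp, tol_lo + tol_extra)
    narrow = count_recovery_steps(lp, tol_lo)
    assert wide <= narrow


def test_adaptation_reduces_recovery_steps_in_cohort():
    """Paired reduction from perturbation 1 to 9 is detectable when the
    response adapts, and null when it does not."""
    from scipy.stats import wilcoxon

    from perturbwalk import PerturbationResponseParams, simulate_recovery_counts

    adapt = PerturbationResponseParams(adaptation_rate=0.25)
    df = simulate_recovery_counts(24, adapt, pert_indices=(1, 9), seed=11)
    wide = df.pivot_table(index="participant", columns="perturbation",
                          values="recovery_steps")
    diff = wide[1] - wide[9]
    assert wilcoxon(diff, alternative="greater").pvalue < 0.05
    assert diff.mean() > 0
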