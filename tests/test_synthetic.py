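"""Generator contracts: determinism, configured-vs-realized, response law."""

import numpy as np
import pytest

from perturbwalk import (
    GaitModelParams,
    PerturbationResponseParams,
    PerturbationSchedule,
    generate_perturbation_session,
    generate_unperturbed_trial,
    response_deviations,
)


def test_same_seed_bit_identical():
    p = GaitModelParams(seed=9)
    a = generate_unperturbed_trial(p, 1.3, 20.0)
    b = generate_unperturbed_trial(p, 1.3, 20.0)
    for m in a.markers.markers:
        assert np.array_equal(a.markers.markers[m], b.markers.markers[m])
    assert np.array_equal(a.forces.left, b.forces.left)
    assert a.truth_events.touchdowns == b.truth_events.touchdowns
    assert np.array_equal(a.truth_mos.mos_ap, b.truth_mos.mos_ap)


def test_different_seed_differs():
    a = generate_unperturbed_trial(GaitModelParams(seed=1), 1.3, 20.0)
    b = generate_unperturbed_trial(GaitModelParams(seed=2), 1.3, 20.0)
    assert not np.array_equal(a.markers.markers["LHLX"], b.markers.markers["LHLX"])


def test_zero_cv_gives_equal_step_times(noiseless_trial):
    steps = noiseless_trial.truth_steps
    assert np.ptp(steps["step_time"].to_numpy()) < 1e-9


def test_realized_step_length_within_three_se():
    p = GaitModelParams(step_length_mean=0.65, walking_speed=1.3,
                        step_time_mean=0.5, seed=5)
    s = generate_unperturbed_trial(p, 1.3, 40.0)
    lengths = s.truth_steps["step_length"].to_numpy()
    assert len(lengths) >= 50
    se = 0.65 * p.step_length_cv / np.sqrt(len(lengths))
    assert abs(lengths.mean() - 0.65) < 3 * se


@pytest.mark.parametrize("cv", [0.0, 0.02, 0.05])
def test_configured_vs_realized_step_time_cv(cv):
    p = GaitModelParams(step_time_cv=cv, seed=17)
    s = generate_unperturbed_trial(p, 1.3, 70.0)
    times = s.truth_steps["step_time"].to_numpy()
    assert len(times) >= 100
    realized = times.std(ddof=1) / times.mean()
    if cv == 0:
        assert realized < 1e-9
    else:
        assert realized == pytest.approx(cv, rel=0.30)


def test_monotone_mos_over_speed_range(noiseless_params):
    means = []
    for v in np.arange(0.4, 1.81, 0.2):
        s = generate_unperturbed_trial(noiseless_params, float(v), 15.0)
        means.append(s.truth_mos.mos_ap.mean())
    assert np.all(np.diff(means) < 0)


def test_force_exceeds_threshold_exactly_during_stance(noiseless_trial):
    s = noiseless_trial
    f = s.forces.as_dict()
    t = s.forces.time
    for side in "LR":
        loaded = f[side] >= 50.0
        for td, ev_side in s.truth_events.touchdowns:
            if ev_side != side:
                continue
            later = s.truth_events.to_times(side)
            later = later[later >= td]
            if later.size == 0:
                continue  # final stance runs past the session end
            toe = float(later[0])
            inside = (t > td + 0.010) & (t < toe - 0.010)
            outside_before = (t > td - 0.3) & (t < td - 0.010)
            assert loaded[inside].all()
            assert not loaded[outside_before].any()


def test_stance_hallux_moves_backward_at_belt_speed(noiseless_trial):
    s = noiseless_trial
    x = s.markers.markers["LHLX"][:, 0]
    t = s.markers.time
    td = s.truth_events.td_times("L")[3]
    toe = s.truth_events.toeoff_after(td, "L")
    mid = (t > td + 0.3) & (t < toe - 0.35)  # steady advection window
    v = np.gradient(x, t[1] - t[0])[mid]
    assert np.allclose(v, -1.3, atol=0.02)


def test_invalid_inputs_rejected():
    p = GaitModelParams()
    with pytest.raises(ValueError, match="speed"):
        generate_unperturbed_trial(p, 3.0, 30.0)
    with pytest.raises(ValueError, match="duration"):
        generate_unperturbed_trial(p, 1.3, 5.0)
    with pytest.raises(ValueError):
        GaitModelParams(double_support_fraction=0.6)
    with pytest.raises(ValueError):
        GaitModelParams(mos_speed_coeffs=(0.0, 0.16, 0.0))  # increasing
    with pytest.raises(ValueError):
        PerturbationResponseParams(recovery_rate=1.5)


# --- perturbation sessions ---


def test_truth_deviation_closed_form():
    resp = PerturbationResponseParams(
        initial_mos_deviation=-0.12, recovery_rate=0.5,
        adaptation_rate=0.0, response_sd=0.0, delay_steps=0,
    )
    dev = response_deviations(resp, 1, 4)
    assert np.allclose(dev, [-0.12, -0.06, -0.03, -0.015])


def test_no_adaptation_equal_deviation_every_perturbation():
    resp = PerturbationResponseParams(adaptation_rate=0.0, response_sd=0.0)
    first = [response_deviations(resp, k, 8)[0] for k in range(1, 11)]
    assert np.ptp(first) == 0.0


def test_full_adaptation_baseline_from_second_perturbation():
    resp = PerturbationResponseParams(adaptation_rate=1.0, response_sd=0.0)
    assert response_deviations(resp, 1, 3)[0] != 0.0
    for k in range(2, 11):
        assert np.allclose(response_deviations(resp, k, 8), 0.0)


def test_delay_steps_hold_the_deviation():
    resp = PerturbationResponseParams(
        initial_mos_deviation=-0.1, recovery_rate=0.5,
        adaptation_rate=0.0, response_sd=0.0, delay_steps=2,
    )
    dev = response_deviations(resp, 1, 5)
    assert np.allclose(dev, [-0.1, -0.1, -0.1, -0.05, -0.025])


def test_session_invariants_and_sides(noiseless_pert_session):
    s = noiseless_pert_session
    s.validate()  # alternation, gaps within 30-90 s
    assert s.truth_pert_sides == ["R"] + ["L"] * 8 + ["R"]
    assert len(s.truth_pert_times) == 10


def test_session_truth_mos_embeds_response(noiseless_pert_session):
    s = noiseless_pert_session
    steps = s.truth_steps
    base = s.params.true_mos(s.params.walking_speed)
    for k in range(1, 11):
        idx = steps.index[steps["post1_of"] == k]
        assert len(idx) == 1
        i = int(idx[0])
        truth = base + response_deviations(s.response, k, 8)
        assert np.allclose(steps["mos_truth"].to_numpy()[i : i + 8], truth, atol=1e-12)


def test_perturbed_belt_follows_commanded_ramp(noiseless_pert_session):
    s = noiseless_pert_session
    sched = s.schedule
    bt = s.markers.belt_time
    v0 = s.params.walking_speed
    for onset, side in zip(s.truth_pert_times, s.truth_pert_sides):
        belt = s.markers.belt_speed_left if side == "L" else s.markers.belt_speed_right
        win = (bt >= onset) & (bt <= onset + 3.0)
        assert belt[win].max() == pytest.approx(sched.speed_factor * v0, abs=1e-6)
        ramp = (bt >= onset + 0.02) & (bt <= onset + 0.15)
        slope = np.polyfit(bt[ramp], belt[ramp], 1)[0]
        assert slope == pytest.approx(sched.acceleration, rel=1e-3)


def test_schedule_validation():
    with pytest.raises(ValueError):
        PerturbationSchedule(sides=("R", "L"), gaps=(30.0, 40.0))
    with pytest.raises(ValueError):
        PerturbationSchedule(sides=("X",) * 10, gaps=(60.0,) * 9)


def test_session_round_trip_to_disk(tmp_path, noiseless_trial):
    from perturbwalk.io import read_forces, read_session

    noiseless_trial.save(tmp_path / "trial")
    back = read_session(tmp_path / "trial")
    assert back.n_frames == noiseless_trial.markers.n_frames
    forces = read_forces(tmp_path / "trial" / "forces.csv")
    assert forces.rate == pytest.approx(1000.0, rel=1e-3)
    assert np.allclose(
        back.markers["LHLX"], noiseless_trial.markers.markers["LHLX"], atol=1e-5
    )
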