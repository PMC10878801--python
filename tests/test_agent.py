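"""Generative walker: evidence integrator, pause law, decisions, full trials."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

from pauseloop import (
    AgentConfig,
    AgentState,
    Behaviour,
    ConfigurationError,
    GatingMode,
    MotionDetectorConfig,
    SignalDirection,
    StimulusConfig,
    active_flags,
    detect_motion,
    run_trial,
)
from pauseloop.agent import (
    TrackballTrace,
    choose_bout_at_pause_end,
    expected_pause_duration,
    pause_hazard,
    sample_baseline_pause,
    baseline_pause_survival,
    step_agent,
    turn_probability,
    update_evidence,
)

FORWARD = SignalDirection.FORWARD
BACKWARD = SignalDirection.BACKWARD


# ---------------------------------------------------------------------------
# evidence integrator
# ---------------------------------------------------------------------------

def test_inactive_stimulus_is_a_fixed_point(agent_config):
    E = update_evidence(0.0, False, BACKWARD, Behaviour.PAUSE, 1 / 120, agent_config)
    assert E == 0.0


def test_evidence_steady_state_matches_closed_form(agent_config):
    """Constant BACKWARD drive during an indefinite pause converges to
    -w_pause * tau_e, following the closed-form relaxation of the linear ODE."""
    dt = 1 / 120
    cfg = agent_config
    E = 0.0
    target = -cfg.w_pause * cfg.evidence_tau
    for k in range(1, 120 * 40 + 1):
        E = update_evidence(E, True, BACKWARD, Behaviour.PAUSE, dt, cfg)
        if k % 1200 == 0:
            t = k * dt
            closed = target * (1 - np.exp(-t / cfg.evidence_tau))
            assert E == pytest.approx(closed, abs=5e-3)
    assert E == pytest.approx(target, rel=1e-3)


def test_walk_weight_used_while_walking():
    cfg = AgentConfig(w_pause=1.0, w_walk=0.25)
    dt = 1 / 120
    e_pause = update_evidence(0.0, True, FORWARD, Behaviour.PAUSE, dt, cfg)
    e_walk = update_evidence(0.0, True, FORWARD, Behaviour.WALK_FORWARD, dt, cfg)
    assert e_pause == pytest.approx(dt * 1.0)
    assert e_walk == pytest.approx(dt * 0.25)


# ---------------------------------------------------------------------------
# pause law
# ---------------------------------------------------------------------------

def test_hazard_unmodulated_for_non_opposite_evidence(agent_config):
    h0 = (agent_config.pause_exponent - 1) / (1.0 + agent_config.pause_t_min)
    assert pause_hazard(1.0, 0.0, agent_config) == pytest.approx(h0)
    assert pause_hazard(1.0, 2.0, agent_config) == pytest.approx(h0)
    boosted = pause_hazard(1.0, -1.0, agent_config)
    assert boosted == pytest.approx(h0 * (1 + agent_config.pause_shortening_gain))
    assert np.isinf(pause_hazard(agent_config.pause_t_max, 0.0, agent_config))


def test_beta_zero_disables_modulation():
    cfg = AgentConfig(pause_shortening_gain=0.0)
    assert pause_hazard(0.7, -5.0, cfg) == pause_hazard(0.7, 0.0, cfg)


def test_baseline_sampler_median_alpha_two(rng):
    """At alpha=2, t_min=0.5 the analytic survival is 0.5 at t = t_min, so the
    sampled median must be 0.5 s (Monte-Carlo check over 1e5 draws)."""
    cfg = AgentConfig(pause_exponent=2.0, pause_t_min=0.5)
    draws = sample_baseline_pause(cfg, rng, 100_000)
    # 3 s.e. of the sample median: 1 / (2 f(m) sqrt(n)), f(0.5) = 0.5
    assert np.median(draws) == pytest.approx(0.5, abs=0.01)


def test_baseline_sampler_matches_analytic_survival(agent_config, rng):
    from _helpers import ks_distance_capped_pause

    draws = sample_baseline_pause(agent_config, rng, 100_000)
    assert ks_distance_capped_pause(draws, agent_config) < 0.01


def test_expected_pause_duration_matches_quadrature(agent_config):
    num, _ = integrate.quad(
        lambda t: baseline_pause_survival(t, agent_config),
        0,
        agent_config.pause_t_max,
    )
    assert expected_pause_duration(agent_config) == pytest.approx(num, rel=1e-8)
    cfg2 = AgentConfig(pause_exponent=2.0)
    num2, _ = integrate.quad(
        lambda t: baseline_pause_survival(t, cfg2), 0, cfg2.pause_t_max
    )
    assert expected_pause_duration(cfg2) == pytest.approx(num2, rel=1e-8)


# ---------------------------------------------------------------------------
# pause-end decision
# ---------------------------------------------------------------------------

def test_turn_probability_limits(agent_config):
    assert turn_probability(0.0, agent_config) == pytest.approx(0.05, abs=1e-3)
    assert turn_probability(-50.0, agent_config) == pytest.approx(1.0, abs=1e-6)
    cfg = AgentConfig(turn_gain=0.0, turn_bias=-2.944)
    p0 = turn_probability(0.0, cfg)
    assert turn_probability(-10.0, cfg) == p0  # gain off: history-independent


def test_baseline_turn_fraction_empirical(agent_config, rng):
    n = 10_000
    kinds = [
        choose_bout_at_pause_end(0.0, agent_config, rng)[0] for _ in range(n)
    ]
    frac = np.mean([k is Behaviour.WALK_TURN for k in kinds])
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(frac - 0.05004) < 3 * se


def test_walk_durations_exponential_mean(agent_config, rng):
    durs = np.array(
        [choose_bout_at_pause_end(0.0, agent_config, rng)[1] for _ in range(5000)]
    )
    se = agent_config.mean_walk_duration / np.sqrt(durs.size)
    assert abs(durs.mean() - agent_config.mean_walk_duration) < 3 * se


# ---------------------------------------------------------------------------
# single-step dynamics
# ---------------------------------------------------------------------------

def test_step_agent_silent_while_paused(rng):
    cfg = AgentConfig(sensor_noise=0.0)
    state = AgentState(behaviour=Behaviour.PAUSE)
    _, sample = step_agent(state, cfg, FORWARD, False, cfg.dt, rng)
    assert sample == (0.0, 0.0, 0.0)


def test_step_agent_forward_increment_exact(rng):
    cfg = AgentConfig(sensor_noise=0.0)
    state = AgentState(behaviour=Behaviour.WALK_FORWARD, walk_bout_end=10.0)
    _, sample = step_agent(state, cfg, FORWARD, False, cfg.dt, rng)
    assert sample[0] == pytest.approx(cfg.walk_speed / cfg.sample_rate, rel=1e-12)
    assert sample[1] == 0.0


def test_step_agent_turn_yaw_increment(rng):
    cfg = AgentConfig(sensor_noise=0.0)
    state = AgentState(
        behaviour=Behaviour.WALK_TURN, walk_bout_end=10.0, turn_sign=-1
    )
    _, sample = step_agent(state, cfg, FORWARD, False, cfg.dt, rng)
    assert sample[1] == pytest.approx(-cfg.turn_yaw_rate / cfg.sample_rate)


def test_step_agent_rejects_mismatched_dt(rng, agent_config):
    with pytest.raises(ConfigurationError):
        step_agent(AgentState(), agent_config, FORWARD, False, 0.01, rng)


# ---------------------------------------------------------------------------
# whole-trial simulation
# ---------------------------------------------------------------------------

def trial(mode=GatingMode.OPEN_LOOP, direction=FORWARD, seed=0, duration=60.0,
          agent=None, **stim_kwargs):
    agent = agent or AgentConfig()
    stim = StimulusConfig(signal_direction=direction, **stim_kwargs)
    return run_trial(agent, stim, mode, duration, seed=seed)


def test_trial_determinism():
    a = trial(seed=5)
    b = trial(seed=5)
    np.testing.assert_array_equal(a.trace.d_forward, b.trace.d_forward)
    np.testing.assert_array_equal(a.trace.behaviour, b.trace.behaviour)
    np.testing.assert_array_equal(a.trace.stimulus_active, b.trace.stimulus_active)
    c = trial(seed=6)
    assert not np.array_equal(a.trace.d_forward, c.trace.d_forward)


def test_trace_satisfies_gating_and_evidence_recurrences():
    """The trial kernel must agree, sample for sample, with the standalone
    gating operations and the evidence-update rule applied to its own logs."""
    for mode in GatingMode:
        r = trial(mode=mode, direction=BACKWARD, seed=3, duration=30.0)
        tr = r.trace
        det = r.detector_config
        moving = detect_motion(tr.magnitudes(), det)
        np.testing.assert_array_equal(moving, r.moving)
        np.testing.assert_array_equal(
            tr.stimulus_active, active_flags(mode, moving, latency=1)
        )
        # evidence recurrence with the logged behaviour and active flags
        cfg = r.agent_config
        w = np.where(tr.behaviour == 0, cfg.w_pause, cfg.w_walk)
        drive = w * (-1.0) * tr.stimulus_active
        expected_next = tr.evidence + cfg.dt * (
            -tr.evidence / cfg.evidence_tau + drive
        )
        np.testing.assert_allclose(
            tr.evidence[1:], expected_next[:-1], rtol=0, atol=1e-12
        )


def test_bout_alternation_no_direct_walk_kind_switches():
    r = trial(mode=GatingMode.OUT_OF_PHASE, direction=BACKWARD, seed=11,
              duration=120.0)
    beh = r.trace.behaviour
    trans = set(zip(beh[:-1][beh[:-1] != beh[1:]], beh[1:][beh[:-1] != beh[1:]]))
    for a, b in trans:
        # every change of behaviour passes through PAUSE (code 0)
        assert a == 0 or b == 0


def test_open_loop_gate_always_active():
    r = trial(mode=GatingMode.OPEN_LOOP, seed=2, duration=10.0)
    assert r.trace.stimulus_active.all()
    log = r.gate_log()
    assert log["active"].all()
    assert (log["mode"] == "OPEN_LOOP").all()


def test_no_stimulus_walking_fraction_matches_renewal_ratio():
    """With no perceptual drive the walker is an alternating renewal process,
    so the walking fraction converges to tau_w / (tau_w + E[pause])."""
    cfg = AgentConfig(w_pause=0.0, w_walk=0.0)
    expected = cfg.mean_walk_duration / (
        cfg.mean_walk_duration + expected_pause_duration(cfg)
    )
    wfs = [
        trial(mode=GatingMode.OPEN_LOOP, seed=s, duration=1000.0, agent=cfg)
        .trace.true_walking_fraction()
        for s in range(10)
    ]
    se = np.std(wfs, ddof=1) / np.sqrt(len(wfs))
    assert abs(np.mean(wfs) - expected) < max(3 * se, 0.01)


def test_simulated_pause_durations_follow_baseline_law():
    """Ground-truth pause durations from hazard thinning at dt=1/120 match the
    analytic survival (KS distance bounded by the discretization error)."""
    cfg = AgentConfig(w_pause=0.0, w_walk=0.0, sensor_noise=0.0)
    pauses = np.concatenate(
        [
            trial(seed=s, duration=3000.0, agent=cfg)
            .trace.true_bout_durations(Behaviour.PAUSE)
            for s in range(10)
        ]
    )
    assert pauses.size > 3000
    from _helpers import ks_distance_capped_pause

    assert ks_distance_capped_pause(pauses, cfg) < 0.03


def test_out_of_phase_backward_shortens_pauses_over_paired_seeds():
    """Opposite-direction stimuli seen during pauses must shorten them and
    raise the walking fraction, on average over 50 paired seeds."""
    rows = []
    for s in range(50):
        f = trial(mode=GatingMode.OUT_OF_PHASE, direction=FORWARD, seed=s)
        b = trial(mode=GatingMode.OUT_OF_PHASE, direction=BACKWARD, seed=s)
        fp = f.trace.true_bout_durations(Behaviour.PAUSE)
        bp = b.trace.true_bout_durations(Behaviour.PAUSE)
        rows.append(
            (
                fp.mean() if fp.size else np.nan,
                bp.mean() if bp.size else np.nan,
                f.trace.true_walking_fraction(),
                b.trace.true_walking_fraction(),
            )
        )
    fp, bp, fw, bw = np.nanmean(np.array(rows), axis=0)
    assert bp < fp
    assert bw > fw


def test_evidence_magnitude_out_of_phase_dominates_in_phase():
    for s in range(5):
        out = trial(mode=GatingMode.OUT_OF_PHASE, direction=BACKWARD, seed=s)
        inp = trial(mode=GatingMode.IN_PHASE, direction=BACKWARD, seed=s)
        assert (
            np.abs(out.trace.evidence).mean() >= np.abs(inp.trace.evidence).mean()
        )


def test_in_phase_evidence_bounded_by_latency_leak():
    """With w_walk=0 the only drive in IN_PHASE comes from the controller
    latency window at pause onsets: (debounce_off + 1) samples of w_pause.
    The evidence magnitude must stay below a few such quanta while an
    OUT_OF_PHASE trial saturates near w_pause * tau_e."""
    det = MotionDetectorConfig()
    leak_quantum = (det.debounce_off + 1) / 120.0 * 1.0
    r_in = trial(mode=GatingMode.IN_PHASE, direction=BACKWARD, seed=8,
                 duration=120.0)
    assert np.abs(r_in.trace.evidence).max() < 4 * leak_quantum
    r_out = trial(mode=GatingMode.OUT_OF_PHASE, direction=BACKWARD, seed=8,
                  duration=120.0)
    assert np.abs(r_out.trace.evidence).max() > 1.0


def test_trace_csv_roundtrip(tmp_path):
    r = trial(seed=4, duration=5.0)
    path = tmp_path / "trace.csv"
    r.trace.to_csv(path)
    back = TrackballTrace.from_csv(path)
    assert back.sample_rate == pytest.approx(r.trace.sample_rate)
    np.testing.assert_allclose(back.d_forward, r.trace.d_forward, atol=1e-12)
    np.testing.assert_array_equal(back.behaviour, r.trace.behaviour)
    np.testing.assert_array_equal(back.stimulus_active, r.trace.stimulus_active)


def test_config_invariants_rejected():
    with pytest.raises(ConfigurationError):
        AgentConfig(w_pause=0.1, w_walk=0.5)
    with pytest.raises(ConfigurationError):
        AgentConfig(pause_exponent=1.0)
    with pytest.raises(ConfigurationError):
        AgentConfig(pause_t_max=0.1)
    with pytest.raises(ConfigurationError):
        run_trial(
            AgentConfig(sample_rate=60.0), StimulusConfig(),
            GatingMode.OPEN_LOOP, 1.0, seed=0,
        )
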