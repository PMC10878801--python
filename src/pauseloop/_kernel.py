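"""Compiled inner loop of the closed-loop trial simulation.

One call simulates a whole trial at the shared sensor/frame clock.  All
randomness is pre-drawn by the caller into flat "tapes" (noise samples,
pause-termination uniforms, turn-decision uniforms, walk-bout durations), so
the kernel itself is a deterministic function of its arguments and trials are
exactly reproducible from a seed.

Per-sample order of operations (sample t, step dt = 1/rate):

1. log state: behaviour, stimulus-active flag, evidence
2. emit sensor increments (forward/yaw/lateral + Gaussian sensor noise)
3. update the threshold+debounce motion detector on the noisy magnitude
4. gate the *next* frame from the detected state (one-sample latency)
5. leaky-integrator evidence update driven by the *current* frame
6. advance bout clocks: pauses terminate by hazard thinning
   (probability min(1, h*dt) per step, hard cap at t_max); walk bouts end at
   their pre-drawn scheduled duration.
"""

import numpy as np
from numba import njit

# behaviour codes shared with pauseloop.agent
PAUSE = 0
WALK_FORWARD = 1
WALK_TURN = 2

# gating mode codes shared with pauseloop.gating
OPEN_LOOP = 0
IN_PHASE = 1
OUT_OF_PHASE = 2


@njit(cache=False)
def simulate_trial_kernel(
    n,
    dt,
    t_min,
    alpha,
    t_max,
    v_walk,
    omega_turn,
    w_pause,
    w_walk,
    tau_e,
    beta,
    k_turn,
    b_turn,
    turn_sign,
    signal_sign,
    mode_code,
    threshold,
    debounce_on,
    debounce_off,
    noise_fwd,
    noise_yaw,
    noise_lat,
    u_pause,
    u_turn,
    walk_durations,
):
    d_fwd = np.empty(n)
    d_yaw = np.empty(n)
    d_lat = np.empty(n)
    behaviour = np.empty(n, dtype=np.int8)
    moving_arr = np.empty(n, dtype=np.bool_)
    active_arr = np.empty(n, dtype=np.bool_)
    evidence = np.empty(n)
    heading = np.empty(n)

    beh = PAUSE
    time_in_bout = 0.0
    walk_end = 0.0
    E = 0.0
    phi = 0.0

    moving = False
    run_on = 0
    run_off = 0

    # initial frame gated from the initial NOT_MOVING state
    if mode_code == OPEN_LOOP:
        active = True
    elif mode_code == IN_PHASE:
        active = False
    else:
        active = True

    turn_ptr = 0
    walk_ptr = 0

    for t in range(n):
        behaviour[t] = beh
        active_arr[t] = active
        evidence[t] = E
        heading[t] = phi

        # sensor emission
        fwd = v_walk * dt if beh != PAUSE else 0.0
        yaw = turn_sign * omega_turn * dt if beh == WALK_TURN else 0.0
        d_fwd[t] = fwd + noise_fwd[t]
        d_yaw[t] = yaw + noise_yaw[t]
        d_lat[t] = noise_lat[t]
        phi += yaw

        # motion detector (hysteresis on the noisy magnitude)
        mag = np.sqrt(d_fwd[t] * d_fwd[t] + d_lat[t] * d_lat[t])
        if mag > threshold:
            run_on += 1
            run_off = 0
        else:
            run_off += 1
            run_on = 0
        if (not moving) and run_on >= debounce_on:
            moving = True
        elif moving and run_off >= debounce_off:
            moving = False
        moving_arr[t] = moving

        # gate the next frame (one-sample controller latency)
        if mode_code == OPEN_LOOP:
            active = True
        elif mode_code == IN_PHASE:
            active = moving
        else:
            active = not moving

        # evidence: leaky integrator driven by the frame shown this sample
        w = w_pause if beh == PAUSE else w_walk
        drive = w * signal_sign if active_arr[t] else 0.0
        E = E + dt * (-E / tau_e + drive)

        # bout dynamics
        if beh == PAUSE:
            h = (alpha - 1.0) / (time_in_bout + t_min)
            if E < 0.0:
                h = h * (1.0 + beta * (-E))
            p = h * dt
            if p > 1.0:
                p = 1.0
            time_in_bout += dt
            if time_in_bout >= t_max or u_pause[t] < p:
                neg_e = -E
                p_turn = 1.0 / (1.0 + np.exp(-(k_turn * neg_e + b_turn)))
                if u_turn[turn_ptr] < p_turn:
                    beh = WALK_TURN
                else:
                    beh = WALK_FORWARD
                turn_ptr += 1
                walk_end = walk_durations[walk_ptr]
                walk_ptr += 1
                time_in_bout = 0.0
        else:
            time_in_bout += dt
            if time_in_bout >= walk_end:
                beh = PAUSE
                time_in_bout = 0.0

    return d_fwd, d_yaw, d_lat, behaviour, moving_arr, active_arr, evidence, heading
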