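"""Shared test utilities."""

import numpy as np


def ks_distance_capped_pause(draws, config):
    """Kolmogorov distance between sampled pause durations and the analytic
    capped power law, handling the atom at t_max correctly.

    On the continuous part (t < t_max) the usual two-sided comparison against
    the uncapped CDF applies; at the cap both the empirical and analytic CDFs
    equal 1, so the atom contributes no discrepancy (unlike a naive
    continuous-law KS test, which misreads the atom as a deviation).
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    xs = draws[draws < config.pause_t_max]
    if xs.size == 0:
        return 0.0
    F = 1.0 - (config.pause_t_min / (xs + config.pause_t_min)) ** (
        config.pause_exponent - 1.0
    )
    i = np.arange(1, xs.size + 1)
    return float(np.max(np.maximum(F - (i - 1) / n, i / n - F)))
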