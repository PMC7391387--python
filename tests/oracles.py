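"""Independent numerical oracles for the probability engine tests.

Two routes that never touch the closed-form segment code:

* :func:`quadrature_probability` integrates the defining integral with
  adaptive quadrature on each constant-hazard segment (machine precision).
* :func:`markov_probability` is a discrete-time three-state Markov chain
  with linearised per-step transition probabilities (O(dt) bias).
"""

import numpy as np
from scipy.integrate import quad


def _hazard_on_grid(schedule, times):
    knots = np.asarray(schedule.knots)
    hazards = np.asarray(schedule.hazards)
    idx = np.clip(np.searchsorted(knots, times, side="right") - 1, 0, len(hazards) - 1)
    return hazards[idx]


def quadrature_probability(schedule_fracture, schedule_death, start_age, horizon, rr=1.0):
    """integral of rr*h_f(t) * exp(-int_0^t (rr*h_f + h_d)) dt by adaptive quadrature."""
    end = start_age + horizon
    cuts = np.unique(
        np.concatenate([schedule_fracture.knots, schedule_death.knots, [start_age, end]])
    )
    cuts = cuts[(cuts >= start_age) & (cuts <= end)]

    def cum(t):
        return rr * schedule_fracture.cumulative(start_age, t) + schedule_death.cumulative(
            start_age, t
        )

    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        f = rr * schedule_fracture.hazard_at(a)

        def integrand(t):
            return f * np.exp(-cum(t))

        val, _ = quad(integrand, a, b, epsabs=1e-14, epsrel=1e-13, limit=200)
        total += val
    return total


def markov_probability(schedule_fracture, schedule_death, start_age, horizon, rr=1.0, dt=1e-4):
    """Three-state chain (at risk / fractured / dead), linear step probabilities."""
    n = int(round(horizon / dt))
    t = start_age + dt * np.arange(n)
    f = rr * _hazard_on_grid(schedule_fracture, t)
    d = _hazard_on_grid(schedule_death, t)
    stay = 1.0 - (f + d) * dt
    s_before = np.concatenate([[1.0], np.cumprod(stay)[:-1]])
    return float(np.sum(s_before * f * dt))
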