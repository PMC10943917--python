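"""Individual-level microsimulation oracle for the cohort trace.

Simulates each patient's path through the decision tree and Markov structure
with explicit Bernoulli draws (death before the response split in cycle 1;
long-term discontinuation and death from cycle 2 on).  The cohort trace is
the analytic expectation of these paths, so state-occupancy fractions must
agree within Monte Carlo error.  Kept independent of the production trace:
only the schedule/mortality plumbing is shared, the transition logic is
re-derived here at the individual level.
"""
import numpy as np

from migraine_cea.cohort import cycle_mortality, cycle_schedule

ON, DISC, DEAD = 0, 1, 2


def microsimulate(arm, population, life_table, settings, n_patients, seed):
    """State-occupancy fractions (cycles 0..K) from n simulated patients."""
    rng = np.random.default_rng(seed)
    weights = cycle_schedule(settings)
    K = len(weights)
    qs = cycle_mortality(population, life_table, settings, weights)

    state = np.full(n_patients, ON, dtype=np.int8)
    occ = np.zeros((K + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)

    # cycle 1: death first, then response and AE-driven discontinuation
    dies = rng.random(n_patients) < qs[0]
    state[dies] = DEAD
    alive = ~dies
    responds = rng.random(n_patients) < arm.response_prob
    tolerates = rng.random(n_patients) >= arm.ae_discontinuation_prob_cycle1
    state[alive & ~(responds & tolerates)] = DISC
    occ[1] = np.bincount(state, minlength=3) / n_patients

    for k in range(2, K + 1):
        dies = (rng.random(n_patients) < qs[k - 1]) & (state != DEAD)
        quits = ((rng.random(n_patients) < arm.longterm_discontinuation_prob_per_cycle)
                 & (state == ON) & ~dies)
        state[dies] = DEAD
        state[quits] = DISC
        occ[k] = np.bincount(state, minlength=3) / n_patients
    return occ


def mc_se(p_hat, n):
    """Binomial Monte Carlo standard error with a floor for p near 0/1."""
    return np.sqrt(np.maximum(p_hat * (1 - p_hat), 1e-6) / n)
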