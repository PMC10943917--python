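"""Decision tree (12-week assessment) plus two-state Markov cohort trace.

All patients start preventive treatment.  At the end of the first 12-week
cycle they are classified as responders (>=50% MMD reduction) or
non-responders; non-responders and responders who stopped for adverse events
move to the discontinuation state, responders who tolerate treatment stay on
it.  From cycle 2 onward an on-treatment patient leaves only through the
long-term per-cycle discontinuation probability or death.  Discontinuation is
absorbing except for death; death is the overall absorbing state, fed from
both living states with background (age- and sex-mixed) general-population
mortality — migraine carries no excess mortality.

The 10-year horizon is discretised into 84-day cycles: 43 full cycles plus a
final partial cycle whose accruals are weighted by the remaining fraction of
a cycle (~0.482).  Costs and utilities attach to the MMD level of each state
at the end of each cycle; no half-cycle correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ArmSpec, LifeTable, ModelSettings, PopulationSpec

DAYS_PER_YEAR = 365.25


class InfeasibleTargetError(ValueError):
    """An arm-average MMD target cannot be met by any responder MMD in range."""


# ---------------------------------------------------------------------------
# schedule and probability plumbing
# ---------------------------------------------------------------------------

def annual_to_cycle_prob(q_annual: float, cycle_days: float) -> float:
    """Convert an annual probability to a cycle probability assuming a
    constant hazard within the year: 1 - (1-q)^(cycle_days/365.25)."""
    if not (0.0 <= q_annual <= 1.0):
        raise ValueError(f"annual probability {q_annual!r} outside [0, 1]")
    if q_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - q_annual) ** (cycle_days / DAYS_PER_YEAR)


def cycle_schedule(settings: ModelSettings) -> np.ndarray:
    """Accrual weight of each cycle 1..K; all 1 except a trailing partial
    cycle covering the remainder of the horizon."""
    horizon_days = settings.horizon_years * DAYS_PER_YEAR
    n_full = int(horizon_days // settings.cycle_length_days)
    frac = horizon_days / settings.cycle_length_days - n_full
    if n_full < 1:
        raise ValueError("horizon shorter than one cycle: the 12-week assessment "
                         "needs at least one full cycle")
    weights = [1.0] * n_full
    if frac > 1e-9:
        weights.append(frac)
    return np.asarray(weights)


def cycle_mortality(population: PopulationSpec, life_table: LifeTable,
                    settings: ModelSettings, weights: np.ndarray) -> np.ndarray:
    """Per-cycle death probability for cycles 1..K.

    The cohort ages continuously (age = start + elapsed cycles x 84/365.25);
    the annual qx is looked up at the floor of the age at cycle start, mixed
    across sexes, then converted to the cycle's actual length (shorter for
    the trailing partial cycle).
    """
    qs = np.empty(len(weights))
    for k, w in enumerate(weights, start=1):
        age = population.start_age + (k - 1) * settings.cycle_length_days / DAYS_PER_YEAR
        q_annual = life_table.qx_mixed(age, population.fraction_female)
        qs[k - 1] = annual_to_cycle_prob(q_annual, w * settings.cycle_length_days)
    return qs


# ---------------------------------------------------------------------------
# state-level MMD assignment
# ---------------------------------------------------------------------------

@dataclass
class MMDAssignment:
    """MMD attached to each health state per cycle.

    ``mmd_responder`` has one entry per cycle 0..K (cycle 0 = baseline);
    non-responders and discontinued patients sit at a single level (the
    baseline-reversion convention unless overridden).
    """

    mmd_responder: np.ndarray
    mmd_nonresponder: float
    mmd_discontinued: float


def run_decision_tree(arm: ArmSpec, population: PopulationSpec,
                      life_table: LifeTable, settings: ModelSettings) -> dict[str, float]:
    """Occupancies at the end of cycle 1 (the 12-week assessment).

    Deaths during the assessment are drawn before the response split
    (mortality is state-independent); among survivors, responders who do not
    stop for adverse events remain on treatment, everyone else discontinues.
    """
    weights = cycle_schedule(settings)
    q1 = cycle_mortality(population, life_table, settings, weights)[0]
    alive = 1.0 - q1
    on = alive * arm.response_prob * (1.0 - arm.ae_discontinuation_prob_cycle1)
    return {"on_treatment": on, "discontinued": alive - on, "dead": q1}


@dataclass
class CohortTrace:
    """Per-cycle state occupancies and attached MMD levels.

    Arrays run k = 0..K with k=0 the model entry (everyone on treatment at
    baseline MMD).  ``weight[k]`` is the accrual weight of cycle k (0 at k=0,
    1 for full cycles, the horizon remainder for the final partial cycle).
    """

    on_treatment: np.ndarray
    discontinued: np.ndarray
    dead: np.ndarray
    mmd_on: np.ndarray
    mmd_discontinued: float
    weight: np.ndarray
    time_years: np.ndarray  # cumulative years at the end of each cycle

    @property
    def n_cycles(self) -> int:
        return len(self.weight) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.on_treatment + self.discontinued

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self.weight)),
            "time_years": self.time_years,
            "weight": self.weight,
            "on_treatment": self.on_treatment,
            "discontinued": self.discontinued,
            "dead": self.dead,
            "mmd_on_treatment": self.mmd_on,
            "mmd_discontinued": np.full(len(self.weight), self.mmd_discontinued),
        })


def run_markov_trace(arm: ArmSpec, population: PopulationSpec,
                     life_table: LifeTable, mmd_assignment: MMDAssignment,
                     settings: ModelSettings) -> CohortTrace:
    """Deterministic cohort trace over the full horizon.

    Transition structure: for k >= 2,
    ``on(k) = on(k-1) * (1 - longterm_disc) * (1 - q_k)``; survivors leaving
    treatment join the discontinued state; the dead fraction accumulates from
    both living states.
    """
    weights = cycle_schedule(settings)
    K = len(weights)
    qs = cycle_mortality(population, life_table, settings, weights)
    on = np.zeros(K + 1)
    disc = np.zeros(K + 1)
    dead = np.zeros(K + 1)
    on[0] = 1.0

    tree = run_decision_tree(arm, population, life_table, settings)
    on[1], disc[1], dead[1] = tree["on_treatment"], tree["discontinued"], tree["dead"]

    lt = arm.longterm_discontinuation_prob_per_cycle
    for k in range(2, K + 1):
        q = qs[k - 1]
        on[k] = on[k - 1] * (1.0 - lt) * (1.0 - q)
        disc[k] = disc[k - 1] * (1.0 - q) + on[k - 1] * (1.0 - q) * lt
        dead[k] = dead[k - 1] + q * (on[k - 1] + disc[k - 1])

    mmd_on = np.asarray(mmd_assignment.mmd_responder, dtype=float)
    if len(mmd_on) != K + 1:
        raise ValueError(f"mmd_responder must have {K + 1} entries, got {len(mmd_on)}")
    return CohortTrace(
        on_treatment=on, discontinued=disc, dead=dead,
        mmd_on=mmd_on, mmd_discontinued=mmd_assignment.mmd_discontinued,
        weight=np.concatenate([[0.0], weights]),
        time_years=np.concatenate([[0.0], np.cumsum(weights)])
        * settings.cycle_length_days / DAYS_PER_YEAR,
    )


def calibrate_responder_mmd(arm: ArmSpec, population: PopulationSpec,
                            life_table: LifeTable, settings: ModelSettings,
                            targets: list[list[float]] | None = None) -> MMDAssignment:
    """Back out the responder-state MMD from printed arm-average trajectories.

    Published results report arm-average MMD at given weeks, not the MMD of
    the responder state.  Given the trace occupancies (which do not depend on
    MMD), each target solves
    ``arm_avg = p_on * mmd_resp + (1 - p_on) * baseline`` for ``mmd_resp``,
    where ``p_on`` is the on-treatment share among the living at the target's
    cycle.  Values are piecewise-constant between target weeks (the first
    value extends back to cycle 1, the last forward to the horizon).

    Precedence: an explicit ``arm.responder_mmd`` wins; otherwise printed
    targets; otherwise the responder definition itself (half the baseline).
    """
    baseline = population.baseline_mmd
    disc_mmd = arm.discontinued_mmd if arm.discontinued_mmd is not None else baseline
    weights = cycle_schedule(settings)
    K = len(weights)
    mmd_resp = np.full(K + 1, baseline)

    if targets is None:
        targets = arm.mmd_targets
    if arm.responder_mmd is not None:
        mmd_resp[1:] = arm.responder_mmd
        return MMDAssignment(mmd_resp, baseline, disc_mmd)
    if not targets:
        mmd_resp[1:] = baseline / 2.0
        return MMDAssignment(mmd_resp, baseline, disc_mmd)

    # occupancies are independent of the MMD assignment: run with a placeholder
    probe = run_markov_trace(arm, population, life_table,
                             MMDAssignment(np.full(K + 1, baseline), baseline, disc_mmd),
                             settings)
    cycle_weeks = settings.cycle_length_days / 7.0
    solved: list[tuple[int, float]] = []
    for week, arm_avg in sorted(targets):
        k = min(max(int(round(week / cycle_weeks)), 1), K)
        alive = probe.on_treatment[k] + probe.discontinued[k]
        p_on = probe.on_treatment[k] / alive if alive > 0 else 0.0
        if p_on <= 0:
            raise InfeasibleTargetError(
                f"week {week}: no on-treatment occupancy left to carry target {arm_avg}")
        value = (arm_avg - (1.0 - p_on) * baseline) / p_on
        if not (0.0 <= value <= baseline):
            raise InfeasibleTargetError(
                f"week {week}: target arm-average {arm_avg} needs responder MMD "
                f"{value:.3f}, outside [0, baseline {baseline}] "
                f"(on-treatment share {p_on:.4f})")
        solved.append((k, value))

    # piecewise-constant assignment over cycles
    for i, (k, value) in enumerate(solved):
        start = 1 if i == 0 else solved[i - 1][0] + 1
        mmd_resp[start:k + 1] = value
    mmd_resp[solved[-1][0] + 1:] = solved[-1][1]
    return MMDAssignment(mmd_resp, baseline, disc_mmd)
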