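"""Accrual of discounted costs, QALYs and migraine days, and pairwise
cost-effectiveness comparison.

Costs attach to the MMD band of each living state at each cycle end:
resource use (hospitalisation, emergency, primary care, neurology, hospital
pharmacy) as unit cost x units x share of patients, acute medication at the
midpoint of the printed 12-week range, preventive drug cost while on
treatment (everyone is on drug during the assessment cycle), and — under the
societal perspective — productivity losses from the work-loss regressions.
QALYs weight the utility of each state's MMD by the year-fraction of the
cycle; migraine days convert the monthly rate with a 30.4375-day month and
accrue undiscounted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regression
from .cohort import DAYS_PER_YEAR, CohortTrace
from .params import ArmSpec, CostInputs, ModelParameters, ModelSettings

DAYS_PER_MONTH = 30.4375  # calendar-mean month for MMD -> migraine-day conversion

#: MMD band partition of the modelled spectrum [0, 28]; fractional MMD is
#: classified by its floor.
BAND_BOUNDS = {
    "no_migraine": (0, 0),
    "low": (1, 3),
    "intermediate": (4, 7),
    "high": (8, 14),
    "chronic": (15, 28),
}


def classify_band(mmd: float) -> str:
    """Band label for an MMD level (floor rule for fractional values)."""
    if not (0.0 <= mmd <= 28.0):
        raise ValueError(f"mmd {mmd!r} outside [0, 28]")
    whole = math.floor(mmd)
    for label, (lo, hi) in BAND_BOUNDS.items():
        if lo <= whole <= hi:
            return label
    raise AssertionError("unreachable: bands partition [0, 28]")


def discount_factor(cycle_index: int, settings: ModelSettings,
                    rate: float | None = None) -> float:
    """(1+r)^(-t) at the end of cycle k, t = k x cycle_length/365.25 years."""
    if rate is None:
        rate = settings.discount_rate_costs
    t = cycle_index * settings.cycle_length_days / DAYS_PER_YEAR
    return (1.0 + rate) ** (-t)


def acute_med_cost(band: str, costs: CostInputs) -> float:
    """Acute-medication cost for one cycle: midpoint of the printed 12-week
    range (a point value where low == high)."""
    rng = costs.acute_med_cost_range[band]
    return ((rng.triptans_low + rng.triptans_high) / 2.0
            + (rng.other_low + rng.other_high) / 2.0) * costs.inflation_multiplier


def resource_cost(band: str, costs: CostInputs, hospital_dispensed: bool) -> float:
    """Healthcare resource cost for one cycle in a band: sum of
    unit cost x units x share of patients (hospital-pharmacy rows only for
    hospital-dispensed arms)."""
    try:
        rows = costs.band_resource_use[band]
    except KeyError:
        raise KeyError(f"no resource-use table for band {band!r}") from None
    total = 0.0
    for r in rows:
        if r.hospital_dispensed_only and not hospital_dispensed:
            continue
        total += r.unit_cost * r.units * r.fraction
    return total * costs.inflation_multiplier


def net_drug_cost_per_cycle(arm: ArmSpec, costs: CostInputs) -> float:
    """Preventive drug cost per cycle after the statutory ex-factory discount
    (applied to hospital-dispensed drugs only)."""
    price = arm.drug_cost_per_cycle
    if arm.hospital_dispensed:
        price *= 1.0 - costs.statutory_discount_pct / 100.0
    return price


def cycle_direct_cost(state_mmd: float, costs: CostInputs, arm: ArmSpec,
                      on_treatment: bool) -> float:
    """Direct healthcare cost of one person-cycle at a given state MMD."""
    band = classify_band(state_mmd)
    total = resource_cost(band, costs, arm.hospital_dispensed) + acute_med_cost(band, costs)
    if on_treatment:
        total += net_drug_cost_per_cycle(arm, costs)
    return total


def cycle_qaly(state_mmd: float, utility_model, ae_decrement: float,
               settings: ModelSettings) -> float:
    """QALYs of one person-cycle: utility x year-fraction, minus the pro-rated
    adverse-event decrement where applicable."""
    year_frac = settings.cycle_length_days / DAYS_PER_YEAR
    base = regression.predict_utility(utility_model, state_mmd) * year_frac
    return max(base - ae_decrement * year_frac, 0.0)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class CostBreakdown:
    drug: float = 0.0
    acute_med: float = 0.0
    resource: float = 0.0
    indirect: float = 0.0

    @property
    def total(self) -> float:
        return self.drug + self.acute_med + self.resource + self.indirect


@dataclass
class ArmResult:
    """Totals for one arm over the horizon (per model entrant)."""

    name: str
    perspective: str
    discounted: CostBreakdown
    undiscounted: CostBreakdown
    qalys: float
    qalys_undiscounted: float
    migraine_days: float  # undiscounted cumulative count
    settings: ModelSettings | None = None

    @property
    def total_cost(self) -> float:
        return self.discounted.total

    @classmethod
    def from_totals(cls, name: str, total_cost: float, qalys: float,
                    migraine_days: float, perspective: str = "healthcare") -> "ArmResult":
        """Build a result directly from reported totals (category breakdown
        unknown: everything filed under resource)."""
        bd = CostBreakdown(resource=total_cost)
        return cls(name=name, perspective=perspective, discounted=bd,
                   undiscounted=CostBreakdown(resource=total_cost),
                   qalys=qalys, qalys_undiscounted=qalys, migraine_days=migraine_days)

    def to_series(self) -> pd.Series:
        return pd.Series({
            "cost_total": self.total_cost,
            "cost_drug": self.discounted.drug,
            "cost_acute_med": self.discounted.acute_med,
            "cost_resource": self.discounted.resource,
            "cost_indirect": self.discounted.indirect,
            "qalys": self.qalys,
            "migraine_days": self.migraine_days,
        }, name=self.name)


@dataclass
class CEResult:
    """Pairwise incremental results (intervention minus comparator)."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_md: float  # intervention minus comparator (negative = days avoided)
    icer_per_qaly: float | None
    cost_per_md_avoided: float | None
    dominance: str  # "none" | "intervention_dominant" | "intervention_dominated"

    @property
    def md_avoided(self) -> float:
        return -self.delta_md

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention, "comparator": self.comparator,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "md_avoided": self.md_avoided, "icer_per_qaly": self.icer_per_qaly,
            "cost_per_md_avoided": self.cost_per_md_avoided, "dominance": self.dominance,
        }


# ---------------------------------------------------------------------------
# accrual and comparison
# ---------------------------------------------------------------------------

def accrue(trace: CohortTrace, params: ModelParameters, arm: ArmSpec,
           perspective: str | None = None) -> ArmResult:
    """Sum occupancy-weighted, discounted outcomes over the trace.

    Conventions: outcomes accrue at cycle ends (no half-cycle correction);
    the dead accrue nothing; every survivor of cycle 1 accrues drug cost for
    the assessment period; the one-off adverse-event disutility is charged in
    cycle 1; migraine days are never discounted.
    """
    if perspective is None:
        perspective = params.settings.perspective
    settings = params.settings
    costs = params.costs
    societal = perspective == "societal"

    disc = CostBreakdown()
    undisc = CostBreakdown()
    qalys = qalys_undisc = md_total = 0.0
    drug_net = net_drug_cost_per_cycle(arm, costs)
    ae_loss = regression.expected_ae_disutility(arm, params.utility)
    if societal:
        labour = regression.daily_labour_cost(
            costs.wage_monthly, costs.working_days_per_month, costs.unemployment_rate)
        abs_model = regression.coeffs_to_model(params.work_loss.absenteeism)
        pres_model = regression.coeffs_to_model(params.work_loss.presenteeism)

    rate_c, rate_e = settings.discount_rate_costs, settings.discount_rate_effects
    year_frac_full = settings.cycle_length_days / DAYS_PER_YEAR

    for k in range(1, trace.n_cycles + 1):
        w = trace.weight[k]
        t = trace.time_years[k]
        df_c = (1.0 + rate_c) ** (-t)
        df_e = (1.0 + rate_e) ** (-t)
        states = ((trace.on_treatment[k], trace.mmd_on[k], True),
                  (trace.discontinued[k], trace.mmd_discontinued, False))
        for occ, mmd, on_flag in states:
            if occ <= 0:
                continue
            band = classify_band(mmd)
            res = resource_cost(band, costs, arm.hospital_dispensed) * occ * w
            acu = acute_med_cost(band, costs) * occ * w
            undisc.resource += res
            undisc.acute_med += acu
            disc.resource += res * df_c
            disc.acute_med += acu * df_c
            u = regression.predict_utility(params.utility, mmd)
            q = u * year_frac_full * occ * w
            qalys_undisc += q
            qalys += q * df_e
            md = mmd * (settings.cycle_length_days / DAYS_PER_MONTH) * occ * w
            md_total += md
            if societal:
                ind = regression.indirect_cost_per_cycle(
                    mmd, abs_model, pres_model, labour,
                    costs.presenteeism_day_fraction, settings.cycle_length_days) * occ * w
                undisc.indirect += ind
                disc.indirect += ind * df_c
        # drug cost: whole surviving cohort in the assessment cycle, the
        # on-treatment state afterwards
        drug_occ = trace.alive[k] if k == 1 else trace.on_treatment[k]
        dr = drug_net * drug_occ * w
        undisc.drug += dr
        disc.drug += dr * df_c
        if k == 1 and ae_loss > 0:
            dq = ae_loss * year_frac_full * trace.alive[1] * w
            qalys_undisc -= dq
            qalys -= dq * df_e

    return ArmResult(name=arm.name, perspective=perspective,
                     discounted=disc, undiscounted=undisc,
                     qalys=qalys, qalys_undiscounted=qalys_undisc,
                     migraine_days=md_total, settings=settings)


def compare(intervention: ArmResult, comparator: ArmResult,
            settings: ModelSettings | None = None) -> CEResult:
    """Incremental cost-effectiveness of the intervention over the comparator.

    Ratios are left undefined (None) when the denominator is zero or a
    dominance flag applies.
    """
    if intervention.settings is not None and comparator.settings is not None:
        if intervention.settings != comparator.settings:
            raise ValueError("arm results computed under different settings")
    if intervention.perspective != comparator.perspective:
        raise ValueError("arm results computed under different perspectives")
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.qalys - comparator.qalys
    d_md = intervention.migraine_days - comparator.migraine_days
    md_avoided = -d_md

    dominance = "none"
    if d_cost < 0 and d_qaly > 0:
        dominance = "intervention_dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "intervention_dominated"

    icer = None
    if dominance == "none" and d_qaly != 0:
        icer = d_cost / d_qaly
    cost_per_md = None
    if md_avoided > 0:
        cost_per_md = d_cost / md_avoided
    return CEResult(intervention=intervention.name, comparator=comparator.name,
                    delta_cost=d_cost, delta_qaly=d_qaly, delta_md=d_md,
                    icer_per_qaly=icer, cost_per_md_avoided=cost_per_md,
                    dominance=dominance)
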