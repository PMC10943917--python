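"""Model/Results interface tying the pipeline together.

:class:`CostEffectivenessModel` is built from a :class:`ModelParameters` set
(``from_defaults('EM'|'CM')``, ``from_config(path)`` or directly); ``fit()``
runs both arms through the decision tree, Markov trace and accrual, compares
them, and returns a :class:`CEResults` carrying the per-arm totals, the
incremental results, the traces and a ``summary()`` table.  Probabilistic,
tornado and scenario analyses, and the CEAC/tornado plots, hang off the
results object.
"""
from __future__ import annotations

import logging
import warnings

import pandas as pd

from . import cohort, outcomes, sensitivity
from .outcomes import ArmResult, CEResult
from .params import ModelParameters, default_paper_parameters, load_config, validate

logger = logging.getLogger(__name__)


def base_mmd_assignments(params: ModelParameters) -> dict[str, cohort.MMDAssignment]:
    """Calibrate each arm's state-level MMD assignment from the base-case
    occupancies.  The assignment is structural: sensitivity analyses freeze it
    at the base case rather than re-calibrating per draw (re-calibration would
    cancel the very perturbation being studied by pinning the arm-average
    trajectory back to its printed targets)."""
    return {arm.name: cohort.calibrate_responder_mmd(
        arm, params.population, params.life_table, params.settings)
        for arm in params.arms}


def evaluate_params(params: ModelParameters, perspective: str | None = None,
                    mmd_assignments: dict[str, cohort.MMDAssignment] | None = None):
    """Full deterministic evaluation of one parameter set.

    Returns ``(arm_results, ce_result, traces)`` with the dictionaries keyed
    by arm name.  ``mmd_assignments`` lets sensitivity analyses reuse the
    base-case calibration.
    """
    if mmd_assignments is None:
        mmd_assignments = base_mmd_assignments(params)
    arm_results: dict[str, ArmResult] = {}
    traces: dict[str, cohort.CohortTrace] = {}
    for arm in params.arms:
        trace = cohort.run_markov_trace(
            arm, params.population, params.life_table, mmd_assignments[arm.name],
            params.settings)
        traces[arm.name] = trace
        arm_results[arm.name] = outcomes.accrue(trace, params, arm, perspective)
    ce = outcomes.compare(arm_results[params.intervention.name],
                          arm_results[params.comparator.name], params.settings)
    return arm_results, ce, traces


class CostEffectivenessModel:
    """Decision-tree + Markov cohort cost-effectiveness model for one
    comparison (intervention vs comparator in one population)."""

    def __init__(self, params: ModelParameters):
        violations = validate(params)
        if violations:
            raise ValueError("invalid parameters:\n  " + "\n  ".join(violations))
        self.params = params
        for arm in params.arms:
            if arm.drug_cost_is_placeholder:
                warnings.warn(
                    f"arm {arm.name!r} uses a PLACEHOLDER drug price "
                    f"({arm.drug_cost_per_cycle:.2f} EUR/cycle); headline costs and "
                    "ICERs are price-dependent — supply the reimbursed price",
                    stacklevel=2)

    @classmethod
    def from_config(cls, path) -> "CostEffectivenessModel":
        return cls(load_config(path))

    @classmethod
    def from_defaults(cls, population_label: str = "EM") -> "CostEffectivenessModel":
        return cls(default_paper_parameters(population_label))

    def fit(self, perspective: str | None = None) -> "CEResults":
        arm_results, ce, traces = evaluate_params(self.params, perspective)
        return CEResults(self, arm_results, ce, traces)


class CEResults:
    """Fitted results: per-arm totals, incremental comparison and traces."""

    def __init__(self, model: CostEffectivenessModel,
                 arm_results: dict[str, ArmResult], ce: CEResult,
                 traces: dict[str, cohort.CohortTrace]):
        self.model = model
        self.params = model.params
        self.arm_results = arm_results
        self.ce = ce
        self.traces = traces

    # -- tabular views -----------------------------------------------------
    def arm_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_series() for r in self.arm_results.values()])

    def summary(self) -> str:
        p = self.params
        ce = self.ce
        lines = [
            "Cost-effectiveness results",
            "=" * 74,
            f"population: {p.population.population_label}   "
            f"perspective: {self.arm_results[p.intervention.name].perspective}   "
            f"horizon: {p.settings.horizon_years:g} y   "
            f"discount: {p.settings.discount_rate_costs:.1%}/{p.settings.discount_rate_effects:.1%}",
            "-" * 74,
            f"{'arm':<16}{'cost (EUR)':>14}{'QALYs':>10}{'migraine days':>16}",
        ]
        for name in (p.comparator.name, p.intervention.name):
            r = self.arm_results[name]
            lines.append(f"{name:<16}{r.total_cost:>14,.0f}{r.qalys:>10.4f}"
                         f"{r.migraine_days:>16,.0f}")
        lines.append("-" * 74)
        icer = f"{ce.icer_per_qaly:,.0f} EUR/QALY" if ce.icer_per_qaly is not None \
            else f"undefined ({ce.dominance})"
        per_md = f"{ce.cost_per_md_avoided:,.2f} EUR/MD" \
            if ce.cost_per_md_avoided is not None else "undefined"
        lines += [
            f"incremental cost: {ce.delta_cost:>12,.0f} EUR",
            f"incremental QALYs:{ce.delta_qaly:>12.4f}",
            f"MDs avoided:      {ce.md_avoided:>12,.0f}",
            f"ICER:             {icer}",
            f"cost per MD avoided: {per_md}",
            f"dominance: {ce.dominance}",
            "=" * 74,
        ]
        placeholders = [a.name for a in p.arms if a.drug_cost_is_placeholder]
        if placeholders:
            lines.append(f"NOTE: placeholder drug prices in arms: {', '.join(placeholders)}")
        return "\n".join(lines)

    # -- sensitivity analyses ---------------------------------------------
    def psa(self, n_iterations: int | None = None, seed: int | None = None,
            specs=None) -> sensitivity.PSAResult:
        return sensitivity.run_psa(self.params, specs=specs,
                                   n_iterations=n_iterations, seed=seed)

    def tornado(self, parameters=None, outcome: str = "nmb",
                wtp: float | None = None) -> list[sensitivity.TornadoEntry]:
        return sensitivity.tornado(self.params, parameters, outcome=outcome, wtp=wtp)

    def scenario(self, name: str) -> CEResult:
        return sensitivity.run_scenario(self.params, name)

    # -- plotting ----------------------------------------------------------
    def plot_ceac(self, psa_result: sensitivity.PSAResult | None = None, ax=None):
        """Cost-effectiveness acceptability curve (runs the PSA if needed)."""
        import matplotlib.pyplot as plt

        if psa_result is None:
            psa_result = self.psa()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(psa_result.ceac_wtp, psa_result.ceac_prob, color="black")
        ax.axvline(self.params.settings.wtp_threshold, ls="--", color="grey")
        ax.set_xlabel("willingness to pay (EUR/QALY)")
        ax.set_ylabel(f"P({self.params.intervention.name} cost-effective)")
        ax.set_ylim(0, 1)
        return ax

    def plot_tornado(self, entries: list[sensitivity.TornadoEntry] | None = None,
                     ax=None, top: int = 12):
        """Horizontal-bar tornado diagram of the outcome swing per parameter."""
        import matplotlib.pyplot as plt

        if entries is None:
            entries = self.tornado()
        entries = entries[:top]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1))
        names = [e.parameter_name for e in entries][::-1]
        for i, e in enumerate(reversed(entries)):
            lo, hi = sorted((e.outcome_low, e.outcome_high))
            ax.barh(i, hi - lo, left=lo, color="steelblue")
        ax.axvline(entries[0].outcome_base, color="black", lw=1)
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("net monetary benefit (EUR)")
        return ax
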