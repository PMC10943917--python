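"""Deterministic (tornado, scenario) and probabilistic sensitivity analysis.

The tornado analysis perturbs one parameter (or one grouped parameter, e.g. a
unit cost shared across MMD bands) at a time by +/-20% and records the swing
of the decision outcome — net monetary benefit at the willingness-to-pay
threshold by default, since the ICER is unstable across sign changes.

The probabilistic analysis assigns each uncertain parameter a distribution by
moment matching the published (mean, SE): beta for probabilities and
adverse-event utility losses, lognormal for odds ratios, gamma for resource
costs and discontinuation rates, multivariate normal for regression
coefficient pairs; a zero SE means the parameter is fixed.  Each Monte Carlo
iteration re-evaluates the full model on an independently seeded child
stream, and the iteration cloud is summarised as a cost-effectiveness
acceptability curve (CEAC).
"""
from __future__ import annotations

import copy
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParameters, validate

# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def _tokens(path: str) -> list[str | int]:
    out: list[str | int] = []
    for part in path.replace("]", "").replace("[", ".").split("."):
        if part == "":
            continue
        out.append(int(part) if re.fullmatch(r"-?\d+", part) else part.strip("'\""))
    return out


def _resolve(obj, tokens):
    for t in tokens:
        if isinstance(obj, dict):
            obj = obj[t]
        elif isinstance(obj, (list, tuple)) and isinstance(t, int):
            obj = obj[t]
        else:
            obj = getattr(obj, t)
    return obj


def get_path(params, path: str):
    """Read a parameter by dotted/indexed path, e.g. ``arms[0].response_prob``
    or ``costs.band_resource_use[chronic][0].unit_cost``."""
    try:
        return _resolve(params, _tokens(path))
    except (KeyError, IndexError, AttributeError) as exc:
        raise KeyError(f"unknown parameter path {path!r}: {exc}") from exc


def set_path(params, path: str, value) -> None:
    tokens = _tokens(path)
    parent = _resolve(params, tokens[:-1]) if len(tokens) > 1 else params
    last = tokens[-1]
    try:
        if isinstance(parent, dict):
            if last not in parent:
                raise KeyError(last)
            parent[last] = value
        elif isinstance(parent, list) and isinstance(last, int):
            parent[last] = value
        else:
            getattr(parent, last)  # raises if absent
            setattr(parent, last, value)
    except (KeyError, IndexError, AttributeError) as exc:
        raise KeyError(f"unknown parameter path {path!r}: {exc}") from exc


_PROB_LEAVES = (
    "response_prob", "ae_discontinuation_prob_cycle1",
    "longterm_discontinuation_prob_per_cycle", "fraction", "fraction_female",
    "unemployment_rate", "presenteeism_day_fraction", "intercept_u0", "loss",
)


def is_probability_path(path: str) -> bool:
    leaf = _tokens(path)[-1]
    return isinstance(leaf, str) and (leaf in _PROB_LEAVES or leaf.endswith("_prob"))


# ---------------------------------------------------------------------------
# moment matching and sampling
# ---------------------------------------------------------------------------

def moment_match(family: str, mean: float, se: float) -> dict[str, float]:
    """Distribution parameters matching the given mean and SE.

    beta: alpha = mean*nu, beta = (1-mean)*nu with nu = mean(1-mean)/se^2 - 1;
    gamma: shape = (mean/se)^2, rate = mean/se^2;
    lognormal: sigma^2 = ln(1 + se^2/mean^2), mu = ln(mean) - sigma^2/2.
    A zero SE collapses any family to a point mass.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0 or family == "fixed":
        return {"family": "fixed", "value": mean}
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise ValueError(f"beta mean {mean!r} outside (0, 1)")
        var = se * se
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"beta variance {var:.4g} >= mean(1-mean) = {mean * (1 - mean):.4g}")
        nu = mean * (1.0 - mean) / var - 1.0
        return {"family": "beta", "alpha": mean * nu, "beta": (1.0 - mean) * nu}
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be > 0")
        return {"family": "gamma", "shape": (mean / se) ** 2, "rate": mean / se ** 2}
    if family == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal mean must be > 0")
        sigma2 = math.log(1.0 + se * se / (mean * mean))
        return {"family": "lognormal", "mu": math.log(mean) - sigma2 / 2.0,
                "sigma": math.sqrt(sigma2)}
    raise ValueError(f"unknown distribution family {family!r}")


def sample_moment_matched(pars: dict[str, float], rng: np.random.Generator) -> float:
    family = pars["family"]
    if family == "fixed":
        return float(pars["value"])
    if family == "beta":
        return float(rng.beta(pars["alpha"], pars["beta"]))
    if family == "gamma":
        return float(rng.gamma(pars["shape"], 1.0 / pars["rate"]))
    if family == "lognormal":
        return float(rng.lognormal(pars["mu"], pars["sigma"]))
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass
class PSADistributionSpec:
    """Distributional assumption for one uncertain parameter (or, for the
    multivariate-normal family, one coefficient pair)."""

    parameter_name: str
    family: str  # lognormal | beta | gamma | multivariate_normal | fixed
    paths: list[str]
    mean: float | None = None
    se: float | None = None
    mean_vec: list[float] | None = None
    cov: np.ndarray | None = None

    def sample(self, rng: np.random.Generator) -> list[float]:
        if self.family == "multivariate_normal":
            return [float(v) for v in rng.multivariate_normal(self.mean_vec, self.cov)]
        return [sample_moment_matched(moment_match(self.family, self.mean, self.se), rng)]


def build_default_psa_specs(params: ModelParameters) -> list[PSADistributionSpec]:
    """The default uncertain-parameter registry for a parameter set.

    Probabilities (response, adverse-event discontinuation) are beta; the
    comparator odds ratio is lognormal; long-term discontinuation rates are
    gamma; the utility regression and the two work-loss regressions are
    multivariate normal with diagonal covariance (no covariances published);
    adverse-event utility losses are beta; resource unit costs are gamma with
    SE a configured fraction of the mean.  Zero-SE parameters stay fixed.
    """
    specs: list[PSADistributionSpec] = []
    for i, arm in enumerate(params.arms):
        specs.append(PSADistributionSpec(
            f"{arm.name}.response_prob", "beta" if arm.response_prob_se > 0 else "fixed",
            [f"arms[{i}].response_prob"], arm.response_prob, arm.response_prob_se))
        if arm.response_or is not None:
            specs.append(PSADistributionSpec(
                f"{arm.name}.response_or",
                "lognormal" if arm.response_or_se > 0 else "fixed",
                [f"arms[{i}].response_or"], arm.response_or, arm.response_or_se))
        specs.append(PSADistributionSpec(
            f"{arm.name}.ae_discontinuation",
            "beta" if arm.ae_discontinuation_se > 0 and arm.ae_discontinuation_prob_cycle1 > 0
            else "fixed",
            [f"arms[{i}].ae_discontinuation_prob_cycle1"],
            arm.ae_discontinuation_prob_cycle1, arm.ae_discontinuation_se))
        specs.append(PSADistributionSpec(
            f"{arm.name}.longterm_discontinuation",
            "gamma" if arm.longterm_discontinuation_se > 0
            and arm.longterm_discontinuation_prob_per_cycle > 0 else "fixed",
            [f"arms[{i}].longterm_discontinuation_prob_per_cycle"],
            arm.longterm_discontinuation_prob_per_cycle, arm.longterm_discontinuation_se))
    u = params.utility
    specs.append(PSADistributionSpec(
        "utility.regression", "multivariate_normal",
        ["utility.intercept_u0", "utility.slope_per_mmd"],
        mean_vec=[u.intercept_u0, u.slope_per_mmd],
        cov=np.diag([u.intercept_se ** 2, u.slope_se ** 2])))
    for name, d in u.ae_disutility.items():
        specs.append(PSADistributionSpec(
            f"ae_disutility.{name}", "beta" if d.se > 0 and 0 < d.loss < 1 else "fixed",
            [f"utility.ae_disutility[{name}].loss"], d.loss, d.se))
    for wl_name in ("absenteeism", "presenteeism"):
        c = getattr(params.work_loss, wl_name)
        specs.append(PSADistributionSpec(
            f"work_loss.{wl_name}", "multivariate_normal",
            [f"work_loss.{wl_name}.intercept", f"work_loss.{wl_name}.slope_per_mmd"],
            mean_vec=[c.intercept, c.slope_per_mmd],
            cov=np.diag([c.intercept_se ** 2, c.slope_se ** 2])))
    frac = params.costs.resource_cost_se_frac
    seen: set[str] = set()
    for band, rows in params.costs.band_resource_use.items():
        for j, r in enumerate(rows):
            if r.resource in seen:
                continue
            seen.add(r.resource)
            paths = [f"costs.band_resource_use[{b}][{jj}].unit_cost"
                     for b, rws in params.costs.band_resource_use.items()
                     for jj, rr in enumerate(rws) if rr.resource == r.resource]
            specs.append(PSADistributionSpec(
                f"unit_cost.{r.resource}",
                "gamma" if frac > 0 and r.unit_cost > 0 else "fixed",
                paths, r.unit_cost, frac * r.unit_cost))
    return specs


def derive_response_from_or(base_prob: float, odds_ratio: float) -> float:
    """Intervention response from comparator probability and odds ratio on the
    odds scale: p = OR*odds / (1 + OR*odds)."""
    odds = odds_ratio * base_prob / (1.0 - base_prob)
    return odds / (1.0 + odds)


def sample_parameter_set(base: ModelParameters, specs: list[PSADistributionSpec],
                         rng: np.random.Generator) -> ModelParameters:
    """One probabilistic draw of the full parameter set.

    Probabilities are clamped to [0, 1] after sampling; the sampled utility
    slope is clamped so the utility at 28 MMD stays nonnegative; when the
    comparator carries an odds ratio, the intervention response probability is
    re-derived from the sampled comparator response and sampled OR.
    """
    draw = copy.deepcopy(base)
    for spec in specs:
        values = spec.sample(rng)
        if spec.family == "multivariate_normal":
            pairs = zip(spec.paths, values)
        else:
            pairs = zip(spec.paths, values * len(spec.paths))
        for path, value in pairs:
            if is_probability_path(path):
                value = min(max(value, 0.0), 1.0)
            set_path(draw, path, value)
    # keep the utility line admissible over the whole MMD spectrum
    draw.utility.slope_per_mmd = min(max(draw.utility.slope_per_mmd, 0.0),
                                     draw.utility.intercept_u0 / 28.0)
    comp = draw.comparator
    if comp.response_or is not None and 0.0 < comp.response_prob < 1.0:
        draw.intervention.response_prob = min(max(
            derive_response_from_or(comp.response_prob, comp.response_or), 0.0), 1.0)
    return draw


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-iteration incremental outcomes plus the acceptability curve."""

    iterations: np.ndarray  # shape (n, 2): delta_cost, delta_qaly
    ceac_wtp: np.ndarray
    ceac_prob: np.ndarray
    seed: int
    n_iterations: int

    def iterations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations, columns=["delta_cost", "delta_qaly"])

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.ceac_wtp, "prob_cost_effective": self.ceac_prob})

    def crossing_threshold(self, prob: float = 0.5) -> float | None:
        """Smallest willingness-to-pay on the grid where the acceptability
        probability reaches ``prob`` (None if never)."""
        hit = np.nonzero(self.ceac_prob >= prob)[0]
        return float(self.ceac_wtp[hit[0]]) if hit.size else None


def default_wtp_grid() -> np.ndarray:
    """0 to EUR 50,000 per QALY in EUR 100 steps."""
    return np.arange(0.0, 50001.0, 100.0)


def ceac(iterations: np.ndarray | PSAResult, wtp_grid: np.ndarray) -> np.ndarray:
    """Fraction of iterations with positive net monetary benefit at each
    willingness-to-pay: P(wtp * dQALY - dCost > 0)."""
    if isinstance(iterations, PSAResult):
        iterations = iterations.iterations
    iterations = np.asarray(iterations, dtype=float)
    if iterations.size == 0:
        raise ValueError("no PSA iterations")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size < 2:
        raise ValueError("willingness-to-pay grid needs at least 2 points")
    d_cost, d_qaly = iterations[:, 0], iterations[:, 1]
    nmb = wtp_grid[:, None] * d_qaly[None, :] - d_cost[None, :]
    return (nmb > 0).mean(axis=1)


def run_psa(base: ModelParameters, specs: list[PSADistributionSpec] | None = None,
            n_iterations: int | None = None, seed: int | None = None,
            wtp_grid: np.ndarray | None = None) -> PSAResult:
    """Monte Carlo PSA: one full model evaluation per parameter draw.

    Reproducible under a fixed seed independent of iteration count: iteration
    i always uses the i-th child stream of the root seed.
    """
    from .model import base_mmd_assignments, evaluate_params  # deferred: model orchestrates this module too

    if specs is None:
        specs = build_default_psa_specs(base)
    if n_iterations is None:
        n_iterations = base.settings.psa_iterations
    if seed is None:
        seed = base.settings.rng_seed
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    assignments = base_mmd_assignments(base)  # structural: frozen across draws
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    out = np.empty((n_iterations, 2))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            draw = sample_parameter_set(base, specs, rng)
            _, ce, _ = evaluate_params(draw, mmd_assignments=assignments)
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        out[i] = (ce.delta_cost, ce.delta_qaly)
    probs = ceac(out, wtp_grid)
    return PSAResult(iterations=out, ceac_wtp=np.asarray(wtp_grid, dtype=float),
                     ceac_prob=probs, seed=seed, n_iterations=n_iterations)


# ---------------------------------------------------------------------------
# tornado (one-way deterministic) analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter_name: str
    base_value: float
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    outcome_base: float

    @property
    def range_width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def default_tornado_parameters(params: ModelParameters) -> dict[str, list[str]]:
    """Named parameter groups for the one-way analysis: arm probabilities and
    costs, the utility regression coefficients, and each resource unit cost
    perturbed jointly across bands."""
    groups: dict[str, list[str]] = {}
    for i, arm in enumerate(params.arms):
        groups[f"{arm.name}: response probability"] = [f"arms[{i}].response_prob"]
        groups[f"{arm.name}: AE discontinuation"] = [
            f"arms[{i}].ae_discontinuation_prob_cycle1"]
        groups[f"{arm.name}: long-term discontinuation"] = [
            f"arms[{i}].longterm_discontinuation_prob_per_cycle"]
        if arm.drug_cost_per_cycle > 0:
            groups[f"{arm.name}: drug cost"] = [f"arms[{i}].drug_cost_per_cycle"]
    groups["utility: intercept (no-migraine utility)"] = ["utility.intercept_u0"]
    groups["utility: loss per MMD"] = ["utility.slope_per_mmd"]
    seen: set[str] = set()
    for band, rows in params.costs.band_resource_use.items():
        for r in rows:
            if r.resource in seen:
                continue
            seen.add(r.resource)
            groups[f"unit cost: {r.resource}"] = [
                f"costs.band_resource_use[{b}][{jj}].unit_cost"
                for b, rws in params.costs.band_resource_use.items()
                for jj, rr in enumerate(rws) if rr.resource == r.resource]
    if params.settings.perspective == "societal":
        groups["labour: monthly wage"] = ["costs.wage_monthly"]
    return groups


def tornado(base: ModelParameters,
            parameters: dict[str, list[str]] | list[str] | None = None,
            outcome: str = "nmb", wtp: float | None = None,
            rel_change: float = 0.2) -> list[TornadoEntry]:
    """One-way +/-20% analysis, sorted by descending outcome swing.

    ``outcome`` is net monetary benefit (``nmb``, default) or ``icer``.
    Probabilities pushed above 1 by the +20% perturbation are capped at 1
    with a warning.
    """
    from .model import base_mmd_assignments, evaluate_params

    if parameters is None:
        parameters = default_tornado_parameters(base)
    elif isinstance(parameters, list):
        parameters = {p: [p] for p in parameters}
    if wtp is None:
        wtp = base.settings.wtp_threshold
    assignments = base_mmd_assignments(base)  # structural: frozen across perturbations

    def outcome_of(p: ModelParameters) -> float:
        _, ce, _ = evaluate_params(p, mmd_assignments=assignments)
        if outcome == "nmb":
            return wtp * ce.delta_qaly - ce.delta_cost
        if outcome == "icer":
            return ce.icer_per_qaly if ce.icer_per_qaly is not None else float("nan")
        raise ValueError(f"unknown outcome {outcome!r}")

    base_outcome = outcome_of(base)
    entries: list[TornadoEntry] = []
    for name, paths in parameters.items():
        base_value = float(get_path(base, paths[0]))
        bounds = []
        for factor in (1.0 - rel_change, 1.0 + rel_change):
            perturbed = copy.deepcopy(base)
            bound_value = base_value * factor
            for path in paths:
                value = float(get_path(base, path)) * factor
                if is_probability_path(path) and value > 1.0:
                    warnings.warn(f"{path}: perturbed probability {value:.3f} capped at 1.0",
                                  stacklevel=2)
                    value = 1.0
                set_path(perturbed, path, value)
            if is_probability_path(paths[0]) and bound_value > 1.0:
                bound_value = 1.0
            bounds.append((bound_value, outcome_of(perturbed)))
        (low_v, out_low), (high_v, out_high) = bounds
        entries.append(TornadoEntry(name, base_value, low_v, high_v,
                                    out_low, out_high, base_outcome))
    entries.sort(key=lambda e: (-e.range_width, e.parameter_name))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter_name, "base_value": e.base_value,
        "low_value": e.low_value, "high_value": e.high_value,
        "outcome_low": e.outcome_low, "outcome_high": e.outcome_high,
        "outcome_base": e.outcome_base, "range_width": e.range_width,
    } for e in entries])


# ---------------------------------------------------------------------------
# scenario analysis
# ---------------------------------------------------------------------------

def _scenario_healthcare(p: ModelParameters) -> ModelParameters:
    p.settings.perspective = "healthcare"
    return p


def _scenario_societal(p: ModelParameters) -> ModelParameters:
    p.settings.perspective = "societal"
    return p


def _scenario_wpai(p: ModelParameters) -> ModelParameters:
    # societal perspective with presenteeism valued from the WPAI regression
    p.settings.perspective = "societal"
    p.work_loss.presenteeism = p.work_loss.wpai_presenteeism
    return p


def _scenario_undiscounted(p: ModelParameters) -> ModelParameters:
    p.settings.discount_rate_costs = 0.0
    p.settings.discount_rate_effects = 0.0
    return p


SCENARIOS = {
    "healthcare_base": _scenario_healthcare,
    "societal": _scenario_societal,
    "wpai_workloss": _scenario_wpai,
    "undiscounted": _scenario_undiscounted,
}


def apply_scenario(base: ModelParameters, scenario_name: str) -> ModelParameters:
    """A deep-copied parameter set with the scenario overlay applied (the base
    object is never mutated, so removing an overlay is just re-using base)."""
    try:
        overlay = SCENARIOS[scenario_name]
    except KeyError:
        raise KeyError(f"unknown scenario {scenario_name!r}; "
                       f"registered: {sorted(SCENARIOS)}") from None
    return overlay(copy.deepcopy(base))


def run_scenario(base: ModelParameters, scenario_name: str):
    """Evaluate the model under a registered scenario overlay."""
    from .model import base_mmd_assignments, evaluate_params

    scenario = apply_scenario(base, scenario_name)
    violations = validate(scenario)
    if violations:
        raise ValueError(f"scenario {scenario_name!r} produced an invalid parameter set: "
                         + "; ".join(violations))
    _, ce, _ = evaluate_params(scenario, mmd_assignments=base_mmd_assignments(base))
    return ce
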