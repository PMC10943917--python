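"""Parameter schema, validation and config I/O for the cost-effectiveness model.

The complete input of one comparison (intervention arm vs comparator arm in one
population) is a :class:`ModelParameters` object: arm-level efficacy and
discontinuation probabilities, the linear utility-by-MMD model with its
adverse-event disutility catalogue, resource-use and unit-cost tables by MMD
band, labour-cost inputs for the societal perspective, discounting and horizon
settings, and a background life table.

Configs are plain YAML (diff-able, versioned with ``schema_version``); the life
table travels as a sidecar CSV with header ``age,sex,qx``.  Two parameter sets
are packaged as defaults: episodic migraine (``EM``: erenumab vs topiramate)
and chronic migraine (``CM``: erenumab vs placebo/best supportive care).
Drug acquisition prices are not public and ship as placeholders flagged
``drug_cost_is_placeholder``.
"""
from __future__ import annotations

import math
from dataclasses import MISSING, dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

SCHEMA_VERSION = 1

#: MMD band labels in increasing order of monthly migraine days.
BAND_LABELS = ("no_migraine", "low", "intermediate", "high", "chronic")

#: The adverse-event disutility catalogue names every event an arm may report.
PERSPECTIVES = ("healthcare", "societal")


class ConfigError(ValueError):
    """Raised when a config cannot be loaded or violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ArmSpec:
    """One treatment strategy (preventive drug + best supportive care).

    ``response_prob`` is the probability of a >=50% reduction in monthly
    migraine days (MMD) at the 12-week assessment.  A comparator may carry the
    odds ratio of the head-to-head comparison (``response_or``); probabilistic
    analysis then derives the intervention response on the odds scale.
    Discontinuation is split into an adverse-event-driven probability applying
    in cycle 1 only and a long-term per-cycle probability from cycle 2 on.
    """

    name: str
    role: str  # "intervention" | "comparator"
    response_prob: float
    response_prob_se: float = 0.0
    response_or: float | None = None
    response_or_se: float = 0.0
    ae_discontinuation_prob_cycle1: float = 0.0
    ae_discontinuation_se: float = 0.0
    longterm_discontinuation_prob_per_cycle: float = 0.0
    longterm_discontinuation_se: float = 0.0
    drug_cost_per_cycle: float = 0.0
    drug_cost_is_placeholder: bool = False
    hospital_dispensed: bool = False
    ae_incidence: dict[str, float] = field(default_factory=dict)
    #: printed arm-average MMD trajectory as (week, arm_average_mmd) pairs;
    #: used to calibrate the responder-state MMD (see cohort.calibrate_responder_mmd)
    mmd_targets: list[list[float]] = field(default_factory=list)
    #: explicit responder-state MMD (overrides calibration when set)
    responder_mmd: float | None = None
    #: MMD after discontinuation; None means reversion to baseline
    discontinued_mmd: float | None = None


@dataclass
class PopulationSpec:
    """Cohort entering the model: a notional trial-like population."""

    population_label: str  # "EM" | "CM"
    start_age: float = 41.0
    fraction_female: float = 0.805
    baseline_mmd: float = 9.44


@dataclass
class AEDisutility:
    """Utility decrement for one adverse event (positive magnitude) and its SE."""

    loss: float
    se: float = 0.0


@dataclass
class UtilityModelSpec:
    """Linear utility-by-MMD model: utility = intercept - slope * MMD.

    The slope is stored as a positive decrement magnitude per monthly migraine
    day.  ``ae_disutility`` catalogues per-event utility losses applied once,
    weighted by per-arm incidence, during the assessment period.
    """

    intercept_u0: float
    slope_per_mmd: float
    slope_se: float = 0.0
    intercept_se: float = 0.0
    ae_disutility: dict[str, AEDisutility] = field(default_factory=dict)


@dataclass
class ResourceUse:
    """One resource row within an MMD band: unit cost x units x share of patients."""

    resource: str
    unit_cost: float
    units: float = 1.0  # per 12-week cycle
    fraction: float = 0.0  # share of band patients using the resource
    hospital_dispensed_only: bool = False  # e.g. hospital pharmacy visit


@dataclass
class AcuteMedRange:
    """12-week acute-medication cost range for one band (point value when low==high)."""

    triptans_low: float
    triptans_high: float
    other_low: float
    other_high: float


@dataclass
class LinearCoeffs:
    """Coefficients of a work-loss regression: days per 3 months = a + b * MMD."""

    intercept: float
    slope_per_mmd: float
    intercept_se: float = 0.0
    slope_se: float = 0.0


@dataclass
class WorkLossSpec:
    """Absenteeism/presenteeism regressions plus the WPAI-based variant."""

    absenteeism: LinearCoeffs
    presenteeism: LinearCoeffs
    wpai_presenteeism: LinearCoeffs


@dataclass
class CostInputs:
    """Everything priced: per-band resource use, acute medication, drug-price
    policy and the labour inputs valuing productivity loss."""

    band_resource_use: dict[str, list[ResourceUse]]
    acute_med_cost_range: dict[str, AcuteMedRange]
    statutory_discount_pct: float = 7.5  # applied to hospital-dispensed drug prices
    wage_monthly: float | None = None
    working_days_per_month: float = 22.0
    unemployment_rate: float = 0.127
    presenteeism_day_fraction: float = 0.5
    inflation_multiplier: float = 1.0
    resource_cost_se_frac: float = 0.2  # gamma SE as fraction of mean in PSA


@dataclass
class ModelSettings:
    """Run settings: cycle/horizon discretisation, discounting, thresholds."""

    cycle_length_days: float = 84.0
    horizon_years: float = 10.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp_threshold: float = 30000.0
    perspective: str = "healthcare"
    psa_iterations: int = 1000
    rng_seed: int = 20240315


class LifeTable:
    """Annual mortality probabilities qx by age and sex (``F``/``M``).

    Lookups floor the age; ages beyond the last row reuse the last row.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(table.columns):
            raise ConfigError(f"life table needs columns {sorted(required)}")
        self.table = (
            table[["age", "sex", "qx"]]
            .astype({"age": int, "sex": str, "qx": float})
            .sort_values(["sex", "age"])
            .reset_index(drop=True)
        )
        self._by_sex = {
            sex: grp.set_index("age")["qx"] for sex, grp in self.table.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def max_age(self) -> int:
        return int(self.table["age"].max())

    def qx(self, age: float, sex: str) -> float:
        series = self._by_sex[sex]
        a = min(int(math.floor(age)), int(series.index.max()))
        a = max(a, int(series.index.min()))
        return float(series.loc[a])

    def qx_mixed(self, age: float, fraction_female: float) -> float:
        """Female/male mixture of qx at the cohort's sex split."""
        return fraction_female * self.qx(age, "F") + (1.0 - fraction_female) * self.qx(age, "M")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return self.table.equals(other.table)

    def __repr__(self) -> str:  # pragma: no cover
        ages = self.table["age"]
        return f"LifeTable(ages {ages.min()}..{ages.max()}, sexes {sorted(self._by_sex)})"


@dataclass
class ModelParameters:
    """The full input of one cost-effectiveness comparison."""

    population: PopulationSpec
    settings: ModelSettings
    utility: UtilityModelSpec
    arms: list[ArmSpec]
    costs: CostInputs
    work_loss: WorkLossSpec
    life_table: LifeTable
    schema_version: int = SCHEMA_VERSION
    life_table_csv: str = "lifetable.csv"

    @property
    def intervention(self) -> ArmSpec:
        return next(a for a in self.arms if a.role == "intervention")

    @property
    def comparator(self) -> ArmSpec:
        return next(a for a in self.arms if a.role == "comparator")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _prob(report: list[str], key: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.append(f"{key}: probability {value!r} outside [0, 1]")


def _nonneg(report: list[str], key: str, value: float) -> None:
    if value < 0:
        report.append(f"{key}: {value!r} must be >= 0")


def validate(params: ModelParameters) -> list[str]:
    """Return a list of invariant violations; empty iff the set is valid.

    Total: reports on any structurally complete parameter object and never
    raises on content.
    """
    v: list[str] = []
    pop = params.population
    if pop.population_label not in ("EM", "CM"):
        v.append(f"population.population_label: {pop.population_label!r} not in ('EM', 'CM')")
    if not (0.0 <= pop.baseline_mmd <= 28.0):
        v.append(f"population.baseline_mmd: {pop.baseline_mmd!r} outside [0, 28]")
    _prob(v, "population.fraction_female", pop.fraction_female)
    if pop.start_age <= 0:
        v.append(f"population.start_age: {pop.start_age!r} must be > 0")

    s = params.settings
    if s.cycle_length_days <= 0:
        v.append("settings.cycle_length_days: must be > 0")
    if s.horizon_years <= 0:
        v.append("settings.horizon_years: must be > 0")
    for key in ("discount_rate_costs", "discount_rate_effects"):
        rate = getattr(s, key)
        if not (0.0 <= rate < 1.0):
            v.append(f"settings.{key}: {rate!r} outside [0, 1)")
    if s.perspective not in PERSPECTIVES:
        v.append(f"settings.perspective: {s.perspective!r} not in {PERSPECTIVES}")
    if s.psa_iterations < 1:
        v.append("settings.psa_iterations: must be >= 1")

    u = params.utility
    if not (0.0 < u.intercept_u0 <= 1.0):
        v.append(f"utility.intercept_u0: {u.intercept_u0!r} outside (0, 1]")
    _nonneg(v, "utility.slope_per_mmd", u.slope_per_mmd)
    if u.intercept_u0 - 28.0 * u.slope_per_mmd < 0:
        v.append(
            "utility: intercept_u0 - 28*slope_per_mmd = "
            f"{u.intercept_u0 - 28.0 * u.slope_per_mmd:.4f} < 0 "
            "(utility negative at the top of the MMD spectrum)"
        )
    _nonneg(v, "utility.slope_se", u.slope_se)
    _nonneg(v, "utility.intercept_se", u.intercept_se)
    for name, d in u.ae_disutility.items():
        if not (0.0 <= d.loss <= 1.0):
            v.append(f"utility.ae_disutility[{name}].loss: {d.loss!r} outside [0, 1]")
        _nonneg(v, f"utility.ae_disutility[{name}].se", d.se)

    roles = sorted(a.role for a in params.arms)
    if roles != ["comparator", "intervention"]:
        v.append(f"arms: need exactly one intervention and one comparator, got roles {roles}")
    for a in params.arms:
        k = f"arms[{a.name}]"
        _prob(v, f"{k}.response_prob", a.response_prob)
        _prob(v, f"{k}.ae_discontinuation_prob_cycle1", a.ae_discontinuation_prob_cycle1)
        _prob(v, f"{k}.longterm_discontinuation_prob_per_cycle",
              a.longterm_discontinuation_prob_per_cycle)
        for key in ("response_prob_se", "response_or_se", "ae_discontinuation_se",
                    "longterm_discontinuation_se"):
            _nonneg(v, f"{k}.{key}", getattr(a, key))
        if a.response_or is not None and a.response_or <= 0:
            v.append(f"{k}.response_or: {a.response_or!r} must be positive")
        _nonneg(v, f"{k}.drug_cost_per_cycle", a.drug_cost_per_cycle)
        for ae, inc in a.ae_incidence.items():
            if ae not in u.ae_disutility:
                v.append(f"{k}.ae_incidence[{ae}]: unknown adverse-event name "
                         "(not in utility.ae_disutility catalogue)")
            _prob(v, f"{k}.ae_incidence[{ae}]", inc)
        for wk, target in a.mmd_targets:
            if not (0.0 <= target <= 28.0):
                v.append(f"{k}.mmd_targets week {wk}: target {target!r} outside [0, 28]")
        if a.responder_mmd is not None and not (0.0 <= a.responder_mmd <= pop.baseline_mmd):
            v.append(f"{k}.responder_mmd: {a.responder_mmd!r} outside [0, baseline "
                     f"{pop.baseline_mmd}]")
        if a.discontinued_mmd is not None and not (0.0 <= a.discontinued_mmd <= 28.0):
            v.append(f"{k}.discontinued_mmd: {a.discontinued_mmd!r} outside [0, 28]")

    c = params.costs
    missing = set(BAND_LABELS) - set(c.band_resource_use)
    if missing:
        v.append(f"costs.band_resource_use: missing bands {sorted(missing)}")
    for band, rows in c.band_resource_use.items():
        if band not in BAND_LABELS:
            v.append(f"costs.band_resource_use[{band}]: unknown band label")
        for r in rows:
            _nonneg(v, f"costs.band_resource_use[{band}][{r.resource}].unit_cost", r.unit_cost)
            _nonneg(v, f"costs.band_resource_use[{band}][{r.resource}].units", r.units)
            _prob(v, f"costs.band_resource_use[{band}][{r.resource}].fraction", r.fraction)
    missing = set(BAND_LABELS) - set(c.acute_med_cost_range)
    if missing:
        v.append(f"costs.acute_med_cost_range: missing bands {sorted(missing)}")
    for band, rng in c.acute_med_cost_range.items():
        key = f"costs.acute_med_cost_range[{band}]"
        for lo, hi, label in ((rng.triptans_low, rng.triptans_high, "triptans"),
                              (rng.other_low, rng.other_high, "other")):
            _nonneg(v, f"{key}.{label}_low", lo)
            if lo > hi:
                v.append(f"{key}.{label}: low {lo!r} > high {hi!r}")
    if not (0.0 <= c.statutory_discount_pct <= 100.0):
        v.append(f"costs.statutory_discount_pct: {c.statutory_discount_pct!r} outside [0, 100]")
    _prob(v, "costs.unemployment_rate", c.unemployment_rate)
    _prob(v, "costs.presenteeism_day_fraction", c.presenteeism_day_fraction)
    if c.inflation_multiplier <= 0:
        v.append("costs.inflation_multiplier: must be > 0")
    if s.perspective == "societal":
        if c.wage_monthly is None or c.wage_monthly <= 0:
            v.append("costs.wage_monthly: required and > 0 under the societal perspective")
        if c.working_days_per_month <= 0:
            v.append("costs.working_days_per_month: must be > 0 under the societal perspective")

    lt = params.life_table
    if (lt.table["qx"] < 0).any() or (lt.table["qx"] > 1).any():
        v.append("life_table.qx: values outside [0, 1]")
    for sex, grp in lt.table.groupby("sex"):
        ages = grp["age"].to_numpy()
        if len(ages) and (ages[1:] - ages[:-1] != 1).any():
            v.append(f"life_table[{sex}]: ages not contiguous")
    if set(lt.table["sex"].unique()) != {"F", "M"}:
        v.append("life_table: both sexes F and M required")
    if lt.max_age < pop.start_age:
        v.append("life_table: does not reach the cohort's start age")

    if params.schema_version != SCHEMA_VERSION:
        v.append(f"schema_version: {params.schema_version!r} != {SCHEMA_VERSION}")
    return v


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

def _to_dict(obj: Any) -> Any:
    if isinstance(obj, (ArmSpec, PopulationSpec, AEDisutility, UtilityModelSpec,
                        ResourceUse, AcuteMedRange, LinearCoeffs, WorkLossSpec,
                        CostInputs, ModelSettings)):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(x) for k, x in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(x) for x in obj]
    return obj


def _build(cls: type, data: dict[str, Any], key: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{key}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{key}: unknown keys {sorted(unknown)}")
    required = {f.name for f in fields(cls)
                if f.default is MISSING and f.default_factory is MISSING}  # type: ignore[misc]
    missing = required - set(data)
    if missing:
        raise ConfigError(f"{key}: missing required keys {sorted(missing)}")
    return cls(**data)


def params_to_dict(params: ModelParameters) -> dict[str, Any]:
    """Plain-dict (YAML-ready) view of a parameter set, life table excluded."""
    return {
        "schema_version": params.schema_version,
        "population": _to_dict(params.population),
        "settings": _to_dict(params.settings),
        "utility": {
            **{k: v for k, v in _to_dict(params.utility).items() if k != "ae_disutility"},
            "ae_disutility": {k: _to_dict(d) for k, d in params.utility.ae_disutility.items()},
        },
        "arms": [_to_dict(a) for a in params.arms],
        "costs": _to_dict(params.costs),
        "work_loss": _to_dict(params.work_loss),
        "life_table_csv": params.life_table_csv,
    }


def params_from_dict(data: dict[str, Any], life_table: LifeTable) -> ModelParameters:
    try:
        utility_raw = dict(data["utility"])
        utility_raw["ae_disutility"] = {
            k: _build(AEDisutility, d, f"utility.ae_disutility[{k}]")
            for k, d in utility_raw.get("ae_disutility", {}).items()
        }
        costs_raw = dict(data["costs"])
        costs_raw["band_resource_use"] = {
            band: [_build(ResourceUse, r, f"costs.band_resource_use[{band}]")
                   for r in rows]
            for band, rows in costs_raw.get("band_resource_use", {}).items()
        }
        costs_raw["acute_med_cost_range"] = {
            band: _build(AcuteMedRange, r, f"costs.acute_med_cost_range[{band}]")
            for band, r in costs_raw.get("acute_med_cost_range", {}).items()
        }
        work_raw = {k: _build(LinearCoeffs, d, f"work_loss.{k}")
                    for k, d in data["work_loss"].items()}
        return ModelParameters(
            schema_version=data.get("schema_version", SCHEMA_VERSION),
            population=_build(PopulationSpec, data["population"], "population"),
            settings=_build(ModelSettings, data["settings"], "settings"),
            utility=_build(UtilityModelSpec, utility_raw, "utility"),
            arms=[_build(ArmSpec, a, f"arms[{i}]") for i, a in enumerate(data["arms"])],
            costs=_build(CostInputs, costs_raw, "costs"),
            work_loss=_build(WorkLossSpec, work_raw, "work_loss"),
            life_table=life_table,
            life_table_csv=data.get("life_table_csv", "lifetable.csv"),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required section {exc.args[0]!r}") from exc
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Write the YAML config and its sidecar life-table CSV next to it."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False, default_flow_style=None)
    params.life_table.to_csv(path.parent / params.life_table_csv)


def load_config(path: str | Path) -> ModelParameters:
    """Load and validate a YAML config; raise :class:`ConfigError` listing every
    violation with its offending key."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    lt_path = path.parent / data.get("life_table_csv", "lifetable.csv")
    if not lt_path.exists():
        raise ConfigError(f"life table CSV not found: {lt_path}")
    params = params_from_dict(data, LifeTable.from_csv(lt_path))
    violations = validate(params)
    if violations:
        raise ConfigError("invalid config:\n  " + "\n  ".join(violations))
    return params


def default_paper_parameters(population_label: str) -> ModelParameters:
    """The packaged parameter set for ``EM`` (erenumab vs topiramate) or ``CM``
    (erenumab vs placebo), populated with the published point estimates; drug
    prices are placeholders."""
    label = population_label.upper()
    if label not in ("EM", "CM"):
        raise ConfigError(f"unknown population label {population_label!r}; use 'EM' or 'CM'")
    data_dir = resources.files("migraine_cea") / "data"
    with resources.as_file(data_dir / f"params_{label.lower()}.yaml") as p:
        return load_config(p)
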