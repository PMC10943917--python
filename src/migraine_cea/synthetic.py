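"""Synthetic patient-level data and life tables.

No individual trial data behind the published analysis are deposited, so this
module generates trial-like datasets with the statistical structure the model
assumes: a linear utility-by-MMD relationship with truncated Gaussian noise, a
monotone (negative-binomial count) work-loss-by-MMD relationship for MIDAS
absent days and WPAI presenteeism, and per-arm adverse-event flags.  The
regression module can then be exercised end to end, and parameter-recovery
tests have a known ground truth.

Everything is driven by one :class:`SyntheticGeneratorSpec` and one seed: the
same spec and seed always produce byte-identical tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ConfigError, LifeTable

MAX_MMD = 28.0
MIDAS_WINDOW_DAYS = 90.0  # MIDAS recall window: 3 months


@dataclass
class SyntheticGeneratorSpec:
    """Ground truth for one synthetic trial dataset.

    Utilities are generated as ``intercept - slope*mmd + N(0, noise_sd)``
    truncated to [-0.5, 1]; absent days (per 3 months) follow a
    negative-binomial count model around the linear mean
    ``a + b*mmd`` with dispersion ``absenteeism_dispersion`` (Poisson in the
    limit of large dispersion); presenteeism percentages are linear in MMD
    with Gaussian noise, clipped to [0, 100].
    """

    n_patients: int = 500
    true_utility_intercept: float = 0.85
    true_utility_slope: float = 0.0176  # positive decrement per MMD
    utility_noise_sd: float = 0.05
    true_absenteeism_intercept: float = 0.3
    true_absenteeism_slope: float = 0.45
    absenteeism_dispersion: float = 5.0  # NB size parameter; larger = closer to Poisson
    true_presenteeism_intercept: float = 0.5
    true_presenteeism_slope: float = 0.95
    presenteeism_noise_sd: float = 2.0
    mmd_mean: float = 9.44
    mmd_sd: float = 4.0
    arms: tuple[str, ...] = ("erenumab", "comparator")
    ae_incidence: dict[str, dict[str, float]] = field(default_factory=dict)
    rng_seed: int = 20240315

    def check(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for key in ("utility_noise_sd", "mmd_sd", "presenteeism_noise_sd"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0")
        if self.absenteeism_dispersion <= 0:
            raise ConfigError("absenteeism_dispersion must be > 0")
        if not self.arms:
            raise ConfigError("at least one arm label required")


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray | float,
                      sd: float, low: float, high: float, size: int) -> np.ndarray:
    """Resampling-based truncated normal (exact conditional distribution)."""
    out = rng.normal(mean, sd, size=size) if sd > 0 else np.full(size, mean, dtype=float)
    if sd > 0:
        bad = (out < low) | (out > high)
        # bounded retry keeps determinism; clip the stragglers
        for _ in range(100):
            if not bad.any():
                break
            out[bad] = rng.normal(np.broadcast_to(mean, (size,))[bad] if np.ndim(mean) else mean,
                                  sd, size=int(bad.sum()))
            bad = (out < low) | (out > high)
    return np.clip(out, low, high)


def _absent_days(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and size=dispersion."""
    mean = np.maximum(mean, 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def generate_trial(spec: SyntheticGeneratorSpec) -> pd.DataFrame:
    """One patient-level trial table.

    Columns: ``patient_id, arm, mmd, utility_observed, midas_days_absent,
    wpai_presenteeism_pct`` plus one boolean ``ae_<name>`` column per
    adverse event named in ``spec.ae_incidence``.
    """
    spec.check()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    arm = np.array([spec.arms[i % len(spec.arms)] for i in range(n)])
    mmd = _truncated_normal(rng, spec.mmd_mean, spec.mmd_sd, 0.0, MAX_MMD, n)
    utility = _truncated_normal(
        rng, spec.true_utility_intercept - spec.true_utility_slope * mmd,
        spec.utility_noise_sd, -0.5, 1.0, n)
    absent_mean = np.maximum(spec.true_absenteeism_intercept
                             + spec.true_absenteeism_slope * mmd, 0.0)
    absent = np.minimum(_absent_days(rng, absent_mean, spec.absenteeism_dispersion),
                        MIDAS_WINDOW_DAYS)
    pres_mean = np.maximum(spec.true_presenteeism_intercept
                           + spec.true_presenteeism_slope * mmd, 0.0)
    pres = pres_mean if spec.presenteeism_noise_sd == 0 else rng.normal(
        pres_mean, spec.presenteeism_noise_sd)
    pres = np.clip(pres, 0.0, 100.0)
    table = pd.DataFrame({
        "patient_id": np.arange(n),
        "arm": arm,
        "mmd": mmd,
        "utility_observed": utility,
        "midas_days_absent": absent,
        "wpai_presenteeism_pct": pres,
    })
    ae_names = sorted({name for incid in spec.ae_incidence.values() for name in incid})
    for name in ae_names:
        probs = np.array([spec.ae_incidence.get(a, {}).get(name, 0.0) for a in arm])
        table[f"ae_{name}"] = rng.random(n) < probs
    return table


def generate_midas_wpai(spec: SyntheticGeneratorSpec) -> pd.DataFrame:
    """Work-loss-only view: MMD, MIDAS absent days and WPAI presenteeism."""
    return generate_trial(spec)[
        ["patient_id", "arm", "mmd", "midas_days_absent", "wpai_presenteeism_pct"]
    ]


def generate_life_table(base_annual_mortality_at_41: float,
                        annual_growth_factor: float,
                        max_age: int,
                        start_age: int = 41,
                        male_excess_factor: float = 1.8) -> LifeTable:
    """Gompertz-like synthetic life table: qx grows geometrically with age.

    ``base_annual_mortality_at_41`` is the female qx at the anchor age; male qx
    is a constant multiple (``male_excess_factor``).  Values that would exceed
    1 before ``max_age`` are capped at 1 with a warning.
    """
    if not (0.0 < base_annual_mortality_at_41 < 1.0):
        raise ConfigError("base_annual_mortality_at_41 must be in (0, 1)")
    if annual_growth_factor < 1.0:
        raise ConfigError("annual_growth_factor must be >= 1")
    if max_age < start_age:
        raise ConfigError("max_age must be >= start_age")
    ages = np.arange(start_age, max_age + 1)
    qx_f = base_annual_mortality_at_41 * annual_growth_factor ** (ages - start_age)
    qx_m = male_excess_factor * qx_f
    if (qx_f > 1).any() or (qx_m > 1).any():
        warnings.warn("life table qx exceeded 1 before max_age; capped at 1",
                      stacklevel=2)
    rows = pd.concat([
        pd.DataFrame({"age": ages, "sex": "F", "qx": np.minimum(qx_f, 1.0)}),
        pd.DataFrame({"age": ages, "sex": "M", "qx": np.minimum(qx_m, 1.0)}),
    ], ignore_index=True)
    return LifeTable(rows)
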