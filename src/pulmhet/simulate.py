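"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a cohort of patients with multiple pulmonary
metastatic nodules measured on two CT scans: per patient, a nodule count
drawn uniformly from the study's range (4-52), an inter-scan interval from
32-151 days, log-normal baseline diameters, and volumes tied to diameters
by the sphere formula (pi/6) * d**3 times a per-nodule persistent lognormal
shape factor.  Growth acts on the diameter — each nodule's diameter change
rate is drawn from a single normal (homogeneous patients) or a two-component
normal mixture (heterogeneous patients) — and propagates to the volume
through the cube law, so the dual-metric consistency properties of the
downstream analyses are exactly testable.  Multiplicative lognormal
measurement noise (coefficient of variation ``measurement_cv``) is applied
independently per visit and per metric; all outputs stay strictly positive.

Rate draws below -95% are truncated there so measurements remain positive;
truncation events are counted on the generated series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import NoduleMeasurement, PatientSeries

__all__ = [
    "SimulationConfig",
    "GrowthModel",
    "generate_patient",
    "generate_cohort",
    "write_truth_table",
    "load_config",
    "save_config",
]

RATE_TRUNCATION_PERCENT = -95.0


class ConfigurationError(ValueError):
    """Simulation config violates its invariants."""


GROWTH_MODELS = ("homogeneous", "two_subgroup")


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 10 patients, 4-52 nodules, 32-151 day interval.

    Baseline diameters are lognormal with median exp(baseline_diameter_log_mean)
    cm; defaults give a median of 1.0 cm with a long right tail, so a
    patient's two largest diameters sum to roughly 1.5-8 cm as in the study
    cohort.  The default growth model is homogeneous with mean rate 0
    (a stable-disease cohort); the two_subgroup model adds a second
    component displaced by ``subgroup_delta_percent``.
    """

    n_patients: int = 10
    nodules_min: int = 4
    nodules_max: int = 52
    interval_days_range: tuple[int, int] = (32, 151)
    baseline_diameter_log_mean: float = 0.0  # log cm; median 1.0 cm
    baseline_diameter_log_sd: float = 0.5
    shape_factor_sd: float = 0.15  # lognormal sigma on the cube-law constant
    growth_model: str = "homogeneous"
    mean_rate_percent: float = 0.0
    subgroup_delta_percent: float = 30.0
    rate_noise_sd_percent: float = 10.0
    subgroup_fraction: float = 0.5
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_model not in GROWTH_MODELS:
            raise ConfigurationError(
                f"growth_model must be one of {GROWTH_MODELS}, got {self.growth_model!r}"
            )
        if not 2 <= self.nodules_min <= self.nodules_max:
            raise ConfigurationError("need 2 <= nodules_min <= nodules_max")
        lo, hi = self.interval_days_range
        if not 0 < lo <= hi:
            raise ConfigurationError("interval_days_range must be positive and ordered")
        if not 0.0 < self.subgroup_fraction < 1.0:
            raise ConfigurationError("subgroup_fraction must lie in (0, 1)")
        for name in ("baseline_diameter_log_sd", "shape_factor_sd",
                     "rate_noise_sd_percent", "measurement_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class PatientTruth:
    """Ground truth recorded for parameter-recovery tests."""

    patient_id: str
    heterogeneous: bool
    n_nodules: int
    subgroup: tuple[int, ...]  # 0 = baseline component, 1 = displaced
    true_rates_percent: tuple[float, ...]
    n_truncated: int = field(default=0)


def generate_patient(
    config: SimulationConfig,
    heterogeneous: bool,
    rng: np.random.Generator,
    patient_id: str = "sim-1",
) -> tuple[PatientSeries, PatientTruth]:
    """Draw one patient's nodule set; returns the series and its ground truth.

    In the two-subgroup model the displaced component receives exactly
    round(n * subgroup_fraction) nodules (positions shuffled), so a config
    fully controls the subgroup sizes that power analyses depend on.
    """
    n = int(rng.integers(config.nodules_min, config.nodules_max + 1))
    interval = int(rng.integers(config.interval_days_range[0],
                                config.interval_days_range[1] + 1))
    d1_true = rng.lognormal(config.baseline_diameter_log_mean,
                            config.baseline_diameter_log_sd, n)
    shape = (
        rng.lognormal(0.0, config.shape_factor_sd, n)
        if config.shape_factor_sd > 0
        else np.ones(n)
    )
    v1_true = (math.pi / 6.0) * d1_true**3 * shape

    subgroup = np.zeros(n, dtype=int)
    means = np.full(n, config.mean_rate_percent)
    if heterogeneous:
        n_b = int(round(n * config.subgroup_fraction))
        n_b = min(max(n_b, 1), n - 1)
        pos = rng.permutation(n)[:n_b]
        subgroup[pos] = 1
        means[pos] += config.subgroup_delta_percent
    rates = means + (
        rng.normal(0.0, config.rate_noise_sd_percent, n)
        if config.rate_noise_sd_percent > 0
        else 0.0
    )
    n_trunc = int(np.sum(rates < RATE_TRUNCATION_PERCENT))
    rates = np.maximum(rates, RATE_TRUNCATION_PERCENT)

    d2_true = d1_true * (1.0 + rates / 100.0)
    v2_true = (math.pi / 6.0) * d2_true**3 * shape

    cv = config.measurement_cv
    d1 = d1_true * _lognormal_noise(rng, cv, n)
    d2 = d2_true * _lognormal_noise(rng, cv, n)
    v1 = v1_true * _lognormal_noise(rng, cv, n)
    v2 = v2_true * _lognormal_noise(rng, cv, n)

    width = len(str(n))
    nodules = tuple(
        NoduleMeasurement(
            nodule_id=f"n{i + 1:0{width}d}",
            diameter_v1=float(d1[i]),
            diameter_v2=float(d2[i]),
            volume_v1=float(v1[i]),
            volume_v2=float(v2[i]),
        )
        for i in range(n)
    )
    series = PatientSeries(patient_id=patient_id, interval_days=interval, nodules=nodules)
    truth = PatientTruth(
        patient_id=patient_id,
        heterogeneous=heterogeneous,
        n_nodules=n,
        subgroup=tuple(int(s) for s in subgroup),
        true_rates_percent=tuple(float(r) for r in rates),
        n_truncated=n_trunc,
    )
    return series, truth


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientSeries], pd.DataFrame]:
    """Generate ``n_patients`` series plus a per-patient truth table.

    Every patient is heterogeneous under the two_subgroup model and
    homogeneous otherwise; mixed cohorts are composed from two configs.
    """
    rng = np.random.default_rng(config.seed)
    het = config.growth_model == "two_subgroup"
    series: list[PatientSeries] = []
    truths: list[PatientTruth] = []
    for i in range(config.n_patients):
        s, t = generate_patient(config, het, rng, patient_id=f"sim-{i + 1}")
        series.append(s)
        truths.append(t)
    truth_df = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in truths],
            "heterogeneous": [t.heterogeneous for t in truths],
            "n_nodules": [t.n_nodules for t in truths],
            "subgroup": [";".join(map(str, t.subgroup)) for t in truths],
            "true_rates_percent": [
                ";".join(f"{r:.6g}" for r in t.true_rates_percent) for t in truths
            ],
            "n_truncated": [t.n_truncated for t in truths],
        }
    )
    return series, truth_df


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["interval_days_range"] = list(config.interval_days_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "seed" not in data:
        raise ConfigurationError("config file must set a seed")
    if "interval_days_range" in data:
        data["interval_days_range"] = tuple(data["interval_days_range"])
    return SimulationConfig(**data)
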