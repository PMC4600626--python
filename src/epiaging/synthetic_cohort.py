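"""Synthetic methylation cohorts with planted ground truth.

Emulates a prospective cohort of postmenopausal women aged 50-79 followed
for up to 20 years with a rare (~2% cumulative) lung-cancer-like event:

* per-subject chronological age, a Gaussian latent *age acceleration*
  (years by which the epigenome is older than the calendar age), smoking
  status/pack-years, CHD and race/ethnicity covariates;
* blood cell composition drawn from a Dirichlet over seven leukocyte
  types, optionally age-dependent to let tests probe confounding control;
* a beta-value matrix composed of the cell-type mixture, an age signal on
  a designated subset of clock probes, and logit-scale Gaussian noise
  mapped back through the logistic function (so values stay in (0,1));
* event times from a constant-baseline-hazard proportional-hazards model
  in which standardized acceleration carries a configurable log hazard
  ratio alongside the usual epidemiological covariates.

Every stage is driven by a single integer seed, expanded into independent
streams per stage, so identical configs reproduce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import hadamard
from scipy.special import expit, logit

from .cell_deconvolution import DEFAULT_CELL_TYPES, ReferenceSignature
from .methylation_core import ClockModel, transform_age

__all__ = [
    "InvalidConfigError",
    "SimulationConfig",
    "simulate_reference_signatures",
    "simulate_subjects",
    "simulate_betas",
    "simulate_events",
    "simulate_cohort",
    "true_clock_model",
    "clock_probe_ids",
]


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


# Log hazard ratios planted on the non-IEAA covariates, chosen to mirror a
# full-cohort lung-cancer model in a comparable population: age per year
# (centered at 65), smoking status, pack-years per year, CHD, race.
DEFAULT_COVARIATE_LOG_HR = {
    "age_per_year": math.log(1.09),
    "former": math.log(2.22),
    "current": math.log(6.17),
    "pack_years": math.log(1.03),
    "chd": math.log(0.64),
    "black": math.log(0.87),
    "hispanic": math.log(1.25),
}

# Mean blood composition for the seven modelled leukocyte types
# (granulocytes dominate whole blood).
_MEAN_FRACTIONS_7 = np.array([0.04, 0.03, 0.02, 0.20, 0.08, 0.08, 0.55])

_AGE_CENTER = 65.0

# Sub-stream identifiers for the per-stage random generators.
_STREAM_SIGNATURES = 0
_STREAM_CLOCK = 1
_STREAM_SUBJECTS = 2
_STREAM_BETAS = 3
_STREAM_EVENTS = 4


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults describe the emulated study population: n=2,000 women aged
    50-79, acceleration SD of 5 years, ~2% cumulative event incidence over
    20 years of follow-up with a planted hazard ratio of 1.5 per SD of
    acceleration, and smoking/race/CHD prevalences matching the cohort's
    baseline table.
    """

    n_subjects: int = 2000
    n_probes: int = 500
    n_clock_probes: int = 60
    n_celltypes: int = 7
    age_range: tuple[float, float] = (50.0, 79.0)
    acceleration_sd: float = 5.0
    beta_noise_sd: float = 0.05
    true_log_hr_per_sd: float = math.log(1.5)
    baseline_rate: float = 2.5e-4  # events per person-year at reference covariates
    followup_max: float = 20.0
    smoking_prevalence: dict = field(
        default_factory=lambda: {"never": 0.544, "former": 0.352, "current": 0.104}
    )
    race_prevalence: dict = field(
        default_factory=lambda: {"white": 0.477, "black": 0.319, "hispanic": 0.204}
    )
    chd_prevalence: float = 0.31
    pack_years_mean: dict = field(
        default_factory=lambda: {"former": 19.4, "current": 25.9}
    )
    dirichlet_concentration: float = 50.0
    cell_age_dependence: float = 0.0  # per-year log shift of Gran vs naive CD8
    clock_mode: str = "logit"  # 'logit' (slope on logit scale) or 'linear'
    clock_slope_range: tuple[float, float] = (0.01, 0.03)  # logit units / year
    covariate_log_hr: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HR)
    )
    missing_rate: float = 0.0
    seed: int = 0
    # Seed for the shared "biology" (reference signatures, clock probe
    # slopes/weights); defaults to `seed`.  Set it explicitly to draw
    # independent cohorts (different subjects/noise) from the SAME
    # underlying methylome, e.g. separate training and test cohorts for
    # clock fitting.
    biology_seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_celltypes < 2:
            raise InvalidConfigError("n_celltypes must be at least 2")
        if self.n_clock_probes > self.n_probes:
            raise InvalidConfigError("n_clock_probes cannot exceed n_probes")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidConfigError("age_range must satisfy min < max")
        for name in ("acceleration_sd", "beta_noise_sd", "baseline_rate",
                     "followup_max", "dirichlet_concentration", "missing_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        p = sum(self.smoking_prevalence.values())
        if abs(p - 1.0) > 1e-12:
            raise InvalidConfigError("smoking_prevalence must sum to 1")
        if abs(sum(self.race_prevalence.values()) - 1.0) > 1e-12:
            raise InvalidConfigError("race_prevalence must sum to 1")
        if self.clock_mode not in ("logit", "linear"):
            raise InvalidConfigError("clock_mode must be 'logit' or 'linear'")
        m = _hadamard_order(self.n_celltypes)
        if self.n_probes < m + self.n_clock_probes:
            raise InvalidConfigError(
                "n_probes too small to host discriminative and clock subsets"
            )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        d["clock_slope_range"] = list(d["clock_slope_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("age_range", "clock_slope_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    seed = config.seed
    if stream in (_STREAM_SIGNATURES, _STREAM_CLOCK) and config.biology_seed is not None:
        seed = config.biology_seed
    return np.random.default_rng([seed, stream])


def _hadamard_order(n_celltypes: int) -> int:
    return 1 << max(1, (n_celltypes - 1).bit_length())


def probe_ids(config: SimulationConfig) -> list[str]:
    return [f"cg{i:06d}" for i in range(config.n_probes)]


def discriminative_probe_ids(config: SimulationConfig) -> list[str]:
    m = _hadamard_order(config.n_celltypes)
    reps = max(1, min((config.n_probes - config.n_clock_probes) // m, 4))
    return probe_ids(config)[: m * reps]


def clock_probe_ids(config: SimulationConfig) -> list[str]:
    n_disc = len(discriminative_probe_ids(config))
    return probe_ids(config)[n_disc : n_disc + config.n_clock_probes]


def cell_type_names(config: SimulationConfig) -> list[str]:
    k = config.n_celltypes
    if k <= len(DEFAULT_CELL_TYPES):
        return list(DEFAULT_CELL_TYPES[:k])
    return list(DEFAULT_CELL_TYPES) + [f"cell{i}" for i in range(len(DEFAULT_CELL_TYPES), k)]


# ---------------------------------------------------------------------------
# Reference signatures

def simulate_reference_signatures(config: SimulationConfig) -> ReferenceSignature:
    """Generate per-cell-type mean methylation profiles.

    The discriminative subset is built from the columns of a Hadamard
    matrix (high=0.9, low=0.1, small jitter): any two distinct columns
    disagree in exactly half the positions, so every pair of cell types
    differs by ~0.4 in mean absolute beta on that subset — comfortably
    above the 0.3 design floor.  Remaining probes share a common baseline
    across cell types (plus tiny jitter), so they carry no composition
    signal.
    """
    config.validate()
    rng = _rng(config, _STREAM_SIGNATURES)
    ids = probe_ids(config)
    disc = discriminative_probe_ids(config)
    k = config.n_celltypes
    m = _hadamard_order(k)

    H = hadamard(m)[:, :k]  # m x k entries in {-1, +1}
    reps = len(disc) // m
    block = np.tile(np.where(H > 0, 0.9, 0.1), (reps, 1))
    block = block + rng.uniform(-0.02, 0.02, size=block.shape)

    baseline = rng.uniform(0.15, 0.85, size=config.n_probes - len(disc))
    rest = baseline[:, None] + rng.normal(0.0, 0.01, size=(baseline.size, k))

    values = np.clip(np.vstack([block, rest]), 0.01, 0.99)
    df = pd.DataFrame(values, index=ids, columns=cell_type_names(config))
    return ReferenceSignature(values=df, discriminative_probes=disc)


# ---------------------------------------------------------------------------
# Clock signal parameters (deterministic given the config seed)

def _logit_slopes(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config, _STREAM_CLOCK)
    lo, hi = config.clock_slope_range
    mag = rng.uniform(lo, hi, size=config.n_clock_probes)
    sign = rng.choice([-1.0, 1.0], size=config.n_clock_probes)
    return mag * sign


def _linear_weights(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config, _STREAM_CLOCK)
    mag = rng.uniform(0.05, 0.15, size=config.n_clock_probes)
    sign = rng.choice([-1.0, 1.0], size=config.n_clock_probes)
    return mag * sign


def true_clock_model(config: SimulationConfig) -> ClockModel:
    """The exact linear clock underlying ``clock_mode='linear'`` betas.

    Clock-probe betas are constructed as 0.5 + v_j (F(a) - F0) with F the
    calibrated age transform and a the biological age; the returned model
    (c_j = v_j / sum v^2, intercept F0 - 0.5 sum c_j) then satisfies
    intercept + sum_j c_j beta_j = F(a) identically, so noiseless clock
    application recovers biological age to machine precision.
    """
    v = _linear_weights(config)
    c = v / np.sum(v**2)
    f0 = transform_age(_AGE_CENTER)
    return ClockModel(
        probe_ids=clock_probe_ids(config),
        coefficients=c,
        intercept=float(f0 - 0.5 * np.sum(c)),
    )


# ---------------------------------------------------------------------------
# Subjects

def simulate_subjects(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-subject covariates and latent ground truth.

    Returns ``(phenotypes, truth)``.  Event columns of the phenotype table
    are left NaN until :func:`simulate_events` fills them.
    """
    config.validate()
    rng = _rng(config, _STREAM_SUBJECTS)
    n = config.n_subjects
    sample_ids = [f"s{i:05d}" for i in range(n)]

    age = rng.uniform(*config.age_range, size=n)
    accel = (
        rng.normal(0.0, config.acceleration_sd, size=n)
        if config.acceleration_sd > 0
        else np.zeros(n)
    )

    smoking_cats = list(config.smoking_prevalence)
    smoking = rng.choice(smoking_cats, size=n, p=list(config.smoking_prevalence.values()))
    race_cats = list(config.race_prevalence)
    race = rng.choice(race_cats, size=n, p=list(config.race_prevalence.values()))
    chd = rng.binomial(1, config.chd_prevalence, size=n)

    pack_years = np.zeros(n)
    for status, mean in config.pack_years_mean.items():
        mask = smoking == status
        # Gamma(shape=2) gives a realistic right-skewed positive dose
        pack_years[mask] = rng.gamma(2.0, mean / 2.0, size=mask.sum())

    # Dirichlet cell fractions, optionally age-dependent (granulocytes up,
    # naive CD8 down with age) to emulate immunosenescent drift.
    k = config.n_celltypes
    base = _MEAN_FRACTIONS_7[:k] if k <= 7 else np.full(k, 1.0 / k)
    base = base / base.sum()
    shift = config.cell_age_dependence * (age - _AGE_CENTER)
    means = np.tile(base, (n, 1))
    if config.cell_age_dependence != 0:
        means[:, -1] *= np.exp(shift)   # granulocyte-like majority type
        means[:, 0] *= np.exp(-shift)   # naive-CD8-like type
        means /= means.sum(axis=1, keepdims=True)
    alphas = config.dirichlet_concentration * means
    # Dirichlet via normalized gammas (vectorized over subjects)
    g = rng.standard_gamma(alphas)
    fracs = g / g.sum(axis=1, keepdims=True)

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "race_ethnicity": race,
            "smoking_status": smoking,
            "pack_years": pack_years,
            "chd": chd,
            "event": np.nan,
            "time": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(
        {"true_age": age, "true_acceleration": accel},
        index=phenotypes.index,
    )
    for j, name in enumerate(cell_type_names(config)):
        truth[f"frac_{name}"] = fracs[:, j]
    return phenotypes, truth


def true_cell_fractions(truth: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in truth.columns if c.startswith("frac_")]
    out = truth[cols].copy()
    out.columns = [c[len("frac_"):] for c in cols]
    return out


# ---------------------------------------------------------------------------
# Beta matrix

def simulate_betas(
    subjects: pd.DataFrame,
    truth: pd.DataFrame,
    signatures: ReferenceSignature,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Compose beta values: cell mixture + clock signal + logit noise.

    Each sample's profile starts as the cell-fraction-weighted mixture of
    the reference signatures.  Clock probes then carry the age signal: in
    'logit' mode a probe-specific slope times (age + acceleration - 65) is
    added on the logit scale; in 'linear' mode clock-probe betas are made
    exactly linear in transformed biological age (see
    :func:`true_clock_model`).  Gaussian noise is added on the logit scale
    and mapped back through the logistic function, so outputs are always
    strictly inside (0, 1).
    """
    ids = probe_ids(config)
    if list(signatures.values.index) != ids:
        raise ValueError("signature probes do not match the configured probe set")
    R = signatures.values.to_numpy()  # probes x celltypes
    W = true_cell_fractions(truth).to_numpy()  # subjects x celltypes
    if W.shape[1] != R.shape[1]:
        raise ValueError("cell-fraction / signature dimension mismatch")

    base = R @ W.T  # probes x subjects
    x = logit(np.clip(base, 1e-12, 1 - 1e-12))

    clock_idx = np.array([ids.index(p) for p in clock_probe_ids(config)])
    bio_age = truth["true_age"].to_numpy() + truth["true_acceleration"].to_numpy()
    if config.clock_mode == "logit":
        slopes = _logit_slopes(config)
        x[clock_idx, :] += np.outer(slopes, bio_age - _AGE_CENTER)
    else:  # 'linear'
        v = _linear_weights(config)
        f = transform_age(bio_age) - transform_age(_AGE_CENTER)
        clock_beta = 0.5 + np.outer(v, f)
        x[clock_idx, :] = logit(np.clip(clock_beta, 1e-12, 1 - 1e-12))

    rng = _rng(config, _STREAM_BETAS)
    if config.beta_noise_sd > 0:
        x = x + rng.normal(0.0, config.beta_noise_sd, size=x.shape)

    betas = pd.DataFrame(expit(x), index=ids, columns=subjects.index)
    if config.missing_rate > 0:
        mask = rng.random(betas.shape) < config.missing_rate
        betas = betas.mask(mask)
    return betas


# ---------------------------------------------------------------------------
# Event times

def simulate_events(
    subjects: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exponential event times under the planted proportional-hazards
    model and apply administrative censoring at ``followup_max`` years.

    hazard_i = baseline_rate * exp(beta_acc * z_i + covariate effects),
    with z the acceleration standardized by its population SD.  Returns
    updated copies of both the phenotype table (event, time columns) and
    the ground truth (true_event_time, censored columns).
    """
    if config.baseline_rate < 0:
        raise InvalidConfigError("baseline_rate must be nonnegative")
    if not (np.isfinite(config.true_log_hr_per_sd) and np.isfinite(config.baseline_rate)):
        raise InvalidConfigError("hazard parameters must be finite")
    rng = _rng(config, _STREAM_EVENTS)
    n = len(subjects)

    z = (
        truth["true_acceleration"].to_numpy() / config.acceleration_sd
        if config.acceleration_sd > 0
        else np.zeros(n)
    )
    b = config.covariate_log_hr
    lin = (
        config.true_log_hr_per_sd * z
        + b.get("age_per_year", 0.0) * (subjects["age"].to_numpy() - _AGE_CENTER)
        + b.get("former", 0.0) * (subjects["smoking_status"] == "former").to_numpy()
        + b.get("current", 0.0) * (subjects["smoking_status"] == "current").to_numpy()
        + b.get("pack_years", 0.0) * subjects["pack_years"].to_numpy()
        + b.get("chd", 0.0) * subjects["chd"].to_numpy()
        + b.get("black", 0.0) * (subjects["race_ethnicity"] == "black").to_numpy()
        + b.get("hispanic", 0.0) * (subjects["race_ethnicity"] == "hispanic").to_numpy()
    )
    rate = config.baseline_rate * np.exp(lin)

    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, size=n) / np.where(rate > 0, rate, 1.0), np.inf)
    observed = np.minimum(t_event, config.followup_max)
    event = (t_event <= config.followup_max).astype(int)
    # person-years recorded at 4-decimal precision, floored away from 0
    observed = np.maximum(np.round(observed, 4), 1e-4)

    phenotypes = subjects.copy()
    phenotypes["event"] = event
    phenotypes["time"] = observed
    truth = truth.copy()
    truth["true_event_time"] = t_event
    truth["censored"] = 1 - event
    return phenotypes, truth


# ---------------------------------------------------------------------------
# One-call cohort

def simulate_cohort(config: SimulationConfig):
    """Run all generator stages; returns (betas, phenotypes, truth, signatures)."""
    signatures = simulate_reference_signatures(config)
    phenotypes, truth = simulate_subjects(config)
    betas = simulate_betas(phenotypes, truth, signatures, config)
    phenotypes, truth = simulate_events(phenotypes, truth, config)
    return betas, phenotypes, truth, signatures
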