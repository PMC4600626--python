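"""Beta values, the calibrated age transform, and DNA-methylation age.

An epigenetic clock predicts chronological age from a sparse weighted sum of
CpG methylation beta values.  Because methylation changes much faster (on a
log scale) in childhood than in adulthood, the clock is fit on a transformed
age scale: logarithmic below a calibration knot (``adult_age``, 20 years by
convention) and linear above it.  DNAm age is the inverse transform of the
linear predictor, in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV

__all__ = [
    "ClockModel",
    "DnamAgeResult",
    "beta_from_intensities",
    "transform_age",
    "inverse_transform",
    "apply_clock",
    "train_clock",
    "read_clock_coefficients",
    "write_clock_coefficients",
    "read_beta_matrix",
    "write_beta_matrix",
]

INTERCEPT_ID = "(Intercept)"


@dataclass
class ClockModel:
    """Sparse linear age predictor on the transformed-age scale.

    Parameters
    ----------
    probe_ids : list of str
        CpG identifiers carrying nonzero weight.
    coefficients : ndarray
        Weight per probe, in transformed-age units per beta unit.
    intercept : float
        Transformed-age units.
    adult_age : float
        Calibration knot of the age transform, years.
    """

    probe_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.probe_ids) != self.coefficients.size:
            raise ValueError("probe_ids and coefficients length mismatch")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe IDs in clock model")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        if self.adult_age <= -1:
            raise ValueError("adult_age must exceed -1")


@dataclass
class DnamAgeResult:
    """Per-sample DNAm age with an explicit record of failed samples."""

    dnam_age: pd.Series
    failed_samples: list[str] = field(default_factory=list)


def beta_from_intensities(M, U):
    """Beta value from methylated (M) and unmethylated (U) intensities.

    beta = Max(M,0) / [Max(M,0) + Max(U,0) + 100].  The +100 offset
    regularizes low-intensity probes, so the result lies in [0, 1) and is
    deliberately not scale-invariant.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    out = m / (m + u + 100.0)
    return out if out.ndim else float(out)


def transform_age(age, adult_age: float = 20.0):
    """Calibrated age transform: log below the knot, linear above.

    F(age) = log(age+1) - log(adult_age+1) for age <= adult_age,
    else (age - adult_age) / (adult_age + 1).  Continuous, strictly
    increasing, zero at the knot.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValueError("age must exceed -1 years")
    out = np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform(t, adult_age: float = 20.0):
    """Exact inverse of :func:`transform_age`, returning years."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        np.expm1(t + np.log1p(adult_age)),
        t * (adult_age + 1.0) + adult_age,
    )
    return out if out.ndim else float(out)


def apply_clock(
    betas: pd.DataFrame,
    model: ClockModel,
    missing_policy: str = "mean",
    min_probe_fraction: float = 0.8,
) -> DnamAgeResult:
    """Predict DNAm age for every sample of a beta matrix.

    Parameters
    ----------
    betas : DataFrame
        Probes x samples, values in [0, 1], NaN for missing.
    model : ClockModel
    missing_policy : {"mean", "midpoint"}
        How missing clock-probe betas are imputed: the probe's cohort mean
        ("mean", falling back to 0.5 when the probe is missing everywhere),
        or a flat 0.5 ("midpoint").
    min_probe_fraction : float
        A sample whose fraction of observed clock probes falls below this
        threshold is flagged as failed (NaN age, listed in
        ``failed_samples``) rather than silently imputed.

    The join is keyed on probe IDs, so probe/sample order and extraneous
    probes are irrelevant.
    """
    present = [p for p in model.probe_ids if p in betas.index]
    if not present:
        raise ValueError("no overlap between clock probes and beta matrix")
    # probes x samples, NaN rows for clock probes absent from the matrix
    sub = betas.reindex(model.probe_ids)
    observed_frac = sub.notna().mean(axis=0)

    if missing_policy == "mean":
        fill = sub.mean(axis=1).fillna(0.5)
    elif missing_policy == "midpoint":
        fill = pd.Series(0.5, index=sub.index)
    else:
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    imputed = sub.T.fillna(fill).T

    lin = model.intercept + imputed.to_numpy().T @ model.coefficients
    ages = pd.Series(
        inverse_transform(lin, model.adult_age),
        index=betas.columns, name="dnam_age", dtype=float,
    )
    failed = list(betas.columns[(observed_frac < min_probe_fraction).to_numpy()])
    ages[failed] = np.nan
    return DnamAgeResult(dnam_age=ages, failed_samples=failed)


def train_clock(
    betas: pd.DataFrame,
    ages,
    l1_ratio: float = 0.5,
    alpha: float | None = None,
    cv: int = 10,
    adult_age: float = 20.0,
    seed: int | None = 0,
) -> ClockModel:
    """Fit an elastic-net clock of transformed age on beta values.

    With ``alpha=None`` the penalty strength is chosen by ``cv``-fold
    cross-validation (fold assignment seeded for reproducibility).  Only
    probes with nonzero coefficients are retained in the returned model.
    """
    ages = np.asarray(ages, dtype=float)
    if betas.shape[1] < 20:
        raise ValueError("need at least 20 samples to train a clock")
    if betas.shape[1] != ages.size:
        raise ValueError("number of samples and ages differ")
    y = transform_age(ages, adult_age)
    if np.ptp(y) == 0:
        raise ValueError("constant response: all ages identical after transform")
    X = betas.to_numpy().T  # samples x probes

    if alpha is None:
        est = ElasticNetCV(
            l1_ratio=l1_ratio, cv=cv, alphas=50, max_iter=10000,
            random_state=seed,
        )
    else:
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=100000)
    est.fit(X, y)

    keep = np.flatnonzero(est.coef_)
    return ClockModel(
        probe_ids=[betas.index[i] for i in keep],
        coefficients=est.coef_[keep],
        intercept=float(est.intercept_),
        adult_age=adult_age,
    )


# ---------------------------------------------------------------------------
# I/O — clock coefficient CSV and beta-matrix TSV

def write_clock_coefficients(model: ClockModel, path) -> None:
    """Write a two-column CSV (CpG, coefficient); the intercept is the row
    with the reserved ID ``(Intercept)``."""
    df = pd.DataFrame(
        {
            "CpG": [INTERCEPT_ID] + list(model.probe_ids),
            "coefficient": np.concatenate([[model.intercept], model.coefficients]),
        }
    )
    df.to_csv(path, index=False)


def read_clock_coefficients(path, adult_age: float = 20.0) -> ClockModel:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("clock coefficient file needs two columns")
    ids = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1].astype(float)
    is_int = ids == INTERCEPT_ID
    if is_int.sum() != 1:
        raise ValueError(f"expected exactly one {INTERCEPT_ID!r} row")
    probes = ids[~is_int].tolist()
    if len(set(probes)) != len(probes):
        raise ValueError("duplicate probe IDs in coefficient file")
    return ClockModel(
        probe_ids=probes,
        coefficients=vals[~is_int].to_numpy(),
        intercept=float(vals[is_int].iloc[0]),
        adult_age=adult_age,
    )


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    """TSV with probe IDs in the first column, sample IDs as header, NA for
    missing values."""
    betas.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate probe or sample identifiers")
    return df
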