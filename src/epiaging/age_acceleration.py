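"""Intrinsic epigenetic age acceleration (IEAA).

IEAA is the residual from an ordinary least squares regression of DNAm age
on chronological age and seven blood cell-type abundance measures.  The
residual is "intrinsic" in the sense that it is orthogonal, by
construction, to chronological age and to cell composition — it captures
epigenetic aging of the blood beyond what age and immune-cell shifts
explain.  A positive value means the methylome looks older than expected.

The standardized form (cohort z-score, mean 0 / SD 1) is the covariate
entered into the downstream survival models, so hazard ratios are per SD
of acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_deconvolution import CellFractions

__all__ = ["IEAAResult", "compute_ieaa", "eeaa_unadjusted"]


@dataclass
class IEAAResult:
    raw_residual: pd.Series       # years
    standardized: pd.Series       # cohort z-score
    regression_coefficients: pd.Series
    r_squared: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_residual.index)


def _as_fraction_frame(cells) -> pd.DataFrame:
    if isinstance(cells, CellFractions):
        return cells.fractions
    return pd.DataFrame(cells)


def compute_ieaa(
    dnam_ages: pd.Series,
    chron_ages: pd.Series,
    cells,
    drop_collinear: str | None = "auto",
    ddof: int = 1,
) -> IEAAResult:
    """Residualize DNAm age on chronological age and cell fractions.

    Parameters
    ----------
    dnam_ages, chron_ages : Series indexed by sample ID (years).  Samples
        with missing DNAm age (failed clock application) are excluded
        listwise.
    cells : CellFractions or DataFrame (samples x cell types).
    drop_collinear : "auto" drops the granulocyte (majority, last) column
        when the fractions sum to one — they are then exactly collinear
        with the intercept; None disables the rule.
    ddof : degrees of freedom for the standardization SD (1 = sample SD).
    """
    fr = _as_fraction_frame(cells)
    common = dnam_ages.dropna().index.intersection(chron_ages.index).intersection(fr.index)
    if len(common) < 10:
        raise ValueError("need at least 10 complete samples")
    y = dnam_ages.loc[common].to_numpy(dtype=float)
    age = chron_ages.loc[common].to_numpy(dtype=float)
    F = fr.loc[common]

    if drop_collinear == "auto":
        sums = F.sum(axis=1)
        if np.allclose(sums, 1.0, atol=1e-6):
            F = F.iloc[:, :-1]
    cols = ["intercept", "age"] + list(F.columns)
    X = np.column_stack([np.ones(len(common)), age, F.to_numpy(dtype=float)])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column for the error message
        dep = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                dep.append(cols[j])
        raise ValueError(f"collinear regressors: {dep}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    sd = resid.std(ddof=ddof)
    if sd <= 1e-10 * max(1.0, float(np.std(y))):
        raise ValueError("zero-variance residuals: DNAm age is an exact "
                         "linear function of the regressors")
    std = (resid - resid.mean()) / sd

    return IEAAResult(
        raw_residual=pd.Series(resid, index=common, name="ieaa"),
        standardized=pd.Series(std, index=common, name="ieaa_std"),
        regression_coefficients=pd.Series(beta, index=cols),
        r_squared=r2,
    )


def eeaa_unadjusted(dnam_ages: pd.Series, chron_ages: pd.Series) -> pd.Series:
    """Age-only residual (not cell-adjusted) — the simpler acceleration
    measure that can remain confounded by blood composition; provided for
    comparison against IEAA."""
    common = dnam_ages.dropna().index.intersection(chron_ages.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least 3 complete samples")
    y = dnam_ages.loc[common].to_numpy(dtype=float)
    age = chron_ages.loc[common].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("constant chronological age: regression is rank-deficient")
    X = np.column_stack([np.ones(len(common)), age])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=common, name="eeaa")
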