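"""Reference-based blood cell-type deconvolution.

A whole-blood methylation profile is approximately a convex combination of
the profiles of its constituent cell types.  Given a reference signature
matrix R (probes x cell types, mean beta per sorted cell population), the
per-sample composition w solves

    min_w || beta - R w ||^2    s.t.  w >= 0  (and optionally  sum w = 1).

Seven leukocyte populations are modelled by default: naive CD8 T cells,
exhausted (CD28-CD45RA-) CD8 T cells, plasmablasts, CD4 T cells, natural
killer cells, monocytes and granulocytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CELL_TYPES",
    "ReferenceSignature",
    "CellFractions",
    "deconvolve",
    "build_reference_from_sorted_profiles",
    "read_reference_signature",
    "write_reference_signature",
]

DEFAULT_CELL_TYPES = (
    "CD8T_naive",
    "CD8T_exhausted",
    "PlasmaBlast",
    "CD4T",
    "NK",
    "Mono",
    "Gran",
)

# Base weight of the sum-to-one penalty row appended to the NNLS system.
SUM_PENALTY = 1e4


@dataclass
class ReferenceSignature:
    """Mean methylation per cell type (probes x cell types, values in [0,1]).

    ``discriminative_probes`` optionally records the subset of probes
    designed (or selected) to separate the cell types.
    """

    values: pd.DataFrame
    discriminative_probes: list[str] | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("reference signature values must lie in [0, 1]")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell-type names")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellFractions:
    """Per-sample composition estimates plus the least-squares residual."""

    fractions: pd.DataFrame      # samples x cell types
    residual_norm: pd.Series     # per-sample ||beta - R w||

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)


def deconvolve(
    betas: pd.DataFrame,
    reference: ReferenceSignature,
    constraint_mode: str = "sum1",
) -> CellFractions:
    """Estimate cell fractions per sample by constrained least squares.

    Parameters
    ----------
    betas : DataFrame
        Probes x samples.  Probes absent from the reference are ignored
        (with a logged count); probe order is irrelevant.
    reference : ReferenceSignature
    constraint_mode : {"sum1", "free"}
        "sum1" enforces w >= 0 and sum(w) = 1 (the seven blood types treated
        as exhaustive); "free" enforces nonnegativity only, matching
        imputation methods that report abundances on an arbitrary scale.

    The sum constraint is imposed through a heavily weighted extra equation
    appended to the NNLS system; the weight scales with the magnitude of the
    reference so the residual sum-to-one violation stays below 1e-8
    regardless of probe count.
    """
    if constraint_mode not in ("sum1", "free"):
        raise ValueError(f"unknown constraint_mode: {constraint_mode!r}")
    shared = betas.index.intersection(reference.values.index)
    n_ignored = betas.shape[0] - len(shared)
    if len(shared) == 0:
        raise ValueError("no probes shared between beta matrix and reference")
    if n_ignored:
        logger.info("deconvolve: ignoring %d probes absent from reference", n_ignored)
    R = reference.values.loc[shared].to_numpy(dtype=float)
    k = R.shape[1]
    if len(shared) < 2 or np.linalg.matrix_rank(R) < k:
        corr = np.corrcoef(R.T)
        pairs = [
            (reference.cell_type_names[i], reference.cell_type_names[j])
            for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(
            "reference is rank-deficient on shared probes; "
            f"collinear cell types: {pairs or 'undetermined'}"
        )

    if constraint_mode == "sum1":
        lam = SUM_PENALTY * max(1.0, np.linalg.norm(R))
        A = np.vstack([R, lam * np.ones((1, k))])
    else:
        A = R

    B = betas.loc[shared].to_numpy(dtype=float)
    W = np.empty((B.shape[1], k))
    res = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        b = B[:, j]
        y = np.concatenate([b, [lam]]) if constraint_mode == "sum1" else b
        w, _ = nnls(A, y)
        W[j] = w
        res[j] = np.linalg.norm(b - R @ w)

    cols = reference.cell_type_names
    return CellFractions(
        fractions=pd.DataFrame(W, index=betas.columns, columns=cols),
        residual_norm=pd.Series(res, index=betas.columns, name="residual_norm"),
    )


def build_reference_from_sorted_profiles(
    pure_samples: pd.DataFrame,
    labels,
    top_k: int | None = None,
) -> ReferenceSignature:
    """Average sorted-cell profiles into a signature matrix.

    ``labels`` assigns a cell type to each column of ``pure_samples``.  With
    ``top_k`` set, only the k probes with the largest between-type one-way
    F statistic are retained (and recorded as the discriminative set).
    """
    labels = pd.Series(np.asarray(labels), index=pure_samples.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two cell types")
    means = {g: pure_samples.loc[:, labels[labels == g].index].mean(axis=1) for g in groups}
    ref = pd.DataFrame(means)

    disc = None
    if top_k is not None:
        per_group = [pure_samples.loc[:, labels[labels == g].index].to_numpy() for g in groups]
        if min(g.shape[1] for g in per_group) < 2:
            # F statistic needs within-group replication; fall back to range
            spread = ref.max(axis=1) - ref.min(axis=1)
            order = spread.sort_values(ascending=False).index
        else:
            f, _ = stats.f_oneway(*[g.T for g in per_group])
            order = pd.Series(f, index=pure_samples.index).sort_values(ascending=False).index
        disc = list(order[:top_k])
        ref = ref.loc[disc]
    return ReferenceSignature(values=ref, discriminative_probes=disc)


def write_reference_signature(reference: ReferenceSignature, path) -> None:
    reference.values.to_csv(path, sep="\t", index_label="probe_id")


def read_reference_signature(path) -> ReferenceSignature:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReferenceSignature(values=df)
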