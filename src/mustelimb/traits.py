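"""Specimen-to-species trait preparation and size-corrected PCA.

The measurement schema is 14 linear forelimb dimensions (mm) spanning the
scapula, humerus, radius, ulna and metacarpal III.  Size correction follows
the log-shape-ratio idea: each log trait is regressed (OLS, with intercept)
on the log geometric mean of all 14 traits across species, and the residuals
— dimensionless log deviations from the shared allometry — enter a covariance
PCA.  Component significance is judged against the broken-stick null.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAIT_NAMES",
    "species_means",
    "geometric_mean",
    "size_residuals",
    "ResidualMatrix",
    "pca",
    "PCAResult",
    "broken_stick",
    "significant_pcs",
]

#: canonical measurement schema: 14 linear forelimb dimensions in mm
TRAIT_NAMES = [
    "scapula_length",
    "humerus_length",
    "humerus_ap_diameter",
    "humerus_ml_diameter",
    "deltoid_ridge_length",
    "epicondylar_breadth",
    "radius_length",
    "radius_ap_diameter",
    "radius_ml_diameter",
    "ulna_length",
    "ulna_ap_diameter",
    "ulna_ml_diameter",
    "olecranon_process_length",
    "metacarpal3_length",
]


def _trait_columns(df: pd.DataFrame) -> list[str]:
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table lacks trait columns: {missing}")
    return TRAIT_NAMES


def species_means(specimens: pd.DataFrame) -> pd.DataFrame:
    """Per-species arithmetic means of each trait, on the raw mm scale.

    ``specimens`` needs a ``species`` column plus the 14 trait columns of
    :data:`TRAIT_NAMES`.  Missing cells and non-positive measurements are
    errors, not silently dropped.
    """
    cols = _trait_columns(specimens)
    if "species" not in specimens.columns:
        raise ValueError("specimen table lacks a 'species' column")
    block = specimens[cols]
    if block.isna().any().any():
        raise ValueError("missing trait measurements are not allowed")
    if (block.to_numpy() <= 0).any():
        raise ValueError("trait measurements must be positive (mm)")
    means = specimens.groupby("species", sort=True)[cols].mean()
    means.index.name = "species"
    return means


def geometric_mean(values: np.ndarray | pd.DataFrame, axis: int = -1) -> np.ndarray:
    """Geometric mean, ``exp(mean(ln x))``; all values must be positive."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.log(arr).mean(axis=axis))


@dataclass(frozen=True)
class ResidualMatrix:
    """OLS residuals of log trait on log geometric mean, per species.

    ``residuals`` is species × traits (dimensionless log deviations);
    ``slopes``/``intercepts`` hold the per-trait allometric regressions.
    """

    residuals: pd.DataFrame
    slopes: pd.Series
    intercepts: pd.Series


def size_residuals(trait_table: pd.DataFrame) -> ResidualMatrix:
    """Size-correct a species × trait mm table via log–log OLS residuals.

    For each trait ``j``, regress ``ln(trait_j)`` on ``ln(GM)`` across species
    (GM = geometric mean of the 14 traits per species) and keep the residuals.
    Natural logarithms are used throughout; the base only rescales residuals
    uniformly.
    """
    if len(trait_table) < 3:
        raise ValueError("need at least 3 species for allometric regressions")
    cols = _trait_columns(trait_table)
    X = trait_table[cols].to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("trait means must be positive")
    log_gm = np.log(geometric_mean(X, axis=1))
    if np.ptp(log_gm) < 1e-12:
        raise ValueError("geometric mean is constant across species; "
                         "allometric regression is degenerate")
    logX = np.log(X)
    slopes, intercepts, resid = [], [], np.empty_like(logX)
    for j in range(logX.shape[1]):
        fit = stats.linregress(log_gm, logX[:, j])
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
        resid[:, j] = logX[:, j] - (fit.intercept + fit.slope * log_gm)
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=trait_table.index, columns=cols),
        slopes=pd.Series(slopes, index=cols, name="slope"),
        intercepts=pd.Series(intercepts, index=cols, name="intercept"),
    )


@dataclass(frozen=True)
class PCAResult:
    """Covariance PCA of the residual matrix.

    ``loadings`` is traits × components with unit-norm columns, signed so the
    largest-magnitude loading of each component is positive; ``scores`` is
    species × components; ``proportions`` are eigenvalue shares of the trace.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    proportions: np.ndarray
    zero_variance: np.ndarray  # mask of numerically degenerate components
    column_means: pd.Series

    @property
    def n_components(self) -> int:
        return self.proportions.size


def pca(rm: ResidualMatrix | pd.DataFrame, mode: str = "covariance") -> PCAResult:
    """Principal components of size-corrected residuals.

    The default decomposes the covariance matrix of the residual columns —
    they are already dimensionless log deviations on a common scale.
    ``mode="correlation"`` standardises columns first (sensitivity check).
    """
    R = rm.residuals if isinstance(rm, ResidualMatrix) else rm
    if len(R) < 3:
        raise ValueError("need at least 3 species for a PCA")
    X = R.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    if mode == "correlation":
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    elif mode != "covariance":
        raise ValueError(f"unknown PCA mode {mode!r}")
    # SVD route: eigenvalues of the (ddof=1) covariance are s^2/(n-1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (len(R) - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("residual matrix has zero total variance")
    load = Vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, k]))
        if load[i, k] < 0:
            load[:, k] = -load[:, k]
    scores = Xc @ load
    zero = eig <= 1e-12 * max(total, 1.0)
    comp = [f"PC{k + 1}" for k in range(load.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(load, index=R.columns, columns=comp),
        scores=pd.DataFrame(scores, index=R.index, columns=comp),
        proportions=eig / total,
        zero_variance=zero,
        column_means=pd.Series(mu, index=R.columns),
    )


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected variance proportions for ``p`` components.

    Component ``k`` (1-based) expects ``(1/p) * sum_{i=k..p} 1/i``; the
    proportions sum to 1.
    """
    if p < 1:
        raise ValueError("number of components must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def significant_pcs(pr: PCAResult) -> list[int]:
    """Component numbers (1-based) whose variance share strictly exceeds the
    broken-stick expectation.

    Exceedances are reported in order; a non-contiguous set (e.g. PC1 and PC3
    but not PC2) is returned as-is with a warning.
    """
    expect = broken_stick(pr.n_components)
    idx = [k + 1 for k in range(pr.n_components) if pr.proportions[k] > expect[k]]
    if idx and idx != list(range(1, len(idx) + 1)):
        warnings.warn(
            "significant components are non-contiguous; interpret with care",
            stacklevel=2,
        )
    return idx
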