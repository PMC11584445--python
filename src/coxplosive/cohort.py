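"""Cohort-level statistics: rank correlations, PCA, and the PC1 regression.

The per-specimen table holds seven magnitudes — the fitted process
parameters (alpha, lam), the Pareto energy exponent nu, the observables
N_AE and eps_max, and the donor covariates age and BMI.  The analysis
stage computes the Spearman correlation matrix with two-sided p-values,
a PCA of the (by default standardized) table, and an ordinary least-
squares regression of the first principal component — the "inveteration"
degradation axis — on age and BMI.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_events import SpecimenRecord

__all__ = [
    "COHORT_COLUMNS",
    "PcaResult",
    "RegressionResult",
    "build_cohort_table",
    "spearman_matrix",
    "run_pca",
    "regress_pc1",
]

log = logging.getLogger(__name__)

#: canonical column order of the seven analyzed magnitudes
COHORT_COLUMNS = ("alpha", "lam", "nu", "n_ae", "eps_max", "age", "bmi")


@dataclass(frozen=True)
class PcaResult:
    """Eigendecomposition of the cohort table's correlation/covariance.

    ``loadings`` has one orthonormal component per column, ordered by
    descending explained variance; the sign convention makes each
    component's largest-magnitude entry positive.  ``scores`` are the
    (standardized) data projected on the components.
    """

    loadings: pd.DataFrame          # variables x components
    variance_fractions: np.ndarray  # descending, sums to 1
    scores: np.ndarray              # n x p
    standardized: bool

    @property
    def pc1_fraction(self) -> float:
        return float(self.variance_fractions[0])


@dataclass(frozen=True)
class RegressionResult:
    """OLS of PC1 on age and BMI."""

    intercept: float
    coef_age: float
    coef_bmi: float
    r_squared: float
    p_intercept: float
    p_age: float
    p_bmi: float
    collinear: bool


def build_cohort_table(records) -> pd.DataFrame:
    """Assemble the seven-column analysis table from specimen records.

    Accepts :class:`SpecimenRecord` objects, dicts, or a DataFrame.  Rows
    with any missing analyzed magnitude are dropped (and logged) — they
    would otherwise silently distort rank correlations and PCA.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [r.to_dict() if isinstance(r, SpecimenRecord) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing column(s) {missing_cols}")
    if "specimen_id" in df.columns:
        df = df.set_index("specimen_id")
    df = df[list(COHORT_COLUMNS)].astype(float)
    complete = df.notna().all(axis=1)
    if (~complete).any():
        log.warning("dropping %d specimen(s) with missing values: %s",
                    (~complete).sum(), list(df.index[~complete]))
    df = df[complete]
    if len(df) < 3:
        raise ValueError(f"cohort analysis needs >= 3 complete specimens, got {len(df)}")
    return df


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the Spearman rho.

    Enumerates all pairings of the rank vectors (feasible for the small
    cohorts this is used on); ties are handled by average ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perms = ry[perms]                              # (n!, n)
    # rho is a monotone transform of the rank dot-product, so compare those
    obs = float(rx @ ry)
    vals = ry_perms @ rx
    mean = rx.sum() * ry.sum() / n
    return float(np.mean(np.abs(vals - mean) >= abs(obs - mean) - 1e-9))


def spearman_matrix(
    table: pd.DataFrame,
    p_method: Literal["auto", "approx", "exact"] = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrix and two-sided p-values of a cohort table.

    Ties get average ranks.  p-values use the t approximation for n >= 10
    and exact rank-permutation enumeration below that (``p_method``
    overrides).  A constant column has undefined rank correlation: its
    cells are returned as NaN, never coerced to zero.
    """
    n, p = table.shape
    if n < 3:
        raise ValueError("spearman_matrix needs >= 3 rows")
    cols = list(table.columns)
    rho = pd.DataFrame(np.eye(p), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((p, p)), index=cols, columns=cols)
    use_exact = p_method == "exact" or (p_method == "auto" and n < 10)
    X = table.to_numpy(dtype=float)
    constant = np.array([np.all(c == c[0]) for c in X.T])
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                r, pv = math.nan, math.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, pv = stats.spearmanr(X[:, i], X[:, j])
                if use_exact:
                    pv = _exact_spearman_pvalue(X[:, i], X[:, j])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = pv
    for i in range(p):
        if constant[i]:
            rho.iloc[i, i] = math.nan
            pval.iloc[i, i] = math.nan
    return rho, pval


def run_pca(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of the cohort table by eigendecomposition of its covariance.

    With ``standardize=True`` (default — the seven magnitudes carry
    incommensurate units) variables are z-scored first, which makes this a
    correlation-matrix PCA.  Components are ordered by descending variance;
    each loading vector is flipped so its largest-magnitude entry is
    positive, making signs reproducible.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("run_pca needs >= 3 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        sd = X.std(axis=0, ddof=1)
        # constant up to float rounding counts as zero-variance
        dead = np.nonzero(sd <= 1e-12 * np.maximum(np.abs(mean), 1.0))[0]
        if dead.size:
            names = [table.columns[i] for i in dead]
            raise ValueError(f"cannot standardize zero-variance column(s) {names}")
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|entry| of each component positive
    flips = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(p)])
    flips[flips == 0] = 1.0
    eigvec = eigvec * flips
    fractions = eigval / eigval.sum()
    return PcaResult(
        loadings=pd.DataFrame(eigvec, index=table.columns,
                              columns=[f"PC{i + 1}" for i in range(p)]),
        variance_fractions=fractions,
        scores=Xc @ eigvec,
        standardized=standardize,
    )


def regress_pc1(pc1_scores, age, bmi) -> RegressionResult:
    """OLS of the inveteration score (PC1) on donor age and BMI.

    Returns the intercept and per-year / per-unit-BMI slopes with r^2 and
    two-sided p-values.  Collinear regressors are flagged (condition number
    of the design > 1e8) with a warning, but coefficients are still
    returned.
    """
    y = np.asarray(pc1_scores, dtype=float)
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if len(y) < 4:
        raise ValueError("regress_pc1 needs >= 4 specimens")
    X = sm.add_constant(np.column_stack([age, bmi]))
    collinear = bool(np.linalg.cond(X) > 1e8)
    if collinear:
        warnings.warn("age and BMI are (near-)collinear; coefficients are unstable",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, X).fit()
    return RegressionResult(
        intercept=float(fit.params[0]),
        coef_age=float(fit.params[1]),
        coef_bmi=float(fit.params[2]),
        r_squared=float(fit.rsquared),
        p_intercept=float(fit.pvalues[0]),
        p_age=float(fit.pvalues[1]),
        p_bmi=float(fit.pvalues[2]),
        collinear=collinear,
    )
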