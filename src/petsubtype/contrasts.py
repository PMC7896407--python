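"""Voxel-wise covariate-adjusted group contrasts and Cohen's d maps.

Per voxel, intensity is regressed on an intercept, a group indicator
(group A = 1, group B = 0) and optional covariates; the t statistic of
the group column visualizes hypometabolism (negative t/d = group A lower
than group B). t maps are converted to Cohen's d via the two-sample
conversion d = t * sqrt(1/n1 + 1/n2). The maps are descriptive; no
voxel-wise multiplicity correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """Rank-deficient design matrix (e.g. covariate collinear with group)."""


@dataclass
class ContrastResult:
    t_map: np.ndarray
    d_map: np.ndarray
    df: int
    n1: int
    n2: int
    covariate_names: list[str]

    def p_map(self) -> np.ndarray:
        """Two-sided p-values from the Student t(df) reference."""
        return 2.0 * stats.t.sf(np.abs(self.t_map), self.df)


def t_to_cohens_d(t: float | np.ndarray, n1: int, n2: int) -> float | np.ndarray:
    """Standard two-sample conversion, sign preserved: d = t*sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    return np.asarray(t, dtype=float) * np.sqrt(1.0 / n1 + 1.0 / n2)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a column whose removal restores full rank
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == min(Xr.shape):
                raise DesignError(f"design is rank deficient; column {names[j]!r} "
                                  "is collinear with the others")
        raise DesignError("design is rank deficient")


def voxelwise_group_contrast(profiles_a: np.ndarray, profiles_b: np.ndarray,
                             covariates: pd.DataFrame | None = None) -> ContrastResult:
    """Vectorized least-squares contrast of two groups over all voxels.

    ``covariates`` (if given) must stack group A rows first, then group B,
    matching the row order of the profile matrices. The residual degrees
    of freedom are identical at every voxel.
    """
    A = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    B = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("profile matrices must share the voxel dimension")
    n1, n2 = A.shape[0], B.shape[0]
    Y = np.vstack([A, B])
    n = n1 + n2

    cols = [np.ones(n), np.concatenate([np.ones(n1), np.zeros(n2)])]
    names = ["intercept", "group"]
    if covariates is not None and len(covariates.columns):
        if len(covariates) != n:
            raise ValueError("covariate rows must match total subject count")
        for c in covariates.columns:
            v = covariates[c]
            if v.isna().any():
                raise ValueError(f"covariate {c!r} has missing values")
            if v.dtype == object or str(v.dtype) == "category":
                v = pd.factorize(v)[0]
            cols.append(np.asarray(v, dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    _check_rank(X, names)

    df = n - X.shape[1]
    if df < 1:
        raise DesignError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y              # (p, V)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    d = t_to_cohens_d(t, n1, n2)
    return ContrastResult(t_map=t, d_map=np.asarray(d), df=df, n1=n1, n2=n2,
                          covariate_names=names[2:])
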