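"""Phylogenetic generalized least squares for multivariate responses.

A one-way design (ecomorph) is fitted to a possibly high-dimensional
response (species-mean asymmetry, or shape) under Brownian motion: the
design matrix and response are whitened by C^(-1/2) and sums of squares
are traces of fitted and residual cross-product matrices, so the F
statistic is well defined even when traits outnumber species.
Significance comes from residual randomization of the reduced
(intercept-only) model in the transformed space (RRPP).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DesignError
from .phylo import PhyloCovariance, inv_sqrt


@dataclass
class PGLSResult:
    """Fit of a one-way multivariate PGLS.

    Sums of squares are traces of cross-product matrices of the
    transformed response; ``ss_model + ss_resid`` equals the total SS
    about the GLS mean.
    """

    f_stat: float
    ss_model: float
    ss_resid: float
    df_model: int
    df_resid: int
    groups: list[str]
    p_value: float | None = None
    z_score: float | None = None
    n_perm: int = 0
    permuted_f: np.ndarray | None = None

    def anova_table(self) -> pd.DataFrame:
        rows = [
            {
                "effect": "groups",
                "df": self.df_model,
                "SS": self.ss_model,
                "MS": self.ss_model / self.df_model,
                "F": self.f_stat,
                "Z": self.z_score,
                "p": self.p_value,
            },
            {
                "effect": "residuals",
                "df": self.df_resid,
                "SS": self.ss_resid,
                "MS": self.ss_resid / self.df_resid if self.df_resid else np.nan,
                "F": None,
                "Z": None,
                "p": None,
            },
        ]
        return pd.DataFrame(rows)


def _design(groups: list[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise DesignError("need at least 2 groups")
    X = np.zeros((len(groups), len(levels)))
    for i, g in enumerate(groups):
        X[i, levels.index(g)] = 1.0
    X = np.column_stack([np.ones(len(groups)), X[:, 1:]])  # intercept + dummies
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("collinear design matrix")
    return X, levels


def _fit_transformed(Xt: np.ndarray, Xt0: np.ndarray, Yt: np.ndarray) -> tuple[float, float, float]:
    """(ss_model, ss_resid, ss_total) on already-whitened matrices."""
    H = Xt @ np.linalg.pinv(Xt)
    H0 = Xt0 @ np.linalg.pinv(Xt0)
    resid = Yt - H @ Yt
    resid0 = Yt - H0 @ Yt
    ss_total = float((resid0**2).sum())
    ss_resid = float((resid**2).sum())
    return ss_total - ss_resid, ss_resid, ss_total


def dpgls_fit(
    Y: np.ndarray,
    groups: list[str] | dict[str, str],
    C: PhyloCovariance,
) -> PGLSResult:
    """Fit species traits on a categorical grouping under BM covariance.

    ``groups`` is either a species->group mapping or a list parallel to
    ``C.species_order``. F = (SS_model/df_model)/(SS_resid/df_resid)
    with SS as trace cross-products of the whitened response.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != C.n:
        raise AlignmentError(f"Y has {Y.shape[0]} rows for {C.n} species")
    if isinstance(groups, dict):
        missing = [s for s in C.species_order if s not in groups]
        if missing:
            raise DesignError(f"species without group assignment: {missing}")
        groups = [groups[s] for s in C.species_order]
    if len(groups) != C.n:
        raise AlignmentError("groups not parallel to species order")
    X, levels = _design(list(groups))
    M = inv_sqrt(C)
    Xt = M @ X
    Xt0 = M @ np.ones((C.n, 1))
    Yt = M @ Y
    ss_model, ss_resid, ss_total = _fit_transformed(Xt, Xt0, Yt)
    df_model = len(levels) - 1
    df_resid = C.n - len(levels)
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    # a response with no variation about the GLS mean carries no signal
    if ss_total <= 1e-12 * float((Yt**2).sum()) or ss_resid <= 0:
        f = 0.0
        ss_model = 0.0
    else:
        f = (ss_model / df_model) / (ss_resid / df_resid)
    return PGLSResult(
        f_stat=f,
        ss_model=max(ss_model, 0.0),
        ss_resid=ss_resid,
        df_model=df_model,
        df_resid=df_resid,
        groups=levels,
    )


def dpgls_permutation(
    Y: np.ndarray,
    groups: list[str] | dict[str, str],
    C: PhyloCovariance,
    n_perm: int = 1000,
    seed: int = 0,
) -> PGLSResult:
    """RRPP permutation test of the group effect.

    Residuals of the reduced (GLS-mean-only) model in the whitened
    space are row-permuted and added back to the reduced fit, and F is
    recomputed each iteration.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    result = dpgls_fit(Y, groups, C)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if isinstance(groups, dict):
        groups = [groups[s] for s in C.species_order]
    X, levels = _design(list(groups))
    M = inv_sqrt(C)
    Xt = M @ X
    Xt0 = M @ np.ones((C.n, 1))
    Yt = M @ Y
    H = Xt @ np.linalg.pinv(Xt)
    H0 = Xt0 @ np.linalg.pinv(Xt0)
    fitted0 = H0 @ Yt
    resid0 = Yt - fitted0
    df_model, df_resid = result.df_model, result.df_resid

    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        Ystar = fitted0 + resid0[rng.permutation(C.n)]
        rm = Ystar - H @ Ystar
        r0 = Ystar - H0 @ Ystar
        ssr = float((rm**2).sum())
        ssm = float((r0**2).sum()) - ssr
        f_perm[b] = (ssm / df_model) / (ssr / df_resid) if ssr > 0 else 0.0
    result.p_value = (float((f_perm >= result.f_stat).sum()) + 1.0) / (n_perm + 1.0)
    sd = float(f_perm.std())
    result.z_score = float((result.f_stat - f_perm.mean()) / sd) if sd > 0 else 0.0
    result.n_perm = n_perm
    result.permuted_f = f_perm
    return result
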