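"""Two-block partial least squares and evolutionary integration tests.

Integration between two trait blocks (here: left and right valve shape)
is summarized by r_PLS, the absolute correlation between projections of
each block onto the first pair of singular vectors of the cross-block
covariance. In a phylogenetic context both blocks are first replaced by
their Brownian-motion-standardized residuals (see :mod:`.phylo`), and
significance comes from permuting species rows of the transformed
second block. Effect sizes on the Fisher-z scale make integration
strength comparable across datasets of different size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MissingDistributionError
from .phylo import PhyloCovariance, phylo_transform

_R_CLIP = 1.0 - 1e-12  # keeps the Fisher transform finite at r = 1


def _fisher(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


@dataclass
class PLSResult:
    """One two-block PLS analysis.

    ``r_pls`` is the absolute Pearson correlation of the first-axis
    scores. ``p_value`` and ``z_score`` are present only after a
    permutation test; ``permuted_r`` stores the null distribution so
    effect sizes can later be compared across analyses.
    """

    r_pls: float
    left_axis: np.ndarray
    right_axis: np.ndarray
    left_scores: np.ndarray
    right_scores: np.ndarray
    n: int
    label: str = ""
    degenerate: bool = False
    p_value: float | None = None
    z_score: float | None = None
    n_perm: int = 0
    permuted_r: np.ndarray | None = None

    def summary_row(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r_pls": self.r_pls,
            "z": self.z_score,
            "p": self.p_value,
            "n_perm": self.n_perm,
        }


def _first_axes(Y1c: np.ndarray, Y2c: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    A = Y1c.T @ Y2c / (Y1c.shape[0] - 1)
    if not np.any(np.abs(A) > 1e-300):
        u = np.zeros(Y1c.shape[1])
        v = np.zeros(Y2c.shape[1])
        if u.size:
            u[0] = 1.0
        if v.size:
            v[0] = 1.0
        return u, v, True
    # only the leading singular pair is needed
    U, _, Vt = np.linalg.svd(A, full_matrices=False)
    return U[:, 0], Vt[0], False


def _score_corr(Y1c: np.ndarray, Y2c: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
    s1 = Y1c @ u
    s2 = Y2c @ v
    d1 = np.sqrt((s1**2).sum())
    d2 = np.sqrt((s2**2).sum())
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(abs(s1 @ s2) / (d1 * d2))


def two_block_pls(Y1: np.ndarray, Y2: np.ndarray, label: str = "") -> PLSResult:
    """Ordinary two-block PLS on row-matched trait matrices.

    Columns are centered internally; the first left/right singular
    vectors of the cross-block covariance give the axes, and r_PLS is
    the absolute correlation of the corresponding scores. A zero
    cross-covariance yields ``r_pls = 0`` with ``degenerate=True``.
    """
    Y1 = np.atleast_2d(np.asarray(Y1, dtype=float))
    Y2 = np.atleast_2d(np.asarray(Y2, dtype=float))
    if Y1.ndim == 2 and Y1.shape[0] == 1:
        Y1 = Y1.T
    if Y2.ndim == 2 and Y2.shape[0] == 1:
        Y2 = Y2.T
    if Y1.shape[0] != Y2.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    if Y1.shape[0] < 3:
        raise ValueError("two-block PLS needs at least 3 rows")
    Y1c = Y1 - Y1.mean(axis=0)
    Y2c = Y2 - Y2.mean(axis=0)
    u, v, degenerate = _first_axes(Y1c, Y2c)
    r = 0.0 if degenerate else _score_corr(Y1c, Y2c, u, v)
    return PLSResult(
        r_pls=r,
        left_axis=u,
        right_axis=v,
        left_scores=Y1c @ u,
        right_scores=Y2c @ v,
        n=Y1.shape[0],
        label=label,
        degenerate=degenerate,
    )


def phylo_pls(
    Y1: np.ndarray, Y2: np.ndarray, C: PhyloCovariance, label: str = ""
) -> PLSResult:
    """Two-block PLS on phylogenetically transformed blocks.

    Both blocks are replaced by their GLS residuals whitened by
    C^(-1/2); on a star phylogeny this reduces exactly to ordinary PLS
    on centered data.
    """
    U1 = phylo_transform(Y1, C).U
    U2 = phylo_transform(Y2, C).U
    return two_block_pls(U1, U2, label=label)


def pls_permutation(
    Y1: np.ndarray,
    Y2: np.ndarray,
    C: PhyloCovariance | None,
    n_perm: int = 1000,
    seed: int = 0,
    label: str = "",
) -> PLSResult:
    """Permutation test of r_PLS, phylogenetic when ``C`` is given.

    The null distribution permutes rows of the (transformed) second
    block relative to the first, which preserves exchangeability under
    the tree after whitening. ``p = (#{r* >= r_obs} + 1)/(n_perm + 1)``;
    the effect size is the standardized deviation of the observed
    Fisher-z r from the permuted ones.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if C is not None:
        Y1 = phylo_transform(Y1, C).U
        Y2 = phylo_transform(Y2, C).U
    result = two_block_pls(Y1, Y2, label=label)
    Y1c = np.atleast_2d(np.asarray(Y1, dtype=float))
    Y2c = np.atleast_2d(np.asarray(Y2, dtype=float))
    if Y1c.shape[0] == 1:
        Y1c = Y1c.T
    if Y2c.shape[0] == 1:
        Y2c = Y2c.T
    Y1c = Y1c - Y1c.mean(axis=0)
    Y2c = Y2c - Y2c.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = Y1c.shape[0]
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        u, v, degenerate = _first_axes(Y1c, Y2c[perm])
        permuted[b] = 0.0 if degenerate else _score_corr(Y1c, Y2c[perm], u, v)
    result.p_value = (float((permuted >= result.r_pls).sum()) + 1.0) / (n_perm + 1.0)
    f_perm = _fisher(permuted)
    sd = float(f_perm.std())
    result.z_score = float((_fisher(result.r_pls) - f_perm.mean()) / sd) if sd > 0 else 0.0
    result.n_perm = n_perm
    result.permuted_r = permuted
    return result


def compare_pls_effects(
    results: list[PLSResult], labels: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise comparison of integration strength between analyses.

    For each analysis the deviation of the observed Fisher-z r_PLS from
    its permutation mean, scaled by the pooled permutation spread of the
    pair, gives a two-sample z statistic with a two-sided normal
    p-value. Returns a long DataFrame with one row per unordered pair.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 PLS results to compare")
    if labels is None:
        labels = [r.label or f"analysis{i}" for i, r in enumerate(results)]
    deltas = []
    sds = []
    for r in results:
        if r.permuted_r is None:
            raise MissingDistributionError(
                f"PLS result {r.label!r} lacks a stored permutation distribution"
            )
        f_perm = _fisher(r.permuted_r)
        deltas.append(float(_fisher(r.r_pls) - f_perm.mean()))
        sds.append(float(f_perm.std()))
    rows = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            denom = np.sqrt(sds[i] ** 2 + sds[j] ** 2)
            z = abs(deltas[i] - deltas[j]) / denom if denom > 0 else 0.0
            rows.append(
                {
                    "label_1": labels[i],
                    "label_2": labels[j],
                    "z": z,
                    "p": float(2.0 * stats.norm.sf(z)),
                }
            )
    return pd.DataFrame(rows)
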