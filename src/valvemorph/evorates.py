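"""Multivariate Brownian-motion rate estimation and comparison.

The net evolutionary rate sigma^2 of a p-dimensional trait is the mean
squared phylogenetically standardized deviation per species per trait
dimension. Rates are compared among species groups (ecomorphs) or
between trait blocks (left vs right valve) through the ratio of the
largest to the smallest rate; significance comes from simulating tip
data under a single-rate Brownian motion null that preserves the
estimated trait covariance, and uncertainty from bootstrapping the
specimens that enter the species means.

Note on scale: dividing by the trait dimensionality p makes rates of
traits with different dimensionality (a scalar asymmetry vs a
606-dimensional shape) comparable per dimension. Pass
``per_dimension=False`` to :func:`sigma2_mult` to recover the
convention without the p division.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .containers import Phylogeny
from .exceptions import AlignmentError
from .phylo import PhyloCovariance, phylo_covariance, phylo_transform, sqrt_covariance

_SIM_CHUNK = 100  # simulations per vectorized block, bounds peak memory


def _as_cov(tree_or_C: Phylogeny | PhyloCovariance) -> PhyloCovariance:
    if isinstance(tree_or_C, PhyloCovariance):
        return tree_or_C
    return phylo_covariance(tree_or_C)


@dataclass
class RateResult:
    """Rates, ratio statistic, simulation p-values and bootstrap CIs.

    ``sigma2`` maps a label (group or trait-block name) to its rate.
    ``ratio`` is max/min over the labels. ``flags`` marks labels whose
    estimates are unstable (single-species groups).
    """

    sigma2: dict[str, float]
    ratio: float
    n_species: dict[str, int]
    p_value: float | None = None
    pairwise_p: dict[tuple[str, str], float] | None = None
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None
    n_sim: int = 0
    n_boot: int = 0
    flags: dict[str, str] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return list(self.sigma2)


def sigma2_mult(
    Y: np.ndarray, C: PhyloCovariance | Phylogeny, per_dimension: bool = True
) -> float:
    """Net Brownian-motion rate of a multidimensional trait.

    With U the phylogenetically standardized deviations,
    ``sigma^2 = sum(U**2) / (N * p)`` (drop the p with
    ``per_dimension=False``). Units: squared trait units per unit of
    tree time (per trait dimension).
    """
    C = _as_cov(C)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    U = phylo_transform(Y, C).U
    denom = U.shape[0] * (U.shape[1] if per_dimension else 1)
    return float((U**2).sum() / denom)


def simulate_bm_tips(
    tree_or_C: Phylogeny | PhyloCovariance,
    rate_matrix: np.ndarray,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Draw tip data under multivariate Brownian motion.

    Tips follow a matrix-normal distribution with row covariance C
    (from the tree) and column covariance ``rate_matrix``, mean zero.
    Returns ``(N, p)``, or ``(size, N, p)`` when ``size`` is given.
    """
    C = _as_cov(tree_or_C)
    R = np.asarray(rate_matrix, dtype=float)
    if R.ndim == 0:
        R = R[None, None]
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rate matrix must be symmetric")
    evals = np.linalg.eigvalsh(R)
    if evals[0] < -1e-10 * max(evals[-1], 1.0):
        raise ValueError("rate matrix must be positive semidefinite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = sqrt_covariance(C)
    S = sqrt_covariance(R)
    n, p = C.n, R.shape[0]
    if size is None:
        return L @ rng.standard_normal((n, p)) @ S
    Z = rng.standard_normal((size, n, p))
    return (L @ Z) @ S  # L broadcasts over the batch axis


def _transform_batch(Ys: np.ndarray, C: PhyloCovariance) -> np.ndarray:
    """phylo_transform applied across a (size, N, p) batch."""
    from .phylo import inv_sqrt

    M = inv_sqrt(C)
    ones = np.ones((C.n, 1))
    Ci1 = np.linalg.solve(C.C, ones)
    w = (Ci1 / (ones.T @ Ci1).item())[:, 0]  # GLS mean weights
    a = np.einsum("j,sjp->sp", w, Ys)
    return M @ (Ys - a[:, None, :])


def _group_rates(U: np.ndarray, group_idx: dict[str, np.ndarray]) -> dict[str, float]:
    p = U.shape[-1]
    return {
        g: float((U[..., idx, :] ** 2).sum() / (len(idx) * p))
        for g, idx in group_idx.items()
    }


def _ratio(values: Sequence[float]) -> float:
    lo, hi = min(values), max(values)
    return float(hi / lo) if lo > 0 else float("inf")


def _null_sims_ratio(
    C: PhyloCovariance,
    Sigma0: np.ndarray,
    label_idx: dict[str, np.ndarray],
    n_sim: int,
    rng: np.random.Generator,
    per_label_cols: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Simulate the single-rate null; return per-label rate draws.

    ``label_idx`` selects rows (species groups); ``per_label_cols``
    instead selects columns (trait blocks) over all rows.
    """
    out = {lab: np.empty(n_sim) for lab in (per_label_cols or label_idx)}
    done = 0
    while done < n_sim:
        m = min(_SIM_CHUNK, n_sim - done)
        Ys = simulate_bm_tips(C, Sigma0, rng, size=m)
        Us = _transform_batch(Ys, C)
        if per_label_cols is not None:
            for lab, cols in per_label_cols.items():
                block = Us[:, :, cols]
                out[lab][done : done + m] = (block**2).sum(axis=(1, 2)) / (
                    block.shape[1] * block.shape[2]
                )
        else:
            for lab, idx in label_idx.items():
                block = Us[:, idx, :]
                out[lab][done : done + m] = (block**2).sum(axis=(1, 2)) / (
                    block.shape[1] * block.shape[2]
                )
        done += m
    return out


def _ratio_pvalues(
    observed: dict[str, float],
    sims: dict[str, np.ndarray],
    n_sim: int,
) -> tuple[float, dict[tuple[str, str], float]]:
    labels = list(observed)
    obs_ratio = _ratio(list(observed.values()))
    mat = np.stack([sims[lab] for lab in labels])  # (L, n_sim)
    sim_ratio = mat.max(axis=0) / mat.min(axis=0)
    p = (float((sim_ratio >= obs_ratio).sum()) + 1.0) / (n_sim + 1.0)
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            o = _ratio([observed[labels[i]], observed[labels[j]]])
            s = np.maximum(mat[i], mat[j]) / np.minimum(mat[i], mat[j])
            pairwise[(labels[i], labels[j])] = (float((s >= o).sum()) + 1.0) / (n_sim + 1.0)
    return p, pairwise


def _pooled_sigma0(U: np.ndarray) -> np.ndarray:
    """Evolutionary trait covariance under the single-rate null.

    UtU/N rescaled so its trace/p equals the pooled rate (a no-op up to
    rounding; stated normalization of the null covariance).
    """
    N, p = U.shape
    Sigma = U.T @ U / N
    pooled = (U**2).sum() / (N * p)
    tr = np.trace(Sigma) / p
    if tr > 0:
        Sigma = Sigma * (pooled / tr)
    return Sigma


def compare_rates_groups(
    Y: np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    C: PhyloCovariance | Phylogeny,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RateResult:
    """Test whether BM rates differ among species groups.

    Each group's rate uses its own rows of the transformed deviations;
    the observed max/min ratio is referred to a null of single-rate BM
    simulations on the full tree with the pooled trait covariance.
    Pairwise p-values reuse the same simulations. Groups with a single
    species are estimated but flagged unstable. ``n_sim=0`` skips the
    simulation test (point estimates only).
    """
    C = _as_cov(C)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if isinstance(groups, Mapping):
        groups = [groups[s] for s in C.species_order]
    groups = list(groups)
    if len(groups) != C.n:
        raise AlignmentError("groups not parallel to species order")
    group_idx = {
        g: np.flatnonzero(np.asarray(groups) == g) for g in sorted(set(groups))
    }
    U = phylo_transform(Y, C).U
    observed = _group_rates(U, group_idx)
    flags = {g: "single-species group; rate unstable" for g, i in group_idx.items() if len(i) < 2}
    result = RateResult(
        sigma2=observed,
        ratio=_ratio(list(observed.values())),
        n_species={g: int(len(i)) for g, i in group_idx.items()},
        flags=flags,
    )
    if n_sim:
        if n_sim < 99:
            raise ValueError("n_sim must be at least 99 (or 0 to skip the test)")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sims = _null_sims_ratio(C, _pooled_sigma0(U), group_idx, n_sim, rng)
        result.p_value, result.pairwise_p = _ratio_pvalues(observed, sims, n_sim)
        result.n_sim = n_sim
    return result


def compare_rates_traits(
    Y_blocks: Mapping[str, np.ndarray],
    C: PhyloCovariance | Phylogeny,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RateResult:
    """Test whether BM rates differ between trait blocks (e.g. valves).

    Blocks must share species order and dimensionality. The null
    simulates all blocks jointly under equal rates while preserving the
    estimated between-block trait covariance (the pooled covariance
    with each block's diagonal block rescaled to the common rate).
    """
    C = _as_cov(C)
    labels = list(Y_blocks)
    mats = [np.atleast_2d(np.asarray(Y_blocks[lab], dtype=float)) for lab in labels]
    mats = [m.T if m.shape[0] == 1 and C.n != 1 else m for m in mats]
    ps = {m.shape[1] for m in mats}
    if len(ps) != 1:
        raise ValueError(f"trait blocks differ in dimensionality: {sorted(ps)}")
    p = ps.pop()
    for m in mats:
        if m.shape[0] != C.n:
            raise AlignmentError("a trait block is not parallel to the species order")
    X = np.hstack(mats)
    U = phylo_transform(X, C).U
    cols = {lab: np.arange(i * p, (i + 1) * p) for i, lab in enumerate(labels)}
    observed = {
        lab: float((U[:, c] ** 2).sum() / (C.n * p)) for lab, c in cols.items()
    }
    result = RateResult(
        sigma2=observed,
        ratio=_ratio(list(observed.values())),
        n_species={lab: C.n for lab in labels},
    )
    if n_sim:
        if n_sim < 99:
            raise ValueError("n_sim must be at least 99 (or 0 to skip the test)")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        Sigma = U.T @ U / C.n
        pooled = (U**2).sum() / (C.n * len(labels) * p)
        scale = np.concatenate(
            [
                np.full(p, np.sqrt(pooled / observed[lab]) if observed[lab] > 0 else 1.0)
                for lab in labels
            ]
        )
        Sigma0 = Sigma * np.outer(scale, scale)
        sims = _null_sims_ratio(C, Sigma0, {}, n_sim, rng, per_label_cols=cols)
        result.p_value, result.pairwise_p = _ratio_pvalues(observed, sims, n_sim)
        result.n_sim = n_sim
    return result


def rates_within_groups(
    Y_left: np.ndarray,
    Y_right: np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    C: PhyloCovariance | Phylogeny,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict[str, RateResult]:
    """Left-vs-right rate comparison inside each species group.

    Each group's species are extracted with the subtree re-rooted at
    their MRCA, and :func:`compare_rates_traits` is applied. A
    single-species group gets point estimates (from the terminal branch
    alone) with a flag, and no simulation test.
    """
    C = _as_cov(C)
    if isinstance(groups, Mapping):
        groups = [groups[s] for s in C.species_order]
    groups = np.asarray(list(groups))
    Y_left = np.atleast_2d(np.asarray(Y_left, dtype=float))
    Y_right = np.atleast_2d(np.asarray(Y_right, dtype=float))
    rng = np.random.default_rng(seed)
    out: dict[str, RateResult] = {}
    for g in sorted(set(groups)):
        idx = np.flatnonzero(groups == g)
        species = [C.species_order[i] for i in idx]
        if len(idx) < 2:
            out[g] = RateResult(
                sigma2={"left": float("nan"), "right": float("nan")},
                ratio=float("nan"),
                n_species={"left": 1, "right": 1},
                flags={"left": "single species; no within-group test", "right": ""},
            )
            continue
        Cg = C.submatrix(species, reroot=True)
        # with 2 species the estimated trait covariance has rank 1, so
        # null ratios are degenerate: report the point estimate untested
        g_sim = n_sim if len(idx) >= 3 else 0
        res = compare_rates_traits(
            {"left": Y_left[idx], "right": Y_right[idx]},
            Cg,
            n_sim=g_sim,
            seed=rng,
        )
        if g_sim == 0 and n_sim:
            res.flags["left"] = res.flags["right"] = (
                "too few species for a null simulation"
            )
        out[g] = res
    return out


def bootstrap_rate_ci(
    values: np.ndarray,
    species_labels: Sequence[str],
    species_order: Sequence[str],
    statistic: Callable[[np.ndarray], Mapping[str, float]],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Bootstrap 95% CIs of a rate statistic over specimens.

    Each iteration resamples specimens within species with replacement,
    recomputes species means (coordinate-wise averages of the rows of
    ``values``), and re-evaluates ``statistic`` on the species-by-trait
    matrix ordered by ``species_order``. The tree is fixed throughout.
    Species represented by one specimen contribute a constant mean.
    Returns (ci_low, ci_high) dictionaries keyed like the statistic's
    output (2.5 and 97.5 percentiles).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(species_labels) != 1:
        values = values.T
    species_labels = np.asarray(list(species_labels))
    groups = [np.flatnonzero(species_labels == sp) for sp in species_order]
    if any(len(g) == 0 for g in groups):
        missing = [sp for sp, g in zip(species_order, groups) if len(g) == 0]
        raise KeyError(f"species without specimens: {missing}")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] | None = None
    S = len(species_order)
    p = values.shape[1]
    for b in range(n_boot):
        M = np.empty((S, p))
        for si, idx in enumerate(groups):
            take = idx if len(idx) == 1 else rng.choice(idx, size=len(idx), replace=True)
            M[si] = values[take].mean(axis=0)
        stat = statistic(M)
        if draws is None:
            draws = {lab: np.empty(n_boot) for lab in stat}
        for lab, v in stat.items():
            draws[lab][b] = v
    assert draws is not None
    lo = {lab: float(np.percentile(v, 2.5)) for lab, v in draws.items()}
    hi = {lab: float(np.percentile(v, 97.5)) for lab, v in draws.items()}
    return lo, hi
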