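"""Phylogenetic covariance and the Brownian-motion transformation.

Under Brownian motion on a rooted tree, the expected covariance of a
trait between two tips equals the shared root-to-MRCA path length. The
matrix C of those path lengths drives generalized least squares: data
premultiplied by C^(-1/2) (after removing the GLS phylogenetic mean)
become exchangeable across species, which is the workhorse behind the
phylogenetic PLS, PGLS and rate estimators in this package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Phylogeny
from .exceptions import AlignmentError, NearSingularError


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance among species tips.

    ``C[i, j]`` is the root-to-MRCA path length between species i and j
    (the tip depth on the diagonal); ``species_order`` names the rows.
    """

    C: np.ndarray
    species_order: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.species_order)
        if self.C.shape != (n, n):
            raise AlignmentError("covariance shape does not match species order")

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def submatrix(self, species: list[str], reroot: bool = False) -> "PhyloCovariance":
        """Covariance restricted to a species subset.

        With ``reroot`` the subset's MRCA becomes the new root: the
        depth of the shallowest shared ancestor (the smallest
        off-diagonal entry) is subtracted throughout, matching the
        covariance of the pruned tree.
        """
        pos = {s: i for i, s in enumerate(self.species_order)}
        try:
            idx = np.array([pos[s] for s in species])
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not in covariance") from None
        sub = self.C[np.ix_(idx, idx)].copy()
        if reroot and len(idx) > 1:
            off = sub[~np.eye(len(idx), dtype=bool)]
            sub -= off.min()
        return PhyloCovariance(sub, list(species))


@dataclass
class PhyloTransform:
    """GLS phylogenetic mean and transformed residuals.

    ``a`` is the (1 x p) GLS estimate of the root state; ``U`` is
    ``C^(-1/2) @ (Y - 1 a)``, the matrix of phylogenetically
    standardized deviations. When C is the identity, U is just the
    column-centered data.
    """

    a: np.ndarray
    U: np.ndarray

    @property
    def p(self) -> int:
        return self.U.shape[1]


def phylo_covariance(tree: Phylogeny, species_order: list[str] | None = None) -> PhyloCovariance:
    """Build the Brownian-motion covariance from a rooted tree.

    Computed by a single postorder traversal: each internal node
    contributes its root distance as the covariance of every cross pair
    of tips descending through different children. ``species_order``
    defaults to the tree's tip order.
    """
    if species_order is None:
        species_order = list(tree.tip_names)
    pos = {name: i for i, name in enumerate(species_order)}
    unknown = [t for t in species_order if t not in set(tree.tip_names)]
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    n = len(species_order)
    C = np.zeros((n, n))

    tree.tree.calc_node_root_distances(return_leaf_distances_only=False)
    tip_sets: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name in pos:
                i = pos[name]
                C[i, i] = node.root_distance
                tip_sets[id(node)] = [i]
            else:
                tip_sets[id(node)] = []
            continue
        children = [tip_sets.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = depth
        tip_sets[id(node)] = [i for ch in children for i in ch]
    return PhyloCovariance(C, list(species_order))


def inv_sqrt(C: PhyloCovariance | np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root of a positive-definite covariance.

    Uses the eigendecomposition root (unique and independent of species
    ordering, unlike a Cholesky factor). Eigenvalues below
    ``floor`` x largest indicate a numerically singular tree (e.g. a
    zero-length cherry) and raise :class:`NearSingularError`.
    """
    M = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    evals, evecs = np.linalg.eigh(M)
    cutoff = floor * evals[-1]
    if evals[0] <= cutoff:
        raise NearSingularError(
            f"phylogenetic covariance is near-singular (eigenvalue {evals[0]:.3g}; "
            "check for zero-length cherries)"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


def sqrt_covariance(C: PhyloCovariance | np.ndarray) -> np.ndarray:
    """Symmetric square root C^(1/2) (for simulating correlated tips)."""
    M = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    evals, evecs = np.linalg.eigh(M)
    evals = np.clip(evals, 0.0, None)
    return (evecs * np.sqrt(evals)) @ evecs.T


def gls_mean(Y: np.ndarray, C: PhyloCovariance | np.ndarray) -> np.ndarray:
    """GLS estimate of the phylogenetic mean: (1' C^-1 1)^-1 1' C^-1 Y."""
    M = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    ones = np.ones((M.shape[0], 1))
    Ci1 = np.linalg.solve(M, ones)
    denom = (ones.T @ Ci1).item()
    return (Ci1.T @ Y) / denom


def phylo_transform(Y: np.ndarray, C: PhyloCovariance) -> PhyloTransform:
    """Remove the GLS mean and whiten by C^(-1/2).

    Rows of ``Y`` must follow ``C.species_order``; a row-count mismatch
    raises :class:`AlignmentError`.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != C.n:
        raise AlignmentError(
            f"Y has {Y.shape[0]} rows but covariance is over {C.n} species"
        )
    a = gls_mean(Y, C)
    U = inv_sqrt(C) @ (Y - a)
    return PhyloTransform(a=a, U=U)
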