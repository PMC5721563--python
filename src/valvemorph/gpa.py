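"""Generalized Procrustes superimposition with sliding semilandmarks.

The superimposition removes translation, scale and rotation from a
stack of landmark configurations, leaving shape. Semilandmarks — points
without one-to-one anatomical correspondence — are additionally allowed
to slide along their tangent directions (curve points) or within their
local tangent plane (surface points) so as to minimize Procrustes
distance to the current consensus. Reflections are never part of the
fitted rotations; handedness differences between left and right valves
must be handled explicitly with :func:`mirror_configuration`.

All heavy operations are batched over the specimen axis with numpy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LandmarkConfiguration, SemilandmarkTopology, SpecimenSet
from .exceptions import (
    ConsistencyError,
    DegenerateConfigurationError,
    ShapeMismatchError,
)

_AXES = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# elementary steps


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances of points to their centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center_and_scale(
    config: LandmarkConfiguration | np.ndarray,
) -> tuple[LandmarkConfiguration | np.ndarray, float]:
    """Translate the centroid to the origin and scale to unit centroid size.

    Returns the normalized configuration and the original centroid size.
    Raises :class:`DegenerateConfigurationError` when all points coincide.
    """
    is_config = isinstance(config, LandmarkConfiguration)
    coords = config.coords if is_config else np.asarray(config, dtype=float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0 or not np.isfinite(size):
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is zero")
    out = centered / size
    if is_config:
        return LandmarkConfiguration(out, config.k_fixed), size
    return out, size


def _center_scale_stack(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched center-and-scale over axis 0. Returns (normalized, sizes)."""
    centered = stack - stack.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise DegenerateConfigurationError("a configuration has zero centroid size")
    return centered / sizes[:, None, None], sizes


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||A @ R - B||_F.

    Reflections are excluded: when the unconstrained orthogonal optimum
    is improper, the singular direction with the smallest singular value
    has its sign flipped (ties broken toward the highest index), giving
    the best proper rotation deterministically.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ShapeMismatchError(f"configurations differ in shape: {A.shape} vs {B.shape}")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    # svd orders singular values descending, so index -1 is the smallest
    D = np.ones(3)
    D[-1] = d
    return (U * D) @ Vt


def _rotate_stack_to(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate every centered shape in ``stack`` onto ``target`` (proper)."""
    H = np.einsum("nki,kj->nij", stack, target)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    D = np.ones((stack.shape[0], 3))
    D[:, -1] = np.where(det < 0, -1.0, 1.0)
    R = np.einsum("nij,nj,njk->nik", U, D, Vt)
    return np.einsum("nki,nij->nkj", stack, R)


def mirror_configuration(
    config: LandmarkConfiguration | np.ndarray, axis: str = "x"
) -> LandmarkConfiguration | np.ndarray:
    """Reflect a configuration across the plane normal to ``axis``.

    Landmark ordering is unchanged; applying the mirror twice is the
    identity. Used to bring right valves into the left valve's
    handedness before joint superimposition.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    j = _AXES[axis]
    is_config = isinstance(config, LandmarkConfiguration)
    coords = (config.coords if is_config else np.asarray(config, dtype=float)).copy()
    coords[..., j] = -coords[..., j]
    if is_config:
        return LandmarkConfiguration(coords, config.k_fixed)
    return coords


def procrustes_distance(
    a: LandmarkConfiguration | np.ndarray,
    b: LandmarkConfiguration | np.ndarray,
    align_first: bool = True,
) -> float:
    """Root summed squared distance between corresponding landmarks.

    With ``align_first`` both configurations are centered, scaled to
    unit centroid size, and ``b`` is optimally rotated onto ``a``
    (proper rotations only) before the distance is taken; otherwise the
    coordinates are compared as given.
    """
    A = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, dtype=float)
    B = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise ShapeMismatchError(f"configurations differ in shape: {A.shape} vs {B.shape}")
    if align_first:
        A, _ = center_and_scale(A)
        B, _ = center_and_scale(B)
        B = B @ optimal_rotation(B, A)
    return float(np.sqrt(((A - B) ** 2).sum()))


# ---------------------------------------------------------------------------
# semilandmark sliding


def slide_semilandmarks(
    shapes: np.ndarray,
    reference: np.ndarray,
    topology: SemilandmarkTopology,
    eps: float = 1e-12,
) -> np.ndarray:
    """Slide semilandmarks toward the reference along their tangents.

    Curve points move only along the unit vector between their two
    chain neighbors; surface points move only within the best-fit plane
    (two leading principal directions) of their topological neighbor
    set. The displacement is the orthogonal projection of the residual
    (reference minus current position) onto that tangent subspace, which
    can only reduce the squared distance to the reference. Fixed
    landmarks are never touched. Degenerate tangents (coincident chain
    neighbors, rank-deficient neighbor clouds) suppress sliding for the
    affected point in this pass.

    ``shapes`` may be a single ``(k, 3)`` configuration or an
    ``(n, k, 3)`` stack; the stack form is vectorized.
    """
    single = shapes.ndim == 2
    X0 = shapes[None] if single else shapes
    X0 = np.asarray(X0, dtype=float)
    # all tangents and residuals come from the pre-slide positions
    # (simultaneous update), so the result is independent of the order
    # in which points are processed
    X = X0.copy()  # fixed landmarks stay bit-identical
    ref = np.asarray(reference, dtype=float)

    if topology.curve:
        idx = topology.curve_indices
        prv = np.array([p for _, p, _ in topology.curve])
        nxt = np.array([q for _, _, q in topology.curve])
        t = X0[:, nxt] - X0[:, prv]
        norm = np.linalg.norm(t, axis=2, keepdims=True)
        ok = (norm[..., 0] > eps)
        t = np.where(norm > eps, t / np.where(norm > eps, norm, 1.0), 0.0)
        r = ref[idx][None] - X0[:, idx]
        disp = (r * t).sum(axis=2, keepdims=True) * t
        X[:, idx] += np.where(ok[..., None], disp, 0.0)

    for j, nbrs in topology.surface:
        P = X0[:, list(nbrs), :]
        Pc = P - P.mean(axis=1, keepdims=True)
        cov = np.einsum("nmi,nmj->nij", Pc, Pc)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        r = ref[j][None] - X0[:, j]
        disp = np.zeros_like(r)
        scale = evals[:, -1:]  # largest eigenvalue per shape
        for c in (-1, -2):  # two leading principal directions
            e = evecs[:, :, c]
            usable = evals[:, c] > eps * np.maximum(scale[:, 0], eps)
            proj = (r * e).sum(axis=1, keepdims=True) * e
            disp += np.where(usable[:, None], proj, 0.0)
        X[:, j] += disp

    return X[0] if single else X


# ---------------------------------------------------------------------------
# generalized Procrustes alignment


@dataclass
class AlignedSet:
    """Result of a generalized Procrustes superimposition.

    ``shapes`` are unit-centroid-size, origin-centered configurations in
    a common orientation; ``centroid_sizes`` records each specimen's
    size before scaling. ``ss_history`` holds, per iteration with
    sliding, the total Procrustes sum of squares against the consensus
    immediately before and after the sliding pass.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    labels: pd.DataFrame
    topology: SemilandmarkTopology
    mean_shape: np.ndarray
    iterations_run: int
    converged: bool
    ss_history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def as_specimen_set(self) -> SpecimenSet:
        return SpecimenSet(self.shapes.copy(), self.labels.copy(), self.topology)


def _consensus(stack: np.ndarray) -> np.ndarray:
    mean = stack.mean(axis=0)
    mean -= mean.mean(axis=0)
    return mean / np.sqrt((mean**2).sum())


def _plain_gpa(
    X: np.ndarray, consensus: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Rotate-to-consensus iterations without sliding."""
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        X = _rotate_stack_to(X, consensus)
        new_consensus = _consensus(X)
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    return X, consensus, iteration, converged


def gpa_align(
    data: SpecimenSet,
    slide: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
    slide_passes: int = 5,
    slide_tol: float = 1e-4,
) -> AlignedSet:
    """Generalized Procrustes superimposition, optionally with sliding.

    The rotation loop (rotate all configurations to the current
    consensus, recompute the consensus) runs until the Procrustes
    distance between successive consensus shapes drops below ``tol`` or
    ``max_iter`` is reached. With ``slide``, up to ``slide_passes``
    sliding passes are interleaved: each slides the semilandmarks
    against the current consensus (tangents recomputed from current
    positions), renormalizes, and re-runs the rotation loop; passes
    stop early once a pass improves the total Procrustes sum of squares
    by less than ``slide_tol`` (relative). The pass cap exists because
    tangent-projection sliding against a moving consensus, iterated
    indefinitely on point data with no underlying surface to relax back
    onto, lets semilandmarks drift along the outline without a fixed
    point; a handful of passes captures essentially all of the
    attainable SS reduction.

    Non-convergence of the rotation loop is reported with a warning and
    ``converged=False``, never silently.
    """
    if data.n < 2:
        raise ConsistencyError("generalized Procrustes alignment needs at least 2 specimens")
    X, sizes = _center_scale_stack(data.coords)
    consensus = X[0].copy()
    X = _rotate_stack_to(X, consensus)
    consensus = _consensus(X)

    X, consensus, iterations, converged = _plain_gpa(X, consensus, max_iter, tol)
    ss_history: list[tuple[float, float]] = []
    if slide and data.topology.k_semi > 0:
        for _ in range(slide_passes):
            X = _rotate_stack_to(X, consensus)
            ss_before = float(((X - consensus[None]) ** 2).sum())
            X = slide_semilandmarks(X, consensus, data.topology)
            ss_after = float(((X - consensus[None]) ** 2).sum())
            ss_history.append((ss_before, ss_after))
            X, _ = _center_scale_stack(X)
            X, consensus, it, converged = _plain_gpa(X, consensus, max_iter, tol)
            iterations += it
            if ss_before - ss_after < slide_tol * ss_before:
                break
    if not converged:
        warnings.warn(
            f"GPA rotation loop did not converge within {max_iter} iterations",
            stacklevel=2,
        )
    X = _rotate_stack_to(X, consensus)
    return AlignedSet(
        shapes=X,
        centroid_sizes=sizes,
        labels=data.labels.copy(),
        topology=data.topology,
        mean_shape=consensus,
        iterations_run=iterations,
        converged=converged,
        ss_history=ss_history,
    )


# ---------------------------------------------------------------------------
# aggregation


def average_replicates(aligned: AlignedSet) -> AlignedSet:
    """Average digitizing replicates of each valve (specimen_id, side).

    The coordinate-wise mean of a valve's aligned replicates is
    re-centered and re-scaled to unit centroid size; the replicate label
    collapses to 1. Valves measured once pass through unchanged.
    """
    key = aligned.labels.groupby(["specimen_id", "side"], sort=True)
    shapes = []
    sizes = []
    rows = []
    for _, idx in key.groups.items():
        idx = np.asarray(idx)
        mean = aligned.shapes[idx].mean(axis=0)
        mean -= mean.mean(axis=0)
        shapes.append(mean / np.sqrt((mean**2).sum()))
        sizes.append(aligned.centroid_sizes[idx].mean())
        row = aligned.labels.iloc[idx[0]].copy()
        row["replicate"] = 1
        rows.append(row)
    return AlignedSet(
        shapes=np.stack(shapes),
        centroid_sizes=np.asarray(sizes),
        labels=pd.DataFrame(rows).reset_index(drop=True),
        topology=aligned.topology,
        mean_shape=aligned.mean_shape,
        iterations_run=aligned.iterations_run,
        converged=aligned.converged,
        ss_history=aligned.ss_history,
    )


@dataclass
class MeanShapes:
    """Per-species mean configurations in a fixed species order."""

    species: list[str]
    shapes: np.ndarray  # (n_species, k, 3)
    n_specimens: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """Species-by-trait matrix: each shape flattened to length 3k."""
        return self.shapes.reshape(self.shapes.shape[0], -1)


def species_means(aligned: AlignedSet, species_order: list[str]) -> MeanShapes:
    """Coordinate-wise species mean shapes, unit-size normalized.

    Output rows follow ``species_order`` (normally the pruned tree's
    tip order) so downstream matrices align with the phylogenetic
    covariance. A species without specimens raises ``KeyError``.
    """
    shapes = []
    counts = []
    groups = aligned.labels.groupby("species").groups
    for sp in species_order:
        if sp not in groups:
            raise KeyError(f"species {sp!r} has no specimens in the aligned set")
        idx = np.asarray(groups[sp])
        mean = aligned.shapes[idx].mean(axis=0)
        mean -= mean.mean(axis=0)
        shapes.append(mean / np.sqrt((mean**2).sum()))
        counts.append(len(idx))
    return MeanShapes(list(species_order), np.stack(shapes), np.asarray(counts))
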