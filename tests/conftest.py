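"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's analytic code paths:
rotation and sliding optima come from hierarchical grid search,
covariances from dendropy's patristic distances, ANOVA from scipy.
"""
from __future__ import annotations

import numpy as np
import pytest

import valvemorph as vm


# ---------------------------------------------------------------------------
# brute-force oracles


def _euler_grid(centers: np.ndarray, half_width: float, n: int) -> np.ndarray:
    """Proper rotation matrices on a (z, y, z) Euler grid around centers."""
    a = np.linspace(centers[0] - half_width, centers[0] + half_width, n)
    b = np.linspace(centers[1] - half_width, centers[1] + half_width, n)
    c = np.linspace(centers[2] - half_width, centers[2] + half_width, n)
    A, B, C = np.meshgrid(a, b, c, indexing="ij")
    angles = np.column_stack([A.ravel(), B.ravel(), C.ravel()])
    ca, sa = np.cos(angles[:, 0]), np.sin(angles[:, 0])
    cb, sb = np.cos(angles[:, 1]), np.sin(angles[:, 1])
    cc, sc = np.cos(angles[:, 2]), np.sin(angles[:, 2])
    R = np.empty((len(angles), 3, 3))
    R[:, 0, 0] = ca * cb * cc - sa * sc
    R[:, 0, 1] = -ca * cb * sc - sa * cc
    R[:, 0, 2] = ca * sb
    R[:, 1, 0] = sa * cb * cc + ca * sc
    R[:, 1, 1] = -sa * cb * sc + ca * cc
    R[:, 1, 2] = sa * sb
    R[:, 2, 0] = -sb * cc
    R[:, 2, 1] = sb * sc
    R[:, 2, 2] = cb
    return angles, R


def grid_min_distance(A: np.ndarray, B: np.ndarray, levels: int = 3) -> float:
    """Minimal ||A R - B|| over proper rotations by refined grid search.

    Starts on a 5-degree global Euler grid and refines twice around the
    incumbent, reaching ~0.05-degree resolution (distance error is
    second-order in the angular step, well below 1e-6 for unit-size
    configurations).
    """
    centers = np.zeros(3)
    half = np.pi
    best = np.inf
    for level in range(levels):
        n = 73 if level == 0 else 21
        angles, R = _euler_grid(centers, half, n)
        AR = np.einsum("ki,nij->nkj", A, R)
        d = np.sqrt(((AR - B[None]) ** 2).sum(axis=(1, 2)))
        i = int(np.argmin(d))
        best = float(d[i])
        centers = angles[i]
        half = half * 2.2 / n
    return best


def grid_slide_residual(
    point: np.ndarray, reference: np.ndarray, directions: np.ndarray, extent: float = 2.0,
    n: int = 201, levels: int = 3,
) -> float:
    """Minimal distance to ``reference`` over displacements in a subspace.

    Hierarchically refined grid search (three levels), reaching step
    sizes small enough that the quadratic error near the optimum is far
    below 1e-6.
    """
    center = np.zeros(directions.shape[0])
    half = extent
    best = np.inf
    for _ in range(levels):
        axes = [np.linspace(c - half, c + half, n) for c in center]
        if directions.shape[0] == 1:
            coeffs = axes[0][:, None]
        else:
            S, T = np.meshgrid(axes[0], axes[1], indexing="ij")
            coeffs = np.column_stack([S.ravel(), T.ravel()])
        cand = point[None] + coeffs @ directions
        d = np.sqrt(((cand - reference[None]) ** 2).sum(axis=1))
        i = int(np.argmin(d))
        best = float(d[i])
        center = coeffs[i]
        half = half * 2.2 / n
    return best


# ---------------------------------------------------------------------------
# fixtures

TINY_PROPORTIONS = {
    "byssal-attaching": 4,
    "recessing": 3,
    "free-living": 3,
    "gliding": 2,
}


def tiny_generator(seed: int = 5, **overrides) -> vm.GeneratorConfig:
    kwargs = dict(
        n_species=12,
        ecomorph_proportions=dict(TINY_PROPORTIONS),
        n_specimens_per_species=2,
        n_replicates=2,
        k_semi=21,
        seed=seed,
    )
    kwargs.update(overrides)
    return vm.GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12-species, 2-specimen, 2-replicate synthetic dataset."""
    return vm.generate_dataset(tiny_generator())


@pytest.fixture(scope="session")
def tiny_aligned(tiny_dataset):
    left, right, phy, truth = tiny_dataset
    aligned = vm.gpa_align(left, slide=True)
    return aligned


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tree86():
    return vm.simulate_tree(86, seed=17)
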