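"""Core in-memory containers for landmark data and phylogenies.

Coordinates live in numpy arrays; specimen metadata in a pandas
DataFrame parallel to the coordinate stack; trees are dendropy trees
wrapped with the invariants the comparative analyses rely on
(rooted, branch lengths present, approximately ultrametric).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError

ECOMORPHS = (
    "cementing",
    "nestling",
    "byssal-attaching",
    "recessing",
    "free-living",
    "gliding",
)

SIDES = ("left", "right")

#: columns of the specimen label table, in canonical order
LABEL_COLUMNS = ["specimen_id", "species", "side", "replicate", "ecomorph"]


@dataclass(frozen=True)
class SemilandmarkTopology:
    """Sliding topology: which points are fixed, on curves, or on surfaces.

    Parameters
    ----------
    k_fixed
        Number of fixed (anatomical) landmarks; they occupy indices
        ``0 .. k_fixed-1`` and never slide.
    curve
        ``(index, prev_index, next_index)`` triples for curve
        semilandmarks; the tangent at ``index`` is the direction from
        ``prev_index`` to ``next_index``.
    surface
        ``(index, neighbors)`` pairs for surface semilandmarks; the
        tangent plane at ``index`` is the best-fit plane of the
        neighbor positions (at least 3 neighbors required).
    """

    k_fixed: int
    curve: tuple[tuple[int, int, int], ...] = ()
    surface: tuple[tuple[int, tuple[int, ...]], ...] = ()

    def __post_init__(self) -> None:
        semi = [i for i, _, _ in self.curve] + [i for i, _ in self.surface]
        if len(semi) != len(set(semi)):
            raise ConsistencyError("a semilandmark index appears in both curve and surface lists")
        if any(i < self.k_fixed for i in semi):
            raise ConsistencyError("semilandmark index falls inside the fixed-landmark block")
        for i, nbrs in self.surface:
            if len(nbrs) < 3:
                raise ConsistencyError(f"surface semilandmark {i} has fewer than 3 neighbors")

    @property
    def k_semi(self) -> int:
        return len(self.curve) + len(self.surface)

    @property
    def curve_indices(self) -> np.ndarray:
        return np.array([i for i, _, _ in self.curve], dtype=int)

    @property
    def surface_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.surface], dtype=int)


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One valve's ordered k x 3 point set.

    Fixed landmarks occupy the first ``k_fixed`` rows; the rest are
    semilandmarks. Units are arbitrary but must be consistent within a
    dataset (Procrustes superimposition removes scale).
    """

    coords: np.ndarray
    k_fixed: int

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise FormatError(f"coordinates must be k x 3, got {coords.shape}")
        if coords.shape[0] < 3:
            raise ConsistencyError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinate in configuration")
        if not 0 <= self.k_fixed <= coords.shape[0]:
            raise ConsistencyError("k_fixed outside [0, k]")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def k_semi(self) -> int:
        return self.k - self.k_fixed


@dataclass
class SpecimenSet:
    """A stack of landmark configurations with parallel specimen labels.

    ``coords`` has shape ``(n_specimens, k, 3)``; ``labels`` is a
    DataFrame with columns ``specimen_id, species, side, replicate,
    ecomorph``, row-parallel to ``coords``.
    """

    coords: np.ndarray
    labels: pd.DataFrame
    topology: SemilandmarkTopology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (n, k, 3), got {self.coords.shape}")
        if len(self.labels) != self.coords.shape[0]:
            raise ConsistencyError("labels not parallel to coordinate stack")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise FormatError(f"label table missing columns: {missing}")
        bad = ~np.isfinite(self.coords).all(axis=(1, 2))
        if bad.any():
            who = self.labels.loc[np.flatnonzero(bad)[0], "specimen_id"]
            raise ValueError(f"non-finite coordinate in specimen {who!r}")
        key = self.labels[["specimen_id", "side", "replicate"]]
        if key.duplicated().any():
            raise ConsistencyError("(specimen_id, side, replicate) not unique")
        eco = self.labels.groupby("species")["ecomorph"].nunique()
        if (eco > 1).any():
            raise ConsistencyError(
                f"ecomorph varies within species: {list(eco[eco > 1].index)}"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def k_fixed(self) -> int:
        return self.topology.k_fixed

    @property
    def k_semi(self) -> int:
        return self.k - self.topology.k_fixed

    @property
    def species(self) -> list[str]:
        return sorted(self.labels["species"].unique())

    def configuration(self, i: int) -> LandmarkConfiguration:
        return LandmarkConfiguration(self.coords[i], self.k_fixed)

    def subset(self, mask: np.ndarray) -> "SpecimenSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpecimenSet(
            self.coords[idx].copy(),
            self.labels.iloc[idx].reset_index(drop=True),
            self.topology,
        )


class Phylogeny:
    """Rooted, ultrametric (within tolerance) tree with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique
    tip names and positive branch lengths, and warns when tip depths
    disagree beyond ``ultrametric_tol`` (relative to tree depth) —
    empirical chronograms carry rounding noise, so this is not fatal.
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        self.tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            raise FormatError("duplicate tip names in tree")
        self.tip_names: list[str] = tips
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError("tree has a missing branch length")
            if edge.length <= 0:
                raise FormatError(f"non-positive branch length {edge.length}")
        depths = self.tip_depths()
        depth = max(depths.values())
        if depth > 0 and (max(depths.values()) - min(depths.values())) > ultrametric_tol * depth:
            warnings.warn(
                "tree is not ultrametric within tolerance "
                f"(tip depth range {min(depths.values()):.6g}..{max(depths.values()):.6g})",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.tip_names)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        out: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))
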