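"""Matching asymmetry between paired valves.

A scallop shell's left and right valves are separate mirrored
structures. Their matching (directional) asymmetry is measured by
mirroring the right valve, superimposing all valves of all specimens
jointly (one generalized Procrustes fit with sliding), and taking the
Procrustes distance between each specimen's left and mirrored-right
valve in that common frame. No per-pair re-rotation is applied: the
joint fit already placed every valve in one orientation, and rotating
pairs onto each other would strip real hinge-orientation asymmetry.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpecimenSet
from .exceptions import PairingError, ShapeMismatchError
from .gpa import AlignedSet, gpa_align, mirror_configuration

_PAIR_KEY = ["specimen_id", "replicate"]


def joint_superimpose(
    left: SpecimenSet,
    right: SpecimenSet,
    mirror_axis: str = "x",
    slide: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> AlignedSet:
    """Mirror right valves and superimpose both sides together.

    Only complete shells participate: specimens present on a single
    side are dropped with a warning (not all shells preserve both
    valves). Returns one aligned set containing left and mirrored-right
    valves in a common frame.
    """
    if left.k != right.k or left.k_fixed != right.k_fixed:
        raise ShapeMismatchError("left and right sets do not share a landmark scheme")
    ids_left = set(map(tuple, left.labels[_PAIR_KEY].itertuples(index=False)))
    ids_right = set(map(tuple, right.labels[_PAIR_KEY].itertuples(index=False)))
    shared = ids_left & ids_right
    dropped = (ids_left | ids_right) - shared
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} incomplete shells (valve present on one side only)",
            stacklevel=2,
        )
    if not shared:
        raise PairingError("no specimen has both valves")

    def _mask(ss: SpecimenSet) -> np.ndarray:
        keys = list(map(tuple, ss.labels[_PAIR_KEY].itertuples(index=False)))
        return np.array([k in shared for k in keys])

    left_kept = left.subset(_mask(left))
    right_kept = right.subset(_mask(right))
    mirrored = mirror_configuration(right_kept.coords, axis=mirror_axis)
    pooled = SpecimenSet(
        np.concatenate([left_kept.coords, mirrored]),
        pd.concat([left_kept.labels, right_kept.labels], ignore_index=True),
        left.topology,
    )
    return gpa_align(pooled, slide=slide, max_iter=max_iter, tol=tol)


@dataclass
class AsymmetryTable:
    """Directional asymmetry per specimen and aggregated per species.

    ``per_specimen`` columns: specimen_id, species, ecomorph, da.
    ``per_species`` columns: species, ecomorph, da_mean, da_var, n.
    ``da`` is the Procrustes distance between the jointly aligned left
    and mirrored-right valves (0 = perfectly equivalve).
    """

    per_specimen: pd.DataFrame
    per_species: pd.DataFrame

    def species_vector(self, species_order: list[str]) -> np.ndarray:
        s = self.per_species.set_index("species")["da_mean"]
        missing = [sp for sp in species_order if sp not in s.index]
        if missing:
            raise KeyError(f"species without asymmetry values: {missing}")
        return s.loc[species_order].to_numpy()


def asymmetry_magnitude(aligned: AlignedSet) -> AsymmetryTable:
    """Procrustes distance between each specimen's two valves.

    ``aligned`` must come from :func:`joint_superimpose` (left and
    mirrored-right valves in one frame). Distances are taken on the
    aligned coordinates as-is. Per-species mean and variance (ddof=1;
    zero for singletons) are aggregated alongside.
    """
    labels = aligned.labels
    rows = []
    grouped = labels.groupby(_PAIR_KEY, sort=True)
    for (spec_id, rep), block in grouped:
        sides = block["side"].tolist()
        if sorted(sides) != ["left", "right"]:
            raise PairingError(
                f"specimen {spec_id!r} replicate {rep}: expected one left and one right "
                f"valve, got {sides}"
            )
        i_left = block.index[block["side"] == "left"][0]
        i_right = block.index[block["side"] == "right"][0]
        diff = aligned.shapes[i_left] - aligned.shapes[i_right]
        rows.append(
            {
                "specimen_id": spec_id,
                "species": block["species"].iloc[0],
                "ecomorph": block["ecomorph"].iloc[0],
                "da": float(np.sqrt((diff**2).sum())),
            }
        )
    per_specimen = pd.DataFrame(rows)
    per_species = (
        per_specimen.groupby(["species", "ecomorph"], as_index=False)["da"]
        .agg(da_mean="mean", da_var=lambda v: float(np.var(v, ddof=1)) if len(v) > 1 else 0.0, n="count")
        .rename(columns={})
    )
    return AsymmetryTable(per_specimen=per_specimen, per_species=per_species)


def ecomorph_summary(table: AsymmetryTable) -> pd.DataFrame:
    """Mean, variance and counts of specimen asymmetry by ecomorph."""
    return (
        table.per_specimen.groupby("ecomorph", as_index=False)["da"]
        .agg(da_mean="mean", da_var=lambda v: float(np.var(v, ddof=1)) if len(v) > 1 else 0.0, n="count")
    )
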