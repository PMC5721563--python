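"""Reading and writing landmark data and phylogenies.

Two interchange formats are supported for landmarks: a long-format CSV
(one row per landmark) and the TPS dialect with ``LM3=`` records for 3D
points. Both carry only coordinates; specimen metadata (species, side,
replicate, ecomorph) travels in a sidecar CSV, and the sliding topology
in a descriptor CSV with columns ``index, kind, neighbors``.
"""
from __future__ import annotations

import os

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    LABEL_COLUMNS,
    Phylogeny,
    SemilandmarkTopology,
    SpecimenSet,
)
from .exceptions import ConsistencyError, FormatError, InsufficientOverlapError

_VALVE_KEY = ["specimen_id", "side", "replicate"]


# ---------------------------------------------------------------------------
# topology descriptor


def read_topology_csv(path: str | os.PathLike) -> SemilandmarkTopology:
    """Read a semilandmark topology descriptor.

    Columns: ``index`` (0-based landmark index), ``kind`` (one of
    ``fixed``, ``curve``, ``surface``), ``neighbors`` (semicolon-joined
    indices; for curve points exactly ``prev;next``).
    """
    df = pd.read_csv(path, dtype={"neighbors": str})
    for col in ("index", "kind"):
        if col not in df.columns:
            raise FormatError(f"topology descriptor missing column {col!r}")
    df = df.sort_values("index").reset_index(drop=True)
    if not (df["index"] == np.arange(len(df))).all():
        raise FormatError("topology indices must be 0..k-1 without gaps")
    fixed = df[df["kind"] == "fixed"]["index"].to_numpy()
    k_fixed = len(fixed)
    if k_fixed and not (fixed == np.arange(k_fixed)).all():
        raise ConsistencyError("fixed landmarks must occupy the first indices")
    curve = []
    surface = []
    for _, row in df[df["kind"] != "fixed"].iterrows():
        nbrs = [int(s) for s in str(row["neighbors"]).split(";") if s not in ("", "nan")]
        if row["kind"] == "curve":
            if len(nbrs) != 2:
                raise FormatError(
                    f"curve semilandmark {row['index']} needs exactly 2 neighbors (prev;next)"
                )
            curve.append((int(row["index"]), nbrs[0], nbrs[1]))
        elif row["kind"] == "surface":
            surface.append((int(row["index"]), tuple(nbrs)))
        else:
            raise FormatError(f"unknown landmark kind {row['kind']!r}")
    return SemilandmarkTopology(k_fixed=k_fixed, curve=tuple(curve), surface=tuple(surface))


def write_topology_csv(topology: SemilandmarkTopology, path: str | os.PathLike) -> None:
    rows = [
        {"index": i, "kind": "fixed", "neighbors": ""} for i in range(topology.k_fixed)
    ]
    for i, prev, nxt in topology.curve:
        rows.append({"index": i, "kind": "curve", "neighbors": f"{prev};{nxt}"})
    for i, nbrs in topology.surface:
        rows.append({"index": i, "kind": "surface", "neighbors": ";".join(map(str, nbrs))})
    pd.DataFrame(rows).sort_values("index").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long-format landmark CSV

_CSV_COLUMNS = LABEL_COLUMNS + ["landmark_index", "x", "y", "z"]


def read_landmarks_csv(
    path: str | os.PathLike, topology: SemilandmarkTopology | str | os.PathLike
) -> SpecimenSet:
    """Read landmarks from a long-format CSV (one row per landmark).

    Required columns: ``specimen_id, species, side, replicate, ecomorph,
    landmark_index, x, y, z``. Every valve (unique ``specimen_id, side,
    replicate``) must carry the same set of landmark indices.
    ``topology`` may be a descriptor path or an already-parsed topology.
    """
    if not isinstance(topology, SemilandmarkTopology):
        topology = read_topology_csv(topology)
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"landmark CSV missing columns: {missing}")
    counts = df.groupby(_VALVE_KEY, sort=False)["landmark_index"].count()
    if counts.nunique() > 1:
        raise ConsistencyError(
            f"ragged landmark counts across valves: {sorted(counts.unique())}"
        )
    k = int(counts.iloc[0])
    df = df.sort_values(_VALVE_KEY + ["landmark_index"], kind="stable")
    grouped = df.groupby(_VALVE_KEY, sort=True)
    coords = np.empty((len(grouped), k, 3))
    labels = []
    for i, (_, block) in enumerate(grouped):
        idx = block["landmark_index"].to_numpy()
        if not np.array_equal(idx, np.arange(k)):
            raise ConsistencyError(
                f"valve {block['specimen_id'].iloc[0]!r} has non-contiguous landmark indices"
            )
        coords[i] = block[["x", "y", "z"]].to_numpy()
        labels.append(block.iloc[0][LABEL_COLUMNS])
    label_df = pd.DataFrame(labels).reset_index(drop=True)
    label_df["replicate"] = label_df["replicate"].astype(int)
    return SpecimenSet(coords, label_df, topology)


def write_landmarks_csv(
    data: SpecimenSet, path: str | os.PathLike, aligned: bool = False
) -> None:
    """Write a specimen set in the long CSV dialect (17 significant digits)."""
    n, k, _ = data.coords.shape
    rep = data.labels.loc[data.labels.index.repeat(k)].reset_index(drop=True)
    out = rep[LABEL_COLUMNS].copy()
    out["landmark_index"] = np.tile(np.arange(k), n)
    flat = data.coords.reshape(n * k, 3)
    out["x"], out["y"], out["z"] = flat[:, 0], flat[:, 1], flat[:, 2]
    if aligned:
        out["aligned"] = True
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# TPS


def read_tps(
    path: str | os.PathLike,
    metadata: str | os.PathLike | pd.DataFrame,
    topology: SemilandmarkTopology | str | os.PathLike,
) -> SpecimenSet:
    """Read 3D landmarks from a TPS file with ``LM3=`` records.

    ``ID=`` values key into the ``metadata`` sidecar table (columns
    ``id`` plus the five specimen label columns). ``SCALE=`` records are
    applied multiplicatively. 2D ``LM=`` records are rejected.
    """
    if not isinstance(topology, SemilandmarkTopology):
        topology = read_topology_csv(topology)
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    if "id" not in metadata.columns:
        raise FormatError("TPS metadata sidecar needs an 'id' column")
    meta = metadata.set_index("id")

    records: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if current is not None:
                    records.append(current)
                current = {"n": int(line.split("=", 1)[1]), "pts": [], "id": None, "scale": 1.0}
            elif upper.startswith("LM="):
                raise FormatError(f"line {lineno}: 2D LM= records are not supported (need LM3=)")
            elif upper.startswith("ID="):
                if current is None:
                    raise FormatError(f"line {lineno}: ID= before any LM3= record")
                current["id"] = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                if current is None:
                    raise FormatError(f"line {lineno}: SCALE= before any LM3= record")
                current["scale"] = float(line.split("=", 1)[1])
            elif upper.startswith(("IMAGE=", "COMMENT=")):
                continue
            else:
                if current is None:
                    raise FormatError(f"line {lineno}: coordinates before any LM3= record")
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"line {lineno}: expected 3 coordinates, got {len(parts)}")
                current["pts"].append([float(p) for p in parts])
    if current is not None:
        records.append(current)
    if not records:
        raise FormatError("no LM3= records found")

    coords = []
    labels = []
    for rec in records:
        if len(rec["pts"]) != rec["n"]:
            raise FormatError(
                f"record {rec['id']!r}: LM3={rec['n']} but {len(rec['pts'])} points given"
            )
        if rec["id"] is None:
            raise FormatError("LM3= record without ID=")
        if rec["id"] not in meta.index:
            raise FormatError(f"TPS record {rec['id']!r} absent from metadata sidecar")
        coords.append(np.asarray(rec["pts"], dtype=float) * rec["scale"])
        labels.append(meta.loc[rec["id"], LABEL_COLUMNS])
    ks = {c.shape[0] for c in coords}
    if len(ks) > 1:
        raise ConsistencyError(f"ragged landmark counts across TPS records: {sorted(ks)}")
    label_df = pd.DataFrame(labels).reset_index(drop=True)
    label_df["replicate"] = label_df["replicate"].astype(int)
    return SpecimenSet(np.stack(coords), label_df, topology)


def write_tps(data: SpecimenSet, path: str | os.PathLike, metadata_path: str | os.PathLike) -> None:
    """Write TPS records (ID = specimen_id_side_rep) plus the metadata sidecar."""
    meta_rows = []
    with open(path, "w") as fh:
        for i in range(data.n):
            row = data.labels.iloc[i]
            rec_id = f"{row['specimen_id']}_{row['side']}_{row['replicate']}"
            fh.write(f"LM3={data.k}\n")
            for pt in data.coords[i]:
                fh.write(f"{float(pt[0])!r} {float(pt[1])!r} {float(pt[2])!r}\n")
            fh.write(f"ID={rec_id}\n")
            meta_rows.append({"id": rec_id, **{c: row[c] for c in LABEL_COLUMNS}})
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | os.PathLike, ultrametric_tol: float = 1e-6) -> Phylogeny:
    """Read a single rooted Newick tree with branch lengths.

    Non-ultrametric trees (beyond ``ultrametric_tol`` relative to tree
    depth) trigger a warning, not an error.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return Phylogeny(tree, ultrametric_tol=ultrametric_tol)


def parse_newick(newick: str, ultrametric_tol: float = 1e-6) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return Phylogeny(tree, ultrametric_tol=ultrametric_tol)


def write_newick(phy: Phylogeny, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(phy.as_newick() + "\n")


def prune_to_common(
    tree: Phylogeny, data: SpecimenSet, min_species: int = 3
) -> tuple[Phylogeny, SpecimenSet]:
    """Restrict tree and data to their shared species.

    Degree-2 internal nodes left by pruning are collapsed with branch
    lengths summed, conserving root-to-tip path lengths. The tip order
    of the returned tree is the canonical species order for downstream
    matrices. Raises :class:`InsufficientOverlapError` when fewer than
    ``min_species`` species are shared.
    """
    data_species = set(data.labels["species"])
    tree_species = set(tree.tip_names)
    shared = data_species & tree_species
    if len(shared) < min_species:
        raise InsufficientOverlapError(
            f"only {len(shared)} species shared between tree and data (need {min_species})"
        )
    if shared == tree_species:
        pruned_tree = tree
    else:
        sub = tree.tree.extract_tree_with_taxa_labels(
            labels=shared, suppress_unifurcations=True
        )
        sub.seed_node.edge.length = None  # drop any stem left by extraction
        pruned_tree = Phylogeny(sub)
    if shared == data_species:
        pruned_data = data
    else:
        mask = data.labels["species"].isin(shared).to_numpy()
        pruned_data = data.subset(mask)
    return pruned_tree, pruned_data
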