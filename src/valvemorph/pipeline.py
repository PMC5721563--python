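"""End-to-end study workflow.

Runs the full analysis in order: load (or simulate) landmarks and
chronogram, prune to shared species, per-valve Procrustes
superimposition with sliding, replicate averaging, species means,
phylogenetic PLS of left against right valve shape (overall and per
ecomorph) with effect-size comparisons, joint mirrored superimposition
and directional asymmetry, D-PGLS of species asymmetry on ecomorph, and
the four evolutionary-rate hypotheses with bootstrap confidence
intervals:

  H1  DA rate differs among ecomorphs
  H2  net shape rate differs between left and right valves
  H3  net shape rate differs among ecomorphs (a: left, b: right)
  H4  left-vs-right rate differs within each ecomorph

A single global seed fans out to per-stage streams through fixed
offsets, so any stage can be rerun in isolation reproducibly.
"""
from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as morphio
from .asymmetry import asymmetry_magnitude, ecomorph_summary, joint_superimpose
from .containers import Phylogeny, SpecimenSet
from .dpgls import dpgls_permutation
from .evorates import (
    bootstrap_rate_ci,
    compare_rates_groups,
    compare_rates_traits,
    rates_within_groups,
)
from .exceptions import ValvemorphError
from .gpa import average_replicates, gpa_align, species_means
from .integration import compare_pls_effects, pls_permutation
from .phylo import phylo_covariance
from .synth import GeneratorConfig, generate_dataset

_STAGE_SEED_OFFSETS = {
    "integration": 101,
    "pgls": 211,
    "rates": 307,
    "bootstrap": 401,
}
#: subset PLS analyses need this many species per ecomorph
MIN_SUBSET_SPECIES = 4
ALL_STAGES = ("align", "integration", "asymmetry", "pgls", "rates")


@dataclass
class AnalysisConfig:
    """Inputs and budgets of one study run.

    Provide either a :class:`~valvemorph.synth.GeneratorConfig` or the
    four file paths. Counts follow the study defaults of 1000
    permutations / simulations / bootstrap iterations; the seed is
    mandatory and drives every stochastic stage.
    """

    seed: int
    generator: GeneratorConfig | None = None
    landmarks_left: str | None = None
    landmarks_right: str | None = None
    topology: str | None = None
    tree: str | None = None
    n_perm: int = 1000
    n_sim: int = 1000
    n_boot: int = 1000
    mirror_axis: str = "x"
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_sim"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be at least 99")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.generator is None:
            needed = (self.landmarks_left, self.landmarks_right, self.topology, self.tree)
            if any(p is None for p in needed):
                raise ValueError("either a generator config or all four input paths are required")

    def config_dict(self) -> dict:
        gen = None
        if self.generator is not None:
            from dataclasses import asdict

            gen = asdict(self.generator)
            gen["n_specimens_per_species"] = list(np.atleast_1d(gen["n_specimens_per_species"]))
        return {
            "seed": self.seed,
            "generator": gen,
            "landmarks_left": self.landmarks_left,
            "landmarks_right": self.landmarks_right,
            "topology": self.topology,
            "tree": self.tree,
            "n_perm": self.n_perm,
            "n_sim": self.n_sim,
            "n_boot": self.n_boot,
            "mirror_axis": self.mirror_axis,
        }


@dataclass
class StudyReport:
    """All tables and statistics of one study run."""

    manifest: dict
    pls_summary: pd.DataFrame | None = None
    pls_pairwise: pd.DataFrame | None = None
    asymmetry_specimen: pd.DataFrame | None = None
    asymmetry_species: pd.DataFrame | None = None
    asymmetry_ecomorph: pd.DataFrame | None = None
    pgls_table: pd.DataFrame | None = None
    rates: dict[str, Any] = field(default_factory=dict)

    def _payloads(self) -> dict[str, str]:
        manifest = {k: v for k, v in self.manifest.items() if k != "runtime_s"}
        out = {"manifest.json": _json_dumps(manifest)}
        frames = {
            "pls_summary.csv": self.pls_summary,
            "pls_pairwise.csv": self.pls_pairwise,
            "asymmetry_specimen.csv": self.asymmetry_specimen,
            "asymmetry_species.csv": self.asymmetry_species,
            "asymmetry_ecomorph.csv": self.asymmetry_ecomorph,
            "pgls.csv": self.pgls_table,
        }
        for name, df in frames.items():
            if df is not None:
                out[name] = df.to_csv(index=False, float_format="%.12g")
        if self.rates:
            out["rates.json"] = _json_dumps(self.rates)
        return out

    def report_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self._payloads()):
            h.update(name.encode())
            h.update(self._payloads()[name].encode())
        return h.hexdigest()

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, payload in self._payloads().items():
            with open(os.path.join(outdir, name), "w") as fh:
                fh.write(payload)


def _json_dumps(obj: Any) -> str:
    def default(o: Any):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    return json.dumps(_round_floats(obj), indent=1, sort_keys=True, default=default)


def _round_floats(obj: Any) -> Any:
    """Round floats to 12 significant digits for hash-stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _rate_result_dict(res) -> dict:
    out = {
        "sigma2": res.sigma2,
        "ratio": res.ratio,
        "n_species": res.n_species,
        "p_value": res.p_value,
        "n_sim": res.n_sim,
        "flags": res.flags,
    }
    if res.pairwise_p is not None:
        out["pairwise_p"] = {f"{a}|{b}": p for (a, b), p in res.pairwise_p.items()}
    if res.ci_low is not None:
        out["ci_low"] = res.ci_low
        out["ci_high"] = res.ci_high
        out["n_boot"] = res.n_boot
    return out


def _renorm_rows(M: np.ndarray) -> np.ndarray:
    """Center and unit-size each flattened configuration row."""
    X = M.reshape(M.shape[0], -1, 3)
    X = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2), keepdims=True))
    return (X / sizes).reshape(M.shape[0], -1)


def run_study(
    config: AnalysisConfig, stages: Sequence[str] | None = None
) -> StudyReport:
    """Execute the workflow; returns (and optionally writes) the report.

    ``stages`` restricts execution to a subset of
    ``("align", "integration", "asymmetry", "pgls", "rates")``;
    prerequisite stages are added automatically. Any stage failure is
    re-raised with the stage name; partial outputs are written with a
    FAILED marker when an output directory is configured.
    """
    t0 = time.time()
    requested = set(stages if stages is not None else ALL_STAGES)
    unknown = requested - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    requested.add("align")
    if "pgls" in requested:
        requested.add("asymmetry")
    if "rates" in requested:
        requested.add("asymmetry")

    cfg_json = _json_dumps(config.config_dict())
    manifest = {
        "seed": config.seed,
        "config": config.config_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": sorted(requested),
        "package": "valvemorph",
    }
    report = StudyReport(manifest=manifest)
    stage = "load"
    try:
        left, right, phy = _load_inputs(config)

        stage = "align"
        phy, left = morphio.prune_to_common(phy, left)
        phy, right = morphio.prune_to_common(phy, right)
        if set(left.labels["species"]) - set(phy.tip_names):
            phy, left = morphio.prune_to_common(phy, left)
        species_order = list(phy.tip_names)
        C = phylo_covariance(phy, species_order)
        aligned_left = average_replicates(gpa_align(left, slide=True))
        aligned_right = average_replicates(gpa_align(right, slide=True))
        means_left = species_means(aligned_left, species_order)
        means_right = species_means(aligned_right, species_order)
        eco_by_species = (
            left.labels.drop_duplicates("species").set_index("species")["ecomorph"].to_dict()
        )
        groups = [eco_by_species[sp] for sp in species_order]

        if "integration" in requested:
            stage = "integration"
            report.pls_summary, report.pls_pairwise = _run_integration(
                means_left.matrix, means_right.matrix, C, groups, config
            )

        asym_table = None
        if "asymmetry" in requested:
            stage = "asymmetry"
            joint = joint_superimpose(
                aligned_left.as_specimen_set(),
                aligned_right.as_specimen_set(),
                mirror_axis=config.mirror_axis,
            )
            asym_table = asymmetry_magnitude(joint)
            report.asymmetry_specimen = asym_table.per_specimen
            report.asymmetry_species = asym_table.per_species
            report.asymmetry_ecomorph = ecomorph_summary(asym_table)

        if "pgls" in requested:
            stage = "pgls"
            da_species = asym_table.species_vector(species_order)
            pgls = dpgls_permutation(
                da_species,
                groups,
                C,
                n_perm=config.n_perm,
                seed=config.seed + _STAGE_SEED_OFFSETS["pgls"],
            )
            report.pgls_table = pgls.anova_table()

        if "rates" in requested:
            stage = "rates"
            report.rates = _run_rates(
                config,
                C,
                groups,
                species_order,
                means_left,
                means_right,
                aligned_left,
                aligned_right,
                asym_table,
            )
    except ValvemorphError:
        _write_failed(config, report, stage)
        raise
    except Exception as exc:  # annotate with the failing stage
        _write_failed(config, report, stage)
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc

    manifest["runtime_s"] = round(time.time() - t0, 3)
    if config.outdir:
        report.write(config.outdir)
    return report


def _write_failed(config: AnalysisConfig, report: StudyReport, stage: str) -> None:
    if config.outdir:
        try:
            report.write(config.outdir)
            with open(os.path.join(config.outdir, "FAILED"), "w") as fh:
                fh.write(stage + "\n")
        except OSError:
            pass


def _load_inputs(config: AnalysisConfig) -> tuple[SpecimenSet, SpecimenSet, Phylogeny]:
    if config.generator is not None:
        left, right, phy, _ = generate_dataset(config.generator)
        return left, right, phy
    topo = morphio.read_topology_csv(config.topology)
    left = morphio.read_landmarks_csv(config.landmarks_left, topo)
    right = morphio.read_landmarks_csv(config.landmarks_right, topo)
    phy = morphio.read_newick(config.tree)
    return left, right, phy


def _run_integration(Y1, Y2, C, groups, config: AnalysisConfig):
    seed = config.seed + _STAGE_SEED_OFFSETS["integration"]
    results = [
        pls_permutation(Y1, Y2, C, n_perm=config.n_perm, seed=seed, label="all")
    ]
    groups_arr = np.asarray(groups)
    for i, eco in enumerate(sorted(set(groups))):
        idx = np.flatnonzero(groups_arr == eco)
        if len(idx) < MIN_SUBSET_SPECIES:
            warnings.warn(
                f"ecomorph {eco!r} has {len(idx)} species (<{MIN_SUBSET_SPECIES}); "
                "excluded from subset PLS",
                stacklevel=2,
            )
            continue
        sub_species = [C.species_order[j] for j in idx]
        Csub = C.submatrix(sub_species, reroot=True)
        results.append(
            pls_permutation(
                Y1[idx], Y2[idx], Csub, n_perm=config.n_perm, seed=seed + 1 + i, label=eco
            )
        )
    summary = pd.DataFrame([r.summary_row() for r in results])
    pairwise = compare_pls_effects(results) if len(results) >= 2 else None
    return summary, pairwise


def _paired_specimen_blocks(aligned_left, aligned_right):
    """Row-matched flattened shapes of complete shells plus species labels."""
    li = aligned_left.labels.set_index("specimen_id")
    ri = aligned_right.labels.set_index("specimen_id")
    shared = sorted(set(li.index) & set(ri.index))
    lpos = {s: i for i, s in enumerate(aligned_left.labels["specimen_id"])}
    rpos = {s: i for i, s in enumerate(aligned_right.labels["specimen_id"])}
    L = np.stack([aligned_left.shapes[lpos[s]].ravel() for s in shared])
    R = np.stack([aligned_right.shapes[rpos[s]].ravel() for s in shared])
    species = [li.loc[s, "species"] for s in shared]
    return L, R, species


def _run_rates(
    config: AnalysisConfig,
    C,
    groups,
    species_order,
    means_left,
    means_right,
    aligned_left,
    aligned_right,
    asym_table,
) -> dict:
    seed = config.seed + _STAGE_SEED_OFFSETS["rates"]
    boot_seed = config.seed + _STAGE_SEED_OFFSETS["bootstrap"]
    YL = means_left.matrix
    YR = means_right.matrix
    da_species = asym_table.species_vector(species_order)
    group_map = dict(zip(species_order, groups))

    h1 = compare_rates_groups(da_species, groups, C, n_sim=config.n_sim, seed=seed)
    h2 = compare_rates_traits({"left": YL, "right": YR}, C, n_sim=config.n_sim, seed=seed + 1)
    h3a = compare_rates_groups(YL, groups, C, n_sim=config.n_sim, seed=seed + 2)
    h3b = compare_rates_groups(YR, groups, C, n_sim=config.n_sim, seed=seed + 3)
    h4 = rates_within_groups(YL, YR, group_map, C, n_sim=config.n_sim, seed=seed + 4)

    # bootstrap CIs: resample specimens within species, redo species means
    per_spec = asym_table.per_specimen
    da_vals = per_spec["da"].to_numpy()[:, None]
    da_labels = per_spec["species"].tolist()

    def da_stat(M: np.ndarray) -> dict[str, float]:
        res = compare_rates_groups(M, groups, C, n_sim=0)
        out = dict(res.sigma2)
        out["overall"] = float(np.mean(list(res.sigma2.values())))
        return out

    h1.ci_low, h1.ci_high = bootstrap_rate_ci(
        da_vals, da_labels, species_order, da_stat, n_boot=config.n_boot, seed=boot_seed
    )
    h1.n_boot = config.n_boot

    L, R, pair_species = _paired_specimen_blocks(aligned_left, aligned_right)
    LR = np.hstack([L, R])
    p = L.shape[1]

    def valve_stat(M: np.ndarray) -> dict[str, float]:
        res = compare_rates_traits(
            {"left": _renorm_rows(M[:, :p]), "right": _renorm_rows(M[:, p:])}, C, n_sim=0
        )
        return dict(res.sigma2)

    h2.ci_low, h2.ci_high = bootstrap_rate_ci(
        LR, pair_species, species_order, valve_stat, n_boot=config.n_boot, seed=boot_seed + 1
    )
    h2.n_boot = config.n_boot

    return {
        "h1_da_by_ecomorph": _rate_result_dict(h1),
        "h2_left_vs_right": _rate_result_dict(h2),
        "h3a_left_by_ecomorph": _rate_result_dict(h3a),
        "h3b_right_by_ecomorph": _rate_result_dict(h3b),
        "h4_within_ecomorph": {g: _rate_result_dict(r) for g, r in h4.items()},
    }
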