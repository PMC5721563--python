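# valvemorph

Phylogenetic geometric morphometrics of paired bivalve valves: Procrustes
superimposition with sliding semilandmarks, matching (directional)
asymmetry between left and right valves, evolutionary integration via
phylogenetic two-block partial least squares, multivariate phylogenetic
GLS, and multivariate Brownian-motion rate comparison — plus a synthetic
shell generator for simulation studies at the scale of a real
macroevolutionary dataset (scallop-like: 86 species in six ecomorphs,
hundreds of specimens, duplicate digitization).

## Who this is for

Evolutionary morphologists asking how the two valves of a bivalved shell
diversify: do ecological groups (ecomorphs) differ in the tempo of valve
shape evolution, do left and right valves evolve at different rates, how
inequivalve are species, and how tightly integrated are the two valves
across a clade? The same machinery applies to any paired 3D structure
with fixed landmarks and sliding semilandmarks.

## The methods at its core

- **Generalized Procrustes analysis (GPA) with sliding semilandmarks.**
  Configurations of k landmarks in 3D are centered, scaled to unit
  centroid size, and rotated (proper rotations only) to a consensus.
  Semilandmarks slide along their tangent directions — curve points
  along the chord between chain neighbors, surface points within the
  best-fit plane of their topological neighbors — to minimize Procrustes
  distance to the consensus.
- **Matching asymmetry.** Right valves are mirrored, all valves are
  superimposed jointly (again with sliding), and each specimen's
  directional asymmetry (DA) is the Procrustes distance between its left
  and mirrored right valve: 0 = equivalve, larger = inequivalve.
- **Phylogenetic transformation.** With C the Brownian-motion covariance
  of the tree (shared root-to-MRCA path lengths), species data Y become
  U = C^(-1/2)(Y − 1â), â the GLS root estimate; rows of U are
  exchangeable under single-rate BM.
- **Integration (r_PLS).** The first singular pair of the cross-block
  covariance of transformed left- and right-valve shapes gives axes
  whose score correlation is r_PLS; significance by permuting
  transformed rows (1000 permutations), effect sizes on the Fisher-z
  scale for cross-group comparison.
- **D-PGLS.** Multivariate one-way PGLS of (e.g.) species-mean DA on
  ecomorph, F from trace sums of squares, significance by residual
  randomization (RRPP).
- **Evolutionary rates.** σ² = Σᵢ‖uᵢ‖²/(Np): the net BM rate per unit
  tree time per trait dimension. Group and trait-block rates are
  compared through max/min ratios against nulls simulated under a
  single-rate BM that preserves the estimated trait covariance;
  bootstrap CIs resample specimens within species.

## Worked example

Simulate the study-patterned dataset and run the full workflow:

```python
import valvemorph as vm

config = vm.AnalysisConfig(
    seed=1,
    generator=vm.paper_pattern(seed=1, n_specimens_per_species=3, n_replicates=2),
    n_perm=199, n_sim=199, n_boot=199,
)
report = vm.run_study(config)

print(report.pls_summary[["label", "n", "r_pls", "p"]])
h2 = report.rates["h2_left_vs_right"]
print("sigma2 R/L =", h2["sigma2"]["right"] / h2["sigma2"]["left"], "p =", h2["p_value"])
```

Output (seed 1):

```
              label   n     r_pls      p
0               all  86  0.860547  0.005
1  byssal-attaching  48  0.897497  0.005
2       free-living  18  0.941897  0.005
3           gliding   6  0.960165  0.010
4         recessing  11  0.978178  0.005
sigma2 R/L = 1.188304657964063 p = 0.005
```

Read: the two valves are strongly integrated across all 86 species
(r_PLS = 0.86, permutation p = 0.005) and within every ecomorph with
enough species; right valves evolve ~19% faster than left valves
(σ²-ratio 1.19, simulation p = 0.005). The report also carries the DA
tables (recessing species the most inequivalve, gliders the most
equivalve), the D-PGLS of species-mean DA on ecomorph, per-ecomorph rate
ratios with bootstrap CIs, and within-ecomorph right/left comparisons.

The same workflow runs from files (landmark CSV or TPS + metadata
sidecar + topology descriptor + Newick chronogram), or from the shell:

```sh
valvemorph run-all --seed 1 --preset paper-pattern --n-specimens 3 --out results/run1
valvemorph simulate --seed 2 --out data/synthetic
```

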