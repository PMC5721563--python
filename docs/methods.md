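# Methods

This note documents the models, numerical schemes and design choices
behind valvemorph, in the order data flows through the package.

## Superimposition

### Generalized Procrustes analysis

Each landmark configuration (k points in 3D; k_fixed anatomical
landmarks first, then semilandmarks) is translated to a zero centroid
and scaled to unit centroid size (the root summed squared distance of
points to their centroid). The rotation loop then alternates rotating
every configuration onto the current consensus and recomputing the
consensus (the coordinate-wise mean, re-normalized), until the
Procrustes distance between successive consensus shapes falls below
`tol` (default 1e-9) or `max_iter` (default 100) is reached;
non-convergence sets a flag and emits a warning. Rotations are the
proper orthogonal Procrustes solution: with H = XᵀM and SVD H = UΣVᵀ,
R = U·diag(1, 1, det(UVᵀ))·Vᵀ. Reflections are never fitted — a silent
reflection would corrupt asymmetry measurement — so handedness must be
handled explicitly with `mirror_configuration`. In the rank-deficient
case the sign flip lands on the smallest singular direction (ties:
highest index), which makes outcomes deterministic.

### Sliding semilandmarks

Semilandmarks carry no one-to-one anatomical correspondence, so during
superimposition they are allowed to move in the directions in which
their position is arbitrary: curve points along the unit vector between
their two chain neighbors, surface points within the plane spanned by
the two leading principal directions of their (≥3) topological
neighbors. The displacement is the orthogonal projection of the
residual to the consensus onto that tangent subspace — the
Procrustes-distance criterion, which can only reduce the point's squared
residual. The update is simultaneous (Jacobi): tangents, planes and
residuals are all evaluated at the pre-slide positions, so the result
does not depend on the order in which points are processed and equals
the stated projection exactly. Degenerate tangents (coincident chain
neighbors, rank-deficient neighbor clouds) suppress sliding for the
affected point in that pass. Fixed landmarks are never touched
(bit-exact).

Sliding passes are interleaved with the rotation loop but capped
(default 5 passes), with early stopping once a pass improves the total
Procrustes sum of squares by less than a relative `slide_tol` (default
1e-4). The cap is essential, not cosmetic: tangent projection against a
consensus that is itself re-estimated each pass has no fixed point on
pure point data — there is no underlying surface to relax back onto, so
iterated sliding lets semilandmarks creep along the outline and the
configuration slowly degenerate while the SS keeps falling. A handful
of passes captures essentially all of the attainable SS reduction
(observed: the first pass does ~80% of the total, the fifth <0.5%).

Replicate averaging happens after alignment (aligned-shape average,
re-normalized); species means likewise, ordered by the pruned tree's
tip order so downstream matrices align with the phylogenetic
covariance.

### Matching asymmetry

Right valves are mirrored across the plane normal to a chosen axis
(default x), pooled with the left valves, and superimposed in a single
GPA with sliding. A specimen's directional asymmetry (DA) is the
Procrustes distance between its left and mirrored-right valve in that
common frame, *without* re-rotating the pair onto each other: the joint
fit already placed every valve in one orientation, and a per-pair
re-rotation would remove real hinge-orientation asymmetry. Incomplete
shells (one valve missing) are dropped with a warning. Species means
and variances of DA are reported together because the spread of
asymmetry within an ecomorph is itself of interest.

## Phylogenetic machinery

The Brownian-motion covariance C has C[i,j] = the root-to-MRCA path
length of species i and j (tip depth on the diagonal), built in one
postorder traversal; the dendropy patristic-distance matrix serves as
an independent oracle in the tests. C^(−1/2) is the symmetric
eigendecomposition root — unique and independent of species ordering,
unlike a Cholesky factor — with eigenvalues below 1e-12 × the largest
treated as a numerically singular tree (zero-length cherry) and
reported as an error. The phylogenetic transformation removes the GLS
root estimate â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y and whitens: U = C^(−1/2)(Y − 1â).
On a star tree this is ordinary centering (scaled by depth^(-1/2)).

Subtree analyses (per-ecomorph PLS, within-group rate comparisons) use
the covariance submatrix re-rooted at the subset's MRCA (the smallest
off-diagonal entry subtracted throughout), equivalent to pruning the
tree.

## Integration

Two-block PLS takes the first singular pair (u, v) of the cross-block
covariance of the (internally column-centered) blocks; r_PLS is the
absolute correlation of the scores Y₁u and Y₂v. Only the first axis
pair defines r_PLS. The phylogenetic variant transforms both blocks
first. Significance permutes rows of the *transformed* second block —
after whitening, rows are exchangeable under the BM null — with
p = (#{r* ≥ r} + 1)/(n_perm + 1), so p is never zero. Effect sizes use
the Fisher z-transform (r values up to ~0.98 occur; the transform
stabilizes the skew near 1): z = (f(r) − mean f(r*))/sd f(r*).

Cross-analysis comparison of integration strength uses the deviations
Δᵢ = f(rᵢ) − mean f(rᵢ*) and their permutation spreads:
z_ij = |Δᵢ − Δⱼ|/√(sdᵢ² + sdⱼ²), two-sided normal p. Under each
analysis's own null Δ ~ (0, sd²) approximately, so the comparison is
calibrated; simulation confirms ~5% size at α = 0.05. Ecomorphs with
fewer than 4 species are excluded from subset PLS (their covariance
estimates are too unstable to interpret).

## D-PGLS

A one-way design (intercept + group dummies) and the response are both
whitened by C^(−1/2); sums of squares are Frobenius norms of fitted and
residual matrices relative to the reduced (GLS-mean-only) model, so the
F statistic is defined for responses of any dimensionality, including
p ≫ N. Significance is by RRPP: reduced-model residuals in the
whitened space are row-permuted, added back to the reduced fit, and F
recomputed. The response may be the scalar species-mean DA or a full
shape matrix.

## Evolutionary rates

σ² = Σᵢ‖uᵢ‖²/(N·p) — the mean squared whitened deviation per species
per trait dimension, in squared trait units per unit tree time.
Dividing by p makes a scalar trait (DA) and a 3k-dimensional shape
trait comparable per dimension; `per_dimension=False` recovers the
un-normalized convention, and absolute rates should only be compared
across traits with the same convention. The estimator is unbiased up to
the (N−1)/N GLS-mean factor (<1% at N ≥ 86; simulation: mean 0.9998 of
truth at N=128).

Group rates use each group's rows of U (denominator N_g·p); trait-block
rates (left vs right valve) use each block's columns. The test
statistic is the max/min rate ratio. Nulls are parametric simulations
of single-rate BM on the tree: tips drawn matrix-normal with row
covariance C and column covariance the pooled evolutionary trait
covariance Σ̂ = UᵀU/N, rescaled so trace(Σ̂)/p equals the pooled rate
(for trait blocks, each block's diagonal block is rescaled to the
common rate, preserving between-block correlation). Pairwise group
p-values reuse the same simulations; no multiple-testing correction is
applied (raw pairwise p-values are reported, as is conventional for
this statistic). Simulation-based p-values carry the +1 correction.

Within-group left/right comparisons run per group on the re-rooted
subtree. Groups with one species get no estimate beyond a flag; groups
with two get point estimates but no test — with N = 2 the estimated
trait covariance has rank 1, so the null ratio distribution is
degenerate and any observed ratio would look extreme.

Bootstrap 95% CIs resample specimens within species with replacement
(the tree fixed), recompute species means and the rate statistic, and
take 2.5/97.5 percentiles. Species with a single specimen contribute a
constant mean, which narrows their contribution to the CI rather than
failing.

## Synthetic shell generator

The generator emulates the structure of a museum-scale study of
scallop valve shape; it is the package's test bed, not a model of any
particular dataset.

**Tree.** Pure-birth, rescaled to unit depth (rates are per unit of
this relative time). Ecomorphs are assigned as contiguous blocks of
the tip order — life habit is phylogenetically conserved in the
emulated clade — with block order shuffled by seed and species counts
2/1/48/11/18/6 (cementing/nestling/byssal-attaching/recessing/
free-living/gliding) by default. Clustering matters statistically: the
whitening transform spreads each species' variance across its
relatives, so randomly scattered group labels would make group-rate
contrasts nearly unidentifiable at these group sizes.

**Shape model.** A valve is a fan-shaped outline in the commissural
(z = 0) plane with five fixed hinge/auricle/umbo landmarks and a
radial grid of semilandmarks lifted to a dome z = convexity·(1 − r²):
convexity 0 is a flat, glider-like valve, large convexity a cupped,
recesser-like one. 18 latent dimensions control it: convexity, outline
eccentricity, auricle width/height, umbo position, fan aperture, six
Fourier outline modes (harmonics 2–4) and six dome relief modes
(harmonics 1–3, vanishing at apex and margin). Configurations are
emitted at unit centroid size (superimposition removes size anyway,
and a size-free map keeps a clade's drift in overall size from
rescaling its apparent shape variance). Wide clip bounds keep the
geometry sane and bind only in extreme tails. The latent-to-landmark
map is smooth and fixed, so Brownian latents induce approximately
Brownian landmark evolution — an approximation, not an identity.

**Evolution.** Left and right valves share every internal branch's
Brownian increment at a global correlation (0.9 unless the scalar
`integration_rho` says otherwise); ecomorph structure lives on terminal
branches only: per-valve rate multipliers scale the terminal increment
variance and a per-ecomorph correlation mixes the terminal increments
of the two valves. Keeping every increment proportional to branch
length is deliberate — constructions that scale whole root-to-tip
paths, or inject branch-independent variance, create discontinuities
between sister species that the whitening transform amplifies without
bound. For the same reason the directional-asymmetry offset (a
constant added to right-valve convexity per ecomorph) is scaled by
√(terminal branch/mean terminal branch), i.e. it accrues like a
directional trend along the species' own branch. A consequence of
terminal-only rate shifts is attenuation: shared history evolves at
the baseline rate, so estimated group contrasts are roughly half the
terminal multipliers at these tree shapes.

**Noise.** Two layers: per-specimen latent noise (sd 0.015 per
dimension — individual variation, ~10% of the between-species latent
spread) and per-replicate coordinate noise (sd 0.002 — digitizing
error, ~2% of a typical interspecific Procrustes distance). Measurement
error is not tree-structured, so whitening amplifies whatever error
survives replicate- and specimen-averaging by roughly the inverse
terminal branch length; unrealistically large digitizing error would
therefore not just blur estimates but bias group comparisons toward
whichever group holds the shortest branches. The defaults keep this
term an order of magnitude below the evolutionary signal.

**The `paper_pattern` preset** expresses the qualitative result
pattern of the emulated study system: high rates for gliding, recessing
and nestling species with near-baseline rates for the others; right
valves faster than left overall, most extremely in the nestler
(per-valve multipliers, e.g. nestling (1.5, 12.0), byssal (1.0, 1.0),
are chosen so the *estimated* contrasts land at observed scale after
attenuation); large DA offsets for the sedentary ecomorphs and
near-symmetry for gliders; integration strongest in gliders (0.97) and
weakest in recessers (0.88). At seed 1 the full workflow on this preset
yields r_PLS(all) = 0.86, σ²(right)/σ²(left) = 1.19, within-ecomorph
right/left ratios of 2.03 (gliding) and 1.69 (recessing), and the
recessing ecomorph with the highest mean DA — all computed by
`scripts/acceptance.py`, never hard-coded.

**What the generator does not emulate:** real surface correspondence
(its semilandmarks are generated at template positions, not resampled
from meshes), shell ornamentation and growth, ancestral ecomorph
history (states are tip states), non-Brownian evolution, and
phylogenetic uncertainty. Passing tests therefore certify the
statistical machinery and its calibration under a BM world with known
truth — not that any particular empirical dataset satisfies those
assumptions.

## Numerical and reproducibility choices

- All permutation and simulation p-values use the +1 correction and a
  single seeded `numpy.random.Generator` per analysis.
- The pipeline fans one global seed out to per-stage streams through
  fixed offsets, so stages can be rerun in isolation; report files are
  written with 12-significant-digit floats and hashed (SHA-256) for
  run-to-run comparison.
- GPA convergence: tol 1e-9 on consensus displacement, max 100
  rotation iterations, 5 sliding passes at relative SS tolerance 1e-4.
- Degenerate inputs: zero centroid size, mismatched landmark schemes,
  non-ultrametric trees (warning, tolerance 1e-6 relative), missing
  branch lengths, zero-length cherries and collinear designs all raise
  typed errors from `valvemorph.exceptions`.
- Problem sizes in the test suite (86 species, 3 specimens, 2
  replicates, 50 landmarks; 500-dataset calibration batches at N = 64)
  are the package's reduced study scale: large enough for every
  qualitative contrast in the preset to be identifiable, small enough
  that the whole suite runs on a laptop in minutes. A paper-scale
  configuration (k_semi = 197, 2–14 specimens per species) is one
  constructor argument away and used in the scale checks.

## Known limitations

- Procrustes-distance sliding (not bending energy); minimum-energy
  sliding would give different semilandmark placements.
- The rate comparison assumes the estimated trait covariance under the
  null; with very few species per group (≤2) that estimate is rank
  deficient and the package refuses to test rather than mis-test.
- Attenuation of terminal-rate-shift contrasts means generator
  multipliers are not directly the recoverable ratios; recovery tests
  that need exact truth use matrix-normal simulation on C directly.
- Object (within-valve) symmetry is out of scope; only matching
  left-right asymmetry is quantified.
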