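# Methods

This note documents the models and procedures implemented in `molarmap`,
the defaults and the reasoning behind the choices that were genuinely
open, and what the synthetic test data do and do not establish.

## Standard pose

A specimen is a triangle mesh plus an ordered cervical outline (vertex
indices or 3D polyline) and a buccal anchor point. The outline's
total-least-squares plane (SVD of the centred points; the plane passes
through their centroid) defines the horizontal; its normal is oriented
toward the mesh centroid so +z is the cusp side. After rotating that
normal to +z and placing the outline centroid at the origin, crown height
is the maximal z (highest cusp tip above the cervical plane) and the model
is shifted down by 20% of it, so the exact plane clip at z = 0 retains the
upper 80% of the crown — the analysis is deliberately restricted to cuspal
morphology, away from cervix digitization noise. A final rotation about z
brings the buccal anchor to azimuth 0. This makes the pose *canonical*:
any rigid pre-transform of the inputs yields the same oriented crown (the
test suite checks this to 1e-6), and the residual orientation freedom
handled later in Fourier space is a refinement, not a substitute, for the
anatomical pre-orientation.

The buccal direction must be supplied as an annotation because anatomical
labels are not derivable from geometry alone.

## Polar morphometric maps

The crown is cut by L equiangular vertical half-planes through the z-axis
(θ = 0 at buccal, increasing counterclockwise); each section curve is
sampled at K equal arc-length intervals from its innermost point (nearest
the z-axis) to its endpoint on z = 0, so row K lies exactly on the basal
plane. Defaults are K = L = 300 (≈ 1.2° angular resolution); the test
suite and examples use 16–32 per axis, which is sufficient for the low
filter sizes that matter downstream and keeps runtimes in seconds.

Sections are computed on the pre-crop surface and clipped at z ≥ 0 — this
is identical to sectioning the cropped crown (the crop is an exact plane
slice) but keeps every sample's containing triangle on the full mesh,
where vertex normals and curvature are estimated away from the cut
boundary. When a half-plane meets the surface in several curve components
(overhangs), the component ending on the basal plane with the largest mean
radius is kept, matching the idea of the section "running from the z-axis
to the outer intersection at z = 0". Arch-shaped components (both ends
basal) are oriented to end at the larger radius.

Six variables are recorded per sample:

- **h** — height above the basal plane (z of the sample);
- **r** — horizontal distance from the centroid axis;
- **Nx, Ny, Nz** — the unit vertex normal, barycentrically interpolated
  and re-normalized;
- **c** — surface curvature. The literature the pipeline descends from
  does not pin down an estimator; we use discrete mean curvature (the
  magnitude of the cotangent-Laplacian mean-curvature normal with
  barycentric vertex areas, signed positive on convex regions). Mean
  curvature is standard in dental topography, and the estimator is exact
  enough that a 10k-face hemisphere yields c = 1 within 5% at ≥95% of
  samples. Gaussian or principal curvatures would be drop-in alternatives
  but are out of scope.

### Normalization and weighting

Centroid size CS = √Σ_kl (h²_kl + r²_kl) is computed from the unweighted
h and r maps over all K·L samples; h and r are divided by CS and c is
*multiplied* by CS (curvature carries units of 1/length, so this is the
dimensionally consistent direction); normals are dimensionless. A mesh
scaled ×5 yields normalized maps identical to 1e-6.

Cell (k, l) of the unit-disk parameter domain has annular-sector area
a_kl = π[(k/K)² − ((k−1)/K)²]/L (the weights sum to π). Maps are
multiplied by √(a_kl/π) rather than a_kl: with square-root multipliers the
plain Euclidean distance between weighted maps *is* the area-weighted L2
distance between raw maps, which is the metric the Fourier distances
should realize. The direct-weight alternative would square the area
factor inside every distance. Weighting also tapers the maps toward zero
at the centre (a_1l → 0), which suppresses the spurious radial
discontinuity of the polar parameterization.

## Fourier features

Each weighted map is transformed with the standard unnormalized 2D DFT
(both axes treated as periodic: θ is naturally periodic; the weighting
makes the radial axis near-periodic by tapering the centre). Filter size
f retains the frequency block u, v ∈ {0, ±1, …, ±f} — (2f+1)² complex
coefficients per map. f may run up to min(K, L)//2; at the top of the
range the retained set is clipped to the axis length, so the maximal
filter keeps every coefficient, reconstruction is exact, and Parseval's
identity holds: squared feature distance = K·L × squared weighted-map
distance. Hermitian redundancy is kept (full block, real and imaginary
parts); this doubles some coordinates uniformly and therefore only scales
distances.

Residual rotations about z act on the retained block as phase factors
e^(−2πi v s / L) for an s-column shift. Alignment is a
generalized-Procrustes iteration: the consensus is initialized at the
first specimen; each specimen takes the integer shift minimizing its
distance to the consensus (found exactly by brute force over all L
shifts, cheap at these block sizes); the consensus is re-averaged;
iteration stops when the total squared distance decreases by < 1e-9
(relative) or after 100 iterations. Shifts are integers (1.2° at
L = 300); sub-grid rotation is not modelled — at the filter sizes used it
is below the grid resolution. Alignment runs once per (combination, f) on
the concatenated blocks of that combination, so all maps of a specimen
rotate together. Because the consensus is seeded with specimen 1, feature
vectors depend (weakly) on specimen order; results with a fixed input
order are bit-reproducible.

Feature vectors concatenate, map by map in combination order, the real
parts then imaginary parts of the aligned block — length
n_maps × 2 × (2f+1)².

## Data-mining grids

**Classification.** For every (combination, f) the features of all
labelled specimens are assembled, then each of seven classifier
configurations is scored by stratified k-fold cross-validation (default
10 folds, reduced to the smallest class size with a warning; fixed seed;
accuracy = 1 − mean CV loss). The bank mirrors an error-correcting
output-codes setup: linear SVM (C = 1) and regularized LDA (lsqr solver,
Ledoit–Wolf shrinkage — plain LDA is singular when features outnumber
specimens) are wrapped one-vs-one with vote decoding; the decision tree,
multinomial logistic regression and kNN (k = 1, 3, 5, Euclidean) are
natively multiclass. Distance- and margin-based learners are preceded by
per-dimension z-scoring fit on training folds only; the tree is
scale-invariant and runs raw. Cells that fail numerically are recorded as
missing, not zero. Individual specimens (not strain means) are
classified — cross-validation requires per-specimen labels.

Model selection takes all cells within `tolerance` of the best accuracy
and returns the one with the smallest f, then the fewest map variables,
then the earliest learner in the canonical order — "most parsimonious
among comparable".

**Phylogenetic signal.** For every (combination, f), features of all
specimens are assembled and aligned jointly, averaged per species
(means are only well-defined after rotational alignment, which is why
they are taken on feature vectors rather than meshes), matched to the
tree tips, and scored with the multivariate K statistic (the
generalization of Blomberg's K to p traits):

    K = [tr(E'E) / tr(E' C⁻¹ E)] / [(tr C − N/(1'C⁻¹1)) / (N − 1)],

with C the shared-path-length (Brownian-motion) covariance of the tree,
a = (1'C⁻¹1)⁻¹ 1'C⁻¹X the phylogenetic mean and E = X − 1a. K is exactly
1 on a star phylogeny for any data (an algebraic identity, tested to
1e-8), ≈ 1 in expectation under Brownian motion (mean over 200
simulations on a 31-tip tree falls in [0.93, 1.07]), and < 1 when close
relatives are less similar than BM predicts. The univariate case was
cross-checked against an independent R implementation to 1e-8.
Significance, when wanted, comes from tip-label permutation with
p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1).

## Comparative statistics

- **Between-group PCA**: eigendecomposition of the covariance matrix of
  group means; individuals and reconstructed ancestors are projected onto
  the axes after centring on the grand mean of means. At most g − 1
  components are kept for g groups.
- **Pseudo-genetic distances**: per-gene dosage codes loss = 0,
  hetero = 0.5, normal = 1, gain = 2; distance from wild type is
  Σ|code − 1| over loci (the worked case — one null plus one heterozygous
  locus — gives 1.5). Pairwise strain distance is the L1 distance on
  codes, the natural matrix extension of "sum of individual mutations";
  genes absent from a strain's record are wild-type.
- **Mantel test**: Pearson r of upper off-diagonal triangles;
  significance by simultaneous row/column permutation of the second
  matrix. Distances on ≥3 strains are required (with two strains the
  off-diagonal is a single number); the workflow records NaN below that.
- **Disparity-from-WT correlation**: Pearson r (and R²) between each
  strain's dosage distance from WT and its Euclidean distance from WT in
  the morphospace (first 2 PCs by default). This is deliberately distinct
  from the Mantel correlation of the full matrices; both are exposed.
- **PGLS with a categorical predictor** (e.g. four diet classes):
  responses and dummy design are premultiplied by the inverse Cholesky
  factor of C (so the transformed errors are iid under BM), sums of
  squares are traces of transformed cross-products, and significance uses
  residual randomization under the reduced (intercept-only) model (RRPP,
  default 999 permutations). With C = I this reduces exactly to ordinary
  permutation MANOVA (tested to 1e-10); type-I error is calibrated at
  0.05 ± 0.02 under the null.
- **Ancestral states**: branch-length-weighted squared-change parsimony —
  minimize Σ_branches (Δx)²/t — solved as one sparse linear system; this
  coincides with the ML reconstruction of internal nodes under BM and is
  a weighted average, so reconstructed ancestors always lie inside the
  tips' per-axis range. Zero-length branches are rejected.
- **Hull coverage**: 2D convex hulls of two score sets in the first two
  PCs; each point of one set is classified against the other's hull via
  the hull's half-plane equations (tolerance 1e-9 × data span, so
  on-hull points count as inside).

## Synthetic data

The generator stands in for the unavailable micro-CT material and defines
the conditions under which the pipeline is tested. A crown is a height
field z = (1 − t⁶)(b(1 − t²) + Σ Gaussian cusps) over a superellipse
domain (semi-axes a, b, exponent n controlling elongation and
squareness), triangulated on a polar grid; the domain boundary is the
cervical outline (exactly z = 0) and the +x boundary point the buccal
anchor. Defaults — semi-axes 1.2 × 0.8, exponent 2.5, six cusps in two
longitudinal rows of three, base height 0.6, cusp height ≈ 1, ~6000
faces — caricature a generalist murine lower first molar. Strain
populations jitter cusp positions and heights with Gaussian noise
(σ = 0.02 in tests, a few percent of crown size, giving within-strain
variation clearly smaller than between-strain differences); BM trait
simulation uses the Cholesky factor of C. Everything is deterministic
per seed.

What this does *not* emulate: enamel wear, digitization noise on the
cervical line, overhanging crown walls (height fields cannot fold over —
the multi-component section logic is exercised by a separately
constructed mushroom-profile fixture), intra-observer annotation error,
and real murine shape statistics. Passing tests therefore demonstrate the
*correctness of the machinery* (identities, oracles, calibration) and its
behaviour under controlled signal/noise, not field performance on real
scans.

## Numerical choices and degenerate inputs

- Plane fit rejects collinear outlines at a relative singular-value
  threshold of 1e-10; flat crowns (height < 1e-9 × mesh extent) are
  rejected.
- Section chaining merges segment endpoints within 1e-8 × mesh extent;
  degenerate segments are dropped; a section that never reaches the basal
  plane raises an error naming the section index.
- Interpolated normals shorter than 1e-12 (degenerate triangles) raise.
- k_mult requires ≥3 tips and a positive-definite C (Cholesky); star
  trees are fine, zero-variance traits are not.
- bgPCA clips negative eigenvalues (numerical zeros) before computing
  variance fractions; identical group means are an error rather than a
  zero morphospace.
- CV folds are reduced to min(10, smallest class) with a warning; the
  recorded seed makes partitions reproducible bit-exactly.
- The acceptance script seeds every stochastic component from `--seed`;
  the single quantity it reports is deterministic.

## Known limitations

- Rotational alignment searches integer grid shifts only and is seeded by
  the first specimen; pathological samples (multi-modal orientation
  clusters) could settle in a local optimum. The anatomical
  pre-orientation makes this a refinement in practice.
- Map comparability assumes every section curve is sampled consistently;
  crowns whose z-axis falls outside the enclosed surface are rejected, not
  repaired.
- Curvature at the crop boundary relies on the pre-crop surface
  extending below z = 0; meshes already truncated exactly at the cervix
  get noisier boundary curvature.
- PGLS assumes the BM covariance; no Pagel's λ or OU transformation is
  implemented.
- The pseudo-genetic coding treats loci as additive and independent;
  epistasis is deliberately out of scope.
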