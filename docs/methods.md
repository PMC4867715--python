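# Methods

## Shape model and superimposition

A specimen is an ordered configuration of k = 15 landmarks in 2D, digitized
on the occlusal surface of a lower molar. Shape is the equivalence class of
a configuration under translation, rotation and scaling. Superimposition
follows the standard generalized Procrustes scheme:

- every configuration is centred and scaled to unit centroid size
  (CS = sqrt of summed squared landmark distances from the centroid);
- each is rotated onto the current consensus by the closed-form (SVD)
  orthogonal Procrustes solution, constrained to proper rotations
  (det = +1) because tooth side has already been standardized — allowing
  reflections here would silently absorb digitization-side errors;
- the consensus is re-estimated as the normalized mean and iteration
  continues until the consensus moves less than `tol = 1e-8` (root summed
  squared displacement) or 100 iterations. Both halves of the iteration
  minimize the same objective Σᵢ‖Xᵢ − C‖², so it is non-increasing; in
  practice convergence takes a handful of iterations. Configurations are
  *not* rescaled toward the consensus (partial Procrustes); a
  full-Procrustes variant (shrink by cos ρ) is available via
  `gpa(..., full_procrustes=True)`.

After convergence the consensus is rotated to its principal axes with a
deterministic sign rule (the largest-magnitude coordinate on each axis is
made positive), so axis orientation — and hence PC score signs downstream —
is reproducible across runs and input orderings.

Procrustes distance is the root of the minimized summed squared
coordinate differences between unit-size shapes (the partial Procrustes
metric). Missing or coincident landmarks are hard errors; the analysis
assumes complete configurations.

## Tangent projection and PCA

Unit-size aligned shapes lie on a sphere; tangent coordinates are obtained
by orthogonal projection of each flattened configuration onto the
hyperplane orthogonal to the (unit) consensus vector, x ↦ x − (x·ĉ)ĉ.
PCA eigendecomposes the covariance matrix of these 30-vectors with no
column scaling — coordinates share units, so correlation-matrix PCA would
distort the geometry. Superimposition removes 4 degrees of freedom, leaving
at most 2k − 4 = 26 non-null components; eigenvalues below 1e-10 of the
total are treated as null. Loadings carry the same largest-coordinate-
positive sign rule as the consensus. Out-of-sample (fossil) configurations
are superimposed on the fixed consensus, tangent-projected, and then
projected onto the extant axes; by default the PCA itself is fit on all
jointly aligned specimens (`pca_scope="all"`), with an extant-only fit
(`"extant_project_fossils"`) available, since a fossil sample this small
barely perturbs the axes either way.

Deformation grids use a thin-plate spline (kernel U(r) = r² log r with an
affine part, the classical bordered system) mapping the consensus onto the
consensus displaced along a PC; the spline is exact at the landmarks and
its bending energy wᵀKw is zero iff the displacement is affine. The spline
is implemented in-package because the bending-energy decomposition is
needed; the interpolant itself is cross-checked against
`scipy.interpolate.RBFInterpolator` in the tests. Requested scores are
limited to 1.5× the observed score range — extrapolating grids far beyond
the data is visually misleading. Scatterplots draw 95% *data* ellipses
(chi-square radius of the per-group 2D normal fit), not confidence ellipses
of the mean; this choice is deliberate and flagged here because published
figures of this kind are often ambiguous about it.

## Discriminant classification

The LDA solves S_b v = λ S_w v, where S_w is the pooled within-group
covariance of the retained PC scores and S_b the (size-weighted)
between-group covariance of group centroids; there are min(g − 1, p)
discriminant functions and each one's share of the eigenvalue sum is its
"percent of discriminant variance". Classification uses Mahalanobis
distance to group centroids under S_w with posteriors
π_g exp(−d_g²/2) (normalized), i.e. the equal-covariance Gaussian model
with linear boundaries. Defaults that matter:

- **PCs retained**: all 26 non-null PCs, automatically reduced until
  cond(S_w) < 1e8. A singular pooled covariance raises an error advising
  fewer PCs. The retained count is recorded in the run metadata because it
  materially affects pcc.
- **Priors**: equal across groups (configurable to proportional). The
  extant sample is strongly imbalanced (e.g. >100 *Alouatta* vs 4
  *Callimico*); equal priors prevent the majority group from dominating
  fossil posteriors.
- **Cross-validation**: genuine leave-one-out refitting — every fold
  re-estimates centroids, pooled covariance and its inverse from the n − 1
  remaining cases. No shortcut updates are used, and the test suite pins
  the routine against an explicit per-fold refit loop.
- **Ties** in the posterior arg-max are broken lexicographically, with a
  warning.

The `family` grouping level assigns Aotinae, Cebinae, Saimiriinae and
Callitrichinae to Cebidae, Callicebinae and Pitheciinae to Pitheciidae, and
Atelinae/Alouattinae to Atelidae; the two subfamily schemes (the
8-subfamily "Groves" arrangement and the 5-subfamily "Rosenberger"
arrangement, which merges *Aotus* + *Callicebus* into Homunculinae and
sinks Saimiriinae into Cebinae) are both carried per specimen so either can
serve as the discriminant factor.

## Error assessment

Repeatability of digitization is analysed from a panel of specimens each
digitized r times over several sessions:

- mean and SD of Procrustes distances over all unordered repetition pairs
  per specimen (unit-size shapes; distances on raw-size configurations are
  available through the full-Procrustes/GPA options);
- the Mantel correlation (Pearson r of strictly-lower-triangle entries,
  row/column joint permutations for p) between the specimen-by-specimen
  distance matrices of every unordered pair of repetitions, averaged;
- a permutational MANOVA on the jointly aligned tangent coordinates with
  repetition (or day) as grouping factor. The pseudo-F is computed from the
  pairwise Euclidean distance matrix via the Gower partition
  (SS_total = Σ_{i<j} d²ᵢⱼ / n, within-group terms analogously); for
  Euclidean distances this is algebraically identical to pooling classical
  one-way ANOVA sums of squares across coordinates, which the tests verify.

All permutation p-values use the (b + 1)/(m + 1) convention, counting the
observed statistic into the null set, which guarantees validity
(P(p ≤ α) ≤ α) at any permutation count. All permutation routines take an
explicit seed and are reproducible.

## Synthetic data generator

The generator emulates the study design so every stage is testable
end-to-end:

- **Taxonomy**: the published comparative sample, verbatim — 63 species
  rows (one a subspecies) in 18 genera, 8/5 subfamilies, 3 families, with
  the published per-species counts (sum n = 792).
- **Template**: a deterministic idealized right lower molar, ~5 mm
  mesiodistally, with the cusp tips inside a simple 8-point outline polygon
  and the three crest points near the midline; axes are lingual = +x,
  mesial = +y, which makes the mirror convention (reflect x → −x plus the
  landmark swap table) geometrically consistent.
- **Group structure**: each family, subfamily, genus and species receives a
  smooth mean-shape offset — random displacements at 5 random landmarks,
  thin-plate-spline interpolated to all 15 — with per-coordinate RMS
  magnitude δ·w, w = (1.0, 0.6, 0.35, 0.2) down the hierarchy. Specimens
  add isotropic N(0, σ²) landmark noise, a random rotation, translation,
  size jitter and image scale, and a random side (left specimens are
  emitted mirrored with remapped landmark order), so reading,
  standardization and GPA are exercised exactly as on real digitizations.
- **Defaults**: δ = 0.15 mm, σ = 0.10 mm. These were calibrated once so
  that the default dataset lands in the published performance regime —
  subfamily-level pcc of roughly 90–94% original and 88–92% cross-validated,
  PC1 around 30–45% of shape variance — and then frozen; they are a
  documented constant of the generator, not a fitted quantity.
  `digit_sigma` defaults to 0.02 mm for repetition studies.
- **Fossils**: generated as exact genus-centroid shapes (default), group
  interpolations, or centroid-plus-novel-offset shapes, each with a recipe
  recorded in `SynthTruth` so classifications can be scored exactly.

What the generator does **not** emulate: allometry (no size–shape
covariance), within-species group structure (sex, wear), landmark-specific
error anisotropy, integration/modularity among landmarks, and phylogenetic
correlation of group means (offsets are independent across groups at each
level). Tests passing on synthetic data therefore demonstrate correctness
of the machinery under the stated generative model, not biological claims
about real molars.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the full 792-specimen design
for the per-tooth analyses (seconds per tooth including leave-one-out
cross-validation), a reduced three-family design (3 × 20 specimens, 20
replicates) for the effect-vs-noise benchmark, n = 500 for consensus
recovery, and 200 replicates at 199 permutations for null-calibration
checks of the permutation tests. These sizes give stable Monte-Carlo
estimates while keeping a full run fast.

## Known limitations

- 2D occlusal projections only; no 3D landmarks or semilandmarks.
- No estimation of missing landmarks; incomplete configurations are
  rejected.
- The classifier is strictly linear (pooled covariance); groups with
  genuinely different covariances would call for QDA or regularized
  variants, which are out of scope.
- The published repeatability statistics of the original study cannot be
  recomputed because the raw repeated digitizations were never deposited;
  the error module is validated by the distributional properties above and
  by its behaviour on synthetic repetition studies instead.
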