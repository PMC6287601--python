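# Methods

## Object symmetry and the components of asymmetry

A configuration of k 2-D landmarks on a *Micrasterias* lateral lobe carries
an internal (object) symmetry axis between the lower and upper sublobes.
The symmetry is encoded by a `SymmetryMap`: p landmark pairs mirrored across
the axis and u unpaired landmarks on it (k = 2p + u; the bundled schemes are
7 landmarks = 3 pairs + 1 axis point and 15 landmarks = 7 pairs + 1 axis
point, with pairs (1,k), (2,k-1), … along the lobe margin).  The
*reflect-and-relabel* operation negates x (the axis is the line x = 0 by
convention) and swaps paired labels; it is an exact involution.

All originals and their reflected/relabelled copies are superimposed in one
generalized Procrustes analysis (GPA): configurations are centered, scaled
to unit centroid size, and rotated to the consensus, iterating until the
mean squared residual changes by < 1e-10 (max 200 iterations; reflections
are never allowed in the alignment, since mirrored copies enter as data).
After convergence the frame is rotated so the consensus is itself a fixed
point of reflect-and-relabel (the residual rotation ambiguity T·m = R(θ)·m
is removed by rotating the frame by θ/2), the consensus is explicitly
symmetrized, and all configurations get one final alignment pass.  In this
frame the decomposition

* symmetric component = (aligned original + aligned mirror) / 2
* asymmetric component = (aligned original − aligned mirror) / 2

is exact (the two parts reconstruct the aligned original to machine
precision), the symmetric part is invariant and the asymmetric part
anti-invariant under reflect-and-relabel.

## Procrustes ANOVA of a balanced n × r design

Sums of squares are computed over all 2·n·r aligned configurations
(originals plus mirrors) in the joint space, so the four effects add to the
total exactly:

| effect                | SS                                     | df              |
|-----------------------|----------------------------------------|-----------------|
| individuals           | 2r · Σᵢ ‖s̄ᵢ − s̄‖²                      | (n−1)·d         |
| positional asymmetry  | 2nr · ‖ā‖²                             | d               |
| fluctuating asymmetry | 2r · Σᵢ ‖āᵢ − ā‖²                      | (n−1)·d         |
| measurement error     | 2 · Σᵢⱼ (‖sᵢⱼ − s̄ᵢ‖² + ‖aᵢⱼ − āᵢ‖²)    | n(r−1)·2d       |

where sᵢⱼ/aᵢⱼ are the symmetric/asymmetric components of specimen i,
replicate j, bars denote means, and d = 2p + u − 2 is the common dimension
of the symmetric and asymmetric shape subspaces in 2-D object symmetry
(they sum to the full shape dimension 2k − 4).  MS = SS/df, R² = SS/SS_total.

F ratios test positional asymmetry and individuals against the FA mean
square (a pooled FA+error denominator is available via
`denominator="pooled"`; the choice cannot be discriminated from published
p-values, and with MS_FA ≫ MS_error both give the same verdicts) and FA
against measurement error.  p-values come from permutations of the
exchangeable units of each effect:

* positional asymmetry — specimen-wise sign flips of the asymmetric
  component, i.e. permuting the arbitrary original/mirror side labels;
  exact under the null ā = 0;
* individuals — shuffling symmetric-component rows across specimens;
* FA — shuffling asymmetric-component rows across specimens and retesting
  against the recomputed error MS.

Always p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), so p is never 0 and the
smallest attainable value at 999 permutations is 0.001.  With r = 1 the
error row is omitted and FA is untestable (flagged).  The seed is recorded
in every table.

## Morphospaces

`mirrored_pca` superimposes the species means together with their mirrors
(2S configurations) and decomposes the aligned coordinates by PCA.  Because
the sample is closed under reflect-and-relabel, each eigenvector with a
distinct eigenvalue is invariant or anti-invariant under it; PCs are
classified from the original/mirror score pattern (equal → symmetric,
opposite → asymmetric, otherwise mixed; tolerance 1e-6 of the score scale,
configurable — sampling ties between eigenvalues can in principle mix the
classes).  The ideally symmetric consensus projects to the center of the
ordination, and the total variance splits additively into a symmetric and
an asymmetric part.  `asymmetric_pca` decomposes the species asymmetric
components alone, centered on the grand-mean asymmetric configuration; its
full score space preserves pairwise distances between species asymmetry
vectors, so phylogenetic statistics computed on all scores equal those on
the raw vectors.  Eigenvectors are oriented so their largest-magnitude
loading is positive, making score plots reproducible up to that convention.

## Phylogenetic comparative methods

Under Brownian motion the phylogenetic covariance C has C[i,j] = depth of
the most recent common ancestor of tips i, j.  Squared-change parsimony
minimizes Q = Σ_branches ‖Δstate‖²/length over ancestral states (length 1
per branch when `weighted=False`); the minimizer solves a sparse tree
Laplacian system, and Q reduces to a quadratic form in the tip data via the
Schur complement of the internal block — which is what makes the 9,999-
permutation signal test cheap.  The signal test permutes tip rows and takes
the left tail of Q (small observed Q = more signal than random), counting
ties as ≤.  Branch-length weighting with the input tree's lengths is the
default; zero-length branches are floored at 1e-8 with a warning.

Phylogenetic two-block PLS transforms both blocks by subtracting the GLS
mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and premultiplying by C^(−1/2) (symmetric inverse
square root by eigendecomposition, eigenvalue floor 1e-12), then takes the
SVD of the cross-block covariance of the transformed data.  r_PLS is the
absolute correlation of the first-axis scores.  The permutation test
shuffles the tip assignment of one block *in the transformed space*, whose
rows are exchangeable under the Brownian null; permuting raw tip rows and
re-transforming each replicate was evaluated and rejected because it is
strongly anticonservative under an independent-Brownian null (about half of
null p-values below 0.1), while the transformed-space permutation gives
uniform null p-values — this matches the behaviour of the established
implementations of evolutionary PLS.  On a star tree with equal branch
lengths C = I and the method reduces exactly to ordinary two-block PLS.

## The synthetic-data generator

The generator emulates the design of the emulated survey: by default 19
species on a pure-birth tree (depth scaled to 1), 75 specimens per species,
2 digitization replicates, 15 landmarks.  Species symmetric means and
asymmetry vectors δ_s evolve as independent-coordinate Brownian motion
along the branches; specimens add a symmetric individual deviation and an
asymmetric FA deviation; replicates add unprojected iid landmark noise
(digitization error hits every coordinate).  All structured perturbations
are orthogonally projected onto the symmetric or asymmetric shape subspace
at the base shape *with the similarity directions (translation, rotation,
scale) removed*, so the ANOVA's partition assumptions hold exactly by
construction and the true δ_s is directly comparable with the recovered
asymmetric components.

Default scales (units of Procrustes distance around a unit-centroid-size
base shape, chosen once as what a morphometric survey of this kind looks
like):

| parameter    | default | meaning                                             |
|--------------|---------|-----------------------------------------------------|
| `sigma2_sym` | 4e-4    | BM rate of the symmetric mean, per coordinate/unit branch |
| `sigma2_asym`| 4e-4    | BM rate of the asymmetry vector (typical ‖δ‖ ≈ 0.07 at depth 1) |
| `sigma_ind`  | 0.02    | sd of the individual symmetric deviation, per coordinate |
| `sigma_fa`   | 0.01    | sd of the individual FA deviation, per coordinate    |
| `sigma_me`   | 0.005   | sd of per-replicate digitization noise, per coordinate |

These put the positional-asymmetry R² of a typical species in the 0.2–0.6
range with MS ratios (positional ≫ FA ≫ error) like those a real survey
reports, while leaving the weakest species near the symmetric midpoint.
The base shape is an idealized lobe outline (k landmarks equally spaced on
a semicircle, exactly symmetric under the standard map); any symmetric base
can be supplied.  The digitization protocol's clockwise/counterclockwise
capture-then-relabel step is modelled simply as independent replicate
noise; the relabeling operation itself is exercised by dedicated unit
tests.  The generator does not emulate allometry, semilandmark sliding,
image-level artefacts, or non-Brownian evolution (OU/EB) — so passing
recovery tests show the estimators are consistent under the model the
analysis assumes, not that real data meet those assumptions.

A four-analysis plan is carved from the 15-landmark configurations: the
7-landmark sublobe scheme uses every other landmark (1,3,5,8,11,13,15 →
relabelled 1–7) for all species; the 15-landmark scheme and the two
terminal-lobule blocks (landmarks 1–7 and 9–15 with their own internal
symmetry) apply only to species annotated as possessing 3rd-order lobules
(a dataset annotation, 14 of 19 by default, never inferred from shapes).

## Numerical conventions and verification

* GPA: convergence on the change in mean squared residual, tol 1e-10, max
  200 iterations (non-convergence sets a flag rather than raising); the
  stored consensus is the arithmetic mean of the aligned configurations;
  plain GPA aligns the consensus to its principal axes for reproducible
  orientation.
* Degenerate inputs: coincident landmarks raise a degeneracy error;
  unbalanced replicate designs are rejected with per-specimen counts.
* Tangent projection is orthogonal at the normalized consensus; for the
  variance levels simulated here tangent distances match Procrustes
  distances to < 1e-3 relative.
* TPS coordinates are stored at full float precision and written with 6
  decimals; specimen metadata use the `<species>_<specimen>_r<replicate>`
  ID convention (overridable by a manifest).  Alignment variable-site
  counts treat gaps as missing (not a state) and collapse IUPAC ambiguity
  codes by default; both behaviours are flags, since published counts
  rarely state their convention.
* Every stochastic routine takes a seed and records it in its result; the
  pipeline derives per-stage seeds from one root seed, so a rerun
  reproduces the report byte for byte.

`scripts/acceptance.py` re-measures the verification quantities end to
end — oracle equivalence of the Procrustes distance (brute-force rotation
grid) and of squared-change parsimony (generic numerical optimizer),
decomposition exactness, the noise-free ANOVA partition, type-I error and
KS uniformity of the three permutation tests under their nulls (200
simulations each; the ANOVA null at n = 20, r = 2 with 199 permutations),
asymmetry recovery at the full 19 × 75 × 2 design, and the star-tree
reductions.  Problem sizes were chosen to make each check decisive while
keeping the whole script around half a minute on one CPU.

## Limitations

* 2-D configurations only; no sliding semilandmarks; no size-shape
  allometry.
* The ANOVA requires a balanced design (the emulated survey's protocol);
  missing replicates must be handled upstream.
* Squared-change parsimony gives point reconstructions, not confidence
  regions; tree inference itself is out of scope (trees are inputs).
* The mixed PC class exists because sampling noise or eigenvalue ties can
  break exact ±invariance in the mirrored PCA.
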