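# Methods

## Scope and model

`mwiseg` treats a reconstructed microwave breast image as a 2D grid of
complex permittivity values ϵ = ϵ' − jϵ'' with a known pixel spacing in
mm. Three scalar component images are analyzed independently: the real
part, the loss magnitude |Im{ϵ}| (used instead of the signed imaginary
part so that lossier — malignant — tissue is highest-valued under either
e^{jωt} or e^{−jωt} time convention), and the magnitude
√(Re² + Im²). When the input is a contrast profile χ relative to a
background ϵ_b over an imaging domain 𝒟, the permittivity is recovered
elementwise as ϵ = ϵ_b·(χ + 1); the conversion is algebraically exact
and invertible inside 𝒟.

The segmentation assumes only that tissue types are *ordered* in
dielectric value — immersion/skin background (excluded), then fat,
transition tissue, fibroglandular tissue, malignant tissue — not that
their ranges are known. It makes no assumption about the number of
value sub-populations per tissue; the cluster count is chosen by the
statistical termination rule below.

## Segmentation procedure

1. **ROI.** The imaging-domain mask is eroded by a discrete disk of
   radius round(d/spacing) pixels, default d = 3.5 mm. Erosion by a
   disk is used as the uniform inward contraction; it is anti-extensive
   and monotone in d, and it exists to exclude bright reconstruction
   artefacts that concentrate near the skin. Values outside the ROI are
   replaced by a sentinel (default −100) that is validated to lie
   strictly below the ROI minimum, so the background is guaranteed to
   form the lowest cluster rather than silently mixing with tissue.
2. **Clustering.** Scalar k-means over all grid values (sentinel
   included). Each k runs Lloyd's algorithm from k-means++ starts
   d = 10 times (`sklearn.cluster.KMeans`, one initialization per
   restart, sub-seeds spawned deterministically from the master seed);
   the restart with the lowest within-cluster sum of squares is kept.
   d = 10 is a compromise between the local-minimum risk of Lloyd's
   heuristic and runtime; on 1-D data with clear structure the global
   optimum is recovered essentially always (the small-instance oracle
   test measures ≥ 95 % exact agreement with exhaustive search at
   d = 20). Labels are renumbered so centroids ascend, with a stable
   sort breaking exact centroid ties by original cluster index.
3. **Termination.** With T̂ the top cluster and T̂ᶜ the union of the
   intermediate clusters, the two-sample KS statistic
   sup_x |E₁(x) − E₂(x)| is computed between the current and previous
   value samples under each mask, with the asymptotic p-value
   (Kolmogorov distribution at √(n₁n₂/(n₁+n₂))·D). The samples here
   are thousands of pixels, where the asymptotic approximation is
   standard; α = 0.01 for both tests. Iteration stops when neither test
   rejects, and a configurable cap k_max = 20 turns pathological
   non-convergence into a diagnosable error that carries the full
   iteration history.

   A structural consequence worth stating: T̂ᶜ is the ROI minus T̂, so
   both KS samples change between consecutive k exactly when the top
   cluster changes. The loop therefore runs until the top cluster
   stabilizes and then performs one confirming iteration. On images
   with a clean value gap below the tumor this yields small final k; on
   heterogeneous images the top boundary keeps shifting and k grows
   correspondingly.
4. **Mapping.** c₁ → background, c₂ → fatty, c₃–c₄ → transition,
   c₅…c_max−1 → fibroglandular, c_max → malignant; if the loop stopped
   after one refinement (max(k) = 4), the three interior clusters map to
   fatty/fibroglandular/malignant. The mapping is implemented
   literally; max(k) = 5 leaves the fibroglandular set empty and is
   surfaced as a warning rather than silently reassigned.

## Metrics

Fidelity = refmaskᵀrecmask/(‖refmask‖‖recmask‖) on vectorized binary
masks; xcorrDiel is the same expression on masked property values (and
is therefore invariant to positive rescaling of either image); Dice,
RD = |ref∩rec|/|ref| and AR = 1 − (|rec|−|ref∩rec|)/|ref| count nonzero
elements. AR is deliberately allowed to go negative (false-positive
area exceeding the reference tumor area). The average Hausdorff
distance takes boundary points from the pixel-corner ("crack") contour
of each mask — a one-pixel region contributes its four corners, keeping
degenerate masks well defined — translates each point set so the
centroid of its enclosed region sits at the origin, and returns
max{h(rec→ref), h(ref→rec)} with h the mean nearest-neighbour distance.
Centroid alignment makes H_A exactly invariant to integer-pixel
translations; H_A is reported in mm. For mask-level comparisons the
pixel centroid of the mask is used as the alignment center, which stays
well defined for multi-component masks.

Per-tumor reporting splits the reference malignant mask into
8-connected components; each reconstructed malignant component is
assigned to the reference tumor with the nearest centroid, so stray
malignant blobs penalize the AR of the closest tumor. The glandular
region is the fibroglandular mask Ĝ only (transition tissue excluded);
an empty reconstructed region yields RD = 0, AR = 1, Dice = 0 and an
undefined (reported as missing) H_A, and a region absent from the
reference is reported absent rather than raising.

## Synthetic phantoms

The generator replaces MRI-derived forward models for testing. Geometry:
a circular breast (default radius 50 mm, 120×120 grid at 1 mm spacing)
with a 2 mm skin ring; a fibroglandular region built as the union of
random Gaussian bumps thresholded so the gland occupies a set fraction
of the interior (default 0.28), wrapped in a 3 mm morphological
transition shell; circular tumors (default one of radius 6 mm) whose
centers must lie in the gland. The first gland bump is anchored at the
first tumor center so the containment invariant is satisfiable by
construction.

Tissue values are drawn per element from ordered, partially overlapping
ranges (real part: fat 4–12, transition 12–25, fibroglandular 25–45,
malignant 50–60, skin 30–40; loss component at one quarter scale, drawn
from the same relative position so the two components share one cluster
structure). Within each range, values come from a mode mixture rather
than a flat band: fat and tumor are unimodal, transition and
fibroglandular tissue are bimodal. This emulates the within-type
heterogeneity of reconstructed tissue properties that real microwave
images show, and it is what gives the ascending-cluster tissue map
something to resolve: a perfectly homogeneous tissue would never
warrant more than one cluster, whereas the mapping assigns two clusters
to transition tissue and a range of clusters to gland. The default mode
positions were chosen, jointly with the region masses, so that the
optimal 1-D clustering peels the high-value structure one cluster per
iteration until the tumor is isolated — the qualitative behavior
reported for real reconstructions — rather than stalling early; they
are simulation defaults, not claims about tissue physics.

Degradation applies, in order: Gaussian blur restricted to the breast
support (normalized masked convolution, so background values never
bleed inward and the immersion region is untouched); a smooth
multiplicative bias field (unit mean, amplitude-scaled); additive
white Gaussian noise per component; and bright Gaussian artefacts
(amplitude at the malignant range midpoint) centered within 5 mm of the
skin — the nuisance the ROI contraction exists to remove. All-zero
parameters give an exact identity, and degradation never touches the
ground-truth tissue map. What the phantoms do *not* model: the
spatially correlated, structured error of an actual inverse solver,
inhomogeneous backgrounds, anatomically realistic gland shapes, or 3D
effects — so passing recovery tests demonstrates the pipeline's
correctness and its qualitative degradation behavior, not clinical
performance.

## Numerical choices and problem sizes

The threshold baseline uses ≥ at the cut value so the 100 % threshold
keeps the argmax elements; thresholded masks are nested in the
percentage, which makes the RD-nondecreasing / AR-nonincreasing
trade-off exact rather than statistical. Matrix files are full-precision
CSV so write→read roundtrips are bit-exact; masks are strictly binary
PNGs. Empty clusters cannot occur in the final labelings
(`KMeans` relocates empty clusters to distant points, keeping every
label occupied as the mapping requires). Test and acceptance runs use
the default 120×120 phantom; the degradation-trend study averages over
20 seeds per blur level (12 in the acceptance script), sizes chosen to
keep the full suite in the tens of seconds while leaving the Monte
Carlo error of the trend means far below the effect size.

## Known limitations

* The contraction of the domain boundary is implemented as disk
  erosion; contour-based contraction methods could differ by up to a
  pixel near high-curvature boundaries.
* The KS termination compares samples whose sizes differ across
  iterations; the two-sample test handles unequal sizes, but very small
  tumor regions (tens of pixels) reduce its power and can stop the
  refinement one iteration early.
* With max(k) = 5 the tissue map has no fibroglandular slot; the
  package warns and reports the mapping as defined rather than
  reallocating clusters.
* Metrics operate on single 2D slices; no volumetric aggregation is
  provided.
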