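# Methods

`dropsig` quantifies the deposition patterns of dried blood droplets and
discriminates the physiological state of the blood that produced them.
This note records the models, parameter choices and numerical conventions
the package commits to, and what its synthetic benchmark does and does not
demonstrate.

## Feature model: rotation-invariant angular log power spectrum

A dried blood droplet leaves a circular deposit with a darker peripheral
rim (the coffee-ring), radial cracks in the corona and disordered short
cracks near the centre.  The orientation of a droplet on the slide is
arbitrary, so useful texture descriptors must not depend on it.  The
feature chain is:

1. **Red channel.** Haemoglobin dominates the image; the texture contrast
   lives almost entirely in the red channel, which is extracted and kept in
   floating point throughout (no re-quantisation between stages).
2. **Crack detection and filling.**  Cracks dry to near-white, so a pixel
   is flagged as crack when *both* its blue and green values exceed a
   threshold α (default 200 of 255; the red deposit has low blue/green and
   is never flagged).  Flagged pixels are replaced by piecewise-linear
   interpolation over a Delaunay triangulation of intact pixel positions;
   pixels outside the convex hull of the support (cracks touching the
   border) are filled nearest-neighbour.  By default the triangulation uses
   only intact pixels within 4 px of the mask (`context_px=4`): cracks are
   1–2 px wide, so the interpolant is determined by its local
   neighbourhood, and restricting the support cuts the per-image cost by an
   order of magnitude.  `context_px=None` restores the global
   triangulation; the two agree to rounding for sparse crack masks, and
   both reproduce any affine intensity field exactly.
3. **Gaussian low-pass.**  The 2-D FFT of the image is multiplied by
   `exp(-(u²+v²)/σ²)` with (u, v) in cycles/pixel, then inverted.  Note the
   deliberately non-standard denominator (no factor 2): σ is the e-folding
   half-width of the transfer function.  The DC weight is exactly 1, so the
   image mean is preserved; the filter is linear, and two passes equal one
   pass at σ/√2.  The default σ = 0.01 cycles/pixel is calibrated for
   full-scale imagery (150 px/mm; droplet radius ≈ 300 px).  Because a
   spatial-frequency cutoff must scale inversely with the imaged size, the
   synthetic pipeline uses the resolution-matched value
   σ = 0.01 × (300 / R) for renders with droplet radius R px (≈ 0.047 at
   the default R = 64).
4. **Laplacian magnitude.**  Edges are exposed as
   `sqrt(f_xx² + f_yy²)` with central second differences on a
   replicate-padded raster (shape-preserving, non-negative).  The
   discretisation is fixed so results are bit-reproducible.
5. **Polar resampling.**  The edge image is bilinearly sampled on a grid of
   48 radii × 103 angles about the droplet centre (radii
   `(i+1)·R/48`, angles `2πj/103`).  The centre and radius come from
   Otsu-thresholding the smoothed red channel, filling holes (bright
   cracks punch holes in the deposit component), taking the largest
   connected component's centroid and equivalent radius √(area/π).
6. **Angular spectrum.**  Per radial ring: `log(value + ε)`, DFT along the
   angle, magnitude, `log(magnitude + ε)`, with ε = 1e-6 flooring both
   logarithms (both quantities can reach zero).  Frequencies are in cycles
   per revolution.  The natural logarithm is used; switching the base only
   rescales the features monotonically.
7. **Truncation.**  The innermost ring carries no usable radial information
   and the upper half of the 103-point spectrum mirrors the lower, so the
   48×103 matrix is cut to 47 rows × 52 columns and flattened row-major
   into a 2444-vector.
8. **Averaging and normalisation.**  The first k replicate vectors of a
   participant/condition cell are averaged in acquisition order
   (default: all), then min-max rescaled to [0, 1].

Because the DFT magnitude is invariant to circular shifts, rotating a
droplet by a multiple of the angular step 2π/103 permutes the polar
columns and leaves the feature vector unchanged to machine precision
(~1e-13 measured).

### How rotation-invariant the features really are

For arbitrary angles the invariance is approximate, and the package's own
measurements are worth stating precisely.  The angular *power spectrum*
of a band-limited (crack-free) droplet moves by ≈ 0.4 % (L2, relative)
under a 15–40° rotation — pure bilinear-interpolation error.  Two effects
degrade this for the final feature vector:

* **Angular aliasing.**  Crack edges put angular harmonics beyond the
  103-sample Nyquist limit (51.5 cycles/revolution); aliased components
  re-phase under rotation, moving the crack-bearing power spectrum by
  ≈ 10 %.
* **Log-floor flicker.**  After low-pass filtering, roughly half of the
  (ring, frequency) cells lie beyond the pass-band and hold small,
  numerically unstable magnitudes far above ε.  The outer logarithm
  weights these junk cells equally with signal cells, so the final
  log-spectrum vector moves by ≈ 6–15 % under arbitrary rotation
  regardless of render precision, interpolation order or ε in
  1e-6…1e-1.  This is intrinsic to log-compressing near-zero magnitudes
  and is scale-invariant (the pass-band in cycles/revolution is fixed
  once σ is resolution-matched).

In practice this flicker behaves as i.i.d. feature noise: replicate
averaging shrinks it by √k and PCA concentrates on the stable,
high-variance signal cells, so classification is unaffected (the
synthetic benchmark reaches 0 % error).  But claims that the *final*
feature vector is quantitatively rotation-invariant at the percent level
hold only in the power-spectrum domain, not after the final logarithm.

## Discriminator: PCA → two-axis LDA → centroid distance ratio

Feature matrices hold one averaged, normalised 2444-vector per participant
per condition.  For a condition pair (A, B):

* **PCA** centres the pooled training vectors and takes the SVD; at most
  n−1 components exist for n training samples, and half of them,
  `n_keep = max(2, ⌊(n−1)/2⌋)`, are retained (the floor of 2 keeps the
  two-axis discriminant defined for the 4-sample training sets that occur
  during subset search).
* **LDA** solves the generalised eigenproblem `S_b v = λ (S_w + γI) v` in
  score space, with ridge `γ = 1e-6 · trace(S_w)/d` since `S_w` can be
  near-singular when `n_keep` approaches the sample count.  For two
  classes `S_b` has rank one, so only one canonical discriminant exists;
  the second axis is taken as the eigenvector with the second-largest
  eigenvalue of the same pencil (the leading residual within-class
  direction, orthogonal to LD1 in the S_w metric).  Directions are
  unit-normalised with a deterministic sign (largest-magnitude coordinate
  positive).
* **Classification.**  Samples are projected onto (LD1, LD2); with d_A and
  d_B the Euclidean distances to the two training centroids, a sample is
  assigned to A iff d_A/d_B < 1; an exact tie goes to A by convention and
  is flagged.  The error rate is the percentage misclassified.
* **LD function maps.**  Each discriminant direction is back-projected
  through the retained PCA loadings and reshaped to 47 × 52
  (radius × cycles/revolution), showing where in the droplet the
  discriminating texture lives.

## Training-subset optimisation

Instead of enumerating all C(30, 20) = 30,045,015 possible 20-of-30
training subsets, a two-stage greedy search is used.  Stage A trains on
{anchor, i} ∪ all-of-B for anchors {participant 0, participant 1} and all
i, keeps the best pair, then repeatedly adds the single participant whose
inclusion lowers the all-sample error, stopping when no addition strictly
improves (ties break to the smaller subset, then lexicographically, so
runs are deterministic).  Stage B repeats the scan over B with A's winner
fixed; the stage-A incumbent (winner + full B) remains a candidate, so
stage B never returns a worse configuration.  The cost is O(n²)
discriminator fits per anchor.  An exhaustive oracle
(`exhaustive_oracle`) exists for small cohorts and is used in the tests to
confirm the greedy attains the global optimum there.

**Validation caveat (important).**  Candidates are scored on *all*
participants of both conditions, including the training subset — the
protocol reproduced here deliberately keeps that property.  Two biases
follow, both quantified by the test suite: the reported error is
optimistic (training samples are nearly always correct, and the greedy
minimises over hundreds of correlated candidates), and under a *null*
study with no class signal the optimised all-sample error settles around
20–37 %, not 50 %.  A fresh cohort never seen by the optimiser is
classified at chance (measured 51.7 % at n = 60), which is the correct
null reference.  Users comparing conditions should treat the optimised
all-sample error as a descriptive training statistic, not a
generalisation estimate.

## Synthetic study generator

The generator stands in for the study photographs: 30 participants ×
conditions × 10–12 images per cell, rendered at desk scale
(144 px images, droplet radius 64 px) so the full benchmark runs in
minutes on one CPU.  A render consists of a pale warm-grey background
(208, 196, 188), a red deposit body (165, 60, 50) with soft (≈1.5 px)
edges, a darker rim annulus (default width 0.16 R, darkening factor
0.62) whose darkening is modulated sinusoidally along the angle,
`n_radial_cracks` near-white (250, 250, 250) radial polylines in the
corona with per-crack angular jitter, Poisson-placed short white central
cracks, and additive Gaussian pixel noise (sd 3 of 255).  Crack cores
(blend fraction > 0.8) are returned as a ground-truth mask for testing
the α-criterion.

The condition signal is carried by the angular structure: the dominant
rim-modulation frequency `angular_mode` (cycles/revolution) and the
radial crack count.  The default two-condition effect separates the
classes by 4 cycles/revolution (8 vs 12) and 4 cracks.  Nuisance
variation mimics real acquisition: per-participant offsets on rim
darkening and modulation depth (sd 0.02), per-image uniform random
rotation, per-image modulation-depth jitter (sd 0.04), per-image crack
count jitter (sd 1 — each replicate is a distinct physical droplet), and
fresh pixel noise per image.  All randomness derives from a master seed
through per-cell seed sequences (participant, condition, replicate), so
studies regenerate byte-identically.

What the generator does *not* emulate: evaporation physics and capillary
flow, realistic broadband granular texture, illumination gradients,
neighbouring droplets, or any claim about which image features real blood
conditions actually change.  Passing the benchmark therefore shows that
the pipeline recovers a known angular-texture signal against realistic
nuisance variation — not that real blood conditions are discriminable at
any particular accuracy.

The chemistry generator draws each analyte per condition from published
per-condition means ± SDs (lactate, Na⁺, K⁺, Ca²⁺, Cl⁻, PCO₂, H⁺, HCO₃⁻,
Hb; glucose and PO₂ use invented but physiologically plausible defaults,
marked as such in the source).  [H⁺] is drawn jointly with PCO₂ at a
per-condition correlation (0.8 at rest decaying to 0.25 by 6-min
recovery) so the resting pH–PCO₂ coupling and its decay through exercise
are reproduced; pH is derived as 9 − log₁₀[H⁺].  Derived quantities:
SID = (Na⁺+K⁺+Ca²⁺) − (Cl⁻+La⁻) mmol/L; [H⁺] = 10^(9−pH) nmol/L;
ΔBV = 100·(Hb_rest/Hb_t − 1) % (the haemoglobin-ratio form; the variant
additionally using haematocrit is not implemented).  ΔBV is identically 0
at rest, so its rest-column correlations are undefined and reported as
missing.  Chemistry PCA standardises the 12 retained variables (pH and
SID are dropped as deterministic functions of the others) before the
decomposition, since the units are incommensurate.

## Problem sizes used by the benchmark

The shipped acceptance run uses three strong-effect studies of
30 participants × 2 conditions × 10 replicates (1800 images total), one
null study of the same shape plus an independent fresh null cohort, ten
random 3–4-participant-per-class cohorts for the greedy-vs-exhaustive
comparison, ten ≤ 8-sample instances for the LDA eigensolver
cross-check, and 10,000-row chemistry panels for the moment checks.

## Known limitations

* The two-axis LDA's second direction is a design choice; any
  reported LD2 structure should be read as residual within-class
  variance, not a second canonical discriminant.
* The optimised error rate is a training-inclusive statistic (see the
  validation caveat above).
* Arbitrary-angle rotation invariance of the final log-spectrum vector is
  approximate (≈10 %); exact invariance holds for grid-step rotations and
  near-exact (≈0.4 %) invariance for the pre-log power spectrum.
* `find_centre` assumes one deposit darker than its background in the red
  channel; multi-droplet frames must be cropped first.
* The linear (non-log) power-spectrum variant is exposed only as
  `log_power_spectrum(..., outer_log=False)` and has not been validated.
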