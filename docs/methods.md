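# Methods

This note documents the models, numerical choices and limitations behind
`linetarget`. It describes what the code computes; every empirical number
quoted elsewhere is produced by the test suite or `scripts/acceptance.py`
at run time.

## Coordinate frames and transforms

All world coordinates are millimetres. The internal world frame is
scanner RAS. Surface vertices live in the surface-RAS ("tkr") frame until
explicitly mapped to the scanner via the volume's two voxel-to-world
matrices (`scanner = vox2ras · inv(vox2ras_tkr)`). Every
`AffineTransform` carries source and destination frame tags, and
composing or applying transforms with mismatched tags raises — silent
frame mix-ups are the classic failure mode when FreeSurfer-style (RAS)
and ITK/ANTs-style (LPS) tooling meet. ITK/ANTs files are declared LPS by
the caller and converted on read by conjugation with diag(−1, −1, 1, 1).
The forward-vs-inverse direction of a registration file is likewise
declared by the caller, never guessed. NIfTI reading honours the sform
over the qform when both are set.

## Surface geometry

Vertex normals are angle-weighted averages of incident face normals,
oriented by face winding. Mean curvature H (1/mm) uses the cotangent
Laplace–Beltrami operator with Meyer-style mixed Voronoi areas; the
magnitude comes from the mean-curvature normal and the sign from its
projection on the vertex normal (a sphere with outward normals has
H = +1/r). Boundary vertices get NaN: their one-ring is open and the
operator is undefined there. On the analytic test surfaces (sphere
r = 20 mm, cylinder r = 10 mm, sinusoidal sheet) the discrete operator is
within 5% of the closed forms at the refinements the tests use.

Curvature drives target selection as minimal |H| — flattest cortex — not
the signed minimum, which would prefer the depths of sulci. A smoothing
knob is deliberately absent (smoothing iterations default to none);
selection on raw curvature is the conservative choice and is configurable
upstream by pre-filtering the overlay.

Geodesics are graph shortest paths (Dijkstra) over mesh edges with
Euclidean weights, not exact polyhedral geodesics. The overestimate is
bounded by mesh anisotropy and is immaterial at the millimetre scales of
line validation.

## Gaussian pRF model

The pRF is an isotropic 2-D Gaussian (x₀, y₀, σ) in visual degrees. The
predicted response is the frame-wise dot product between the Gaussian and
the binary stimulus aperture, convolved causally (zero-padded, truncated
at series end) with the HRF, then scaled (β) and offset (baseline).

* **HRF**: canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6),
  sampled at the design TR and normalised to unit peak so β is in %BOLD.
  It is pluggable because the line TR (0.105 s) versus whole-brain TR
  (1.5 s) changes the sampling density substantially.
* **Fitting**: stage 1 is an exhaustive grid (default 21 positions per
  axis over the stimulated extent, 12 log-spaced σ between 0.1° and half
  the extent) with closed-form (β, baseline) least squares per candidate;
  stage 2 refines (x₀, y₀, σ) with bounded trust-region minimisation of
  the residual sum of squares (xtol/gtol 1e−6, far finer than any
  tolerance used downstream). Grid ties break to lowest residual, then
  smallest σ, then lexicographic (x₀, y₀). The heavy per-candidate
  prediction matrix is precomputable (`CandidateGrid`) and reused across
  fits of the same design.
* **cvR²**: a fixed-shape prediction is refit to held-out data by OLS
  with free amplitude and intercept, so cvR² equals the squared Pearson
  correlation and is non-negative. The free sign avoids penalising
  negative-amplitude refits asymmetrically when comparing models.
* **Percent-signal-change baseline**: the empty-screen (blank) frames
  when a design is available, otherwise the full-series mean.
* Degenerate input (constant series) yields r² = 0 with spatial
  parameters flagged unreliable rather than an arbitrary optimum.

The bar-design generator builds one traversal per
orientation × direction × width combination, inserts mean-luminance
blanks after every two passes, and clips frames to a circular aperture.
Both canonical sessions therefore count 8 configurations (4 × 2 × 1 and
2 × 2 × 2).

## Line planning

The line is centred on the target coordinate and directed along the
surface normal. Cardinal-axis angles use the rule of cosines,
θᵢ = arccos(|n·eᵢ|), folded to [0°, 90°] because a physical line has no
polarity. The base slice is coronal unless the angle to the left–right
axis exceeds 45° (exactly 45° stays coronal), in which case sagittal;
this keeps the line within 45° of the base slice plane for every
direction. The console-facing angulation is the decomposition
a = arccos(d·f), b = atan2(d·p, d·s) in the base triad (frequency f,
phase p, slice-normal s): rotate about the in-plane phase axis by a, then
about the frequency axis by b. Any consistent parameterization would
satisfy the placement; this one is validated purely by the direction
round trip (max error < 1e−6 rad over 500 random normals).

The nominal line mask keeps the central `round(gap/phase_res)` voxels
along the phase axis — 16 for the 4 mm gap at 0.25 mm — with the extra
voxel on the lower-index side when the leftover is odd (an arbitrary but
fixed and tested convention). When white and pial surfaces are both
available the target should sit at mid-thickness; the synthetic sheet has
a single surface, so its vertex is used directly.

## The signal chain

Order is fixed and enforced by `PreprocChain`: SVD denoise → coil combine
→ echo combine → DCT high-pass → aCompCor → %change → Savitzky–Golay →
iteration averaging.

* **SVD denoising** operates on the position × time (Casorati) matrix of
  each coil and echo separately, complex or magnitude. Singular values at
  and past the scree elbow are zeroed; the elbow is the point of maximal
  perpendicular distance to the chord joining the first and last scree
  points, with ties broken toward retaining more components and a
  constant spectrum retaining everything.
* **Coil combination** weights are w_c = (tSNR_c·|s_c|)², normalised to
  sum to one per position so the uniform case reduces to the root mean
  square; all-zero weights fall back to unweighted root-sum-of-squares
  with a warning. tSNR is computed from the denoised data (computing it
  before denoising would mix the quantity being suppressed into the
  weights). Echo combination is a plain sum of squares.
* **Drift removal** regresses out zero-mean DCT-II basis functions below
  0.01 Hz; the constant is excluded so each position keeps its temporal
  mean. Note the quality of ramp removal scales with the number of
  available basis functions, i.e. with run duration.
* **aCompCor** pools WM and CSF positions inside the nominal line mask,
  standardizes them, takes the first 5 principal-component scores
  (count configurable; unspecified by convention, 5 is the common
  default), high-passes each score above 0.18 Hz — slightly below the
  respiratory band, so slow task-band content is never regressed out —
  and removes the filtered scores from every position. The high-pass is
  implemented as removal of the sub-cutoff DCT projection, sharing the
  drift-filter machinery.
* **Savitzky–Golay** (window 11, order 3) uses polynomial extrapolation
  of the terminal windows at the edges, matching interior behaviour; a
  cubic series is reproduced exactly.
* %change precedes smoothing; the chain narrative supports either order
  and this reading is implemented and fixed.

## Synthetic data

The generators define the study conditions for all tests:

* **Folded sheet**: z = a·sin(2πx/λ) (default a = 1.5 mm, λ = 24 mm,
  0.5 mm spacing), with analytic normal (−z′, 0, 1)/‖·‖ and mean
  curvature −z″/(2(1+z′²)^{3/2}) attached as oracles, and a central "V1"
  band label.
* **Retinotopy**: eccentricity linear along one surface axis, polar angle
  along the orthogonal axis (V1-like), σ growing with eccentricity,
  seeded r² noise about 0.6. A constant polar range yields a pure linear
  visual-field gradient for the match-distance oracle.
* **Line session**: 40 positions (8 CSF, 16 GM at 0.25 mm, 16 WM). GM
  carries the target pRF response scaled linearly from 2× (superficial)
  to 1× (deep) — the simplest shape consistent with the roughly doubled
  superficial BOLD amplitude; it is an amplitude model, not a vascular
  model. All tissue shares a 1%/min linear drift and cardiac (1.0 Hz) and
  respiratory (0.3 Hz) sinusoids at 0.5% amplitude; per-coil smooth
  Gaussian sensitivity profiles; per-echo exp(−TE/T2*) scaling with
  T2* = 28 ms (typical gray matter at 7 T — only the relative weighting
  matters); i.i.d. Gaussian thermal noise. Thermal SNR is defined as the
  peak superficial BOLD amplitude over the thermal SD; the canonical
  test condition is SNR 5 with a 3% BOLD amplitude. Default runs use the
  line-session design (2 orientations × 2 directions × 2 widths, 0.105 s
  frames, ~195 s per iteration, two iterations).
* **Transform jitter**: rigid perturbations from seeded rotation vectors
  and translations, emulating registration repetition and run-to-run
  motion.

What the fixtures do **not** emulate: realistic cortical folding beyond a
single sinusoid, spatially correlated physiological noise, coil noise
covariance, k-space trajectories, imperfect OVS leakage (a mixing knob
exists but defaults to off), or motion within a run. Passing tests
demonstrate the correctness and internal consistency of the pipeline
under these conditions, not performance on human data.

## Validation metrics

Dispersion metrics map a coordinate through each of a set of transforms
and summarise Euclidean distances to the reference. Curvature-in-line
summarises |H| over the back-projected line vertices. Tissue fractions
normalise GM/WM/CSF counts inside the mask to percentages (background
excluded). The best-match metric computes, for every labelled vertex, the
visual-field distance between its pRF center and the line estimate
(centers only — σ is deliberately excluded), takes the argmin (ties:
smaller geodesic to the target, then lower index), and reports the match
in degrees, Euclidean mm and geodesic mm. Paired comparisons use
t = mean(d)/(sd(d)/√n) with df = n−1 and Cohen's D on difference scores,
D = mean(d)/sd(d); identical samples return the exact null (t = 0, p = 1,
D = 0), while a constant nonzero difference is an error (no variance to
test against).

## Problem sizes and determinism

End-to-end suites run 20 seeded sessions at thermal SNR 5 with the full
line design and two iterations; unit oracles use smaller designs
(whole-brain TR 1.5 s, 30-pixel grids) where the property under test does
not depend on size. Every stochastic component is driven by an explicit
seed through `numpy.random.default_rng`; identical seeds give
bit-identical simulations. `scripts/acceptance.py` derives all sub-seeds
from its `--seed` argument.

## Package shape

The pRF core follows the model/results convention of statistical
packages: `GaussianPRFModel` binds data to a design; `fit()` returns
`PRFResults` with estimates, linearised (Gauss–Newton) standard errors, a
`summary()` table, and plotting. The surrounding planning, preprocessing
and validation steps are procedural by nature (a targeting *tool*, not a
statistical model) and remain plain modules behind the `linetarget` CLI.

## Known limitations

* The graph geodesic overestimates true surface distance on anisotropic
  meshes.
* The scree-elbow rule assumes a visible spectral knee; at very low rank
  or flat spectra it degrades gracefully (retain-all) but cannot be
  optimal.
* cvR² as squared correlation cannot distinguish sign-flipped responses;
  that is intentional for cross-session amplitude comparison but matters
  if absolute polarity is of interest.
* The r² eligibility threshold is an input; it is subject-dependent in
  practice and is not auto-selected.
* Whether line-scanning fits should reuse the whole-brain HRF is an open
  empirical question; the default uses the same canonical form sampled at
  each session's TR.
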