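# Methods

## The model

A grayscale ultrasound loop is a stack of M x N intensity images
I_t(x, y), t = 1..n.  Stacked, these form a multivariate image space whose
frame-to-frame variation encodes tissue motion.  The package analyses that
space in four stages.

**1. Congruent wavelet features.**  Each frame is decomposed with the 2-D
discrete wavelet transform (Symlet 8 by default).  Because every frame has
the same shape and transform configuration, each coefficient address
(level, subband, row, col) refers to the same image feature in every frame
— the coefficient images are *congruent* — so the loop unfolds into an
ordinary two-way table X (frames x coefficients).  The table is compressed
by keeping the `n_keep` coefficients with the largest sample variance
across frames (ddof = 1): coefficients that never change carry no
information about the movement.  Ties are broken by a fixed flattening
order (deepest approximation band first, then per level diagonal /
vertical / horizontal, row-major), so the selection is deterministic and
index maps are portable.

**2. NIPALS PCA.**  After column mean-centering, X_c = T P' + E with scores
T (n x k), orthonormal loadings P (p x k) and residuals E.  Components are
extracted sequentially by NIPALS with deflation — practical when p >> n, as
it is here (thousands of coefficients, hundreds of frames).  Start vector:
the column of largest variance; sign: fixed so each component's
largest-magnitude loading is positive; convergence: relative score change
below `tol` (default 1e-10, cap 500 iterations).  On unstructured
noise-like matrices the leading eigenvalues are nearly degenerate and the
power iteration converges slowly; raise `max_iter` there.  R2X per
component is ||t_a||^2 over the total centered sum of squares.  No
unit-variance scaling by default: the coefficients of one sequence share a
scale, and scaling would inflate noise-only coefficients (a `scale` flag
exists for other uses).

**3. Distance to model (DModX).**  Per observation,
s_i = sqrt(sum_j e_ij^2 / (p - k)); the pooled training value is
s_0 = sqrt(sum e^2 / ((n - k - 1)(p - k))), one extra degree of freedom
consumed by centering, following the standard chemometric convention.
DModX_i = s_i / s_0, and the critical limit at significance alpha is
sqrt(F^-1(1 - alpha; p - k, n - k - 1)).  On training data the identity
mean(DModX^2) = (n - k - 1)/n holds exactly, which the tests use as a
calibration check.

**4. Trajectory analytics.**  The time-ordered scores trace the movement:

- *Adjacent distances* ||t_{i+1} - t_i|| measure instantaneous tissue
  dynamics (rotation-invariant in score space).
- *Turning points*: the chosen score (component 1 by default — it separates
  the two flexion directions) is smoothed with a centered moving average
  (default 5 frames, about 64 ms at 78.6 FPS), and interior extrema are
  located with `scipy.signal.find_peaks` under a minimum separation and a
  prominence floor (default 5% of the smoothed range).  The prominence
  floor is deliberate: rest and hold phases are flat, so strict
  sign-change extrema there are noise, not movement turns.  Because a hold
  phase makes the extremum a noisy plateau, each turn is re-centred on the
  median frame of the band within 5% of the peak's prominence.
- *Repetition segmentation*: repetitions are assumed to begin and end near
  rest, so the score is oriented by its starting level, and the sequence is
  cut at the n-1 deepest return-to-baseline dips (baseline = median of the
  smoothed score, robust to asymmetric dwell times).  Each cut lands on the
  median frame of the dip's near-minimum band, again because the dip bottom
  is noise-dominated.
- *Repetition similarity*: each segment's score is linearly resampled to a
  common length (no dynamic time warping — repetitions differ mainly in
  duration, and linear time-normalisation is the simplest defensible
  alignment), then Pearson-correlated pairwise.

**Loading images.**  A loading vector lives in coefficient space; placing
it at its addresses in an otherwise-zero decomposition and inverting the
transform yields a spatial image of which regions drive the component.
Unselected coefficients stay at zero — the reconstruction shows what the
model saw, nothing more.  Localization is quantified as the fraction of
absolute pixel mass inside the region of interest dilated by the wavelet
filter's support radius at the decomposition depth, absorbing the spatial
spread of the synthesis filters.

**Speckle tracking (reference analysis).**  A pyramidal Lucas-Kanade point
tracker implements the classical matching criterion: find (dy, dx)
minimising the uniformly weighted SSD between a patch in frame t and its
displaced copy in frame t+1, by Gauss-Newton iteration on the linearised
brightness-constancy equations, coarse-to-fine over a Gaussian pyramid.
Defaults: 21 x 21 window, 3 pyramid levels, 30 iterations per level,
termination at 0.01 px; all configurable.  A point is refined at a pyramid
level only when its whole window fits inside that level's image (border
replication corrupts gradients and can make the iteration diverge), and
per-iteration updates are clamped to half a window.  A track is invalidated
— permanently — when its window crosses the frame border or the structure
tensor's smallest eigenvalue falls below 1e-4 x window area (no trackable
texture).  Derived outputs: segmented-ROI transversal (row/depth direction)
displacement in px and mm, whole-image grids, PCA of the frames x
(2 x n_tracks) coordinate table for comparison with the wavelet-domain
trajectory, and the pennation angle at a vertex between two tracked arms
(normalized dot product, degrees).

## The synthetic-data generator

No study data accompany the method, so validation uses simulated loops
with exact ground truth.  Speckle-like texture: uniform random point
scatterers (default 0.05 per px^2, amplitudes uniform in [0.1, 1]) splatted
bilinearly onto a padded canvas and blurred with a Gaussian PSF
(sigma = 1.2 px).  Motion: rigid translation, or row-direction shear whose
gain grows piecewise-linearly with depth — superficial tissue moves less
than deep tissue, as in a heel raise.  Because the forward map is piecewise
linear in the row it is inverted exactly, so the rendered frames and the
returned dense displacement fields agree by construction; warping uses
cubic-spline interpolation, then additive Gaussian noise (sigma = 0.01 in
[0, 1] units) and clipping.  Identical spec + seed gives bit-identical
output.

The heel-raise preset drives the shear with a per-repetition
concentric (linear ramp up) / hold (6 frames) / eccentric (ramp down)
profile, 5 rest frames between repetitions split 3-before/2-after each
boundary so that with zero jitter every repetition segment is congruent
frame-for-frame.  Defaults: 3 repetitions of 140 frames at 128 x 128 px
(420 frames, about 1.8 s per repetition at the 78.6 FPS frame-rate
metadata), peak displacement 6 px at the deepest row and 25% of that at the
surface (at 0.5 mm/px lateral resolution, a realistic few-mm excursion),
and 5% relative jitter on per-repetition peak amplitude.  Ground truth
records the amplitude profile, per-frame phase labels, turning frames (hold
centers), repetition boundaries (rest centers) and the dense displacement
fields.

What the generator does *not* emulate: acoustic physics (no RF signal,
beamforming, attenuation, shadowing or anisotropic PSF), out-of-plane
motion, speckle decorrelation under large strain, and probe motion.
Passing tests therefore show that the pipeline recovers known in-plane
motion from speckle-textured images; they do not certify performance on
clinical loops, where those effects dominate failure modes.

## Numerical and design choices

- Intensities are normalised by the integer dtype maximum, never the
  per-sequence maximum, so inter-frame brightness changes remain signal.
- Decomposition depth defaults to 4 but is clipped to the maximum feasible
  depth for the frame size (the usual log2(n / (filter length - 1)) rule);
  the feature table records the depth actually used.
- Boundary handling: symmetric (half-sample) padding, the standard choice
  for Symlet analysis of images.
- `n_keep` defaults to 3000 coefficients; k defaults to 2 components,
  which is what a score *plot* shows.
- Degenerate inputs fail loudly: static scenes are rejected by the track
  PCA, constant segments by the correlation, rank-exhausted matrices by
  NIPALS, p <= k by DModX.
- Problem sizes in the test suite and acceptance script (420-frame
  128 x 128 heel-raise study, 20 x 20 tracking grid, 100-frame translation
  sequence) were chosen as the smallest sizes at which every stage operates
  in its intended regime — hundreds of frames per repetition, thousands of
  candidate coefficients, hundreds of tracks.

## Known limitations

- The tracker estimates pure translation per patch; rotation or strain
  within a window biases estimates (as with any Lucas-Kanade variant).
- Turning-point and boundary conventions (smoothing, prominence floor,
  plateau re-centring) are operational definitions; on real data the turn
  frames reported by an analyst reading a score plot may differ by a few
  frames.
- Loading-image interpretation is qualitative: unselected coefficients are
  zeroed, so reconstructed intensity is not calibrated to physical
  contrast.
- DModX critical limits use the F-approximation; they are guides, not
  exact test levels, especially for strongly structured residuals.
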