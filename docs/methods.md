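# Methods

## The two generative models

Both models describe a preprocessed image patch `y` (D pixels) as a noisy
combination of a subset of H basis functions (columns of `W`, D x H).
Hidden units are binary — a component is either present or absent — with
independent Bernoulli(pi) priors, and the noise is isotropic Gaussian with
standard deviation sigma.  The full parameter set is Theta = (W, sigma, pi)
for both models; the only difference is the superposition rule:

* **MCA** (maximal causes analysis, occlusive): pixel d of the noiseless
  patch is the value `W[d, h*]` of the *active* unit with the largest
  absolute value at that pixel.  This winner-take-all rule approximates
  opaque occlusion of image components without modelling depth order.
  Sign is preserved, so the model applies directly to signed
  (center-surround filtered) data; on nonnegative data (e.g. after ON/OFF
  separation) it reduces to the conventional pointwise max.
* **BSC** (binary sparse coding, linear): the noiseless patch is `W s`,
  the plain sum of active columns.

`H * pi` is the mean number of active causes per patch and serves as the
(inverse) sparsity measure.

Degenerate conventions: an empty active set maps to the zero patch (both
models); max-magnitude ties go to the lowest unit index.  Probabilities
are handled in log space throughout, with the per-patch maximum
subtracted before exponentiation.

## Expectation-truncation inference

Exact EM needs sums over all 2^H states per patch.  The E-step instead
restricts each patch to a candidate set K_n built from the H' units with
the largest selection scores, enumerating all subsets with at most gamma
simultaneously active units, always including the zero state and every
singleton (so no unit is starved of update evidence).  The candidate
count is `sum_{g<=gamma} C(H', g) + (H - H')`.

* **Selection score**: normalized cross-correlation
  `score_h = (W_h . y) / ||W_h||`, invariant to positive column
  rescaling.  This is a design choice (the closed form is not pinned
  down by the training recipe we follow); it is validated by the bars
  recovery results.
* **Truncated expectations** are candidate-restricted posterior averages
  computed with log-sum-exp normalization.  With H' = H and gamma = H they
  equal the exact posterior expectations (tested to 1e-10 against brute
  force enumeration).
* **Truncated free energy**:
  `F = sum_{n in M} log sum_{K_n} p(s, y_n) - |M| log B(pi)` with
  `B(pi) = P(|s| <= gamma)` under the prior.  The correction term makes F
  reduce exactly to the log-likelihood in the no-truncation limit
  (tested).  M is the `round(N * B(pi))` patches with the largest
  truncated evidence — the patches the truncation approximates well;
  ties break to the lower patch index.

### Annealing schedule

The first third of EM iterations runs on the full dataset; over the
middle third the retained fraction decreases linearly from 1 to B(pi);
the final third holds the ET cut.  A deterministic-annealing temperature
(dividing the log-joints, decaying linearly to 1 over the first two
thirds) is available and **off by default**.  The bars benchmark runs use
a mild start temperature of 1.5: bars stimuli have pronounced local
optima because their pixel values are not continuously distributed, and
annealing reliably avoids most of them; for image-like data with
continuous value distributions annealing makes no difference and is left
off.

## M-steps

* **BSC basis**: `W = (sum_n y_n <s>^T)(sum_n <s s^T>)^-1` over M —
  ordinary least squares of patches on expected states.  Singular Gram
  matrices fall back to the pseudo-inverse.
* **MCA basis**: a responsibility-weighted fixed-point update
  `W_dh <- sum_n <A_dh(s)> y_dn / sum_n <A_dh(s)>`.  The responsibility
  `A_dh` is the derivative of the smoothed (rho-norm) combination, whose
  large-rho limit is the indicator that unit h carries the max-magnitude
  value at pixel d.  The update uses this **limit (indicator) form by
  default**: the finite-rho derivative diverges wherever active entries of
  opposite sign nearly cancel (e.g. +a/-a bar crossings), which corrupts
  the fixed point — with the indicator form the generating parameters are
  a fixed point on noiseless data (tested).  The finite-rho form, clipped
  to the limit's [0, 1] range, remains available (`mode="smooth"`) and is
  used to verify convergence to the indicator as rho grows (rho = 101
  agrees to 1e-6 on matrices with distinct per-pixel magnitudes);
  `rho = 25` is the smoothing default wherever the smooth form is used.
* **Evidence-based learning rate** (MCA): entries whose accumulated
  responsibility mass e is small are blended conservatively,
  `W_new = (1 - lambda) W_old + lambda W_candidate` with
  `lambda(e) = e^2 / (e^2 + 4)` — 0.5 when an entry is supported by two
  patches, ~0.96 at ten.  The anchors are the documented behaviour
  ("slow below a few patches, ~1 above ten"); the algebraic form is this
  package's choice.  Zero-evidence entries are left unchanged.
* **Noise**: `sigma^2 = <||y - W_bar(s)||^2> / (|M| D)`, with the expected
  residual evaluated under the *updated* basis (closed form for BSC;
  recomputed combinations for MCA — using the stale basis produced a
  two-cycle oscillation in sigma).  Floored at 1e-4 of the data RMS scale.
* **Sparsity**: the stationarity condition of the truncated free energy is
  `A(pi)/B(pi) = mean <|s|>`, where A and B are the expected active count
  and total mass of the prior restricted to `|s| <= gamma`.  A/B is
  monotone in pi, so the update solves the condition by bisection
  (tolerance 1e-12, iterates clamped to (1e-6, 1-1e-6)); gamma = H gives
  the closed form `pi = mean<|s|> / H`.
* **Initialization**: columns of W are the data mean plus unit-variance
  Gaussian noise; `pi = 1/H` (one active component on average);
  `sigma^2` is the mean empirical pixel variance.

The recorded free energy for iteration t is evaluated at the pre-update
parameters, so with no truncation it is the exact EM objective: for BSC
it is non-decreasing to 1e-9 per iteration (tested).  The MCA W-step is a
fixed-point, not a guaranteed ascent step; run-level likelihood
improvement is what the tests pin down.

## Preprocessing

* **DoG kernel**: difference of two concentric Gaussians, each normalized
  to unit mass, so the weights sum to zero and constant input maps to 0.
  Surround/center std ratio defaults to 3.0 (configurable).  Patch
  filtering uses a 'valid' central crop by default (no padding
  artifacts); receptive-field estimation uses same-size convolution.
* **Contrast scaling**: a single global factor maps the dataset's extreme
  magnitude to exactly 10 ("fill [-10, 10]" read as a dataset-level
  statement; a per-patch mode exists).  Divisive variance normalization
  is provided as the alternative normalizer.
* **ZCA**: symmetric whitening `C^{-1/2}` from the eigendecomposition of
  the centered covariance, with an eigenvalue floor for rank-deficient
  data.
* **ON/OFF separation**: positive and negative parts become separate
  nonnegative channels (dimension 2D); the original patch is their
  difference, and the occlusive rule reduces to a plain max on the
  separated data.
* Readers: grayscale PGM/PNG/TIFF via Pillow; van Hateren raw `.iml`
  frames as 16-bit big-endian 1024 x 1536 with an optional log-intensity
  transform.

## Receptive-field analysis

The receptive-field estimate of a learned unit is its basis column
convolved with the preprocessing DoG kernel (the linear two-stage map:
LGN filter then linear read-out).  Reverse correlation from posterior
responses is available as the optional alternative; the convolution
estimate is the default.

Each field is matched by least squares against

* an 8-parameter **Gabor wavelet** (center, orientation, envelope stds
  along/orthogonal to the wave vector, frequency, phase, amplitude), and
* an 8-parameter **difference of Gaussians** (center, orientation, inner
  stds, outer/inner size factor k > 1, two amplitudes).

Fitting is multi-start Levenberg-Marquardt: an FFT-derived
orientation/frequency guess plus a deterministic grid over orientations,
phases, centers, widths and amplitude scales of both signs (with a
strong surround the field's extremum is the off-center surround ring and
the center peak is `a1 - a2`, so amplitude seeds must reach well beyond
the observed extremum); starts are ranked by initial cost and the best
12 (Gabor) or 24 (DoG) refined — single-start local optimization is
known-insufficient for these fits.  Parameter equivalences (theta + pi with phase
negation, amplitude sign with phase shift, DoG Gaussian swap for k < 1,
DoG axis swap under a 90-degree rotation) are canonicalized before any
comparison.

**Classification**: a field is *globular* when the DoG residual beats the
Gabor residual and the DoG aspect ratio is below 2.0; *ambiguous* when
the two residuals differ by less than 5% of the smaller one (a package
choice making the qualitative notion concrete; configurable, and inert
on clean fields);
*unspecific* when both fits leave more than 50% of the field power
unexplained; otherwise *gabor_like*.  Precedence: unspecific > ambiguous
> globular/gabor_like.  Globular percentages are reported with the
ambiguous fields counted half (all/none give the interval bounds).
Gabor-like fields are summarized by `nx = sigma_x * f`,
`ny = sigma_y * f` — envelope widths in units of the spatial wavelength —
after globular fields are removed, which avoids matching center-surround
fields with Gabors.

## Synthetic data

The **bars benchmark** is the standard ground-truth test for component
extraction: on a b x b patch (default b = 5, so D = 25), the H = 2b
generating basis functions are the b horizontal and b vertical bars at
amplitude +10 or -10 (random sign per bar by default), pi = 2/H (two
bars active on average), noise sigma = 2, N = 1000 patches, 100 EM
iterations with H' = 6, gamma = 4.  Each bar pixel carries a Gaussian
perturbation of std 1.0 (10% of the amplitude).  The perturbation both
keeps the benchmark non-degenerate and, crucially, decides which bar wins
at a +a/-a crossing under the occlusive rule; it must exceed the basis
estimation error (about `sigma / sqrt(N pi)` per entry, ~0.16 at the
defaults) or the generating winner order is information-theoretically
unrecoverable and every mis-ordered crossing charges (2a)^2 to the
residual, inflating the recovered noise by 20-35% at the
maximum-likelihood solution itself.  Recovery is scored by greedy
max-cosine matching of learned to generating columns (a bar and its
negation count as different causes); success requires every bar at
cosine >= 0.95.

Synthetic Gabor/DoG fields (the oracles for the fitting round-trip) are
rendered from the same closed-form models the fitter uses, with known
parameters.  The occlusive scene generator paints opaque random shapes
back-to-front and exists for end-to-end smoke tests; it is not a
calibrated dead-leaves model.

### What the generators do and do not emulate

The bars data share the structure that matters for the learning
machinery — binary causes, occlusive vs. linear crossings, inferable
sparsity and noise — but none of the heavy-tailed, scale-invariant
statistics of natural images.  Passing the recovery tests shows the
inference and updates are correct under each model's own assumptions; it
does not by itself predict receptive-field shapes on natural input,
which requires large image corpora and far larger H than these tests
use.

## Problem sizes and runtimes

The validation battery is sized for a single CPU: bars recovery uses
N = 1000 patches, H = 10, 100 EM iterations, five seeds per model
(roughly 25 s per MCA run, 3 s per BSC run); exactness and monotonicity
checks enumerate up to 2^8-2^10 states; the fitting round trip uses 100
noise-free fields per family on 16 x 16 grids.  E-step and M-step inner
loops are vectorized over patches in chunks of 256 to bound memory.

## Known limitations

* Natural-image experiments (H up to ~1600, 1e6 patches) are supported by
  the API (chunked, patch-parallel E-step; checkpointing) but not
  exercised by the tests.
* The MCA free energy is not guaranteed monotone per iteration (fixed-
  point W update); divergence is caught by NaN guards and run-level
  checks.
* The finite-rho responsibility mode is numerically fragile near
  opposite-sign cancellations even with clipping; it exists for analysis
  of the smooth-max approximation, not as the recommended update.
* Classification thresholds (5% ambiguity gap, 50% unspecific power) are
  package choices; on clean synthetic fields they are inert, on noisy
  measured fields they matter and are exposed in the configuration and
  output metadata.
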