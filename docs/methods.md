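# Methods

## The quadratic convolutional model

`qconv` fits position-invariant, multi-feature receptive-field models to
stimulus/spike data. The stimulus is a grayscale movie `X_t` (T frames of
H x W pixels, one frame per time bin, typically 16 ms); the response is a
spike count per bin. The model has three stages:

1. **Quadratic logistic subunits (QLS).** Identical subunits are evaluated
   on every patch `x` extracted from the movie at a grid of spatial offsets
   and a range of temporal lags:

       s = sigma(a1 + v1 . x + x' J x),      sigma(u) = 1/(1+e^-u).

   `v1` is a linear filter over the patch pixels and `J` a symmetric
   quadratic kernel; its eigenvectors with positive (negative) eigenvalues
   act as excitatory (suppressive) stimulus features of the subunit.

2. **Pooling.** Subunit outputs are combined across grid positions and lags
   with weights `v2` (lag-major, then row-major grid order).

3. **Output nonlinearity.** The default is the soft-plus rectifier,
   `rate = log(1 + exp(d * (v2 . s) + a2))`; a saturating variant
   `rate = d * sigma(v2 . s + a2)` is available, where `d` acts as an
   amplitude so spike counts can be matched.

Reduced variants are expressed through `ModelSpec`: `quadratic=False` fixes
`J = 0` (linear convolutional, LC, or linear non-convolutional, LNC);
`convolutional=False` collapses the grid to the single central patch
position per lag (quadratic non-convolutional, QnC — the classical
multi-feature quadratic model without position invariance). Frames without
a full lag history are dropped from the likelihood rather than zero-padded,
which avoids edge artifacts in fitting.

Geometry conventions: 0-based row-major pixels, patch positions labeled by
their top-left corner, lag `l` meaning the patch from frame `t - l`
(causal). The grid extent per axis is `floor((H - patch)/stride) + 1`,
anchored at offset 0. Movies are mean-centered on load and not variance
normalized; the model biases absorb offsets and the raw scale keeps `J`
interpretable.

## Fitting

All parameters `(a1, v1, J, v2, a2, d)` are fitted by minimizing the
Poisson negative log-likelihood `sum_t rate_t - y_t log rate_t` with
stochastic gradient descent (analytic chain-rule gradients; the `J`
gradient is symmetric by construction and `J` is stored as its symmetric
part throughout, so the eigen-analysis of the fitted kernel is always
valid).

The training frames are divided into four **contiguous** temporal fourths.
Four models are fitted, each using three fourths for gradients and the
held-out fourth for early stopping (validation NLL checked each epoch,
best-validation parameters kept, stop after `patience` non-improving
epochs); the four are averaged element-wise. Contiguous fourths are used
because temporal correlation in movie stimuli would leak across shuffled
splits.

**Sign canonicalization before averaging.** Because
`sigma(-u) = 1 - sigma(u)`, flipping `(a1, v1, J)` together with `v2` and
shifting `a2` by `d * sum(v2)` leaves the predicted rate identical. Folds
can converge on either branch of this exact symmetry, and the raw
element-wise average of mixed-branch folds cancels the structure in `J`.
Every fold is therefore flipped onto the branch where the
largest-magnitude pooling weight is positive before averaging.

Optimizer defaults (plain SGD with momentum on the mean-per-frame NLL; all
exposed in `FitConfig`, none hard-coded):

| parameter       | default | why |
|-----------------|---------|-----|
| `learning_rate` | 0.01    | stable for patch dimensions up to ~256 on unit-variance stimuli |
| `batch_size`    | 512     | smooths Poisson gradient noise at ~200 steps/epoch for 1e5 frames |
| `momentum`      | 0.9     | speeds the slow growth of the weak quadratic signal |
| `max_epochs`    | 80      | past the observed validation minima at desk scale |
| `patience`      | 10      | validation NLL is noisy; stopping late never harms the kept best |
| `init_sd`       | 1e-3    | near-linear start, unsaturated subunits (v1 and J) |
| `v2_init_sd`    | 0.1     | gradient into (a1, v1, J) is proportional to v2; a 1e-3-scale v2 would throttle early learning of the kernel |

Initialization: `a2` from the mean spike count through the inverse output
nonlinearity, `d = 1` (soft-plus) or twice the mean count (logistic
amplitude), `a1 = 0`.

**Evaluation.** On a repeated-trial test block the model is scored by the
Pearson correlation between prediction and the trial-averaged response,
divided by an estimate of the best correlation any model could attain
given trial-to-trial variability: trials are split into random halves, the
correlation between half-means is averaged over 20 splits, Spearman-Brown
doubled to the reliability of the full-trial mean, and square-rooted. The
corrected value is clipped to [0, 1] and the method name is embedded in
the output.

## Eigenfeature significance

The scalar mean of `J` is subtracted first (a nonzero mean alone creates a
spurious outlying eigenvalue). Null distributions of extreme eigenvalues
come from shuffling the diagonal entries among diagonal slots and the
upper-triangle entries among off-diagonal slots (mirrored), which preserves
both entry multisets and the trace. Eigenvalues are tested in order of
decreasing magnitude against the matching tail (max-null for positive,
min-null for negative) with the add-one p-value estimate; testing stops at
the first p >= 0.05, and no deflation is performed (none is described for
the procedure this implements; with strong components the non-deflated
test is conservative about later, smaller components). The default 1000
shuffles resolve p = 0.05 with a standard error near 0.7 percentage
points. Under the null the sequential rule rejects at a familywise rate
between alpha and 2*alpha (one tail is tested per draw, whichever sign has
the larger extreme); the calibration test asserts exactly that band.

## Gabor decomposition

The excitatory (suppressive) part of `J` — rebuilt from the significant
eigencomponents of one sign — is approximated as `sum_i w_i g_i g_i'` with
unit-norm Gabor images

    g(x, y) = A exp(-(xr^2 + gamma^2 yr^2)/(2 sigma^2)) cos(2 pi xr / lambda + phi),

`xr, yr` the patch coordinates rotated by `theta` about `(x0, y0)`.
Parameters (and weights) are fitted by minimizing the reconstruction MSE
with self-adaptive rand/2/bin differential evolution:

- population `10 P` for `P` free parameters (floor 7: the mutation needs
  five distinct partners plus the target);
- mutant `u' = u_r1 + F (u_r2 - u_r3) + F (u_r4 - u_r5)`, binomial
  crossover with a forced coordinate;
- per-member `CR ~ U[0,1)` and `F ~ 0.1 + 0.9 U[0,1)`, each regenerated
  with probability `tau = 0.1` before mutation;
- `x0, y0` uniform within the frame, `theta`, `phi` uniform on (-pi, pi],
  `sigma`, `gamma`, `lambda` and `|w|` log-uniform and mutated as
  logarithms (steps are changes of scale);
- proposals outside the initialization bounds receive infinite error;
  replacement is greedy on MSE; a run ends when a full generation passes
  with no replacement (a `max_gens` cap of 2000 guards against
  pathological stagnation); the best of `restarts` independent runs wins.

The MSE is evaluated through Gram matrices
(`||sum w gg' - J||^2 = w'(G G')^2 w - 2 w' q + ||J||^2`), so no P^2 x P^2
object is ever formed. Suppressive parts are detected by eigenvalue energy
and fitted as their positive mirror, with weight signs restored on output.

**Quadrature mode** constrains pairs to share every parameter except the
spatial phase, fixed at 0 and pi/2; each member keeps its own nonnegative
weight (a shared-weight mode exists but is off by default — nothing forces
the two phases to contribute equally, and the relaxation costs one
parameter). A free pair has 16 parameters, a quadrature pair 8.

**Pairing and phase differences.** Gabors are paired greedily: a candidate
pair qualifies when the center distance is under one mean wavelength and
the axial orientation difference under 30 degrees (the source procedure
says only "similar positions and orientations"; both thresholds are
exposed). The phase difference of a pair is
`phi_a - phi_b - (2 pi / lambda_bar) (dx . n_hat)` folded into [0, 180)
degrees, where `n_hat` is the mean carrier direction (axial circular mean)
and `lambda_bar` the harmonic mean of the two wavelengths — the wavelength
of the mean spatial frequency, since "mean frequency" acts on frequency,
not wavelength. Orientation is treated axially (mod 180 degrees)
throughout; carrier sign is absorbed by phase.

## Population metrics

- **Lifetime sparseness** uses the Treves-Rolls / Vinje-Gallant form
  `S = (1 - (mean r)^2 / mean(r^2)) / (1 - 1/n)`; scale invariant, 0 for
  constant rates. (No formula is fixed by the source analyses; this is the
  standard choice in the V1/V2 literature and is recorded in outputs.)
- **Suppression removal** rebuilds `J` from the significant excitatory
  eigencomponents only, all other parameters fixed, and reports
  `S_without / S_with`; a ratio below 1 means suppression sharpens
  responses. Computed on held-out stimuli. A companion routine resamples
  the suppressive Gabors' orientations uniformly (fresh draw each time,
  all else fixed) to isolate the role of the orthogonal arrangement.
- **Orientation spread** is the circular standard deviation on doubled
  angles, halved back to orientation units; infinite when the doubled
  resultant vanishes (e.g. two orthogonal orientations). Neurons are split
  into orientation-uniform and non-uniform classes at a supplied threshold
  or at the midpoint of the largest gap in the spread distribution.
- **Excitatory-suppressive orientation differences** (nearest-neighbour in
  space, or all pairs) are histogrammed into 8 equal bins over [0, 90]
  degrees and tested against uniformity by chi-squared with 7 degrees of
  freedom.
- **Pooling masks** are factored space x time by SVD of the lag x position
  matrix (sign fixed so the temporal peak is positive). A map is biphasic
  when its opposed-sign lobes each carry over 20% of the total absolute
  mass — the threshold is a package choice, exposed as `lobe_frac`.
- **Dip test.** The Hartigan dip (smallest sup-norm distance from the
  ECDF to any unimodal CDF) is computed exactly from its variational
  characterization: for each placement of the mode between order
  statistics, the minimal distance is a small linear program (ECDF band
  constraints, convex-then-concave chains anchored at 0 and 1, monotone
  join at the mode); a hull-based per-split lower bound prunes all but a
  few splits. Equally spaced samples attain the lower bound `1/(2n)`; a
  constant sample has dip 0 (a point mass is unimodal); tied observations
  are separate ECDF steps, as in the classical algorithm. p-values are
  Monte Carlo against uniform samples of the same size, with a reusable
  null table per sample size.

## Synthetic ground truth

Every recovery and calibration claim is tested against data generated
in-package:

- **Stimuli** are Gaussian movies, spatially white or 1/f-filtered
  ("pink", random phases, unit variance) — a stand-in for the second-order
  statistics of natural movies. The 1/f ensemble reproduces the spectral
  falloff and spatial correlation of natural input but none of its
  higher-order structure (edges, occlusions, phase alignments), so
  recovery results here bound what the machinery can do, not what any
  cortical dataset will give.
- **QC neurons** are built from quadrature-pair Gabor features (phases 0
  and 90 degrees) with known signed weights, a uniform or two-lobed
  pooling mask, and an output stage calibrated on a probe movie: the
  kernel is scaled so the subunit drive has SD 2 (clearly inside the
  logistic's sensitive range without saturating), the subunit bias centers
  the drive, and `d`, `a2` are set so the mean rate is ~1 spike/bin — a
  deliberately well-driven cell at 16 ms bins, chosen so recovery tests
  measure the estimator rather than spike scarcity. The classic
  cross-orientation cell is one excitatory pair at 0 degrees plus a
  suppressive pair at 90.
- **Third-order neurons** respond with
  `baseline + gain * softplus(scale * (u1.x)(u2.x)(u3.x))` through three
  orthonormalized Gabor-like features (0, 60, 120 degrees); `scale`
  normalizes the triple product to unit SD on the probe and `gain` sets
  the mean rate to ~1 spike/bin. No pairwise-only term drives the cell, so
  recovering `u1..u3` from a fitted quadratic kernel probes exactly the
  higher-order sensitivity of the quadratic analysis.
- Poisson spikes per bin, all generators deterministic under a seed, and
  the QC fixtures carry an independent straight-loop response
  implementation (explicit sums over patches, pixels and kernel entries)
  against which the vectorized forward pass is verified.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: the
third-order recovery runs the full 1e5 frames of 12x12 pink noise
(P = 144, quadratic non-convolutional fit, ~40 s); end-to-end QC fits use
14x14 frames, 10x10 patches at stride 4 (2x2 grid), 3e4 frames; shuffle
calibrations use 20x20 kernels with 500 shuffles. The 16x16/20x20/10-lag
geometry of the original recordings is supported throughout and checked by
the geometry tests; only the recovery simulations are run smaller.

## Known limitations

- Plain SGD with momentum; no second-order optimizer, schedule, or GPU
  path. Very weak signals may need more epochs than the defaults.
- The shuffle null treats kernel entries as exchangeable within
  diagonal/off-diagonal groups; strongly correlated stimuli color the
  estimation noise in `J`, which can admit extra "significant" components
  beyond the planted ones (observed as a handful of small extra features
  in the third-order recovery).
- DE is stochastic; self-recovery tolerances assume the default restart
  counts. Single restarts can stagnate early.
- No loader for real cortical recordings is included; performance
  numbers from such datasets are out of scope and are not reproduced by
  any test.
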