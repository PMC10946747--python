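# Methods

## Problem and model

`radstar` reconstructs quantitative T2\* maps from multi-echo, multi-coil
golden-angle radial k-space data whose trajectory is corrupted by unknown
gradient timing delays. On MR systems whose gradient chains are hard to
calibrate (split-coil MR-Linacs are the motivating case), the actual k-space
sample positions lag the nominal ones by a fraction of a dwell time per
physical gradient axis; left uncorrected, the resulting spoke misregistration
produces streaking and banding that bias the fitted relaxation times.

The package estimates images, trajectory errors and relaxation parameters
jointly by minimizing

```
sum_{n,c} || F_n(dk_n) S_c x_n  -  y_{n,c} ||^2
        + lambda * sum_n || x_n - xhat_n(M0, T2*) ||^2
```

where `x_n` is the image at echo time `TE_n`, `y_{n,c}` the radial samples of
coil `c`, `S_c` the coil sensitivity, `F_n(dk_n)` the non-uniform Fourier
transform evaluated at the delay-shifted sample positions, and
`xhat_n = M0 exp(-TE_n / T2*) * exp(i arg x_n)` the mono-exponential model
image that keeps the complex phase of the current iterate. `lambda = 1` gives
the data-consistency and model-consistency terms equal weight.

The delay parameterization is deliberately low-dimensional: one `(tau_x,
tau_y)` pair per readout polarity, in dwell-time units, mapped to a rigid
per-spoke shift `-p * dk * (tau_x cos(theta), tau_y sin(theta))`. This
matches the physics of a per-axis timing error for a bipolar multi-echo
readout (odd and even echoes traverse the spokes in opposite directions and
are corrected separately) and keeps the estimation well-posed under
undersampling. A free per-spoke error vector is out of scope.

The minimization alternates three steps until the relative cost change drops
below `rel_tol` (default 1e-4) or `max_outer_iters` (default 10) is reached:

1. **Trajectory correction** — the delay pair of each polarity is updated by
   damped Gauss-Newton on the data-consistency cost. The Jacobian of a
   sample w.r.t. its k-coordinate is the transform of the coordinate-ramped
   image (`-2*pi*i*r/N` weighting), chained with the analytic `d k / d tau`
   of the shift model; the same three transforms per echo/coil yield cost,
   gradient and Gauss-Newton Hessian. Backtracking halving keeps the step a
   descent step. The two polarities decouple exactly, so two independent
   2-parameter problems are solved. (A general nonlinear-CG solver is the
   natural choice for a high-dimensional per-spoke error vector; for the
   2-parameter-per-polarity model used here Gauss-Newton reaches the same
   minimizer in a handful of cost evaluations.)
2. **Data consistency** — each echo image is updated by warm-started linear
   CG on the SENSE normal equations, including the `lambda`-weighted
   proximity term once a model estimate exists (from the second outer
   iteration on). Warm starting makes the quadratic cost non-increasing over
   CG iterations, which in turn makes the outer cost trace monotone.
   The data term is expressed in units of the mean eigenvalue of the SENSE
   normal operator (`trace(S^H F^H F S)/N^2`, closed form): "equal weight"
   at `lambda = 1` is only meaningful if the two quadratic forms have
   comparable curvature, and this normalization makes the trade-off
   invariant to the Fourier normalization convention and to problem size.
   (The mean — not the spectral norm — is the right yardstick for radial
   sampling, whose largest eigenvalue is a DC-density outlier; weighting by
   the norm, or using a raw `1/N^2`-normalized transform, silently turns
   the model term into the dominant one and degrades the joint mode below
   the sequential one.)
3. **Model consistency** — per-pixel fit of `|x_n| = M0 exp(-TE_n/T2*)` by
   variable projection: for a trial rate `R2* = 1/T2*` the optimal `M0` is
   closed-form, leaving a 1-D profile maximization per pixel solved by a
   96-point log-spaced grid plus bisection on the profile derivative within
   the bracketing cell. The fit is exact (to solver precision) on
   model-consistent input. The complex phase of `x_n` is copied to `xhat_n`
   unchanged.

Three reconstruction modes share this machinery: `uncorrected` pins the
delays at zero (steps 2-3), `sequential` alternates steps 1-2 without the
model term and fits `(M0, T2*)` once at the end, and `joint` runs all three
steps every outer iteration.

Initialization: images from the density-compensated gridded reconstruction,
delays at zero, sensitivities estimated from the first-echo gridded coil
images by the adaptive (Walsh) method — per-pixel dominant eigenvector of
the box-smoothed coil covariance, phase-referenced to coil 1 and normalized
to unit root-sum-of-squares. Reconstructed images therefore carry a smooth
RSS-of-true-sensitivities intensity weighting; this cancels in the
echo-to-echo ratios and leaves T2\* unaffected (M0 inherits the weighting,
as with any autocalibrated SENSE reconstruction).

## Non-uniform FFT

No suitable NUFFT dependency was adopted; the package implements its own:
Kaiser-Bessel gridding with oversampling 2.0 and kernel width 8 (Beatty's
shape parameter), kernel values served from a 32k-entry lookup table inside
numba-compiled spread/interpolate loops. Width 8 was chosen over the more
common 6 to keep the error against a direct-summation NDFT below 1e-6
relative (measured ~1e-7), the accuracy the CG solvers and the
delay-gradient computation assume. The adjoint is exact by construction, not
merely approximate, so adjointness tests hold to machine precision.

Conventions: image pixels at centered coordinates `r = i - N//2`; k in
cycles/FOV with `|k| <= N/2` nominal; the forward transform is normalized so
the DC sample of a unit image is 1. Because pixel positions are integers,
the discrete model is exactly N-periodic in k; delay-shifted samples that
fall marginally past the nominal edge wrap consistently, and the coordinate
validator only rejects coordinates beyond 0.75 N (a unit-error guard).

Density compensation for the gridded initial guess uses a ramp-initialized
Pipe-Menon iteration (15 passes of dividing each weight by the
kernel-smoothed sampling density). The plain analytic ramp leaves a
few-percent object-dependent amplitude bias; the iterative estimate removes
it and adapts automatically to echo-dependent spoke subsets after
undersampling.

## Synthetic data generator

The generator emulates the 2-D numerical validation study: a 256x256 labeled
brain-like slice (procedurally generated: skull annulus, cortical GM ribbon,
WM interior, one connected two-lobed CSF ventricle, from seeded smooth
closed contours) with tissue-constant parameters T2\* = 84 ms (GM), 66 ms
(WM), 2000 ms (CSF) and proton density 100 on every tissue pixel. Skull T2\*
is not part of the evaluated region; the package default is 10 ms,
configurable. Echo images follow `M0 exp(-TE_n/T2*)` exactly, with TE = 5,
10, ..., 40 ms (eight echoes, matching the acquisition protocol the method
targets). Eight circularly arranged virtual coils provide smooth Gaussian
magnitude profiles with mild linear phase. The trajectory is golden-angle
(111.246 deg increment on a 0-360 convention, full spokes) with 402 spokes
and 512 readout points for a 256 grid (`dk = grid/readout`, i.e. 2x readout
oversampling, no cropping); 402 spokes is almost exactly the radial Nyquist
count `pi/2 * 256`.

Gradient-delay corruption shifts each spoke rigidly as described above
(the study conditions are `(1, -1)` and `(1, 2)` dwell); the sign convention
(positive delay shifts samples opposite the readout direction) is internal —
only consistency between corruption and estimation is observable. Complex
Gaussian noise is added per sample with per-component standard deviation
`noise_level * mean|first-echo sample| / 100`, tying the study's noise grid
{0, 0.1, 0.5, 1} to the proton-density scale regardless of geometry.

Two retrospective 2x undersampling schemes are provided: `uniform` keeps the
last half of the acquired spokes for every echo (dropping the leading spokes
emulates a shortened acquisition without early non-steady-state spokes);
`alternate` keeps the first half for odd echoes and the last half for even
echoes, so each echo retains consecutive golden-angle increments and the
odd/even spoke sets are complementary.

What the generator does **not** emulate: 3-D (stack-of-stars) encoding, B0
inhomogeneity, motion, flow, realistic tissue microstructure or noise
correlation between coils. Passing tests therefore demonstrate correctness
of the estimation machinery under the stated corruption model, not clinical
robustness.

### A note on resolution and CSF

Radial sampling covers the inscribed k-space disc; the corner frequencies of
the square pixel grid are only very weakly coupled to the data and behave as
a numerical null space. The sharp-edged, tissue-constant phantom has a small
but real fraction of its energy there, so even a noiseless fully sampled
reconstruction retains a few percent of edge-localized (Gibbs-like)
residual. This matters for CSF: with T2\* = 2000 ms the entire decay across
a 40 ms echo train is ~2%, so CSF T2\* is only identifiable where the
residual is locally much smaller — i.e. in ventricle interiors a few pixels
away from edges. At the full 256 grid the ventricle has such an interior; at
the reduced test grids (64, 96) nearly every CSF pixel is edge-adjacent and
the fitted CSF values saturate at the fit bounds. Consequently the
millisecond-RMSE at reduced grids is dominated by CSF and is reported for
orderings only, while GM/WM medians and per-tissue relative errors remain
meaningful at every scale.

## Parameters that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `lambda` | 1 | — | equal weight of data and model terms |
| `max_outer_iters` | 10 | — | alternation typically settles in <10 |
| `cg_iters_images` | 10 | — | per-echo CG steps per outer iteration |
| `cg_iters_delays` | 15 | — | Gauss-Newton iteration cap (rarely hit) |
| `rel_tol` | 1e-4 | — | outer stop: relative cost change |
| `t2star_bounds_ms` | (1, 2500) | ms | brackets all tissues incl. CSF |
| `mask_threshold` | 0.05 | — | skip pixels < 5% of 99th-pct magnitude |
| delay bound | 5 | dwell | validity limit of the shift model |
| noise levels | {0, 0.1, 0.5, 1} | — | study grid |

Problem sizes: the full profile is 256 grid / 402 spokes / 512 readout / 8
echoes / 8 coils; the `--quick` profile (64 grid / 100 spokes / 128 readout
/ 4 echoes / 4 coils, 5 outer iterations) preserves the radial-Nyquist spoke
count and 2x readout oversampling and runs in seconds per reconstruction,
which is the scale the test suite uses for end-to-end properties. The
headline self-consistency computation (`scripts/acceptance.py`) runs the
full 402x512 geometry on the 256 grid.

## Design choices where the design was open

- **Echo parity is 1-based**: echo 1 is "odd" and acquired on the positive
  readout lobe; even echoes traverse the same spoke reversed.
- **Uniform undersampling keeps the *last* spokes**, consistent with
  shortening an acquisition from the front.
- **Model term activation**: on the first outer iteration no model estimate
  exists yet, so the image update is plain CG-SENSE; the proximity term is
  active from the second outer iteration onward. The recorded cost trace
  starts after the first projection, so every entry measures the same
  objective and the trace is monotone.
- **Sequential mode** uses the same outer-loop limits as joint for
  comparability.
- **T2\* fit masking**: background pixels (first-echo magnitude below 5% of
  the image's 99th percentile) are set to `M0 = 0`, `T2* = lower bound` and
  excluded from fitting; evaluation masks are label-based and exclude skull
  and background entirely, so this choice does not touch reported metrics.
- **Skull T2\*** defaults to 10 ms (short, bone-adjacent soft tissue); it
  is excluded from every evaluation metric.
- **Alternate-scheme echo geometry**: keeping complementary spoke halves
  makes the even-echo fan an effective rigid rotation of the odd-echo fan by
  `m * 111.246 mod 360` degrees, `m` the per-echo spoke count. For the
  402-spoke simulation geometry this is 40.45 deg (already in the 0-90
  folded range); for a 269-spoke acquisition with 134-spoke halves it folds
  to -33.04 deg. Each echo's subset remains a golden-angle sequence in its
  own right, so every echo keeps near-uniform angular coverage.

## Known limitations

- 2-D single-slice only; stack-of-stars kz encoding is a documented
  extension point, not implemented.
- No B0-inhomogeneity, motion or flow correction; no compressed-sensing
  spatial regularization.
- The delay model is rigid per spoke and per axis; anisotropic
  gradient-impulse-response effects beyond a pure delay are not modeled.
- Absolute error levels on the procedural anatomy are not comparable to
  studies based on a specific reference anatomy; orderings between modes
  and schemes are the meaningful comparison. A user-supplied labeled slice
  (`--labels`) enables anatomy-matched studies.
- CSF T2\* is at the edge of identifiability of a 40 ms echo train even in
  ideal data; see the resolution note above.
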