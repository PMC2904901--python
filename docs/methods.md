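# Methods

## Model

A skin conductance (SC) recording is modelled as

    SC(t) = tonic(t) + (driver * b)(t) + remainder(t),

where `tonic` is a slowly varying baseline, `driver` is a nonnegative,
compactly supported signal representing sudomotor burst activity, `b` is the
Bateman impulse response

    b(t) = exp(-t / tau2) - exp(-t / tau1),    0 < tau1 < tau2,

and `remainder` is a nonnegative residual capturing deviations of individual
responses from the standard shape.  The Bateman function is the solution of a
two-compartment first-order diffusion model (sweat enters the duct, diffuses
forward into the corneum, and is eliminated from there); `tau1` governs the
rise and `tau2` the slow recovery.  Remainder deflections beginning near an
impulse peak are interpreted, under the poral-valve picture, as pore-opening
(PO) components: transient conductance added when sweat is expelled through
an opened pore rather than diffusing through the corneum.

All kernels are discretised with unit area in the `dt` sense
(`sum(h) * dt = 1`), so convolution has DC gain 1 and drivers, remainders and
all amplitude thresholds share the microsiemens scale of the data at any
sampling rate.  The kernel is sampled from `t = dt` (b(0) = 0 would zero the
long division's leading coefficient); reported latencies correct the
resulting one-sample offset.

## Decomposition procedure

1. **Tonic estimation.**  The recording is deconvolved with the kernel and
   segmented by peak detection (threshold 0.2 uS); everything outside impulse
   sections is averaged on a 100-s grid (window +-50 s) and interpolated with
   a natural cubic spline, held constant beyond the outermost grid points.
   An explicit grid point is added at the final sample.  Grid points with no
   inter-impulse samples in range are omitted and bridged by the spline.
   Subtracting the interpolated tonic yields the phasic data.
2. **Nonnegative deconvolution.**  The phasic data, prefixed with a
   kernel-rise fade-in so they start from zero, are divided by the kernel
   under a nonnegativity constraint: walking left to right, each quotient
   digit is the minimum of the residual-to-divisor ratios over the divisor,
   clipped at zero, and its scaled kernel is subtracted from the residual.
   The final residual is the remainder.  For data exactly generated from a
   nonnegative driver plus a nonnegative extra this reproduces both exactly.
3. **Segmentation.**  Driver and remainder are smoothed (Gaussian,
   sigma = 200 ms) and segmented by peak detection (driver threshold
   0.01 uS; remainder threshold 0.005 uS).  Each remainder deflection is
   allotted to the impulse whose epoch (onset to next onset) contains its
   onset; deflections before the first impulse are discarded, several
   deflections in one epoch are merged (summed area, maximum amplitude,
   flagged).
4. **Reconstruction.**  Each SCR is the convolution of its (raw) driver
   section with the kernel plus its PO segment; amplitudes, areas and
   latencies are measured on these non-overlapped waveforms.  SCRs below
   0.01 uS are dropped; PO components below 0.005 uS are detached (both
   thresholds inclusive).  Amplitudes are reported raw and as log(1 + a)
   (natural logarithm, recorded in the output metadata).

## Numerical choices

These choices matter in practice and are where this implementation makes its
own decisions; each was validated on synthetic recordings with known ground
truth (see the test suite).

* **Stable tonic-stage deconvolution.**  The long-division recursion that
  inverts the truncated kernel (`standard_deconvolve`) is kept for its exact
  algebraic contract, but it is marginally unstable and diverges on noisy
  recordings beyond ~10^4 samples.  The tonic stage therefore uses the
  closed-form AR(2) whitening inverse of the biexponential
  (`biexponential_inverse`), which is unconditionally stable at the price of
  a relative error of the order of the truncated tail area (~1e-4).
* **Smoothing before the tonic-stage inverse.**  Deconvolution amplifies
  wideband sample noise by `1/(h[0] dt)` (~1.5e4 at 32 Hz); since both
  operations are LTI, smoothing the data first is the identical operator to
  smoothing the driver afterwards and avoids the amplification.  The tonic
  stage smooths with sigma = 1 s by default (`tonic_smooth_sigma`): it only
  carries DC-scale information, and at realistic wideband noise the 200-ms
  window leaves whitened-driver oscillations above the 0.2 uS exclusion
  threshold, which voids entire grid windows.  The phasic stage keeps
  sigma = 200 ms, where latencies matter.
* **Symmetric exclusion and edge margins in the tonic stage.**  Kernel-shape
  deviations whiten into bipolar oscillations, so trough sections are
  excluded alongside peak sections; the outermost 4-sigma margins
  (reflection-contaminated) are excluded as well.  The initial level is
  subtracted before the inverse and added back (a constant is its own driver
  under unit DC gain), which removes the onset transient exactly.
* **Noise floor in the division.**  The greedy minimum inspects residuals up
  to `10 * tau2` ahead, where the divisor is tiny; a single negative noise
  excursion there would clamp the driver to zero everywhere, and no impulse
  could ever be detected on noisy data.  The pipeline therefore stops the
  minimum at the first residual at or below a floor of 4 noise SDs (robustly
  estimated from second differences), never before the kernel's rising limb.
  With a floor of zero — the operation's default — this is algebraically
  identical to the unrestricted minimum, so all exact guarantees are
  unchanged on noise-free data.
* **Onset refinement.**  Smoothing advances every deflection onset by up to
  its window; impulse onsets and offsets are therefore refined to the raw
  driver's support (0.1% of the section maximum) inside each smoothed
  section, which is exact on noise-free data.  Under noise the division
  assigns its first mass only once a response clears the noise floor, so
  onsets lag truth by roughly 0.2-0.35 s at 5 nS white noise — an intrinsic
  property of causal support estimators on this signal scale, consistent
  with the ~250 ms onset-latency spread reported for event-related SCRs.
* **Peak sections.**  Local extrema are found through first-difference sign
  changes with plateaus collapsed; a maximum is significant if it rises by
  the threshold above its preceding *or* following local minimum, and its
  section spans the flanking minima (recording boundaries act as minima).

## Model criterion and optimisation

Model quality combines the discreteness of driver and remainder (sum of
squared above-threshold run lengths over total samples; thresholds 0.2 uS
and 0.005 uS), the number of significant responses `n`, and the RMSE between
raw and recomposed data:

    c = d_driver + d_remainder + w_n * n + w_e * rmse.

Driver discreteness is scored on the smoothed driver (where impulse sections
are defined); remainder discreteness on the raw remainder, where wideband
noise yields only isolated crossings while genuine shape deviations produce
long runs.  The weights default to `w_n = 0.05` and `w_e = 10`, calibrated
once so that one superfluous response costs about as much as a ~0.7-s driver
run: with a much smaller `w_n` a degenerate fast-recovery kernel (tau2 ~ 2),
which absorbs every shape deviation into a fragmented driver, can outscore
the generating kernel.  All weights are config-exposed and echoed in the
output metadata.

The time constants are optimised per recording by multi-start gradient
descent in `(log tau1, log tau2)`: central finite differences with a 5%
relative step, backtracking line search, stopping below 1e-4 relative
improvement or 50 iterations, constrained to `tau1 >= 0.05 s`,
`tau2 <= 300 s`, `tau2/tau1 >= 1.5`.  The four standard starts are
(0.75, 2), (0.75, 20), (0.75, 40), (0.75, 60) s and the lowest-criterion
solution is kept.  The objective is deterministic, so results are exactly
reproducible.  On synthetic recordings (300 s, 10 responses, 5 nS noise,
44% PO rate) both constants are recovered within 20%; `tau1` is weakly
identified — its criterion basin is flat within ~1% of `c` across +-25% —
and individual datasets can favour a displaced optimum, in line with the
large between-subject spread of published rise-constant estimates.

## Synthetic data generator

`scdecomp.synthgen` emulates a startle-probe session: a tonic level with
linear drift and a slow sinusoid; raised-cosine driver bumps (strictly
compact support, so onset/offset ground truth is unambiguous) with
durations ~N(1.6 s, 0.4 s) truncated at 0.3 s and log-scale amplitudes;
stimulus ISIs drawn from {4, 8, 16, 32} s (or uniform onsets with a minimum
separation); optional pore-opening bumps added in conductance space just
before the parent impulse peak with probability 0.441, amplitude about a
third of the parent's diffusion amplitude and duration ~4.3 s; and additive
white Gaussian noise (default SD 5 nS).  Identical spec and seed reproduce
a recording bit for bit, and the generative components are returned so
every pipeline stage can be scored against exact ground truth.

What the generator does **not** emulate: correlated/filtered sensor noise,
respiratory and cardiac modulation of sudomotor activity, habituation
across trials, movement artifacts, and electrode drift nonlinearities.
Passing tests on this generator therefore demonstrate correctness of the
algorithms under the stated model, not robustness to every property of real
recordings; in particular, real acquisition chains lowpass-filter the noise,
which is *more* benign for the deconvolution than the white noise used here.

Test problem sizes (600-s recordings for segmentation and tonic checks,
300-s recordings for the optimisation experiments, 100 randomized signals of
up to 512 samples for the division identities) were chosen as the smallest
sizes at which the statistics of interest stabilise.

## Known limitations

* Onset latencies on noisy data lag the true onset by ~0.2-0.35 s (see
  above); noise-free onsets are exact.
* `tau1` is weakly identified by the compound criterion; multi-start results
  should be inspected (`OptimizationResult.per_start`), and occasional
  datasets converge to a fast-recovery local minimum.
* Exact area conservation of the division holds for recordings whose phasic
  content clears the final ~2 kernel lengths; mass convolved past the edge
  is otherwise unaccounted.
* The tonic estimate inherits a lead of roughly the kernel's first moment
  (~`tau1 + tau2` seconds) on drifting baselines, a property of estimating
  the baseline in driver space; with 100-s grid spacing the induced error is
  well below the grid resolution for physiological drift rates.
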