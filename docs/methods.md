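# Methods

## Signal model and acquisition assumptions

The package models a multi-echo spin-echo acquisition with a long
repetition time. With TR = 4000 ms and tissue T1 at or below 1000 ms the
saturation factor 1 − exp(−TR/T1) is at least 0.98, so the voxel signal
is treated as proton density times pure transverse decay and fitted as

S(θ, t) = Σₑ Aₑ exp(−t/T2ₑ),  e ∈ {1, 2, 3, 4},

sampled on a uniform 30 ms echo grid (61 echoes to 1830 ms for the fruit
protocol; 45 for the default phantom). The fit criterion is the weighted
least-squares form C(θ) = 1/(2σ²) Σ (yₜ − S(θ,t))², where σ is a
per-curve noise scale: for structure-mean curves the standard error of
the region mean, otherwise 1 (plain least squares). Components are
reported in ascending-T2 order; for e = 3 they are interpreted as bound,
semi-bound and free water, with amplitude fractions as relative
contents. R² and RMSE are computed on curves normalised by their
first-echo value, so RMSE lands on the conventional 0–1 scale;
raw-amplitude fits keep physical units internally.

## Synthetic data: what it emulates and what it does not

The phantom generator emulates three things about real low-field MESE
data: per-voxel multi-exponential decay, the uniform TE grid, and the
noise path — independent zero-mean Gaussian noise on the real and
imaginary channels, white across space and echoes, turned Rician by
magnitude reconstruction (Rayleigh in signal-free background). The
default phantom is three concentric annuli centred in the grid, equal
radial thickness spanning 80% of the half-width, every ring at amplitude
250 with T2 = 80/200/600 ms inner to outer; an equal-area variant makes
the foreground mean an exact equal-amplitude three-component mixture.
Ring geometry is irrelevant to inversion correctness (region fits use
region means), so it is configurable. Intensities are floating point
throughout; no bit-depth quantisation is applied.

Not emulated: partial-volume mixing at structure boundaries, spatially
varying coil sensitivity and B0/B1 inhomogeneity, T1 weighting beyond
the long-TR check, stimulated echoes, motion, and spatially correlated
noise. Passing tests on the phantom therefore demonstrate the estimator
chain (noise handling, denoising, inversion) under the stated noise
model, not robustness to acquisition artefacts of a particular scanner.

The six-structure fruit template (`tomato_template`) is a purely
geometric stand-in for a segmented slice (exocarp shell, endocarp ring,
partition spokes, ovary locules, seed clusters, placenta core); real
analyses supply a label map from whatever segmentation is available.
Deep-learning segmentation is out of scope by design — every downstream
computation is independent of how the label map was made.

## Noise estimation and Rician bias

Per-echo noise power is estimated from signal-free background as
σ̂² = mean(M²)/2 (for Rayleigh magnitudes E[M²] = 2σ²); per-echo SNR is
the ratio of mean squared foreground intensity to σ̂². On a constant-σ
stack the signal power decays with TE while σ̂ stays flat, reproducing
the layer-by-layer SNR decline that motivates echo-adaptive smoothing.

Structure-mean curves are extracted with the same second-moment logic:
when the stack's σ is known, y(te) = sqrt(max(mean(M²) − 2σ², 0)) over
the structure. For a homogeneous structure this is an (asymptotically)
unbiased estimate of the true signal, where a plain magnitude mean
flattens at the Rayleigh floor σ√(π/2) once the decay falls below the
noise — which would otherwise bias the slowest fitted T2 upward by tens
of percent at late echoes. With no recorded σ the plain mean is used.
The correction assumes within-structure homogeneity; for strongly mixed
regions it estimates the root-mean-square rather than the mean signal.

## Denoising

Two filters share one core. The layer-wise baseline replaces each voxel
by a weighted average over its spatial search window, with weights from
Gaussian-kernel-weighted patch distances. The echo-aware 3D variant
extends patches along the echo axis — voxel series are strongly
correlated through their common decay — with a separable Gaussian patch
kernel (std `a1` = 1 echo along TE, `a2` = 2 px spatially), and uses a
per-echo bandwidth h(te).

Numerical choices:

* Patch distances are kernel-normalised mean squared differences;
  kernels are clipped and renormalised at borders.
* Weights are w = exp(−max(d − 2σ̂², 0)/h²): the expected distance
  between two identical, equally noisy patches is 2σ̂², so subtracting it
  (floored at zero) gives true matches full weight. With σ̂ = 0 this is
  the plain exponential kernel, so all noiseless fixed-point properties
  hold exactly.
* h(te) = scale · σ̂(te), scale defaulting to 1.0 under compensation,
  made non-decreasing across echoes by a running maximum (late echoes
  are noisier relative to signal and tolerate harder smoothing); a small
  positive floor (1e−8) covers the zero-noise edge case.
* The self-weight is the maximum off-centre weight in the window
  (standard practice; exp(0) = 1 self-weights suppress denoising).
* Defaults: patch radius 2 px / 1 echo, search radius 5 px.

Setting the echo patch radius to 0 with a fixed h reduces the 3D filter
exactly to the per-layer baseline, which is verified in tests. Denoised
stacks are clipped at zero to remain valid magnitudes. No Rician bias
correction happens inside the filter; bias handling lives in region
extraction (above), where the noise level is actually known.

## Inversion engine

Multi-exponential least squares is ill-conditioned: long, curved,
nearly flat valleys where very different parameter vectors fit the curve
almost equally well, plus genuine local minima for e ≥ 2. The engine is
a global stochastic search:

* **Swarm**: 60 particles, 500 iterations, inertia 0.9 → 0.4 linearly,
  c1 = c2 = 2.0. Velocity/position updates clip to the component
  intervals; clipped dimensions get zero velocity.
* **Chaotic coefficients**: r1, r2 evolve by the logistic map
  r′ = 4r(1−r). The map's degenerate values (exact fixed point 0.75,
  inputs outside (0,1)) are reseeded uniformly, which also breaks the
  0.5 → 1 → 0 trap one step after it closes.
* **Immune operators** (every 20 iterations): the top 10% of particles
  by affinity 1/(1+C) are cloned 3× each; clones undergo chaotic
  per-dimension mutation (p = 0.1, replacement within the current
  intervals) and arithmetic crossover (p = 0.5); parents and clones
  compete and the best survive, so the global best never worsens. The
  cadence matters: applied every iteration, elitist selection collapses
  swarm diversity faster than reseeding can restore it.
* **Chaotic reseeding**: each iteration the worst 10% of particles are
  regenerated inside the current intervals, maintaining the population
  spread the probe families below rely on.
* **Receptor correction** of the incumbent best, three probe families
  per iteration, each accepted only if it improves the incumbent:
  directional steps along differences of personal bests (valley
  following), probes shaped by the covariance of the elite cloud
  (curvature anisotropy), and isotropic probes whose radius decays from
  the interval width by four decades over the run (final polish).
* **Variable projection**: the criterion is linear in the amplitudes, so
  probes that jitter the incumbent's T2s in log space (radius decaying
  over the run) get their amplitudes from the closed-form least-squares
  solution, clipped into bounds. This collapses the effective search to
  T2 space and is the single largest accuracy contributor.
* **Adaptive component intervals**: each parameter lives in a physical
  interval — amplitudes in [0, 2·y(first echo)], T2 in non-overlapping
  ascending intervals per component ((1,100], (100,400], (400,2000] ms
  for e = 3, bracketing bound/semi-bound/free water). Every 10
  iterations, if the incumbent's improvement over the window fell below
  0.1% (adaptation on a still-moving incumbent locks in transients), the
  interval edge far from the incumbent moves toward it by |ln m|/γ of
  the width when the normalised margin m ∈ (s, 1), with s = 0.6, γ = 5.
  Intervals only shrink, never exclude the incumbent, and stay
  disjoint.
* **Restarts**: up to 5 independently seeded swarms; the best result is
  kept, stopping early once the residual falls below 1e−9 of the
  noise-scaled signal energy (a solved curve). Voxel-wise mapping uses a
  light budget (25 particles, 150 iterations, 2 restarts).

All randomness flows from a single integer seed through spawned
generator streams; identical inputs and seed give identical results.
Fitted components are sorted by ascending T2 to resolve label switching.

Measured on the reference phantom: noiseless mono fits match the
log-linear oracle to ~1e−7 relative; noiseless tri-exponential fits
recover 80/200/600 ms within 0.02%; under stack-level Rician noise at
first-echo SNR 50 the 20-seed median T2 errors of the mixture fit are
3–7% (these figures are exactly what `tests/test_acceptance.py`
recomputes).

## Echo exclusion

Isolated anomalous echoes (interference spikes) are removed before the
final fit: a provisional bounded least-squares model is fitted, refitted
once with a soft-L1 loss scaled by the robust residual spread (so the
outlier cannot drag the provisional model), and echoes whose absolute
residual exceeds k = 3 times the MAD-based scale are removed, worst
first, capped at 20% of the echoes and never leaving fewer than 2e + 2.
The reduced curve is refitted once. If the curve is too short the
original is returned with a refused flag. The provisional fitter is a
hook, so callers can substitute the swarm engine; the default keeps
preprocessing cheap and deterministic.

Detection has physical limits: an echo whose clean signal has decayed to
the noise floor carries no evidence of corruption, so exclusion
validation corrupts echoes still carrying ≥ 5% of the first-echo signal.

## Degenerate inputs and tie-breaks

Constant curves have undefined R² (reported NaN). Zero total amplitude
makes water-state proportions undefined (error). Zero noise gives an
h-schedule floor rather than division by zero. Per-voxel fit failures in
mapping runs are recorded and masked (NaN), not fatal. Region σ falls
back to 1 when the stack has no recorded noise level.

## Problem sizes

Tests and the acceptance checks run at desk scale chosen once: 256×256
(61 echoes) for noiseless region fits, 128×128 for the mixture-recovery
study, 96×96×45 for the denoising comparison, and strided voxel maps
(~150 voxels per condition). The properties checked — recovery accuracy,
PSNR ordering, spread reduction, SNR monotonicity — do not depend on
grid size beyond sampling noise.

## Known limitations

* The Rician bias correction in region extraction assumes within-region
  homogeneity and a known (or background-estimable) σ.
* Discrete multi-exponential fits, not continuous T2 spectra (no
  inverse-Laplace/NNLS spectrum estimation).
* The immune/receptor-correction operator set follows the family's
  verbal description; where details were open, the choices above were
  fixed empirically on the phantom and are all configurable.
* Tri-exponential component separation degrades when T2s approach the
  interval boundaries or each other; the default intervals assume
  fruit-tissue-like water pools.
* Voxel-wise tri-exponential mapping at full 256² resolution is outside
  the default budgets (use stride, or the light config per voxel).
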