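# Methods

## Problem setting

Multi-slice cardiac cine MRI acquires, for each of S slices and P cardiac
phases, a multi-coil k-space frame. Acceleration keeps one of every R
phase-encode lines (lattice anchored at row 0) plus a centered, fully
sampled ACS block of `n_acs` lines; supported presets pair R = 4/5/6 with
26/30/36 ACS lines. All k-space is centered (DC at `⌊n/2⌋`) and all Fourier
transforms are unitary, so Parseval holds exactly and PSNR is
scale-stable. Indices are 0-based and intervals half-open throughout.

## Interpolation models

All scan-specific models map the zero-filled complex frame, packed as
2·N_coils real channels (`[Re(c0)…Re(cN−1), Im(c0)…Im(cN−1)]`), to the
complete k-space with the same channel count.

**GRAPPA.** For each missing-line offset d ∈ {1,…,R−1} a complex kernel
over 5 acquired ky lines (spaced R apart) × 5 kx taps × all coils is fit to
the ACS by least squares and applied with zero-padded boundaries. The ky
taps are counted in acquired-line units (dilated by R); the alternative
dense-row reading of a "5×5" kernel cannot reach acquired lines for all
offsets at R ≥ 4. Calibration windows slide over *all* ACS row alignments
(standard practice; it multiplies the observation count by R and relies on
shift invariance of the underlying coil mixing). The default Tikhonov factor
is relative: the penalty is `ridge · trace(AᴴA)/n_unknowns` with
`ridge = 1e-6`, stabilizing near-singular ACS systems while leaving
well-posed ones essentially untouched; `ridge = 0` requests the plain
minimum-norm solution. Every target sample is accumulated with a single
`np.dot` per (pixel, coil), fixing the floating-point reduction order so
results are reproducible to the bit across vectorization changes.

**SRAKI / RAKI / rRAKI.** SRAKI is one linear 5×5 convolution (bias, no
activation). RAKI is conv 2N→64 (5×5) + ReLU, 64→32 (1×1) + ReLU,
32→2N (3×3); the hidden widths 64/32 are pinned uniquely by the published
parameter counts at 15 coils (22 530 / 58 814 / 81 344 for
SRAKI / RAKI / rRAKI). rRAKI runs the RAKI stack and a parallel SRAKI layer
and outputs their sum; its loss is `MAE(sum, target) + λ·MAE(linear,
target)` with λ = 1 (the combined-loss composition is not printed in the
source describing the architecture; this form makes the linear path an
explicitly supervised regularizer, and the reported loss is exactly this
combination evaluated at the returned weights).

Training is full batch on a single ACS pair (the ACS is one small tensor):
input = the ACS with rows off the global acquisition lattice zeroed, target
= the full ACS, both divided by the maximum ACS magnitude so the fixed
learning rate behaves uniformly across datasets. The loss is masked to a
valid region excluding half the receptive field per side (margin 2 for
SRAKI, 3 for RAKI/rRAKI) to avoid zero-padding bias. Optimization is Adam
(lr 0.01, β = 0.9/0.999) for 600 epochs with reduce-on-plateau (factor 0.1,
patience 10, relative threshold 1e-3, monitoring the training loss). The
convolution engine is im2col-based numpy (float64) with hand-derived
gradients; initialization draws uniform values scaled by 1/√fan-in from a
seeded stream, and with a fixed seed two runs are bit-identical. A
non-finite loss raises a divergence error naming the epoch. The loss trace
stores the loss before each update plus a final evaluation at the returned
weights (epochs + 1 entries); its running minimum is non-increasing.

Joint training (the ms(9/9) variant) concatenates the per-slice ACS pairs
and averages loss and gradients over them. GRAPPA's shared-calibration
analog stacks the calibration equations of all contributing ACS blocks.

## Strategies and timing

A plan assigns every (slice, phase) frame to exactly one weight set:
`per_frame` (S·P trainings), `mp` (S; one phase per slice), `ms(1/B)`
(one per group of B consecutive slices per phase; trained slice =
`start + (len−1)//2`, so a truncated trailing group of 4 trains its second
slice, giving trained slices {2, 6} for the 1/5 scheme on 9 slices),
`mp_ms` (one per group, default B = 3: 9×23 → 3 trainings vs 207
per-frame). The training phase is the middle phase by default
(deterministic pipelines) or a seeded per-slice/per-group draw. Each stage —
data loading, training/calibration, network evaluation, inverse FFT + SoS —
is wall-clock timed per frame; absolute times are hardware-dependent and
only orderings are ever asserted.

## Metrics

On a nominal 70×70 ROI centered on the heart (intersected with the image
bounds): PSNR = 10·log₁₀(MAX_I²/MSE) with MAX_I the reference ROI maximum
(+∞ sentinel at zero MSE); NMSE = MSE / mean(I²); SSIM is the canonical
three-component (luminance/contrast/structure) product with
c1 = (0.01L)², c2 = (0.03L)², c3 = c2/2 on 7×7 uniform windows fully inside
the ROI, population moments, both images pre-divided by MAX_I (so L = 1).
The equation as often typeset arranges the three factors nonstandardly; the
canonical form from the original SSIM reference is implemented. Aggregates
are mean ± sample std over frames.

Weight stability uses ρ(X, Y) = |Cov(X, Y)| / (σ_X σ_Y) with population
covariance on flattened weight vectors (biases included; GRAPPA complex
matrices interleaved real/imaginary, per-offset in increasing order;
networks layer-by-layer, main path before linear path). The denominator is
computed as √(var_X·var_Y) so the self-correlation is exactly 1.0 in
floating point. Cross-method comparison is not offered (different weight
spaces).

## The phantom

The phantom generates what the strategies exploit, with known ground truth:

* anatomy: a torso ellipse, two lung ellipses, a spine disc, and 12 small
  seeded ellipses (vessel/trabecula analogs) that give the image enough
  high-frequency content for undersampling artifacts to be nontrivial; all
  static across phases. The heart is a smooth-edged disc whose radius runs
  one full cycle, `r(p) = r_min + (r_max − r_min)(1 − cos 2πp/P)/2`, so any
  two phases differ only inside the maximal disc;
* coils: Gaussian-magnitude profiles (σ = 0.30·FOV) with smooth seeded
  phase ramps, centered on a ring of radius 0.55·FOV. Broader profiles make
  the R = 4 system so ill-conditioned that noise amplification swamps the
  reconstruction; the localized choice also better resembles a cardiac
  array. Slice dependence is a rotation of the ring by
  `slice_drift · (s − middle)` radians — profiles are exactly
  phase-constant and drift smoothly across slices;
* `slice_drift` defaults to 0.15 rad/slice, calibrated so the per-frame
  SRAKI weight correlation decays near-linearly from ≈0.93 to ≈0.47 over
  four slices, matching the reported magnitude of inter-slice weight decay;
  no quantitative model of inter-slice sensitivity change exists to copy,
  so the printed decay trend is the calibration target;
* noise: complex Gaussian added in k-space after full sampling (where
  acquisition noise enters physically), std relative to the peak k-space
  magnitude, default 2e-3. The stored coil images / SoS stay noise-free and
  serve as ground truth;
* all randomness flows from one seed through named sub-streams (per slice,
  per purpose), so every array is bit-reproducible;
* default stack: 9 slices × 8 phases × 8 coils at 96×96 — a scaled-down
  short-axis protocol.

What it does **not** emulate: physiological myocardium contrast, ECG
irregularity, respiratory motion, realistic coil coupling/noise
correlation, or gradient-system imperfections. Passing tests demonstrate
the algorithms' correctness and the redundancy mechanisms, not clinical
image quality.

An optional `bandlimit` parameter confines coil spectra to a central b×b
k-space block. With 3×3-bandlimited coils and an object whose spectrum has
a border margin, the linear interpolation model is *exactly* realizable at
R = 2, giving machine-precision recovery oracles. At R ≥ 3 a ±1-line coil
bandwidth cannot see the skipped object rows at all, so exactness is
impossible there by construction — exactness fixtures therefore use R = 2.
The gradient-vs-least-squares comparison uses the same realizable fixture
with a 1% noise floor: with a near-zero optimum the loss ratio is
numerically meaningless, while against a noise-dominated floor it cleanly
measures optimizer quality (and is stable across noise levels 0.5–2% and
seeds).

## Numerical choices and edge cases

* Zero "same" padding in convolutions and kernel application; boundary
  sources outside k-space contribute zeros.
* Data consistency copies acquired rows from the measured data bit-exactly
  and is idempotent; it is applied after every interpolation.
* Normalization rejects all-zero input; calibration rejects ACS blocks too
  small for the kernel geometry and all-zero (singular) systems;
  rank-deficient systems are handled by the minimum-norm solution
  (ridge = 0) or the relative ridge.
* ISMRMRD-style reading normalizes the phase-encode center to `⌊ny/2⌋` by
  shifting the maximum-energy line; only Cartesian fully sampled
  multi-slice cine layouts are supported, anything else is rejected with a
  diagnostic.
* Test and acceptance problem sizes: 32–64 pixel grids, 2–8 coils, 2–9
  slices, 1–23 phases; training checks run the full 600 epochs, plan/count
  checks use 1-epoch trainings since only orderings are asserted. These
  sizes keep the exhaustive suite comfortably reproducible on a laptop
  while exercising every code path at the published hyperparameters.

## Known limitations

* Training is CPU numpy; it is intentionally simple and deterministic, not
  fast. No parallel or GPU path.
* The rRAKI combined-loss composition and the ms(9/9) joint-training
  interpretation ("the weights are averaged") are design choices where the
  source text underdetermines the algorithm; both are isolated behind the
  strategy/network seams.
* Whether biases belong in the correlated weight vectors is unspecified;
  they are included (their contribution is small relative to the kernel
  weights).
* Prospective sampling design (acquiring the ACS only at one slice/phase)
  is out of scope; undersampling here is retrospective.
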