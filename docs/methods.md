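# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `cspress`. Everything stated here is either a design
decision or reproducible with the package's own test suite and experiment
drivers.

## Acquisition model and conventions

Images are `(N, M)` complex arrays on the unit field of view `[-1, 1]²`,
sampled at pixel centers, row index increasing downward. k-space is the
centered unitary 2D DFT of the image (`to_kspace` /`from_kspace`, both
`norm="ortho"` with fftshift on both sides), so the DC bin sits at
`(N//2, M//2)` and energy is identical in both domains to ~1e-15 relative.
Unitarity makes the energy-preserving ratio and all threshold settings
scale-free.

Undersampling is modeled as `F_u x = mask ⊙ FFT(x)`; its adjoint is the
zero-filled inverse. `F_u F_u*` is the identity on the sampled subspace.

## Randomized phantom families

The synthetic-data generator emulates a reference-scan archive: a family of
head phantoms that share gross anatomy but differ in intensity, scale,
position and orientation. Each image is the analytic Shepp-Logan ellipse
phantom (the modified intensity set, `A = 1, -0.8, -0.2, -0.2, 0.1 ...`,
which is the Matlab `phantom` default), rasterized by point-in-ellipse
tests at pixel centers, after perturbing each ellipse's six parameters
`(A, a, b, x0, y0, φ)` with independent zero-mean Gaussian noise of
variances `(0.1, 0.05, 0.05, 0.05, 0.05, 10)` — φ in degrees. Perturbation
subsumes intensity distortion (`A`), anisotropic scaling (`a, b`),
translation (`x0, y0`) and rotation (`φ`). Draws producing non-positive
semi-axes or centers outside the FOV are redrawn (bounded retries), which
slightly truncates the tails for the smallest ellipses. The default study
uses 21 images of 128×128: 20 references and 1 held-out test.

What this does *not* emulate: receive-coil sensitivities, noise in the
acquisition, anatomical texture (phantoms are piecewise constant and hence
unrealistically wavelet-sparse), pulse-sequence contrast, and scanner phase.
The last is supplied separately: `synth_phase` multiplies a magnitude image
by `exp(iφ(x, y))` with φ a random second-order polynomial field recentred
and scaled to the range `[-strength, strength]` radians — a reasonable
stand-in for smooth B0/receive phase, but not for rapid phase transitions
at tissue interfaces. Consequences for interpreting results are flagged
below.

## Sampling design

**iPDF.** Sum of `|K_r|` over reference k-spaces, normalized to unit mass.
For point masks the full 2D map is kept; for line masks it is collapsed to
a per-row profile (readout lines are all-or-nothing). The power-method
comparator uses `|K_r|²` instead.

**Window.** The 2D hamming window is separable with per-axis factor
`0.54 − 0.46 cos(2πm/N)` evaluated at `m = 0..N−1`, giving exactly 1 at the
DC bin (for even `N`) and 0.08 per axis at the corners; it is symmetric
under `m → (N − m) mod N`. The windowed map is `wPDF ∝ iPDF · ω^α`
(renormalized). The multiplicative form is deliberate: it smooths the
selection surface while preserving the energy ranking, and it is the form
under which the energy dominance below holds at every ratio. A
`operator="divide"` variant (`wPDF ∝ iPDF / ω^α`) is provided for
completeness; it pushes probability mass toward the k-space periphery so
aggressively that both captured energy and downstream reconstruction
quality collapse on phantom data, so it is not the default. α defaults to
0.8 for piecewise-constant phantoms; ~1.4 is the sensible starting point
for textured in vivo objects, and `run_alpha_sweep` implements the
trial-and-error sweep (0.5 to 2.0, step 0.1).

**Selection.** Exact top-k of the wPDF (top rows by summed wPDF in line
mode), ties broken by (row, col) order. This is the exact limit of lowering
a threshold level until the point budget is met — no iterative root-finding
on the threshold-count curve is needed, and the resulting masks are nested
in the budget, which makes EPR provably nondecreasing in the sampling
ratio. Every mask always includes a configurable block of central rows
(default 4, counted against the budget) so that symmetric low-frequency
data for phase and support estimation is guaranteed.

**Random comparators.** VD and power masks are drawn by exact-count
weighted sampling without replacement (`Generator.choice` with the map as
weights), so acceleration factors are exact rather than Bernoulli-average.
They can also force the central rows on; the experiment drivers do this so
all methods satisfy the improved cost function's preconditions.

On the default phantom study the measurable consequences, verified by the
acceptance tests across seeds, are: the iPDF correlates with a held-out
test k-space around r ≈ 0.87 (VD p=10: ≈ 0.62), and
EPR(ePRESS) ≥ EPR(VD) and EPR(power) at every ratio in {0.05, ..., 0.5} —
with a thin margin at generous ratios (everything saturates above 0.95) and
a wide one below ratio 0.15.

## Reconstruction

**Sparse transform.** PyWavelets multilevel separable 2D DWT, symmetric
(half-sample) boundary extension, complex images transformed natively.
Defaults: haar at 3 levels for the 128² phantom studies (haar is orthonormal,
so coefficient energy equals image energy); bior4.4 at 6 levels is supported
for textured data (biorthogonal — perfect reconstruction holds, energy
equality does not). Requested depths beyond the boundary-safe maximum are
honored (round trips remain exact to well below 1e-8).

**Phase correction.** `estimate_phase` keeps the `n_central` (default 4)
fully sampled rows around DC, zero-fills the rest, inverse-transforms to a
low-resolution image `Is`, and returns the unit-modulus corrector
`P = exp(−i·angle(Is))`. The solver's state is the *corrected* object
(corrector × zero-filled inverse), which is approximately real and hence
sparser; data consistency maps back to the physical object with the
conjugate (restorer) before comparing with measurements. Getting this
pairing right matters: applying the corrector on both sides double-phases
the object and makes the correction strictly harmful.

**Region of support.** `estimate_support` thresholds the same
low-resolution magnitude at `frac × max` (default 0.05), then binary
closing and hole filling produce a solid projector `S` (idempotent, never
energy-increasing). With only 4 central rows this estimate is loose —
vertical resolution is essentially 4 cycles across the FOV, so `S` covers
the object (≥ 99% of true object pixels on phantoms) but also much
background, and then contributes little. The experiment drivers instead
pass a *tight* support (the known phantom support), standing in for the
coarse prescan or other imaging modality that would supply `S` in practice;
the support constraint is only as useful as that prior is tight.

**ITA.** Zero-filled (phase-corrected) initialization; per iteration:
wavelet hard threshold at `T(k)` (complex magnitude, phase preserved;
coarsest approximation band exempt, since zeroed DC content is
unrecoverable under a decreasing schedule), exact data-consistency
replacement of sampled k-space entries, support projection. The schedule is
linear from `Tᵢ` (default 0.5× the largest detail-coefficient magnitude of
the initial image) to `T_f` (default 0.001×) over `MaxITER` (default 200)
iterations, endpoints exact. Termination: change norm (Frobenius, global)
`≤ F` for `I` consecutive iterations, or the budget. `F` defaults to 0 —
exact stationarity, which still catches the full-sampling limit in a few
iterations — because with a decreasing schedule the iterate converges to a
fixed point of the *current* threshold and then idles until `T(k)` crosses
the next coefficient magnitude; any sizeable `F` fires on such a plateau
and forfeits the rest of the schedule (about a 4× error penalty in the
half-sampling phantom run).

**FISTA baseline.** Monotone accelerated proximal gradient on
`λ‖Ψx‖₁ + ½‖F_u x − y‖²` with unit step (valid: the forward operator is
non-expansive) and complex soft thresholding of *all* bands as the proximal
map; λ defaults to 0.01× the largest detail magnitude of the zero-filled
image. The monotone (best-iterate) variant is used so the recorded
objective is non-increasing by construction; plain FISTA ripples.

## What the phantom experiments do and do not show

- Full-information limits are exact: full sampling is recovered in one
  iteration; at ratio 0.5 the noiseless phantom reconstructs to a median
  error below 1% of the intensity range; reconstruction error is
  monotone in the sampling ratio for nested masks.
- The improved cost function's advantage on phantoms comes almost entirely
  from a *tight* support; phase correction at weak phase
  (|φ| ≲ π/4) is neutral-to-slightly-harmful because the corrector's own
  estimation error (4 rows of vertical resolution) rivals the phase it
  removes. It becomes consistently beneficial for line-mode undersampling
  and for point masks once the object phase is substantial (|φ| ~ π) —
  the regimes partial-Fourier-style correction targets.
- Sampling-pattern rankings under the *conventional* cost function are
  close on phantoms: ePRESS, VD(p=10) and even low-resolution masks all
  capture > 97% of the energy at 4×, and the reconstruction ordering
  between ePRESS and VD varies with the random mask draw and phantom seed.
  The robust, every-seed advantages of the reference-driven design on
  phantom data are the map-to-test correlation and the captured energy;
  on textured in vivo data (where the VD model fits poorly) the
  reconstruction gap would be expected to widen, but no such data ships
  with this package and the claim is not tested here.
- Median-based MAE/MSE saturate at exactly zero when more than half of the
  pixels are exactly recovered — common on piecewise-constant phantoms —
  and should be read accordingly; mean variants are available via
  `statistic="mean"`.

## Problem sizes

Default experiments use 128×128 grids, 20 references, 150 solver
iterations, and 20 seeds for the correlation study; each driver completes
in seconds on a single CPU, and the whole test suite in well under a
minute.

## Known limitations

- No acquisition noise model; EPR and error metrics are noiseless.
- Line masks undersample along one axis only; no 3D mask tensors.
- The support estimator is a heuristic stand-in for an external prior.
- Timing comparisons between solvers are out of scope (hardware-bound).
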