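# cspress

Energy-preserving k-space sampling design and iterative thresholding
reconstruction for compressed-sensing MRI (CS-MRI).

## The problem

CS-MRI shortens scan time by acquiring only a fraction of k-space and
recovering the image by sparsity-regularized reconstruction. Two choices
dominate the result: *where* to sample, and *how* to reconstruct.

Classic variable-density (VD) random sampling draws points from a
parametric probability map `(1 − r)^p` that decays with the distance `r`
from the k-space center. It ignores everything known about the object being
scanned. When previous scans of similar objects (reference scans) are
available, their k-space magnitudes predict where the energy of the next
scan will lie, and sampling can be designed to capture it.

`cspress` implements that reference-driven design — **ePRESS**
(energy-preserving sampling) — together with the standard comparators and a
complete reconstruction stack:

- **Sampling design** (`cspress.sampling`): the initial probability map
  (iPDF) summed from reference k-space magnitudes, the hamming-windowed map
  `wPDF = iPDF · ω(m, n)^α`, and deterministic exact-count threshold
  selection of the highest-probability points (equivalently, lowering a
  threshold level until the sampling budget is met). Comparators: VD with
  exact-count weighted random draws, power-spectrum-driven random sampling,
  and low-resolution (central) sampling. Point masks (two phase-encoding
  axes) and line masks (full readout lines) are both supported.
- **Reconstruction** (`cspress.recon`): the conventional cost function
  `min ‖Ψx‖₁ s.t. ‖F_u x − y‖₂ < ε` solved by a monotone FISTA baseline,
  and the improved cost function (ICF)
  `min ‖Ψx‖₁ s.t. ‖F_u P x − y‖₂ < ε, x = Sx`
  with a unit-modulus phase-correction matrix `P` estimated from the
  symmetric central rows of k-space and a binary region-of-support
  projector `S`, solved by the iterative thresholding algorithm (**ITA**):
  wavelet hard-thresholding with a linearly decreasing threshold schedule
  `T(k) = Tᵢ − (Tᵢ − T_f)/(MaxITER − 1) · (k − 1)`, exact replacement of
  sampled k-space entries, and support projection, per iteration.
- **Phantom data** (`cspress.phantom`): randomized Shepp-Logan families —
  each image rasterized from the canonical ellipse set after zero-mean
  Gaussian perturbation of the six ellipse parameters `(A, a, b, x0, y0, φ)`
  — plus the centered unitary Fourier acquisition model and a synthetic
  smooth phase field to exercise the phase-correction path.
- **Evaluation** (`cspress.metrics`): energy-preserving ratio
  (EPR — the fraction of total k-space energy captured by a mask), 2D and
  row-wise Pearson correlations between a probability map and a test
  k-space, and median absolute / median square error (MAE / MSE) on a 0-255
  intensity scale.
- **Experiment drivers** (`cspress.experiments`) and a CLI (`cspress`).

## Worked example

```sh
$ cspress experiment correlation --out out/
2D correlation with test k-space: ePRESS 0.891, VD 0.680
```

With 20 randomized 128×128 phantom references, the reference-built energy
map predicts the held-out test phantom's k-space magnitude far better
(Pearson r = 0.891) than the parametric VD map with p = 10 (r = 0.680).

```sh
$ cspress experiment epr-sweep --out out/
ratio 0.25: EPR ePRESS 0.9763  VD 0.9753  power 0.9662
ratio 0.10: EPR ePRESS 0.9551  VD 0.9480  power 0.9387
ratio 0.05: EPR ePRESS 0.9184  VD 0.8300  power 0.9140
```

At every sampling ratio the deterministic energy-preserving mask captures
at least as much of the test k-space energy as the random comparators, with
the margin widening as sampling gets scarcer.

```sh
$ cspress experiment recon-compare --out out/
 lowres + CF  MAE 0.553  MSE 0.306  EPR 0.988
 lowres + ICF MAE 0.157  MSE 0.025  EPR 0.988
     vd + CF  MAE 0.515  MSE 0.266  EPR 0.987
     vd + ICF MAE 0.149  MSE 0.022  EPR 0.987
 epress + CF  MAE 0.507  MSE 0.257  EPR 0.987
 epress + ICF MAE 0.161  MSE 0.026  EPR 0.987
```

At 4× acceleration (sampling ratio 0.25) on a phantom carrying synthetic
smooth phase, the improved cost function — phase correction plus a tight
region of support, solved by ITA — cuts the median absolute error roughly
threefold relative to the conventional cost function solved by FISTA, for
every sampling pattern. MAE/MSE are medians over pixels on a 0-255 scale.

The same studies are available as library calls
(`run_phantom_correlation`, `run_epr_sweep`, `run_recon_comparison`,
`run_alpha_sweep`), all pure functions of an `ExperimentConfig`.

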