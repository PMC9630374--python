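# Methods

## Model and pipeline

Every pixel carries a 4×4 real Mueller matrix M with m00 ≥ 0. The pipeline
is purely per-pixel:

1. **Covariance construction.** H(M) = (1/4) Σ_ab m_ab (σ_a ⊗ σ_b*), with
   the Pauli basis in the conventional order (identity, σ_z, σ_x, σ_y).
   H is Hermitian with trace m00; for a physically realizable matrix it is
   positive-semidefinite. This is the standard Cloude construction; it
   reproduces the two analytic fixed points (pure element → spectrum
   (1,0,0,0); ideal depolarizer diag(1,0,0,0) → four equal eigenvalues) and
   makes the two closed forms of the depolarization index coincide.
2. **Eigen-spectrum.** Eigenvalues from `numpy.linalg.eigvalsh`, sorted
   descending, clamped and normalized to unit sum (see Numerical choices).
3. **Observables.** IPPs P₁ = λ̂₀−λ̂₁, P₂ = λ̂₀+λ̂₁−2λ̂₂,
   P₃ = λ̂₀+λ̂₁+λ̂₂−3λ̂₃ from the normalized spectrum; CPs D, P from the
   first row/column of the m00-normalized matrix and P_S as the Frobenius
   norm of the normalized 3×3 submatrix divided by √3 ("2-norm of the
   submatrix" is read as the Frobenius norm — the only reading under which
   the CP and IPP forms of P_Δ agree, which we verify to ~1e-15 on random
   convex sums). All observables are therefore invariant to a global
   intensity rescaling of M.
4. **Coloring.** Euclidean weights or Gaussian memberships over a chosen
   triplet (IPP or CP; always n = 3 observables), clipped to displayable
   RGB in [0, 1]. Masked pixels render black.

The Gaussian membership is deliberately the bare product
Π_j exp(−z_j²) with no 1/2 factor and no normalizing constant: it is a
bounded similarity score with maximum exactly 1 at the class means, not a
probability density.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `clamp_eps` | 1e-8 (× trace) | eigenvalues in [−ε, 0) are treated as measurement noise and set to 0; more negative values additionally flag the pixel as non-physical (a warning, not an error — experimental matrices are only approximately physical) |
| `sigma_floor` | 1e-6 | lower bound on ROI standard deviations; a constant ROI would otherwise make the Gaussian membership divide by zero. Dimensionless, like all observables |
| `degenerate_tol` | 1e-9 | if the two class means coincide in some observable within this tolerance, the Euclidean per-observable scaling is undefined; that observable is dropped with a warning (all degenerate → error) |
| classify `threshold` | 1e-3 | memberships below it export as "unassigned" (−1) in the optional label map; it never affects the RGB rendering. With unit-variance residuals the bare product behaves like exp(−χ²₃), so at 1e-3 roughly 7 % of a class's own pixels fall below it — raise the threshold's value toward 1 to be stricter, lower it to assign more pixels |

ROI standard deviations are sample statistics (ddof = 1), recorded in the
run metadata. ROIs are unions of 0-based, half-open rectangles
(x0, y0, x1, y1); multiple rectangles per class are pooled before the
statistics are taken, which is the recommended way to capture a class whose
appearance varies across the image.

## Synthetic scenes

Real polarimetric tissue data is rarely distributable, so the generator
builds ground-truth scenes from first principles: class matrices are convex
(Cloude) mixtures of pure elements — retarders, diattenuators, rotations,
all derived from Jones matrices, plus the diagonal family diag(1, a, a, a)
whose IPPs, P_S and P_Δ all equal a — laid out as half-planes, stripes
(ring-like structures) or disks on a background (lesions). Element-wise
additive Gaussian noise with scale `noise_sd · m00` stands in for detector
noise; 0.005 (0.5 %) is a realistic default for a well-calibrated imaging
polarimeter. Noisy matrices are intentionally allowed to be slightly
non-physical so the clamping path is exercised.

What the generator does **not** emulate: spatial correlation of noise,
texture within a tissue class, illumination gradients, optical blur, or any
actual light–tissue scattering physics. Passing tests on these scenes
demonstrate that the pipeline computes the defined quantities correctly and
that well-separated classes are recovered; they say nothing about how well
the observables separate real tissue types.

## Numerical choices

* Eigenvalues are clamped at −ε with ε = 1e-8 × trace, then renormalized by
  the clamped sum. Degenerate eigenvalues need no tie-break: the IPPs
  depend only on the sorted values.
* Pixels with m00 = 0 (no light) or zero covariance trace are masked
  invalid, carry 0 in every channel, and render black.
* The CP and IPP forms of P_Δ are both computed; a disagreement beyond
  1e-6 on pixels that passed the realizability check raises a warning. The
  stack stores the CP form.
* Euclidean weights at exactly zero total distance (possible only in
  degenerate geometry) are defined as (1/2, 1/2).
* PNG output quantizes as round(255·c); full pipeline runs with fixed
  inputs and seed are byte-identical.

## Estimator bias near purity boundaries

Under element-wise noise the IPPs are biased estimators wherever the
covariance spectrum is degenerate: sorting the perturbed eigenvalues
systematically widens their spread, so e.g. a pure class's P₁ reads low by
O(noise) and a diag(1, a, a, a) class's P₃ reads high, regardless of how
many pixels are averaged. At 0.5 % noise the bias is ~0.005–0.02 —
irrelevant for coloring and classification (class separations are tens of
noise SDs) but visible whenever ROI means are compared against noiseless
ground truth at the standard-error scale. Recovery checks therefore use an
absolute tolerance (0.02) calibrated to this bias rather than a pure
standard-error bound.

## Known limitations

* No Lu–Chipman or other product decompositions; retardance only enters
  through P_S.
* The Euclidean method is inherently two-class; the CLI refuses more
  classes and points to the Normal method.
* The Normal method is sensitive to non-Gaussian class distributions and
  outliers: under-representative ROI statistics leave large regions black.
  Pooling several ROIs per class mitigates this.
* No automatic ROI discovery, no color spaces beyond RGB, no morphological
  post-processing of label maps.
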