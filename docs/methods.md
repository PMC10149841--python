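# Methods

## Forward model and discretization

Susceptibility χ (ppm) maps to the fractional field shift b (ppm) through
b = Fᴴ D F χ, where F is the unitary 3D FFT (`norm="ortho"`, so Fᴴ = F⁻¹
exactly) and D is the dipole kernel 1/3 − (k·ĥ)²/|k|², evaluated at the
discrete frequencies k_i = n_i/(N_i Δ_i) in cycles/mm. Anisotropic voxel
sizes Δ_i enter per axis; the B0 direction ĥ is configurable (default third
axis). This is the continuous k-space formulation of the kernel; the
discrete-Laplacian variant is not implemented. Two conventions are fixed by
decision rather than by the underlying physics:

* **D(0) := 0.** The analytic expression is undefined at k = 0. Consequence:
  simulated fields have zero mean over the periodic domain, and the volume
  mean of χ is not observable through the data — the IS reconstruction
  recovers it through the support constraint instead.
* **Real output.** Fᴴ(D·Fχ) has a float-noise imaginary residue (D is real
  and even); it is discarded.

On even grid sizes the Nyquist plane stores only one of the aliased ±1/2
frequencies. For an axis-aligned ĥ the kernel is still even under negation
of each frequency axis (D depends on squares only); for oblique ĥ the
cross terms break that per-axis grid symmetry on the Nyquist planes, while
the analytic D(−k) = D(k) symmetry is untouched. Tests check the per-axis
property only for axis-aligned ĥ.

## Supports

The band limit S_k keeps frequency samples with |D| strictly greater than
t_well; a single threshold, no transition band. Strict inequality means
thresholding at max|D| = 2/3 yields an empty support, and t_well = 0 keeps
exactly the samples with D ≠ 0. Because |D| = 0 at k = 0, the band limit
excludes the zero frequency for every t_well > 0; this is documented
behavior, not an error (see above). Mask morphology uses a discrete ball:
integer offsets with Euclidean norm ≤ diameter/2, so "erode/dilate by n
voxels" means a ball of diameter n (diameter 1 = identity, diameter 3 = the
19-voxel ball). An erosion that empties the mask warns rather than raises.

## The incomplete-spectrum solver

The data equation S_k F S_χ χ = S_k ν (ν = D⁻¹Fb on the band limit, exact
zeros elsewhere) is solved via its normal equation with CGLS, applied
matrix-free (two FFTs per iteration). Key numerical choices:

* **Zero initialization.** On singular systems CGLS from zero converges to
  the minimum-norm least-squares solution; the test suite verifies this
  against explicit dense solves to ~1e−12 relative error.
* **Stopping.** Relative residual ‖r‖ ≤ tol·‖ν‖ or relative normal-equation
  residual ‖Aᴴr‖ ≤ tol·‖Aᴴν‖, whichever first, with tol = 1e−6 by default.
  The second criterion matters on inconsistent data, where ‖r‖ plateaus at
  the inconsistency level; without it the recurrence eventually breaks down
  in float arithmetic.
* **Iteration budget: 50 by default.** The input field is masked with S_χ
  before inversion (the method's consistency requirement), which truncates
  the dipole tails of near-boundary sources and makes the system slightly
  inconsistent. CGLS then *semiconverges*: reconstruction quality rises for
  a few tens of iterations and degrades steadily afterwards, as directions
  with small singular values begin fitting the truncation error. On the
  synthetic phantom the quality plateau spans roughly iterations 20–60 on
  both PSNR and XSIM, so the default budget sits inside it. Running to full
  convergence (the true minimum-norm LS solution) is supported — raise
  `max_iter` and tighten `tol` — but is the wrong operating point on noisy
  or truncated data.
* The reconstruction is returned masked by S_χ exactly (it already lies in
  the mask's span; the final multiply makes the support exact at the bit
  level).

t_well = 0.25 is the default band-limit threshold — the XSIM-optimal value
on the simulated benchmark this method was tuned on; at 64³ it retains
about a third of k-space. `threshold_sweep` reports XSIM and PSNR per
threshold plus both arg-max rows, since the two metrics often prefer
different thresholds (PSNR favors smoother, lower-contrast maps).

## Regularized variant and compressed sensing

The regularized IS objective ‖S_kν − S_kFS_χχ‖² + λ‖Ψχ‖₁ and the CS
objective (identical but without S_χ) are minimized by the same monotone
proximal-gradient scheme: gradient steps on the data term with step 1/L
(L = 2 for a projection–FFT operator), soft-thresholding of wavelet
coefficients as the prox, and backtracking halving whenever a step would
increase the objective — so the recorded objective history is non-increasing
by construction. Ψ is a Daubechies-2 wavelet, 3 decomposition levels,
*periodized* boundary handling: periodization keeps the transform
orthonormal, which makes coefficient soft-thresholding the exact proximal
operator. Shapes are padded to a multiple of 2^levels and cropped on
output; the decomposition depth is clamped on small grids. λ = 0 reduces to
plain least squares; at large λ both solvers shrink to zero, and their
solutions approach each other as λ grows (they differ at moderate λ because
the objectives differ by S_χ in the data term — the two coincide exactly
under an all-ones mask, which the tests assert).

## TKD baseline

TKD replaces kernel values with |D| < δ by sign(D)·δ (sign(0) := +1, needed
on the cone zeros) and divides: χ = Re Fᴴ(Fb/D_δ), with δ = 2/3 by default
(the theoretical optimum). The systematic underestimation introduced by the
rescaling is corrected by a single global scalar: the central value of the
effective point-spread function Fᴴ(D/D_δ), with the k = 0 ratio set to 1 so
that an un-thresholded kernel gives exactly c = 1. A spatially varying
deconvolution-style correction would be a drop-in replacement for this
scalar; the global form is the simplest reading of the published
correction.

## Metrics

XSIM is SSIM with susceptibility-tuned constants K1 = 0.01, K2 = 0.001
entering as C_i = (K_i·L)², local moments from a 3D Gaussian window
(σ = 1.5, truncated to a 7³ footprint — standard SSIM practice; the
benchmark's exact window is unpublished, so absolute XSIM values may differ
from published tables by small amounts), averaged over the ROI. The dynamic
range L defaults to the joint (max − min) of both volumes within the ROI:
this keeps the index exactly symmetric in its arguments and coincides with
the reference-only rule whenever the two ranges agree; both alternatives
("reference", explicit float) are exposed in `XsimConfig`. PSNR is
10·log₁₀(peak²/MSE) with peak = (max − min) of the reference within the
ROI and MSE over ROI voxels; identical inputs return +inf. ROI statistics
are mean ± standard error (sample SD/√n; a single-voxel ROI reports SE 0).

## Synthetic phantom

The generator emulates the role of a simulated QSM benchmark: a known
ground truth with deep-gray-matter ROIs, a strong focal calcification, a
brain-like mask, and a forward-simulated noisy field. Concretely: an
ellipsoidal head mask filling ~15% of the FOV (brain masks do not fill the
FOV, and padding improves the conditioning of the space-limited
band-limited operator); bilateral ellipsoidal nuclei — globus pallidus
(0.15 ppm), substantia nigra (0.12), red nucleus (0.10), putamen (0.07),
caudate (0.05), thalamus (0.02) — at anatomically plausible relative
positions; a spherical calcification at −1 ppm near the top of the brain
(the classic streak source); and a smooth seeded susceptibility texture
(0.02 ppm SD, 2.5-voxel correlation length) over the tissue. The χ values
are plausible order-of-magnitude settings, *not* measured values. The
texture matters for evaluation: on a piecewise-constant background the
reference's local variance is zero and SSIM-family indices degenerate into
a pure noise-variance test, which is not how they behave on realistic data.
Sources stop ~3 voxels short of the mask edge, emulating the low-contrast
CSF rim of real brain masks; masking the input field then removes only
far-field tails. Structure centers are jittered by ±0.5 voxel from the
seed. Grids below ~48³ cannot contain the geometry and raise a validation
error.

The field is forward-simulated and degraded with additive Gaussian noise,
σ = rms(noiseless field within mask)/SNR (default SNR 100, seeded), then
masked. Real field maps derive from complex-valued phase fitting, so their
noise is neither Gaussian nor stationary; simulating phase/complex noise is
out of scope. Passing tests on this phantom therefore demonstrate the
solver's algebra, its ordering relative to TKD, and graceful degradation
under mask errors — not performance on anatomically realistic anatomy,
microstructure effects, or realistic noise.

## Problem sizes and limitations

The shipped tests and the acceptance script run at desk scale: 64³ phantoms
(50 CGLS iterations, seconds per reconstruction), 48³ for the
regularization studies, and 8³–10³ grids for dense-oracle comparisons.
Known limitations: single-orientation inversion only (no COSMOS), no
total-variation regularization, no GPU path, isotropic susceptibility only,
NIfTI as the sole volume format, and B0 direction taken from configuration
rather than the NIfTI header. The reconstructed "doubling" of streaks at
the band-limit boundary seen around strong focal sources is a property of
the method (the filled-in spectrum remains band-edged), not an
implementation artifact.
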