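# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic validation does and does not demonstrate.

## Linear mixing model and the LASSO convention

A hyperspectral SRS cube assigns each pixel a spectrum *y* ∈ ℝᴹ over M
Raman shifts. SRS signal is linear in analyte concentration, so *y* is
modeled as a non-negative combination of K reference spectra (the rows
*aₖ* of the library matrix A ∈ ℝ^{K×M}) plus noise. Concentrations are
estimated per pixel by the non-negative LASSO

    c* = argmin_{c ≥ 0} ‖y − Aᵀc‖₂² + λ‖c‖₁ .

Conventions (these determine what a given λ means, and common libraries
differ):

- reference spectra are scaled to unit Euclidean norm when a library is
  constructed, and the applied normalization is recorded on the library
  and in every output manifest;
- the pixel spectrum is **not** normalized;
- the objective carries no 1/(2M) factor.

Under these conventions the default penalty is λ = 0.01. Non-negativity is
enforced by default because negative concentrations are physically
meaningless; `nonneg=False` gives the unconstrained LASSO for comparison.

After channel restriction the library spectra are sliced, **not**
renormalized. Restricted-channel abundances therefore stay on the same
concentration scale as full-spectrum abundances, which is what makes the
SSIM/PSNR comparison between reduced and full results meaningful.

### Solver

Cyclic coordinate descent from c = 0 with a fixed component order; each
update is the one-sided soft threshold cₖ ← max((zₖ − λ/2)/Gₖₖ, 0) with
G = AAᵀ. Convexity plus the fixed order makes the output deterministic.
Convergence is declared when the largest coefficient change in a sweep,
relative to max(1, ‖c‖∞), falls below `tol` (default 1e-10; sweep budget
2000). For an orthonormal library the solution is the closed form
max(aₖᵀy − λ/2, 0); at λ = 0 the solver reduces to non-negative least
squares. Both limits are verified in the test suite against independent
implementations (exhaustive active-set enumeration, projected gradient,
scipy NNLS).

The λ penalty biases abundances downward: on the noiseless default
phantom the exact minimizer differs from ground truth by up to ≈0.021 in
abundance units (the λ-induced bias at λ = 0.01), and the package solver
reproduces that minimizer to ~1e-8. This bias is the price of crosstalk
suppression and is uniform across full-spectrum and reduced-channel fits.

### Protein reference by subtraction

Cultured-cell spectra mix protein and lipid. The cellular-protein
reference is derived by removing an α-scaled unsaturated-lipid spectrum
from the cell spectrum, with α ≥ 0 fit by least squares on the channels
within ±10 cm⁻¹ of the lipid-specific =C-H band (≈3009 cm⁻¹), where
protein contributes least; the clipped residual is renormalized. Fitting α
on a lipid-marker window rather than the full spectrum minimizes protein
leakage into α; the marker position and window are parameters.

## Spectral total-variation denoising

Cubes are denoised before unmixing by the anisotropic ROF problem

    min_u ½‖u − y‖₂² + λ_tv Σ_a ‖D_a u‖₁ ,

with forward differences along the two spatial axes and the spectral axis
(selectable: `all`, `spatial`, `spectral`), Neumann boundaries, and
λ_tv = weight × max(y) so the default weight (0.05) transfers across cube
brightness. The solver is Chambolle-type projected gradient ascent on the
dual (step 1/(4·n_axes)) with a monotone safeguard: an iterate is accepted
only if the primal objective does not increase, otherwise the previous
iterate is returned — so the energy trace is non-increasing by
construction, the output's total variation never exceeds the input's, and
the mean intensity is preserved exactly before the final clip at zero.
Stopping: relative iterate change below `tol` (default 1e-4) or `max_iters`
(200); non-convergence is flagged in the cube's provenance rather than
raised.

Regime note: at the default weight, denoising improves PSNR-to-truth under
strong noise (σ = 0.05 of peak: ≈ +3 dB on the phantom) but over-smooths
when noise is weak (σ = 0.02: ≈ −3 dB). The weight should be chosen
against the measured noise level; denoising is optional in the pipeline
(`--no-denoise`).

## Channel selection (selective spectral sampling)

Backward recursive feature elimination against the full-spectrum result:

1. **Balanced sample.** Each pixel is labeled by its argmax-abundance
   component; 2100 pixels are drawn as 5 equal groups of 420, uniformly
   without replacement per dominant component with a fixed seed. Balancing
   stops abundant components (water) from dominating the selection
   criterion. A component without enough dominant pixels raises an error
   naming it.
2. **Elimination.** Repeatedly, each surviving channel is tentatively
   removed, the sample is re-unmixed on the remaining channels, and the
   MSE between these abundances and the full-spectrum abundances
   (unweighted mean over pixels and components — the sample is already
   balanced) is computed. The channel whose removal yields minimum MSE is
   discarded; ties break toward the lowest wavenumber, making the
   procedure deterministic. The trace of (eliminated channel, MSE) pairs
   is recorded.

MSE is computed on **abundance vectors**, not reconstructed spectra or
rendered images: the quantity the pipeline ultimately reports is the
concentration map, so fidelity is measured there.

Implementation: the tentative re-unmixes of one elimination step share
their pixels, so they are solved as one batched coordinate descent using
rank-1 Gram downdates, warm-started from the current surviving-channel
solution, with two accelerations that do not change the result: (i) each
(candidate, pixel) row is frozen once its sweep step falls below the
tolerance (rows are independent problems), and (ii) every 5 sweeps an
exact active-set finishing step solves the KKT system on each row's
current support and freezes rows whose solution verifies the full KKT
conditions — such a row is at the unique minimizer, so freezing it is
exact. Without the finisher, near-collinear component pairs (protein/ECM,
cosine ≈ 0.98) drive coordinate descent through thousands of sweeps.

The identity of the selected channels is *not* asserted anywhere:
different samples give slightly different but similarly-performing
subsets, because the C-H band profiles are broad and carry redundant
contrast. Tests assert the performance of the selected subset (SSIM/PSNR
of the reduced maps) and exactness on a planted instance where the
informative channels are known by construction.

The acquisition cost model is channels × pixels × dwell time; 45 → 5
channels is a 9.0× speed-up by arithmetic.

## Quality metrics

SSIM uses the standard mean-local form with a 7×7 uniform window and
stabilizers C1 = (0.01·R)², C2 = (0.03·R)² (computed via
scikit-image; an independent windowwise implementation of the formula
serves as the test oracle). PSNR is 10·log₁₀(R²/MSE) with a +∞ sentinel
for identical planes. The dynamic range R per component is the maximum of
the *reference* (full-spectrum) map, keeping PSNR comparable across
channel counts; aggregation over components is an unweighted mean. Both
choices are recorded on every report.

## Tile fusion

Tiles are placed on the nominal grid (pitch = tile − overlap). With
refinement, each tile's translation relative to its left/top neighbor is
estimated on the mean-over-channels image by exhaustive integer-offset
search minimizing the squared difference over the overlap, within ±25% of
the nominal overlap — the window is tiny, so exhaustive matching is exact
and deterministic, and a tile can never move beyond the window.
Registration is translation-only with integer offsets (stage/galvo tiling
has negligible rotation). Blending is a separable linear feather over the
overlap margins, normalized by total weight: non-overlap regions are
copied exactly, and agreeing tiles fuse losslessly.

## Synthetic phantom: what it emulates, and what it does not

Component spectra are sums of Gaussian bands placed near the canonical
C-H features (2850 CH₂ sym, 2880 CH₂ asym, ≈2930 CH₃, 3009 =C-H, and the
broad O-H band centered above the window for water); ECM is the protein
band model uniformly blue-shifted by 8 cm⁻¹, reproducing the
hydrogen-bond/fibril shift that makes the two hardest to separate
(cosine similarity 0.98; library condition number ≈ 17). The default
scene (64×64 px, 45 channels, 2820–3030 cm⁻¹) contains a tumor-cell duct
with a denser necrotic core ringed by ECM, collagen fibers, an adipocyte
with an unsaturated-lipid membrane around a saturated-lipid core, a
cytoplasm patch, a solid-fat deposit, and water everywhere — each
component dominates at least 420 pixels so the balanced sampler works at
its defaults. Truth maps may sum above 1 per pixel (water coexists with
everything); there is no simplex constraint. The cube is the exact linear
mixture plus additive white Gaussian noise (σ relative to peak signal;
default 0.02, seed 17), clipped at zero; generation is bit-reproducible
via a seeded PCG64 generator.

Not emulated: optical point-spread blur, shot-noise scaling with signal,
spectral axis miscalibration, sample-preparation artifacts, and real
tissue texture. Passing tests therefore demonstrate the correctness of
the algorithms under the stated linear-mixture model, not
field performance on tissue cubes.

## Problem sizes and test design

Tests run the study conditions at desk scale: 64×64 phantoms for recovery
and channel selection (the per-pixel problems are independent, so spatial
extent does not change the estimator), 32×32 for the multi-seed denoising
checks, 88×88 for stitching (2×2 tiles of 52×52 with 16-px overlap). The
channel-reduction ladder (45/20/10/5 over ten seeds) re-runs the complete
selection pipeline per seed. Thresholds for the noisy-phantom RMSE, the
noiseless bias bound, the k = 5 SSIM floor and the library condition
number were pre-registered from oracle runs and frozen in
`tests/fixtures/preregistered.json`; tests compare against the frozen
values, never against re-tuned ones.

## Known limitations

- λ is fixed, not selected per dataset; crosstalk/bias trade-off is the
  user's choice.
- The TV weight needs manual matching to the noise level (see above).
- Stitching refines offsets pairwise against the left/top neighbor; there
  is no global consistency optimization, and offsets are integer-pixel.
- The unconstrained (`nonneg=False`) fit clips negatives when stored in
  concentration maps, recording the clipped fraction in metadata.
- Reference spectra are assumed given; endmember extraction is out of
  scope.
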