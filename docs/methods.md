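# Methods

This note records the models, estimators, parameter choices and
numerical conventions behind `topostat`, and what the simulation-based
validation does and does not establish.

## Data model and conventions

An epoched dataset is a `trials × channels × time` array. Time is in
milliseconds relative to stimulus onset (0 = onset) on a uniform grid;
every window specification in the package uses peristimulus ms.
Channel types are EEG, MEG, MEGPLANAR, LFP or Other; LFP/Other channels
are carried through averaging but excluded from image export, and bad
channels are likewise retained in averages and dropped (or interpolated
over) only when images are made. Condition labels match by exact,
case-sensitive string equality, so no two conditions are ever silently
merged. The 2D layout lives on the unit head disc (apex at the origin),
produced from 3D sensor positions by azimuthal-equidistant projection:
planar radius proportional to polar angle from the apex, azimuth
preserved.

## Image export

Scalp maps use Delaunay triangulation of the good-channel layout
positions with barycentric (piecewise-linear) interpolation; this
reproduces affine fields exactly and leaves pixels outside the convex
hull missing (NaN). The default grid is 64 pixels per spatial
dimension over the layout bounding box plus a 5% margin. Removing
(rather than interpolating) a bad channel masks every pixel whose
nearest channel is that bad channel — distance ties resolve in favour
of the good channel, i.e. toward less masking. The nearest-channel
footprint is a package choice; the hole's exact shape is otherwise
unconstrained.

Layouts are normalized, but smoothing kernels are physical, so the
unit disc radius is mapped to a nominal 100 mm and the time axis keeps
its ms sampling: kernels are specified in mm × mm × ms (Hz × ms for
time-frequency images). Smoothing is separable Gaussian convolution,
kernel truncated at 4σ, with masked renormalization: missing voxels
contribute no kernel mass and stay missing afterwards, and the same
renormalization handles the image border. Kernel choice follows the
matched-filter principle — match the expected extent of dipolar scalp
patterns (order of a few cm); the examples use 8 mm × 8 mm × 8 ms on
the toy montage, a deliberate scaled-down analogue, not a
recommendation for real 10-20 data.

Images are NIfTI-1, float32, NaN as the missing value, pixel sizes in
the pixdim fields and the axis-unit/field/dof metadata in the
description string.

## Time-frequency decomposition

The Morlet wavelet w(t; f) = A·exp(i2πft)·exp(−t²/2σ_t²) with
σ_t = n_cycles/(2πf) is truncated at 5σ_t and normalized to unit total
energy (A chosen so Σ|w|² = 1). The default n_cycles = 7 keeps the
wavelet comfortably above the ~5-cycle stability floor; the frequency
grid is linear with 1 Hz spacing by default. Epoch edges use
reflection padding, and samples within 5σ_t of either edge are flagged
as edge-contaminated in the result. Power (squared magnitude), not
amplitude, is the exported quantity. The wavelet normalization is a
package convention; every ratio- or shape-based property (and all
tests) are invariant to it.

With unit-energy wavelets on a grid of spacing df (Hz) at sampling
step dt (s), summed power across a wide band obeys
Σ_f Σ_t |x∗w_f|² · 2·df·dt ≈ Σ_t x(t)², the discrete Parseval
equivalence used by the energy contrasts and verified to 5% in the
tests.

## Window contrasts

Time-window weights are the indicator of the segment union convolved
with a Gaussian of 8 ms FWHM, normalized to unit sum. A degenerate
segment (t1 = t2) therefore reduces exactly to an 8 ms-FWHM Gaussian —
the single-time-point convention — and the same formula extends the
8 ms edge to finite windows, an extrapolation the package makes
explicit rather than leaving the edge width undefined. Band = 0 means
a weighted temporal average (which can legitimately be zero for a
polarity-reversing response); a nonzero band builds Morlet projectors
at 1 Hz spacing, n_cycles = 7, and accumulates window-weighted power.
Modes: `evoked` applies projectors to the trial average, `induced`
averages per-trial energies (capturing non-phase-locked activity),
`trials` returns per-trial values. By Jensen's inequality evoked ≤
induced for any ensemble; the trials-mode mean equals the induced value
identically. These contrasts accept any labelled time-series ensemble
(channels here; reconstructed sources would work identically), which is
what makes them testable without a source model.

## GLM and random field theory

Per voxel, β̂ = X⁺Y, σ̂² = RSS/ν with ν = n − rank(X); voxels missing
in any image are masked everywhere. Designs: one-sample (ones),
two-sample (two indicators), paired (condition indicators + subject
blocks; 2n images, rank n+1). t and F statistics use the generalized
inverse of X'X; estimability of a contrast is checked against the row
space of X.

Corrected peak inference uses the expected Euler characteristic
P(max ≥ u) ≈ Σ_{d=0..D} R_d ρ_d(u) with the standard Gaussian EC
densities (e.g. ρ₂ = (4ln2)/(2π)^{3/2}·u·e^{−u²/2}) and their t- and
F-field counterparts from the unified RFT results. Internal
consistency is enforced by the exact identity
ρ_d^F(u²; 1, ν) = 2·ρ_d^t(u; ν) — the excursion set of a 1-df F field
above u² is the two-sided excursion of the t field — asserted
numerically for d = 0..3, and by Monte-Carlo calibration (below).
Because the EC expansion only approximates the max tail in its
decreasing range, the reported p is floored at the uncorrected tail
probability, frozen below a Gaussian-equivalent threshold of 2.5 (where
the expansion is not a probability at all), capped at 1, and finally
min-ed with the Bonferroni p over the mask. The min(RFT, Bonferroni)
rule keeps the procedure valid at low smoothness, where Bonferroni is
the sharper of the two.

Smoothness is estimated from residuals standardized to unit sum of
squares per voxel: λ_j is the sum over images, averaged over in-mask
voxel pairs, of squared first differences along dimension j, and
FWHM_j = √(4ln2/λ_j). For white noise λ_j ≈ 2 (FWHM ≈ 1.18 voxels);
for noise convolved with a Gaussian kernel the estimator returns the
kernel FWHM, with a small negative discretization bias (≈1–2% at
FWHM 6–8). No small-sample bias correction is applied; estimates are
meant for ≥ 20 residual images. Resel counts: R_D = (mask voxels)/∏FWHM_j;
lower orders from the mask bounding-box edge lengths in FWHM units
(R₁ = ΣL_j, R₂ = Σ_{j<k}L_jL_k) — exact for cuboid masks, a
bounding-box approximation for irregular ones (the exact counting
algorithm for irregular masks is deliberately out of scope).

Cluster-level p-values use the Gaussian-field extent approximation:
E[m] = ΣR_dρ_d(u_c), P(extent ≥ k) = exp(−β·k_resels^{2/D}) with
β = [Γ(D/2+1)·E[m]/E[n_resels]]^{2/D}, and
p = 1 − exp(−E[m]·P(extent ≥ k)); t/F cluster-forming thresholds are
probit-transformed to the Gaussian scale first (a standard, simple
choice, validated by the same null simulations). Local maxima use
8-connectivity in 2D and 18-connectivity in 3D, ties kept in
first-index order; window-restricted (small-volume) searches recompute
the resel counts on the restricted mask. The default corrected
significance level is α = 0.05, and the default cluster-forming
threshold is uncorrected p = 0.001.

## Coregistration and surfaces

Landmark fitting is closed-form orthogonal Procrustes (SVD) with the
determinant sign guarded, so a reflection is never returned — mirrored
inputs yield a proper rotation with a large reported residual. ICP
iterates nearest-neighbour correspondence to the target vertices,
rigid fit, apply; the RMS is non-increasing by construction, and
iteration stops when it improves by less than 1e-6 m (default) or at
50 iterations — both caps are package defaults, chosen to be well past
convergence on head-sized problems. Correspondence is to vertices, not
to surface points; at icosphere level-4 density (~6 mm spacing on a
9 cm head) this recovers small rigid perturbations exactly when
initialized by a landmark fit, which is how the algorithm is meant to
be used — ICP refines a good initial estimate, it does not search
globally, and a symmetric (spherical) target leaves rotation
unidentifiable in principle. Icospheres subdivide the regular
icosahedron (each triangle into four, midpoints deduplicated and
re-projected), giving 10·4^L + 2 vertices; level 4 = 2562, the
canonical head-surface resolution. Units are meters internally.

## Synthetic data

The generator is the package's ground truth. Montages are Fibonacci
spirals on the upper hemisphere of a 9 cm sphere with nasion/left/right
preauricular fiducials. Effects are sums of signed Gaussian bumps over
layout distance (a ± pair mimics a dipolar topography) with Gaussian
temporal envelopes, optionally carrying an oscillation whose phase is
fixed (phase-locked) or uniform per trial (induced). Noise is AR(1) in
time (marginal SD as specified, independent of the AR coefficient) with
exp(−d/ℓ) spatial correlation over the layout, jitter-regularized by
1e-8 on the diagonal. Null volumes are white Gaussian noise convolved
with a separable Gaussian kernel on a padded lattice and cropped so
every retained voxel has full kernel support — a genuinely stationary,
non-periodic field (a periodic field has no boundary and would make the
cuboid boundary resel terms overcount) — then scaled by the exact
kernel norm to unit pointwise variance. All generators are pure
functions of (spec, seed), with sub-streams derived via `SeedSequence`.

What the simulations emulate: smooth dipolar-like topographies, ERP
latencies/widths, band-limited induced oscillations, spatially and
temporally correlated sensor noise, and Gaussian null fields of known
smoothness. What they do not: volume conduction from actual dipoles
through a head model, non-Gaussian artefacts (blinks, muscle), 1/f
spectra, nonstationary noise, or between-subject anatomical
variability. Passing tests therefore certify the statistical machinery
under its stated assumptions, not robustness to every property of real
recordings.

## Validation sizes and results

The family-wise error calibration runs 500 null experiments
(32×32×20 images, FWHM 6 voxels, two-sample n = 12/12, F contrast,
α = 0.05), a size chosen to give a binomial SE of ~0.01 at minute-scale
runtime; the empirical FWER lands around 0.03–0.045 — at or slightly
below nominal, the expected mild conservatism of the EC bound at ~95
resels. Smoothness recovery uses 30 volumes of 48×48×20 at FWHM
{4, 6, 8} (recovered within a few percent; the 10% test tolerance
leaves room for the documented discretization bias). The Parseval and
evoked/induced checks use 1 s epochs at 1 kHz with 50 trials at
amplitude SNR 2.

## Known limitations

- Search dimensionality is capped at 3 (reduce 4D time-frequency data
  by channel- or band-averaging first); FDR and permutation inference
  are out of scope.
- Custom design matrices are accepted but only the three standard
  designs are statistically validated.
- The smoothness estimator is biased for < ~20 residual images.
- Resel counts for irregular masks use the bounding-box approximation.
- EEG template scaling and everything involving head models, forward
  computation or source reconstruction is out of scope; the rigid
  transforms produced here are inputs to such pipelines, not
  replacements for them.
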