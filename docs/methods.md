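# Methods

This note documents the models, the estimator conventions, the synthetic
ground truth, and the numerical choices behind `onoffmap`, in the order the
pipeline runs them.

## Stimulus and response model

The sparse-noise ensemble is an 18 × 8 grid of ~8° tiles; each presentation
independently sets every tile bright (p = 0.1), dark (p = 0.1) or gray
(p = 0.8), flashed 166 ms at 1 s⁻¹ while the microscope runs at 15.6 Hz.
A 25-minute session therefore yields 1500 presentations, with a per-tile
bright (or dark) count of 150 ± 11.6 (binomial mean ± SD).  The ensemble is
stored one row per flashed image with the onset microscope frame; the flash
is collapsed to its onset frame because all kernel math indexes delay from
onset.  Tile indexing is row-major and 0-based, (row, col) = (elevation,
azimuth), azimuth increasing rightward; this convention is used everywhere.

Responses are linear–nonlinear–Poisson.  Per presentation the drive of a
linear cell is `max(⟨ON map, bright tiles⟩ + ⟨OFF map, dark tiles⟩, 0)`;
complex cells sum two separately rectified subunits so that co-centred ON
and OFF kernels emerge without spatial antagonism.  Event counts are
Poisson(gain · drive), placed `delay` frames (default 5) after onset, on top
of Poisson baseline noise in every frame.  The rectified-linear subunit is a
modelling choice — the response nonlinearity of these neurons is not
constrained by the data the analysis consumes — and `noise_model="none"`
replaces both draws with their expectations for exact impulse-style checks.

**Operating point.**  Kernel signal-to-noise is governed by `gain` (events
per unit drive over 150 qualifying presentations) while the significance
statistic S (below) is governed by gain relative to the spontaneous
baseline.  The defaults gain = 2.0, baseline = 0.08 events/frame put the
median peak S of mono-contrast cells at ≈ 10 with ≥ 90 % class recovery and
≥ 95 % mono-label accuracy; they were chosen as the generator's reference
condition, not per-test.

## Ground-truth populations

The bias field b(y₁, y₂) ∈ [−1, 1] is a sum of signed Gaussian bumps
(default 6 bumps of amplitude 0.8, length scale 20°, balanced signs) plus an
optional constant imbalance, clipped to [−1, 1].  Mono-contrast RF centres
are drawn with density ∝ (1 + b) for ON and (1 − b) for OFF by rejection
sampling; a bias saturated at ±1 makes the opposite polarity's density
unnormalizable and raises an error.  Cortical positions are an affine image
of the visual centre (the 144 × 64° stimulated field maps onto the
900 × 540 µm field of view, ≈ 6–8 µm/°) plus Gaussian scatter — 40 µm for
ON, 25 µm for OFF, encoding the larger retinotopic scatter of ON cells —
and a depth drawn from 6 optical planes spaced 30 µm from 150 µm.

Simple cells pool up to 3 nearest mono ON and 3 nearest mono OFF cells
(3-D cortical distance, the same metric the analysis uses, so the
neighbourhood model has an exactly recoverable truth), with weights from a
sparse Dirichlet(0.3) prior.  A candidate is accepted only when its ON and
OFF sub-region centroids are ≥ 0.9 component sigmas apart (safely above the
0.5 classification boundary); complex cells get co-centred ON/OFF Gaussians
(separation 0).  Mono RF maps are isotropic Gaussians of σ = 6° sampled at
tile centres.  Default population sizes (450 ON, 900 OFF, 150 simple, 150
complex) match the median volume of the bundled thirteen-dataset reference
table, whose pooled composition is 55 % OFF, 27 % ON, 18 % dual.

What the generator does *not* emulate: eye movements, running-state
modulation, calcium-indicator dynamics and deconvolution artefacts, spatial
correlations in noise, and non-Gaussian RF shapes.  Green tests therefore
demonstrate correctness of the estimators under the stated statistical
structure, not robustness to those real-data features.

## Kernel estimation and classification

Kernels are raw event-triggered averages over delays 0..15 (one second at
15.6 Hz); no smoothing is applied.  A tile never flashed in a state is
flagged and imputed as 0.  ‖·‖ is the Frobenius norm; `S(t) = ‖K(t)‖/‖K(0)‖`
is anchored at the pre-response frame exactly as defined, with argmax ties
broken toward the smaller delay.  If ‖K(0)‖ = 0 but signal exists elsewhere
(a noiseless-simulation artefact), the denominator is floored at a
machine-epsilon multiple of the largest norm and logged; an all-zero stack
is a degenerate baseline and the cell is classified NONE.

The Gaussian fit is an elliptical (rotatable) Gaussian with constant
offset, initialised from image moments, solved by bounded trust-region
least squares with an analytic Jacobian; the centre is constrained within
one tile beyond the grid, sigmas within [0.2, max(rows, cols)] tiles.
Variance explained is 1 − SS_res/SS_tot; non-convergence marks the fit
failed with VE 0.  Rotation and offset are configurable because the
original fitting protocol underdetermines them; the defaults (both on) are
recorded here.

Significance per polarity: max S > 5 **and** VE ≥ 0.5.  Normalised distance
divides the distance between fitted centres by the mean over the two fits
of each fit's mean principal sigma (the symmetric reading of "average
standard deviation"); > 0.5 is simple, ≤ 0.5 complex.  Cells with no
significant kernel are excluded downstream.  Fits are skipped for
polarities already failing the norm test, which cannot become significant.

## Density maps, shuffle nulls, level sets

Densities are means of isotropic Gaussian bumps, no edge correction;
bandwidths σ = 30 µm in native cortical space and σ = 0.25 in canonical
space (the n^(−1/5) rule of thumb at n ≈ 500).  Native maps use a 10 µm
grid over the 900 × 540 µm field padded by 2σ; canonical maps a 0.05 grid
over [−2.5, 2.5]².  Depth is projected out everywhere except the split-half
test, which splits the population into the lower and upper halves of its
optical planes.

Significance is pointwise: for each of n_shuffles (default 1000) label
permutations with group sizes fixed, the difference map is recomputed; the
envelopes at each node are the k-th extreme order statistics with
k = ⌊α · n_shuffles⌋ (min/max at α = 0.001 with 1000 shuffles).  No
family-wise correction is applied, matching the level-set construction;
this is recorded in the output metadata.  When n_shuffles cannot resolve α
the code warns and clamps α to 1/n_shuffles.  Level sets are
marching-squares contours of the significance indicator on a zero-padded
array (so boundary regions close along the grid edge) at level ≈ 1, which
places the contour essentially through flagged node centres; areas use the
shoelace formula in physical units.  Reported domain areas are stable to
within 10 % under halving of the grid spacing.

## Canonical correlation alignment

CCA is solved by SVD of the whitened cross-covariance
`Sxx^(−1/2) Sxy Syy^(−1/2)`; projections use the row-vector convention
`x̂ = (x − x̄)A` with A 3 × 2 and B 2 × 2.  Canonical variables have unit
sample variance (ddof = 1) and non-matching pairs are uncorrelated to
numerical precision; correlations are non-negative and descending by the
SVD itself, which also makes the fit deterministic.  Depth x₃ is included
on the cortical side so the projection can absorb a tilt of the imaging
plane.  Exactly constant coordinates are rejected as rank-deficient with
the offending column named.  The alignment stage uses mono-contrast cells
only (each contributes one centre); per-polarity CCA fits support the
ON-vs-OFF scatter comparison, whose across-dataset test is a paired
Wilcoxon sign-rank over the per-dataset (ρ₁, ρ₂) pairs.  The
cortical–visual map correlation is computed over the full canonical grid
(a data-supported subregion would change r; the full grid is the default
and is what the outputs record), with p from joint label shuffles
recomputing both maps, two-sided on |r|, using the (1 + hits)/(N + 1)
estimator.

## Neighbourhood model

The design matrix holds flattened peak-delay neighbour maps, ON with
positive and OFF with negative sign, so the non-negative solution builds an
ON − OFF field; no per-map normalisation is applied (weights absorb scale).
k counts neighbours per polarity (k ON and k OFF), selected by 3-D
Euclidean cortical distance with ties broken by cell id; a depth-projected
2-D option and a pooled-2k option exist behind flags since both phrasing
choices are defensible.  Weights come from active-set NNLS; fit quality is
the Pearson correlation between model and measured RF.  n₉₀ is the smallest
number of same-polarity neighbours whose normalised weights sum to ≥ 0.9.
The k-sweep reports the smallest k whose median fit correlation is within
ε = 0.02 (configurable) of the maximum.  Neighbour-distance comparisons
report all k neighbours by default, with a nonzero-weight-only variant
behind a flag.

A structural property worth knowing: under a *uniform* input density the
correlation between μ_on − μ_off and μ_s saturates well below 1 even
noiselessly, because each simple cell draws a fixed number of components —
local excesses of one polarity (exactly what μ_on − μ_off expresses) are
partially equalised by selection competition.  The correlation is
nevertheless consistently positive and highly significant, and grows with
the number of simple cells; tests assert significance and a positive r
rather than r ≈ 1.

## Orchestration and reproducibility

`run_pipeline` executes simulate → kernels → native domains → CCA →
canonical maps → neighbourhood model.  The master seed fans out one
independent SeedSequence-derived stream per stage, so changing one stage's
seed leaves the others untouched; identical configs reproduce identical
output digests, and stages are resumed from disk when their outputs exist
under the same configuration hash.  Units are fixed at the I/O boundary
(cortical µm, visual degrees, canonical dimensionless, delays in frames
with the frame rate in metadata).  Validation fails loudly: missing
columns, NaN coordinates, truncated archives and unknown format versions
all raise with the offending item named.

Problem sizes: the default pipeline simulates 1650 neurons and 1500
presentations with 1000 shuffles.  The test suite runs its Monte-Carlo
calibrations at 50–100 seeds with 200 shuffles and populations of a few
hundred cells — sizes chosen so the binomial error of the asserted rates
stays well inside the asserted margins.

## Known limitations

- Pointwise (per-node) significance means domain masks are liberal under
  multiple comparisons; cluster-mass or max-statistic inference is out of
  scope.
- The KDE has no edge correction, so densities are biased low within ~2σ of
  the imaged-field border; difference maps largely cancel this but level
  sets near the border inherit it.
- CCA is linear and unregularised; it needs ≥ 10 cells and full-rank
  coordinates, and small-n fits overstate ρ.
- The simulator's complex cells are a minimal stand-in (two rectified,
  co-centred subunits); they exercise the classifier, not complex-cell
  physiology.
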