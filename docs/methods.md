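# Methods

This note documents the models implemented in `chronospeckle`, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions a user should know before
trusting a result.

## Damped-cosine decomposition (matrix pencil)

A uniformly sampled series `x_0..x_{n-1}` is modeled as a sum of
exponentially damped cosines plus aperiodic (infinite-period) trend
terms. The solver builds the Hankel matrix `Y[i,j] = x[i+j]` of shape
`(n−L) × (L+1)` with pencil parameter `L = ⌊n/2⌋`, takes its SVD, keeps
the `M` right singular vectors whose singular values exceed
`rank_tol × σ_max`, and solves the shift-invariance eigenproblem
`pinv(V1) V2` whose eigenvalues are the signal poles
`z_j = d_j·e^{iω_j}`. Complex-conjugate pairs merge into one real
cosine with period `T = 2π·Δt/ω`, per-sample damping `d = |z|`, and
amplitude/phase from a least-squares Vandermonde solve against the data.
Real positive poles are reported as trend terms; real negative poles as
Nyquist (period `2Δt`) oscillations.

Properties that the tests pin down: noiseless inputs with up to
`⌊(n−1)/2⌋` components reconstruct to `< 10⁻⁶·max|x|`; on the two-day
design (2-h sampling, 48 h) the median period error of a sustained 12-h
component under 10%-of-amplitude noise is below 1%.

**Model order (`rank_tol`).** The default `1e-3` is appropriate for
clean or lightly noisy series of ~24 samples. For long noisy records
(e.g. 192-frame imaging series) that threshold admits many noise poles,
and because components are ranked by their cosine coefficient at the
first sample, a large-amplitude fast-decaying transient can outrank the
sustained rhythm of interest. For such data use `rank_tol = 1e-2`, which
restores the sustained component as dominant; this is the setting used
by the movie-analysis tests.

**Damping convention.** The decay windows used for classification
(0.8–1.2) act on the per-sample damping at the dataset's native Δt,
matching their use on 2-h-sampled data; `decay_per_hour()` converts
(`d^(1/Δt)`) when series at different sampling rates must be compared.
A sustained oscillation has `d ≈ 1` under either convention.

**Classification.** Windows are inclusive at both ends: circadian
= period ∈ [21, 25] h, ultradian12 = period ∈ [10.5, 13.5] h, both with
decay ∈ [0.8, 1.2]; everything else is `other`. The dominant component
is the finite-period component of largest amplitude, ties broken toward
the shorter period. Amplitude means the cosine coefficient (half the
peak-to-trough swing).

**Permutation FDR.** One common random permutation of the time order is
applied to every series per round (preserving cross-series dependence),
the labeled-call count is recomputed, and FDR = mean permuted count /
observed count, clipped to [0, 1], with FDR = 1 when nothing was called.
B defaults to 1000 and must be ≥ 100; the seed is mandatory. Note the
estimate's stability depends on the observed count: panels with few
series and a near-boundary null rate give noisy ratios. At 2-h sampling
of 24 points the null call rate of the 12-h window is ≈ 5%; at 1-h
sampling of 48 points it drops to ≈ 2%, and to ≈ 0.5% at 0.5-h sampling,
because the permutation null spreads dominant periods over a much larger
frequency range.

**Detrending** is plain least-squares polynomial regression (degree 2 by
default where used), returned as (trend, residual) with exact
reconstruction; it is idempotent. Raw values — not spline fits — feed
the pencil for time-lapse data.

## Processing-rate inversion

The kinetic model is first-order conversion of pre-mRNA to mature mRNA
with constant decay: `dm/dt = k_p(t)·p(t) − k_d·m(t)`, inverted
pointwise as `k_p = (dm/dt + k_d·m)/p`. Steps:

1. **Densify** p and m from the 2-h grid to 0.25 h by spline
   regression. Default is the interpolating cubic spline (exact at the
   knots — correct for noiseless data). For noisy data pass
   `smoothing="gcv"` (roughness penalty chosen by generalized
   cross-validation) or a fixed penalty; interpolation through noise
   otherwise amplifies it catastrophically in the derivative.
2. **Differentiate** by the forward difference at the dense step,
   `[m(t+0.25) − m(t)]/0.25`. This carries a deliberate small bias
   (≈ `0.125·m''`, ~3% of k_p on the default simulation) that is part of
   the method's definition.
3. **Divide** by `max(p, p_floor)` with `p_floor` defaulting to 1% of
   the median positive p. Points with `p < p_floor`, and points where
   k_p comes out negative (a diagnostic of the constant-k_d assumption
   failing), are **flagged, never clipped or altered**.

`k_d` comes from a per-gene lookup table when available, else 0.1 h⁻¹.
Units are per hour throughout.

**Accuracy envelope.** On the default simulated conditions
(k_p = 0.2·(1 + 0.5·cos 2πt/12), constant or 12-h-rhythmic p, k_d = 0.1)
the noiseless round trip has relative RMSE < 5% and > 90% of genes are
re-labeled ultradian12. Under 10% multiplicative log-normal observation
noise the median relative RMSE is ≈ 0.23 with GCV smoothing. This is an
information-limited regime, not a tuning artifact: with k_d = 0.1 h⁻¹
and ω = 2π/12 h⁻¹ the ODE attenuates the k_p rhythm to a relative
amplitude of `0.5·k_d/|k_d + iω| ≈ 9.4%` in m(t) — the same size as the
noise — and the error budget is dominated by the derivative term. Treat
single-gene k_p estimates from noisy data as qualitative
(rhythm/phase/label) rather than quantitative point estimates; the
12-h labeling itself is far more robust than the pointwise values.

The rhythm summary decomposes log2 k_p on the dense grid, reports the
amplitude and acrophase of the largest component inside the 12-h window
(NaN when none), and labels the series by its dominant component.
Flagged or non-positive interior points are bridged by linear
interpolation because the pencil needs a uniform grid; leading/trailing
bad points are trimmed.

## Read counting and coverage

Counting is per gene and per read: any aligned base overlapping an
intron makes the read intronic (junction-spanning reads are intronic by
definition); reads touching only exons are exonic, and a spliced read
across several exons of one gene counts once. A read overlapping two
genes counts independently for each. Counts normalize to FPKM
(`count / (len/10³) / (total/10⁶)`) against exonic and intronic feature
lengths respectively. Coordinates are 0-based half-open internally; GTF
(1-based closed) is converted at read time. Strandedness of counting is
not modeled (unstranded default; the underlying rules are
strand-agnostic).

Gene-body integration takes the length-weighted mean of a bedGraph
track over the gene span ± 10 kb (missing bases count as zero coverage),
clipped at chromosome bounds. Metagene matrices use fixed-width flank
bins and length-scaled body bins (defaults 50/200/50, figure-scale
resolution); minus-strand rows are reversed so the TSS is always left.

## Speckle morphometry

Sphericity is `2·sqrt(π·area)/perimeter` — the square root of the
isoperimetric quotient — 1 for a circle and → 0 for a line. Area and
perimeter come from the 0.5-level marching-squares contour of each
segmented component. The mask is smoothed with a Gaussian of σ = 1 px
before contour extraction: the raw contour of a hard binary mask
staircases along pixel diagonals and overestimates a disk's perimeter by
7–14%, which would drag disk sphericity to ≈ 0.93; with smoothing,
rasterized disks score 0.990–0.995 across radii 5–80 px (< 1% spread)
and elongated shapes are unbiased. Very thin regions that vanish under
smoothing fall back to the raw contour.

Segmentation is deliberately simple: per-nucleus Otsu threshold (or a
fixed value), 8-connected components, minimum area 4 px². There is no
cross-frame tracking; temporal series are per-frame weighted means, and
the population series averages the cells present in each frame. Cells
with no detected speckles report NaN (missing), never 0.

## FRAP

Normalization is `(bleached − background)/(reference − background)`
pointwise, which cancels acquisition photobleaching that affects both
signal channels proportionally. Fits use `scipy.optimize.curve_fit`
with data-derived initial values (offset from the first frame, plateau
from the tail, rate from a log-linear fit of the residual gain) and
three perturbed restarts per model; plain (unadjusted) R² selects
between single and double exponential, with ties within 10⁻⁶ going to
the simpler model. Rates are bounded below at `ln2/(50·t_max)` so the
fit stays identifiable and the double-model half-life bracket is finite;
the double-model half-life is found by root bracketing to 10⁻⁶ s. A
trace with no net recovery raises a fit error rather than returning a
number. Defaults mirror a 1.29-s × 50-frame acquisition but any grid is
accepted.

Under 2%-of-plateau Gaussian noise the median half-life error over 100
simulated single-exponential traces is below 5%. Note that with noise
the double model (which nests the single) is sometimes selected on a
marginal R² gain; its half-life remains accurate, which is why the
half-life — not the model label — is the reported summary statistic.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* of the study designs — 48-h
courses at 2-h sampling with superposed damped cosines; pre/mature pairs
forward-integrated from the first-order model (fixed-step RK4 at 0.01 h,
verified against an adaptive solver to < 0.1%); toy genomes with block
reads of four known categories; two-regime speckle images (disjoint
anti-aliased disks vs thresholded Gaussian random fields, σ = 3 px,
75th-percentile threshold); three-channel FRAP traces with optional
linear reference photobleaching. Expression noise is multiplicative
log-normal (sd on the log2 scale) so values stay positive for the
kinetic division; plain series use additive Gaussian noise. Every
generator is deterministic under its seed.

Not emulated: sequencing error, PCR duplicates, alignment artifacts,
multimapping, microscope PSF/3-D structure, cell movement or division,
bleach-spot geometry. Passing tests therefore demonstrate correctness of
the *analysis* under the stated models, not robustness to every artifact
of real data.

Default simulation conditions (chosen once, as realistic for this
biology): k_p baseline 0.2 h⁻¹ with relative 12-h amplitude 0.5 (a
three-fold peak-to-trough swing, consistent with the two- to three-fold
protein-level oscillations this system shows), constant pre-mRNA
baseline 1.0 in arbitrary expression units, k_d = 0.1 h⁻¹, m(0) at
steady state. The movie generator alternates regimes every half period
(a 12-h morphology square wave over 48 h at 15-min frames) with nuclei
fixed across frames and speckles re-randomized per frame.

## Reproducibility

Pipeline runs are driven by a single YAML config; every stochastic stage
derives its streams from the config seed, stages communicate only
through files, and the manifest records the package version and SHA-256
of every output. Re-running an identical config reproduces byte-identical
tables.

## Known limitations

- The pencil requires strictly uniform sampling; non-uniform series are
  rejected (no Lomb-Scargle fallback by design).
- Per-sample damping windows make classifications sampling-rate
  dependent; compare series at a common Δt or via `decay_per_hour`.
- k_p inversion assumes constant k_d within a day; violations surface as
  flagged negative rates rather than being hidden.
- The FDR estimator's null rate depends on series length and sampling;
  small panels give coarse FDR values.
- Segmentation quality on real micrographs will depend on background and
  nucleus masking; all thresholds are exposed as parameters.
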