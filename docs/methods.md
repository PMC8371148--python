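# Methods

## The measurement being modeled

A microwell-array immunoblot separates, for each single cell, monomeric
proteins from their polymeric complexes by bi-directional gel
electrophoresis: monomers (G-actin, vimentin monomer) migrate to one side of
the well, depolymerized complexes (F-actin, microtubules, intermediate
filaments) to the other. After in-gel immunoprobing, a fluorescence scan
shows one approximately Gaussian band per protein state per cell. The
abundance readout is the band's area under the curve (AUC) on the
background-subtracted intensity profile, and the central derived metric is
the polymerization ratio, e.g. F-ratio = F/(F+G).

## Synthetic data generator

`sample_population` draws per-cell quantities from the distributions this
assay family exhibits:

- **Total actin** ~ Gamma(shape, scale); default Gamma(2, 5000) AFU. Protein
  totals in single cells are right-skewed and gamma-like, the signature of
  bursty transcription. The scale is arbitrary (AFU are instrument units);
  the shape-2 default gives the heavy right tail seen in real blots.
- **F-ratio** ~ Normal(0.45, 0.10) truncated to [0, 1] — the population mean
  and sd observed for this metric in epithelial-like cells. F = ratio·total
  and G = total − F, so F + G ≡ total holds exactly per cell.
- **IF-ratio** ~ Normal(0.63, 0.11) truncated to [0, 1]; the vimentin
  monomer column is derived from it.
- **Cross-complex correlation.** F-actin, microtubule and intermediate-
  filament levels are coupled through a Gaussian copula whose latent Pearson
  correlation is 2·sin(πρ/6) of the target Spearman ρ; defaults
  ρ(F,MT) = 0.70, ρ(F,IF) = 0.72, ρ(MT,IF) = 0.59, the values measured in
  vehicle-control cells. F itself is coupled by rank-reordering whole cell
  records (Iman–Conover), which preserves every marginal and the within-cell
  F/G/total identity exactly.
- **Subpopulations** are planted by shifting complex columns by a configured
  number of (population) standard deviations in a randomly chosen fraction
  of cells, with clipping at zero AFU. Note the clip bounds how far a
  *negative* shift can take a subpopulation: a "−4 sd" raw-AFU shift
  saturates near zero and, after z-scoring, lands ~1.6 sd out. Scenarios
  that need exact standardized-space separations should construct matrices
  in z-space directly (as the fishing tests do).

`render_array` draws each band's center from Normal(350, 16) μm and its
Gaussian σ from Normal(66, 8) μm — the measured migration distance and peak
width of the monomer band — and sets amplitude A = AUC/(σ√2π) so band area
equals the cell's AFU exactly. "Peak width" is interpreted as the Gaussian σ
(the parameterization the fit downstream uses). Detector noise is additive
zero-mean Gaussian (scanner read noise; these scans are far from
shot-noise-limited), default sd 5 AFU over a 100 AFU baseline. Pixel size
defaults to 10 μm, a typical microarray-scanner setting. A configurable
fraction of lanes is rendered *dispersed* — the band replaced by a monotone
exponential smear from the well edge, the failure mode of incomplete
solubilization — and the microwell itself is rendered dark. What the
generator does **not** model: optics/PSF blur, photobleaching, diffusive
protein loss, multi-cell well occupancy, spatial illumination gradients.
Passing tests therefore certify the analysis pipeline's correctness on
idealized-but-noisy images, not robustness to every real-image artifact.

## Densitometry

Per image: (1) hot-pixel removal — a pixel exceeding its (2r+1)² window
median by more than a threshold (defaults r = 2, 50 AFU) is replaced by that
median; one-sided by design, since the artifact is bright scanner pixels
(two-sided is available). This single pass is a fixed point in its target
regime (sparse outliers over noise well below the threshold), though not for
dense noise near the threshold. (2) Lane segmentation from the supplied
grid geometry: two ROIs per well, starting one pixel outside the dark well.
(3) Profile extraction: mean across the lane width per axial position,
minus the median of the flanking gutter rows (the baseline estimator; the
assay itself does not prescribe one). (4) Bounded least-squares Gaussian
fit, initialized at A₀ = max, μ₀ = argmax, σ₀ = span/10, b₀ = min, with
μ ∈ [x₀, x₁] and σ ≤ span/2. R² is computed on the background-subtracted
profile. (5) QC gates, replacing interactive quality control with a
deterministic rule set:

- `fit_fail` — no convergence;
- `low_r2` — R² ≤ 0.7;
- `unresolved` — fitted center within two fitted widths of the microwell
  edge. This gate exists because a *bounded single Gaussian fits monotone
  smears well* (R² ≈ 0.93–0.96 for exponential or linear decays), so the R²
  gate alone cannot reject dispersed lanes; physically, a band overlapping
  the injection well is off-target dispersed signal, not a resolved peak.
- `low_snr` — SNR ≤ 3 (strict), SNR = fitted amplitude over the sd of raw
  pixel intensities in the lane block beyond μ + 2σ (the ROI edge). A
  noiseless region reports +inf and passes.
- `manual_reject` — optional explicit veto list, for parity with
  interactive workflows.

AUC is the trapezoidal integral of the background-subtracted profile over
[μ − 2σ, μ + 2σ]; a window spilling past the profile is flagged, not
salvaged. The ±2σ window captures erf(√2) ≈ 95.45% of a Gaussian's area;
`TWO_SIGMA_FRACTION` is exported so users can convert to full-band area.

## Heterogeneity statistics

Quartiles use linear interpolation between order statistics (the common
statistical-software default; all quartile-derived numbers depend on this
convention and it is applied consistently). CQV = (Q₃−Q₁)/(Q₃+Q₁) is the
skew-robust spread measure appropriate for gamma-like expression data.
Pearson's moment skew uses the population σ. The coefficient of variation
across replicate medians uses the population (÷n) standard deviation — the
convention under which three device medians {0.47, 0.42, 0.46} give 4.8%
(≈5%); the sample-sd convention would give 5.9% and is available via
`ddof=1`. Gamma QQ assessment fits by method of moments (closed form,
stable at modest n). Mann–Whitney, Kruskal–Wallis and Spearman are scipy
wrappers; Dunn's post-hoc pairwise rank test (with tie correction and
Šidák family-wise adjustment) is implemented here because no installed
library provides it.

## Cell fishing

Bait selection: each protein complex is z-scored *within its dataset*
(treated and control separately — faithful to the source workflow even
though it mixes scales at pooling; joint standardization is available by
passing `by=None`), then Ward/Euclidean agglomerative clustering proposes
coherent sub-lineages as bait groups.

Each fishing round pools the bait with a ~100-cell candidate subsample and
clusters semi-supervised: Gaussian-kernel affinity exp(−d²/2h²) with h =
median pairwise distance (or a fixed value), symmetric-normalized graph
Laplacian, top-2 non-trivial eigenvectors, and a two-component
Gaussian-mixture EM fit (k-means++ seeding, 5 restarts, tol 10⁻⁶). The
eigenvector rows are **not** rescaled to unit norm: cells weakly connected
to every cluster have near-zero eigenvector mass, and unit-scaling hands
them an essentially random direction that lets bulk outliers co-cluster
with a tight bait group round after round — exactly the stable false
positives the 0.999 capture threshold is meant to exclude. Left at their
natural scale, such cells stay near the origin with the candidate bulk.

A round is valid when EM converges and ≥ 90% of the bait lands in one
component (the round-validity rule for split bait; capture frequency is
normalized by valid rounds participated). Candidates are re-partitioned
into ⌈n/100⌉ near-equal groups every round, so each participates exactly
once per round and meets a fresh context each time — this churn is what
starves coincidental co-clusterers of a sustained 0.999 capture rate while
cells genuinely expressing the bait phenotype are captured in essentially
every round. With the default 3000 rounds, "fished out" (frequency ≥
0.999) effectively requires capture in all but a vanishing fraction of
rounds.

## Joule heating

ΔT(z) = E²σ_c(a²−z²)/(2k) is the steady-state rise of an infinite slab
conductor relative to its surface, maximal at the mid-plane and zero at
|z| = a; no transient behavior is modeled. The default thermal conductivity
k = 0.59 W·m⁻¹·°C⁻¹ (water near room temperature) reproduces the ~6.2 °C
mid-plane rise of a 5 mm slab at 30 V/cm in a 0.13 S/m buffer. For a
0.54 mm-thick gel the same formula gives ~0.07 °C — small enough that
complex-destabilizing heating is negligible, though thinner than published
~0.02 °C figures that presumably fold in additional cooling pathways
(hydrogel lid, glass substrate) outside this model's scope.

## Problem sizes and numerical choices

The test suite exercises 60-cell (120-lane) arrays for densitometry
round-trips, 10⁴-cell populations for marginal checks, 200 seeds × 500
cells for parameter-recovery coverage, and 500-round fishing on 200
candidates — sizes chosen so the full suite runs comfortably on a single
CPU while leaving the statistical margins wide. Gaussian fits use relative
tolerances of 10⁻⁸; fit bounds and initialization are listed above;
degenerate inputs (constant samples, zero variance, empty groups, all-zero
ratios) raise typed errors rather than returning NaN.
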