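# cytoblot

Analysis toolkit for **single-cell cytoskeletal immunoblots**: microwell-array
assays in which each cell is lysed in a complex-stabilizing buffer and its
protein monomers and polymeric complexes are electrophoresed in opposite
directions out of the well, blotted in gel, and immunoprobed. The scanned
image carries one Gaussian band per protein state per cell, and the band's
area under the curve (AUC, in arbitrary fluorescence units) is that cell's
abundance readout.

The package covers the full computational arc of such an experiment:

- **`cytoblot.synthetic`** — generates cell populations with the statistical
  structure this assay family exhibits (gamma-distributed total actin,
  truncated-normal F-actin ratio, copula-coupled F-actin / microtubule /
  intermediate-filament levels, optional planted subpopulations) and renders
  them as 16-bit array images with exact ground truth.
- **`cytoblot.densitometry`** — image → per-cell AFU: hot-pixel median
  filtering, lane segmentation, background-subtracted intensity profiles,
  bounded Gaussian fits, and deterministic quality gates (R² > 0.7,
  SNR > 3, band resolved from the microwell). AUC is integrated within ±2
  fitted peak widths of the center.
- **`cytoblot.stats`** — heterogeneity statistics: the F-actin ratio
  F/(F+G) and intermediate-filament ratio IF/(IF+VIM), quartiles and the
  coefficient of quartile variation CQV = (Q₃−Q₁)/(Q₃+Q₁), Pearson's moment
  skew E[((X−μ)/σ)³], fold changes of medians, Spearman ρ, QQ assessment
  against normal/gamma families, and Mann–Whitney / Kruskal–Wallis +
  Dunn–Šidák wrappers.
- **`cytoblot.fishing`** — subpopulation discovery ("cell fishing"):
  per-dataset z-scoring, Ward/Euclidean hierarchical clustering to pick bait
  groups, then repeated 100-cell subsampling with spectral embedding and
  two-component Gaussian-mixture EM; candidates co-clustering with the bait
  in ≥ 99.9% of rounds are *fished out*.
- **`cytoblot.thermal`** — Joule heating of the electrophoresis slab:
  ΔT(z) = E²σ_c(a²−z²)/(2k), the parabolic steady-state temperature rise
  that explains why a 0.5 mm gel stays cool where a 5 mm slab heats by ~6 °C.
- **`cytoblot.workbench`** + the `cytoblot` CLI — end-to-end orchestration
  (`simulate | quantify | stats | fish | thermal | repro`) with a single
  global seed fanned out deterministically per stage.

## Worked example

```python
from cytoblot import synthetic, densitometry, stats

pop = synthetic.PopulationSpec(n_cells=60, seed=12)
cells = synthetic.sample_population(pop)
image, truth = synthetic.render_array(cells, synthetic.RenderSpec(grid=(10, 6)), seed=13)
blots, report = densitometry.quantify_array(image)
table = densitometry.blots_to_cell_table(blots, truth)

print(f"lanes quantified: {report.n_lanes}, passing QC: {report.n_pass}, rejects: {report.rejects}")
both = table.dropna(subset=["F", "G"])
fr = both.f_ratio
print(f"F-ratio ({len(both)} cells with both bands): mean {fr.mean():.3f}, sd {fr.std(ddof=1):.3f}, median {fr.median():.3f}")
print(f"F-actin CQV: {stats.cqv(both.F):.3f}")
print(f"F vs G Spearman rho: {stats.spearman(both.F, both.G):.2f}")
```

prints

```
lanes quantified: 120, passing QC: 92, rejects: {'low_r2': 15, 'low_snr': 13}
F-ratio (42 cells with both bands): mean 0.427, sd 0.100, median 0.421
F-actin CQV: 0.293
F vs G Spearman rho: 0.54
```

Reading: 120 lanes (one monomer and one complex lane per cell) were fitted;
28 were rejected by the deterministic QC gates, mirroring how noisy or
unresolved bands are dropped in practice. The 42 cells for which *both*
bands passed give an F-ratio distribution centered near the generator's 0.45
with sd ≈ 0.10; the CQV quantifies the skew-robust spread of F-actin
abundance, and Spearman ρ measures F/G coordination across cells (the
generator couples them at 0.70; losses and QC attrition at n = 42 leave a
noisier estimate).

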