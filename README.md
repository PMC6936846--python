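# octshape

Orientation-invariant shape analysis of the retinal contour in OCT B scans.

Eyes change shape as they elongate: myopic eyes develop irregular posterior
contours, up to frank staphylomata. Optical coherence tomography (OCT)
resolves the retinal surface at micron scale, but every acquired B scan sits
in its own coordinate frame — translated and rotated relative to every
other scan — so raw coordinates cannot be compared across scans, sessions
or eyes. `octshape` quantifies local retinal shape with descriptors that do
not care where in the scan window the retina sits:

* **Vertex curvature `K`.** Each traced contour `z(x)` gets an ordinary
  least-squares quadratic fit `z = a x² + b x + c` (mm units); the curvature
  at the vertex of the fitted parabola is `K = 2a` (mm⁻¹, positive concave
  toward the vitreous, negative for contours convex into the eye, e.g. at a
  staphyloma border). Because long eyes optically distort measured
  curvature, `K` can be corrected through the radius of curvature:
  `r = 1/K`, `r' = r − Δr(AL)`, `K_corr = 1/r'`, with `Δr` evaluated from a
  second-order polynomial through a per-axial-length correction table.
* **Residual Fourier spectrum.** The fit is subtracted, the residual is
  zero-padded (or symmetrically cut) to 1024 samples, and the moduli
  `m_k = (2/n) |Z_k|` of the 30 lowest DFT bins are kept, where `n` is the
  real sample count — so a sinusoidal ripple of amplitude `A` mm reads as a
  modulus of `A` mm whether the retina crosses the whole window or only
  part of it.
* **Deviation features.** Every scan is compared with an average spectrum
  built from eyes other than its own (five axial-length-balanced groups;
  each scan is scored against the mean spectrum of the other four groups,
  per gaze region or pooled). With `d_k = m_k − ref_k`:
  `sumdiff = Σ|d_k|`, `MaxE = max|d_k|`, `rmse = √(mean d_k²)`.
* **Cohort statistics.** Per-eye medians and interquartile ranges of
  `sumdiff`, `MaxE`, `rmse` and `K` are correlated with axial length by
  Spearman's ρ with Fisher-z confidence intervals, Holm-corrected across
  the full table of features × gaze regions; repeat sessions are compared
  with exact Wilcoxon signed-rank tests.

The package also ships a synthetic-cohort generator that renders pixel-space
contour traces with a known, axial-length-linked irregularity structure, so
the entire pipeline is testable end to end without any clinical data.

## Worked example

```python
from octshape import SynthConfig, synth_cohort, run_shape_analysis

cfg = SynthConfig(n_eyes=20,
                  regions=("macula", "posterior inferior", "anterior nasal"),
                  scans_per_cube=7, seed=3)
synth = synth_cohort(cfg)
result = run_shape_analysis(synth.cohort, seed=1)

c = result.correlations
row = c[(c.scope == "all of eye") & (c.feature == "median_sumdiff")].iloc[0]
print(f"eyes: {synth.cohort.n_eyes}, B scans: {synth.cohort.n_scans}")
print(f"median sumdiff vs axial length: rho = {row.rho:.2f} "
      f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}), p = {row.p:.2e}, "
      f"Holm-significant: {row.holm_significant}")
macula = result.region_table[result.region_table.region == "macula"].iloc[0]
print(f"macula: median K = {macula['median_K']:.3f} mm^-1, "
      f"median sumdiff = {macula['median_sumdiff']:.2f} mm")
```

prints

```
eyes: 20, B scans: 420
median sumdiff vs axial length: rho = 0.93 (95% CI 0.81-0.97), p = 2.19e-10, Holm-significant: True
macula: median K = 0.022 mm^-1, median sumdiff = 0.41 mm
```

The generator injected low-frequency contour irregularity whose amplitude
grows linearly with axial length; the pipeline recovers that relationship
as a strong, Holm-significant Spearman correlation between each eye's
median total spectral deviation (`sumdiff`, in mm) and its axial length.
The macular median vertex curvature sits near the 0.02–0.03 mm⁻¹ typical
of fundus-shaped contours.

Real cohorts enter through a manifest CSV naming one two-column
(x-pixel, z-pixel) trace file per B scan plus eye metadata — see
`octshape.load_cohort` — or from the command line:

```bash
octshape synth --n-eyes 20 --seed 3 --out cohort/
octshape analyze --manifest cohort/manifest.csv --out results/ --exclude-eye eye019
```

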