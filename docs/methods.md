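# Methods

## The measurement problem

An OCT B scan images a 9 mm × 2 mm cross-section of the retina on (by
default) a 1024 × 1024 pixel grid; a "cube" is 21 parallel B scans 0.4 mm
apart acquired at one gaze position, and a full protocol covers 17 gaze
regions (the macula plus posterior and anterior cubes in eight directions
of gaze). Each acquisition sits in its own coordinate frame, so any useful
shape statistic must be invariant to translation, rotation and the lateral
position of the retina within the scan window. The pipeline therefore
reduces each traced contour to (i) the curvature at the vertex of its
best-fit parabola and (ii) the modulus spectrum of the residual about that
fit — both unchanged (exactly or to leading order) under the nuisance
transformations above.

## Contour conditioning

Traces arrive as (x-pixel, z-pixel) pairs, z increasing posteriorly.
Duplicate x columns are collapsed to the mean of their z values; gaps in
the integer x sequence are filled by linear interpolation; the result is
converted to millimetres with the window scale factors. Conditioning runs
in pixel space (guaranteeing an exact integer grid) and conversion is
linear, so the order is immaterial to the result. Traces shorter than 16
samples are rejected: the quadratic fit and the spectrum are meaningless on
shorter segments, and a fixed threshold keeps rejection deterministic.
After conditioning, x spacing is exactly one pixel pitch everywhere — an
asserted invariant.

## Descriptors

**Curvature.** For the least-squares quadratic `z = a x² + b x + c`, the
general curvature expression `z'' / (1 + z'²)^{3/2}` reduces at the vertex
(where `z' = 0`) to `K = 2a`. The fit is performed in millimetre
coordinates so `K` is in mm⁻¹ directly. Eye optics bias the measured
curvature in long eyes; the correction converts to radius of curvature,
subtracts an axial-length-dependent `Δr`, and converts back. `Δr` comes
from a user-supplied table (typically tabulated at integer axial lengths
21–28 mm) through a second-order polynomial fit, which also extrapolates
(logged) outside the tabulated range. The package ships no numeric table —
the published correction values are device-specific — so
`CurvatureCorrection.zero()` provides a documented identity placeholder,
and real analyses must supply their own CSV. `K_raw = 0` maps to
`K = 0` (an infinite radius is unchanged by a finite correction); a
corrected radius passing through zero raises and excludes the scan.

**Spectrum.** The residual about the fit is zero-mean by construction
(the fit includes a constant term), which suppresses endpoint-mismatch
contamination of the DFT. It is padded with trailing zeros to 1024 samples,
or, if longer, cut symmetrically (⌊excess/2⌋ from the start, the remainder
from the end). The 1024-point FFT gives moduli on 512 frequencies up to
Nyquist; the 30 lowest bins, including the DC bin (zero-padding
reintroduces a DC component even for a zero-mean residual), form the
descriptor. Moduli are length-corrected as `m_k = (2/n) |Z_k|` with `n` the
real sample count, making them amplitude-like: a full-window sinusoid of
amplitude `A` at an integer bin yields `m = A` exactly, and a half-window
retina's peak modulus stays within ~10% of the full-window value (leakage
spreads, but does not rescale, the peak). Alternative length corrections
(`1/n`, `1024/n`) are selectable for sensitivity analyses.

**Invariances and their limits.** Vertical translation and the lateral
position of the padding are exact invariances (< 1e-9 in practice; the
tests require 1e-6). A pure linear tilt is absorbed exactly by the fit.
Sideways translation of full-window periodic features is a phase change and
leaves integer-bin moduli unchanged; the observable discrepancy (~1e-2 of
the feature amplitude) comes from the small, phase-dependent share of each
sinusoid that the quadratic fit absorbs. The same coupling means an
injected sinusoid is recovered to ~5–10% rather than exactly, most strongly
at the lowest bins.

## Reference construction and deviation features

Eyes are sorted by axial length and each consecutive block of five is
randomly permuted over five groups, so groups are balanced on axial length;
a remainder of `n < 5` eyes lands in `n` distinct groups. The reference for
a scan is the per-bin arithmetic mean spectrum over the B scans of the
other four groups — 80% of the cohort, never containing the scored eye —
built per gaze region ("regional") or pooled ("all"). References average
over scans rather than eyes, weighting eyes by their scan counts; an
eye-level weighting would be a one-line change but is not the default.
Scoring a scan against a profile whose held-out group is not the scan's own
is a contract violation and raises.

Deviations over the 30 bins use absolute differences:
`sumdiff = Σ|d_k|`, `MaxE = max|d_k|`, `rmse = √(mean d_k²)`, giving the
invariants `MaxE ≤ sumdiff ≤ 30·MaxE` and `rmse ≤ MaxE`, checked on
construction. Summaries at cube, eye × region, region and eye level report
the median and IQR of each feature plus the median summed spectrum
(`Σ m_k`, the per-region irregularity magnitude); quartiles use linear
interpolation between order statistics (the numpy default), a convention
that must be fixed explicitly because IQRs of five values differ across
quartile rules.

## Statistics

Spearman's ρ (midranks for ties) is paired per eye with axial length. The
95% CI is `tanh(atanh ρ ± z₀.₉₇₅ · c/√(n−3))` with `c = 1.06`, the
variance-inflation constant appropriate for Spearman's statistic
(`c = 1` recovers the Pearson interval); the two-sided p-value uses the
same z scale. The Holm step-down family is *all* estimable tabulated
correlations — 8 features × (1 all-of-eye + up to 17 regions) — with the
implied smallest threshold `α/m` logged; scopes with fewer than five eyes
or zero variance are reported but excluded from the family. Repeat-session
comparisons take, per eye, the max, min, median and IQR over regions of
each regional descriptor and apply the two-sided Wilcoxon signed-rank test
(exact for ≤ 25 non-zero pairs, zeros dropped; an all-zero comparison is
degenerate and reported as p = 1 with a warning).

## Synthetic cohorts

The generator emulates the acquisition geometry (17 regions, 21 scans per
cube, 9 × 2 mm window, partial-window retinas in anterior regions) and an
axial-length-linked irregularity structure:

* axial lengths uniform on 21.1–36.9 mm, 70 eyes;
* per-cube base curvature `a ~ N(0.013, 0.004)` mm⁻¹, so `K ≈ 0.026`
  matches a typical macular median;
* a per-eye **design amplitude** `A(AL) = 0.03 + 0.008·(AL − 21.1)` mm per
  irregularity bin (bins 2–12), strictly increasing in axial length,
  jittered multiplicatively per eye × region (lognormal, σ = 0.15);
* per scan, each irregularity bin is expressed with probability 0.35 and
  lognormal (σ = 0.3) amplitude scatter, with a random phase, so successive
  slices through the same bumpy region carry different low-frequency
  content;
* per-scan nuisance: lateral placement of a partial window (extent
  0.8–1.0 posterior, 0.45–0.8 anterior), vertical offset, a small linear
  tilt (σ = 0.02) standing in for acquisition rotation, and 5 µm-scale
  axial noise.

The per-scan bin sparsity is load-bearing, not decoration. The deviation
features measure *distance from the cohort-average spectrum*, which is
V-shaped in an eye's own amplitude with its minimum at the reference: if
every scan expressed every bin at its design amplitude, low-AL eyes would
deviate *below* the average as much as high-AL eyes deviate above it and
the AL–sumdiff correlation would vanish. Sparse, scattered expression
dilutes the reference mean to well below every eye's own active-bin
amplitude, so all eyes sit on the rising branch and median `sumdiff` is
monotone in axial length — the structure the method is designed to detect,
and (via scan-to-scan variability of real retinal texture) the plausible
reason the statistic works on real eyes. Sinusoid frequencies are integer
cycles per full window, so noise-free full-window scans round-trip exactly
(`K_raw = 2a` to 1e-9, injected moduli to 1e-3).

What the generator does *not* emulate: real segmentation error and tracing
dropouts, mirror artefacts, eye-specific staphyloma geometry (amplitudes
are stationary within a region), any optics of image formation, and
realistic between-region covariance. Passing recovery tests therefore shows
the pipeline measures what it claims on data with the assumed statistical
structure; it does not validate the biological model. Feature magnitudes
(cohort median `sumdiff` ≈ 0.4–0.5 mm) are deliberately conservative —
about a quarter of what heavily myopic clinical cohorts show — to keep
every rendered trace comfortably inside the 2 mm axial window.

## Problem sizes and numerical choices

The acceptance script runs the full default conditions (70 eyes × 17
regions × 21 scans ≈ 25 000 B scans, ~2 minutes single-threaded); the test
suite uses cohorts of 10–70 eyes over 3–5 regions, chosen so the whole
suite runs in well under a minute while leaving the statistical assertions
comfortable margins. The family-wise error control is estimated by
permuting axial lengths across eyes (200 replicates in the acceptance
script), which nulls the AL–feature association while preserving the
feature covariance; observed flag rates (~0.5–2%) sit below α = 0.05, as
expected for positively dependent tests under Holm. Group assignment,
generation and analysis seeds are independent; every randomised output
records its seed. Repeat-session minimum p-values over the 16 compared
statistics can fall below 0.05 by multiplicity alone; the reliability claim
is the absence of Holm-corrected flags, which is what the tests assert.

## Known limitations

* The curvature correction table is a placeholder (identity) unless the
  user supplies device-appropriate values; corrected and raw `K` are both
  reported so the effect is auditable.
* Length correction of moduli is exactly amplitude-preserving only at
  integer-bin frequencies; partial windows introduce leakage that the 2/n
  rule compensates in scale but not in shape.
* The Fisher-z interval and p-value are large-sample approximations; at
  n < ~15 they are optimistic, and an exact permutation p would be
  preferable (the building blocks are exposed, but it is not the default).
* `sumdiff` and friends are distances from a cohort mean: they cannot
  distinguish "smoother than average" from "rougher than average", and
  their correlation with axial length depends on the cohort's amplitude
  distribution, not only on the per-eye signal.
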