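# Methods

`leaf2dcos` estimates leaf nitrogen content from reflectance spectra
(350–2500 nm, 1 nm grid) by selecting nitrogen-sensitive wavebands with
generalized two-dimensional correlation spectroscopy (2DCOS) and
calibrating regression models on band-level features. This note documents
the model, the numerical choices, and what the synthetic test-bed does and
does not establish.

## The 2DCOS model

Let y(v, t) be reflectance at wavelength v for a leaf whose nitrogen
content is t. Nitrogen plays the role of the external perturbation: the m
spectra are ordered by ascending t and centered on a reference spectrum
ȳ(v) (the mean spectrum by default) to give dynamic spectra
ỹ(v, t) = y(v, t) − ȳ(v). Two maps spread the covariation across a
wavelength × wavelength plane:

- synchronous: ø(v₁, v₂) = ỹ(v₁)ᵀ ỹ(v₂) / (m − 1). With the mean
  reference this is exactly the sample covariance matrix of the spectra
  across the perturbation axis; its diagonal holds the per-wavelength
  variance and its auto-peaks mark the most nitrogen-responsive bands.
- asynchronous: ψ(v₁, v₂) = ỹ(v₁)ᵀ N ỹ(v₂) / (m − 1), with the discrete
  Hilbert–Noda matrix N[j, k] = 1/(π(k − j)) for j ≠ k, zero diagonal.
  ψ is antisymmetric and vanishes identically for perfectly in-phase
  (rank-1) dynamics and always at m = 2.

Sequential-order reading (the v₁ > v₂ convention): same nonzero signs of
ø and ψ at a cross-peak mean v₁ changes before v₂; opposite signs, after;
ψ ≈ 0 means the two bands change together. Because ψ of a noisy but
in-phase system is noise, a cross-peak's asynchronous sign is set to zero
unless its magnitude exceeds the peak-detection threshold fraction of the
map's own maximum — reading a phase off noise would manufacture spurious
"before/after" verdicts.

The continuous formalism behind the dynamic spectrum involves a
perturbation cycle with explicit end points; for a sampled cohort this
collapses to the discrete ordered nitrogen series, which is what the
implementation uses. Ties in nitrogen keep the stable sample-id order
(logged).

## Screening and band selection

Before 2DCOS, wavelengths are screened by Pearson correlation between
reflectance and nitrogen; p-values use the exact t distribution with
n − 2 degrees of freedom, two-sided, with no multiple-testing correction
(the screen is per-wavelength by design and only feeds a region-level
decision). Defaults: α = 0.01; regions are maximal runs of significant
wavelengths at least `min_run` = 5 nm long, which suppresses one-point
"regions". Three regions are excluded regardless of significance:
350–400 nm (instrument noise at the detector edge) and 1362–1458 /
1834–1895 nm (water-vapour and atmospheric absorption dominate leaf
signal there). The exclusion list is configuration, not code.

Auto-peak detection works on the synchronous diagonal. Candidate maxima
must clear both a height and a topographic-prominence floor of 5% of the
diagonal's range (noise ripple on a band shoulder otherwise fragments one
band into slivers). A peak's band extent mirrors how an 8-level contour
map is read: among the equally spaced levels, the band is the contiguous
diagonal stretch at or above the lowest level whose stretch still
encloses only that peak. Eight levels is the conventional contour density
for these spectrograms; band edges snap to the 1 nm grid. Overlapping
auto-peak bands are merged at selection.

## Features and models

Per selected band b and leaf i: Rx = max reflectance in b, Sx = sum of
reflectance over b's integer-nm wavelengths (a plain sum, not trapezoidal
integration — on a uniform closed 1 nm grid the sum is the exact "total
reflectivity" and avoids arbitrary half-weights at band edges).

Two regression families, no hyperparameter search:

- PLSR (NIPALS, via scikit-learn), 2 latent components by default (two
  features per family), reduced with a warning when the calibration
  features are rank-deficient. The fitted model is collapsed to its
  explicit y = b₀ + Σ bᵢxᵢ form for reporting.
- ν-SVR with RBF kernel (libsvm via scikit-learn), fixed at gamma 0.5,
  ν 0.5, cost 1, termination tolerance 0.001; degree/coef0 are accepted
  for interface completeness but inert for RBF, and probability training
  does not affect regression point predictions. Features are not scaled
  by default; a min–max switch exists for sensitivity analysis.

Units. Nitrogen is stored in g·kg⁻¹ throughout the package. Model fitting
happens on the g·(100 g)⁻¹ scale (g·kg⁻¹/10) — the natural scale of the
reported linear coefficients and the one on which the fixed ν-SVR
hyperparameters are usable — and all metrics are mapped back to g·kg⁻¹
(R² is invariant; RMSE scales by 10). A consequence worth knowing: with
unscaled features the RBF kernel is nearly constant over the narrow
dynamic range of Rx (~±0.02 reflectance units), so the fixed-parameter
ν-SVR on Rx stays close to a mean predictor, while on Sx (band sums,
~25× the range) it fits well. This is a property of fixed kernels on
unscaled features, not a defect of either feature family.

Evaluation: R² = 1 − SSres/SStot about the observed mean and RMSE, on
calibration and validation subsets of a uniform random 75/25 split.
Because any single random split is arbitrary and unrecoverable, model
quality is always summarised distributionally: means ± sd over ≥ 50
seeded splits. Rankings order by validation R² (descending), ties broken
by validation RMSE (ascending), stably.

## Synthetic cohort

The generator produces the package's ground-truth test-bed and its
default study conditions: 100 leaves; nitrogen truncated-normal with mean
30.56, sd 1.69, range 26.84–34.75 g·kg⁻¹; additive device noise with
sd 0.002 reflectance units. The baseline curve is a logistic red edge
(midpoint 712 nm) plus Gaussian components for the green peak (550 nm)
and the two SWIR water troughs (1450/1940 nm) over a low visible floor —
the simplest shape family with the right qualitative features; a
radiative-transfer leaf model would add realism that band-selection tests
do not need. Nitrogen enters as a multiplicative amplitude modulation
with compact support (raised-cosine bumps at 548 ± 12 and 713 ± 6 nm,
sensitivity −0.05 per sd of nitrogen, i.e. ~±10% amplitude across the
cohort, consistent with clearly separated group-mean spectra), linear in
nitrogen so the correlation screen is well-posed and exact ground truth
exists: zero nitrogen effect outside the planted bands, correlation
exactly ±1 at band centers when noise is off. One seeded generator stream
draws nitrogen first, then noise, so fixtures are byte-stable.

What passing on synthetic data shows: the 2DCOS/band-selection/modeling
machinery recovers a planted monotone mechanism at realistic noise.
What it does not show: performance on real leaves, where band responses
are non-linear in nitrogen, confounded by water/structure covariation,
and correlations are far weaker (|r| ≈ 0.6 rather than ≈ 0.99); the
synthetic validation R² (~0.97–0.995) is therefore an upper bound of the
machinery, not a field-performance claim.

## Numerical choices and degenerate inputs

- Wavelength grids other than 1 nm steps inside 350–2500 nm are rejected,
  never resampled — downstream indexing stays exact.
- Zero-variance wavelengths have undefined r; they are recorded missing
  (NaN) and can never enter a significant region. Constancy is tested by
  exact equality, since the centered norm of a constant column is fp
  round-off, not zero.
- CSV round-trips are exact: writing uses shortest-round-trip float
  representation and reading parses via strtod (pandas' fast numeric
  path can drop the last ulp and is used only for error detection).
- Sync/async maps satisfy symmetry/antisymmetry to 1e-10 relative and a
  zero ψ diagonal to absolute 1e-14; these are enforced as tests, not by
  post-symmetrisation.
- Stage orchestration writes every intermediate table next to the report
  so each summary number is recomputable; re-run caching is limited to
  the config hash recorded in the report (a six-stage in-memory pipeline
  gains nothing from makefile-style staleness tracking).

## Problem sizes

Default analyses run a 100-leaf cohort, full 2151-wavelength screen,
2DCOS maps over the screened window (tens of wavelengths), and 50-split
model summaries; the complete pipeline takes ~2 s on one core. The
acceptance script uses exactly these sizes.

## Known limitations

- Legacy binary .xls workbooks need an external conversion to .xlsx or
  CSV; the reader names the missing engine explicitly.
- Cross-peaks are searched only between detected auto-peak bands; free
  off-diagonal extrema elsewhere (e.g. against bands outside the analysis
  window) are not enumerated.
- No spectral derivatives, continuum removal, vegetation indices, or
  hetero-spectral 2D variants; the screen operates on raw reflectance.
- The ν-SVR uses the fixed hyperparameters above by design; there is no
  tuning loop, so results on other datasets may favour rescaled features
  (use the min–max switch) rather than different kernels.
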