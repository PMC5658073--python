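# leaf2dcos

Leaf-nitrogen estimation from reflectance spectra via generalized
two-dimensional correlation spectroscopy (2DCOS).

Nitrogen status drives orchard and crop management, but wet-chemistry
determination (Kjeldahl digestion) is slow and destructive. Leaf
reflectance in the visible/near-infrared responds to nitrogen through
pigment absorption, so a spectrum (350–2500 nm) measured with a leaf-clip
spectroradiometer can stand in for the assay — if the few genuinely
nitrogen-sensitive wavebands can be isolated from 2151 collinear channels.
`leaf2dcos` is a library for that workflow: it treats nitrogen content as
the external perturbation of a 2DCOS analysis, selects sensitive wavebands
from the correlation spectrograms, and calibrates regression models on
band-level features.

## Method

For m spectra ordered by nitrogen t and mean-centered into dynamic spectra
ỹ(v, t) = y(v, t) − ȳ(v), the two correlation maps are

    ø(v₁, v₂) = ỹ(v₁)ᵀ ỹ(v₂) / (m − 1)          (synchronous)
    ψ(v₁, v₂) = ỹ(v₁)ᵀ N ỹ(v₂) / (m − 1)        (asynchronous)

with the Hilbert–Noda matrix N[j,k] = 1/(π(k−j)), j ≠ k. Auto-peaks on the
synchronous diagonal mark wavebands whose intensity responds most strongly
to nitrogen; cross-peak signs in ø and ψ encode whether two bands change
together or sequentially (Noda's rules). The pipeline is:

1. **screen** — Pearson r between reflectance and nitrogen per wavelength,
   exact-t p-values, maximal significant runs (α = 0.01), minus excluded
   regions (350–400, 1362–1458, 1834–1895 nm).
2. **2DCOS** — dynamic spectra over the screened window; ø and ψ maps.
3. **bands** — auto-/cross-peak detection with 8-level contour extents;
   sensitive-band selection.
4. **features** — per band and leaf: Rx (max reflectance) and Sx (summed
   reflectance).
5. **models** — PLSR (2 components) and ν-SVR (RBF, γ = 0.5, ν = 0.5,
   C = 1) on random 75/25 calibration/validation splits, reported as
   R²/RMSE means over ≥ 50 seeded splits.

## Worked example

The package ships a seeded synthetic cohort — 100 leaves whose green-peak
(548 nm) and red-edge (713 nm) amplitudes decrease with nitrogen
(truncated-normal, mean 30.56 g·kg⁻¹, sd 1.69) under device noise — so the
whole workflow runs with known ground truth:

```python
import leaf2dcos as l2

spectra, nitrogen, _ = l2.simulate_dataset()
profile = l2.correlation_profile(spectra, nitrogen)
window  = l2.apply_exclusions(l2.significant_regions(profile), l2.DEFAULT_EXCLUSIONS)
maps    = l2.CorrelationMaps.from_dynamic(l2.dynamic_spectra(spectra, nitrogen, window=window))
bands   = l2.select_bands(l2.detect_autopeaks(maps, n_levels=8))
feats   = l2.compute_features(spectra, bands)
summary = l2.split_family_metrics(feats, nitrogen, seeds=list(range(50)))
```

Running `python examples/04_fit_models.py` prints:

```
PLSR (Rx features, nitrogen in g/100g): y = 7.615 - 15.564·Rx1 - 7.024·Rx2
  single split: R2_cal=0.977  RMSE_cal=0.231 g/kg  R2_val=0.967  RMSE_val=0.294 g/kg

mean metrics over 50 random 75/25 splits (RMSE in g/kg):
  plsr_rx  R2_cal= 0.975  RMSE_cal=0.244  R2_val= 0.970  RMSE_val=0.253
  svr_rx   R2_cal= 0.047  RMSE_cal=1.517  R2_val=-0.001  RMSE_val=1.478
  plsr_sx  R2_cal= 0.997  RMSE_cal=0.089  R2_val= 0.996  RMSE_val=0.095
  svr_sx   R2_cal= 0.996  RMSE_cal=0.100  R2_val= 0.995  RMSE_val=0.104
```

Reading this: the screen and 2DCOS maps recovered the two planted bands
(543–553 and 710–716 nm, within the planted supports); the negative PLSR
coefficients say leaves richer in nitrogen reflect less in both bands; the
split-mean validation R² ≈ 0.97–0.995 shows the planted mechanism is
recovered almost perfectly from held-out leaves. The ν-SVR needs the wider
dynamic range of Sx — with fixed kernel parameters and unscaled features,
the tiny Rx spread leaves its RBF kernel nearly constant (see
`docs/methods.md`). Examples `01`–`05` walk the stages one at a time;
`examples/05_full_pipeline.py` produces the per-stage artifact files and
the ranked report.

Real data enter through the same surface: a wide CSV/XLSX of spectra
(wavelength column + one column per leaf) and a two-column nitrogen table,
via `read_spectra` / `read_nitrogen(..., unit_scale=...)`, or the CLI:

```sh
leaf2dcos simulate default-100 --outdir fixtures
leaf2dcos screen --spectra fixtures/default-100-spectra.csv \
                 --nitrogen fixtures/default-100-nitrogen.csv
leaf2dcos run --outdir runs/demo
```

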