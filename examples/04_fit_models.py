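"""Calibrate and validate nitrogen-estimation models on band features.

For each selected band, Rx (maximum reflectance) and Sx (summed
reflectance) are computed per leaf; PLSR and nu-SVR models are fitted on a
random 75/25 calibration/validation split and summarised as means over 50
splits (the single split behind any one result is arbitrary, so quality is
judged distributionally).
"""

import leaf2dcos as l2

spectra, nitrogen, _ = l2.simulate_dataset()
profile = l2.correlation_profile(spectra, nitrogen)
window = l2.apply_exclusions(l2.significant_regions(profile), l2.DEFAULT_EXCLUSIONS)
maps = l2.CorrelationMaps.from_dynamic(l2.dynamic_spectra(spectra, nitrogen, window=window))
bands = l2.select_bands(l2.detect_autopeaks(maps))
features = l2.compute_features(spectra, bands)

# a single split, to show the explicit linear model PLSR collapses to
split = l2.make_split(features.sample_ids, ratio=0.75, seed=0)
model, metrics = l2.fit_plsr(features, nitrogen, split, components=2, family="rx")
print("PLSR (Rx features, nitrogen in g/100g):", model.equation(["Rx1", "Rx2"]))
print(f"  single split: R2_cal={metrics.r2_cal:.3f}  RMSE_cal={metrics.rmse_cal:.3f} g/kg"
      f"  R2_val={metrics.r2_val:.3f}  RMSE_val={metrics.rmse_val:.3f} g/kg")

summary = l2.split_family_metrics(features, nitrogen, seeds=list(range(50)))
print("\nmean metrics over 50 random 75/25 splits (RMSE in g/kg):")
for name, s in summary.items():
    m = s["mean"]
    print(f"  {name:8s} R2_cal={m['r2_cal']:6.3f}  RMSE_cal={m['rmse_cal']:.3f}"
          f"  R2_val={m['r2_val']:6.3f}  RMSE_val={m['rmse_val']:.3f}")
# negative PLSR coefficients: higher nitrogen -> darker green/red-edge bands.
# The nu-SVR with its fixed RBF hyperparameters needs the larger dynamic
# range of Sx; on the narrow Rx scale its kernel is nearly constant and the
# model stays close to the mean predictor.
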