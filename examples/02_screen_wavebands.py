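"""Correlation screening: which wavelengths track leaf nitrogen?

Pearson r between reflectance and nitrogen is computed at every wavelength
(350-2500 nm); runs of wavelengths significant at p <= 0.01 become
candidate regions, and the device-noise (350-400 nm) and water/atmosphere
(1362-1458, 1834-1895 nm) regions are excluded.
"""

import leaf2dcos as l2

spectra, nitrogen, _ = l2.simulate_dataset()
profile = l2.correlation_profile(spectra, nitrogen)
significant = l2.significant_regions(profile, alpha=0.01, min_run=5)
kept = l2.apply_exclusions(significant, l2.DEFAULT_EXCLUSIONS)

print("significant regions:", ", ".join(str(r) for r in significant))
print("after exclusions:   ", ", ".join(str(r) for r in kept))
wl, r = profile.extreme(within=kept)
print(f"strongest correlation: r = {r:.3f} at {wl} nm")
# the extreme r is negative: leaves richer in nitrogen reflect less light
# in the green and red-edge bands
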