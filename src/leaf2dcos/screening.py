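"""Per-wavelength correlation screening of reflectance against nitrogen.

Each wavelength's reflectance vector across samples is correlated with the
nitrogen series (Pearson r); two-sided p-values come from the exact
t-distribution with n−2 degrees of freedom. Wavelengths whose p-value stays
at or below alpha over a long-enough contiguous run form candidate regions;
device-noise and water/atmosphere regions are then excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import NitrogenTable, SpectrumSet
from .regions import Region, RegionSet


@dataclass
class CorrelationProfile:
    """Pearson r and two-sided p per wavelength; NaN where r is undefined."""

    wavelengths_nm: np.ndarray
    r: np.ndarray
    p: np.ndarray

    def extreme(self, within: RegionSet | None = None) -> tuple[int, float]:
        """(wavelength, r) of the largest |r|, optionally restricted to regions.

        Reported signed: with leaf spectra the strongest nitrogen response is
        typically a negative correlation in the visible bands.
        """
        mask = ~np.isnan(self.r)
        if within is not None:
            in_reg = np.array([within.contains(w) for w in self.wavelengths_nm])
            mask &= in_reg
        if not mask.any():
            raise ValueError("no wavelengths to take the extreme over")
        absr = np.where(mask, np.abs(self.r), -np.inf)
        i = int(np.argmax(absr))
        return int(self.wavelengths_nm[i]), float(self.r[i])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm\tr\tp\n")
            for w, r, p in zip(self.wavelengths_nm, self.r, self.p):
                fh.write(f"{int(w)}\t{r:.10g}\t{p:.10g}\n")


def correlation_profile(
    spectra: SpectrumSet, nitrogen: NitrogenTable
) -> CorrelationProfile:
    """Pearson r (and exact-t p) of reflectance vs nitrogen at every wavelength.

    Zero-variance wavelengths have undefined r; they are recorded as NaN
    (p = NaN) with a warning and are thereby auto-excluded from region
    extraction.
    """
    y = nitrogen.aligned_to(spectra.sample_ids)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 samples for a correlation screen")
    X = spectra.reflectance  # (n, w)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ValueError("nitrogen series has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    # a wavelength is degenerate when every sample has the same value
    # (exact test; the centered norm alone is blurred by fp round-off)
    degenerate = np.all(X == X[0:1], axis=0) | (sx == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance wavelength(s) excluded "
            "from the correlation screen",
            stacklevel=2,
        )
        r[degenerate] = np.nan
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n-2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return CorrelationProfile(spectra.wavelengths_nm.copy(), r, p)


def significant_regions(
    profile: CorrelationProfile, alpha: float = 0.01, min_run: int = 5
) -> RegionSet:
    """Maximal runs of consecutive wavelengths with p <= alpha, length >= min_run."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = np.nan_to_num(profile.p, nan=np.inf) <= alpha
    regions: list[Region] = []
    w = profile.wavelengths_nm
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                regions.append(Region(int(w[start]), int(w[i - 1])))
            start = None
    if start is not None and sig.size - start >= min_run:
        regions.append(Region(int(w[start]), int(w[-1])))
    return RegionSet(regions)


def apply_exclusions(
    regions: RegionSet, exclusions: RegionSet, min_run: int = 5
) -> RegionSet:
    """Interval set-difference; fragments shorter than min_run are dropped."""
    return regions.difference(exclusions, min_width=min_run)
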