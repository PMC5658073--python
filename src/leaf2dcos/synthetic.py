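"""Seeded synthetic leaf spectra with a known nitrogen→reflectance mechanism.

The generator emulates the qualitative shape of a green-leaf reflectance
curve over 350–2500 nm: low visible reflectance with a green reflection
peak near 550 nm and a red absorption trough near 670 nm, a sharp red-edge
rise to a near-infrared plateau, and two short-wave-infrared water troughs
near 1450 and 1940 nm. Nitrogen enters as a multiplicative amplitude
modulation confined to configured "planted" wavebands (compact support), so
downstream band selection has exact ground truth: away from the planted
bands the nitrogen partial effect is identically zero, and at a band center
the pre-noise reflectance is a strictly monotone (linear) function of
nitrogen with the configured sensitivity sign.

This is a statistical test-bed, not a radiative-transfer model: no
biochemical absorption coefficients, no canopy or illumination geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io import NitrogenTable, SpectrumSet, write_nitrogen, write_spectra


@dataclass(frozen=True)
class PlantedBand:
    """A nitrogen-sensitive waveband: support is the closed ±width interval."""

    center_nm: float
    width_nm: float
    sensitivity: float  # fractional amplitude change per 1 sd of nitrogen

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated cohort.

    Nitrogen defaults reproduce the field cohort this package targets:
    100 leaves, mean 30.56 g·kg⁻¹, sd 1.69, range 26.84–34.75 (truncated
    normal). Planted bands default to the green peak and red edge.
    """

    n_samples: int = 100
    nitrogen_mean: float = 30.56  # g/kg
    nitrogen_sd: float = 1.69
    nitrogen_min: float = 26.84
    nitrogen_max: float = 34.75
    bands: tuple[PlantedBand, ...] = (
        PlantedBand(548.0, 12.0, -0.05),
        PlantedBand(713.0, 6.0, -0.05),
    )
    # baseline shape
    visible_level: float = 0.06
    green_peak_height: float = 0.10
    green_peak_center: float = 550.0
    green_peak_sigma: float = 24.0
    red_edge_midpoint: float = 712.0
    red_edge_scale: float = 14.0
    nir_level: float = 0.46
    swir_trough_1450_depth: float = 0.13
    swir_trough_1940_depth: float = 0.24
    noise_sd: float = 0.002
    seed: int = 20170
    wavelength_min: int = 350
    wavelength_max: int = 2500

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.nitrogen_min < self.nitrogen_max:
            raise ValueError("nitrogen range must be positive and ascending")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def baseline_spectrum(wavelengths: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Nitrogen-free leaf reflectance curve (logistic red edge + Gaussians)."""
    v = np.asarray(wavelengths, dtype=float)
    green = cfg.green_peak_height * np.exp(
        -0.5 * ((v - cfg.green_peak_center) / cfg.green_peak_sigma) ** 2
    )
    edge = 1.0 / (1.0 + np.exp(-(v - cfg.red_edge_midpoint) / cfg.red_edge_scale))
    swir_decline = np.clip((v - 1300.0) / (2500.0 - 1300.0), 0.0, 1.0) * 0.12
    trough1 = cfg.swir_trough_1450_depth * np.exp(-0.5 * ((v - 1450.0) / 35.0) ** 2)
    trough2 = cfg.swir_trough_1940_depth * np.exp(-0.5 * ((v - 1940.0) / 55.0) ** 2)
    base = cfg.visible_level + green + (cfg.nir_level - cfg.visible_level) * edge
    base = base - edge * (swir_decline + trough1 + trough2)
    return np.clip(base, 1e-4, 1.0)


def _bump(u: np.ndarray) -> np.ndarray:
    """Raised-cosine bump: 1 at u = 0, smoothly 0 at |u| >= 1 (compact support)."""
    out = np.zeros_like(u, dtype=float)
    inside = np.abs(u) < 1.0
    out[inside] = np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


def band_response(
    wavelengths: np.ndarray, nitrogen: np.ndarray, cfg: SyntheticConfig
) -> np.ndarray:
    """Multiplicative modulation factor per (sample, wavelength).

    The factor is 1 + Σ_b sensitivity_b · z · bump((v − c_b)/w_b) with
    z = (N − mean)/sd, so the effect is linear in nitrogen and exactly zero
    outside every planted band's support.
    """
    v = np.asarray(wavelengths, dtype=float)
    z = (np.asarray(nitrogen, dtype=float) - cfg.nitrogen_mean) / cfg.nitrogen_sd
    factor = np.ones((z.size, v.size))
    for band in cfg.bands:
        shape = _bump((v - band.center_nm) / band.width_nm)
        factor += band.sensitivity * z[:, None] * shape[None, :]
    return factor


def draw_nitrogen(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal nitrogen draws on [min, max] g·kg⁻¹."""
    a = (cfg.nitrogen_min - cfg.nitrogen_mean) / cfg.nitrogen_sd
    b = (cfg.nitrogen_max - cfg.nitrogen_mean) / cfg.nitrogen_sd
    dist = stats.truncnorm(a, b, loc=cfg.nitrogen_mean, scale=cfg.nitrogen_sd)
    return dist.rvs(size=cfg.n_samples, random_state=rng)


def simulate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[SpectrumSet, NitrogenTable, list[PlantedBand]]:
    """Generate a seeded cohort: spectra, nitrogen table and ground-truth bands.

    Draw order (stable across releases): nitrogen values first, then the
    device-noise matrix, from one `default_rng(seed)` stream. Reflectance is
    clipped to [0, 1]; if the pre-clip signal leaves that range a warning
    reports the clipped cell count.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = np.arange(cfg.wavelength_min, cfg.wavelength_max + 1)
    nitrogen = draw_nitrogen(cfg, rng)
    base = baseline_spectrum(wl, cfg)
    signal = band_response(wl, nitrogen, cfg) * base[None, :]
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    n_out = int(np.sum((signal < 0) | (signal > 1)))
    if n_out:
        warnings.warn(f"clipped {n_out} reflectance cell(s) to [0, 1]", stacklevel=2)
    signal = np.clip(signal, 0.0, 1.0)
    ids = [f"s{i + 1:03d}" for i in range(cfg.n_samples)]
    spectra = SpectrumSet(wl, signal, ids)
    table = NitrogenTable(ids, nitrogen)
    return spectra, table, list(cfg.bands)


# hard-coded micro-fixture for exact-arithmetic oracle tests (4 samples x
# 5 wavelengths, 500-504 nm); nitrogen ascends with sample index
TINY_4X5_WAVELENGTHS = [500, 501, 502, 503, 504]
TINY_4X5_REFLECTANCE = [
    [0.10, 0.20, 0.30, 0.25, 0.15],
    [0.12, 0.19, 0.28, 0.24, 0.16],
    [0.11, 0.18, 0.27, 0.22, 0.14],
    [0.09, 0.17, 0.25, 0.21, 0.13],
]
TINY_4X5_NITROGEN = [28.0, 29.5, 31.0, 33.0]


def _tiny_4x5() -> tuple[SpectrumSet, NitrogenTable, list[PlantedBand]]:
    ids = ["t1", "t2", "t3", "t4"]
    return (
        SpectrumSet(np.array(TINY_4X5_WAVELENGTHS), np.array(TINY_4X5_REFLECTANCE), ids),
        NitrogenTable(ids, np.array(TINY_4X5_NITROGEN)),
        [],
    )


FIXTURE_REGISTRY = {
    "tiny-4x5": _tiny_4x5,
    "default-100": lambda: simulate_dataset(SyntheticConfig()),
}


def make_fixture(
    name: str, outdir: str | Path | None = None
) -> tuple[SpectrumSet, NitrogenTable, list[PlantedBand]]:
    """Build a registered fixture; optionally write its files to ``outdir``.

    Writes are deterministic (fixed seeds, fixed float formatting), so the
    same name always produces byte-identical files.
    """
    if name not in FIXTURE_REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURE_REGISTRY)}"
        )
    spectra, nitrogen, bands = FIXTURE_REGISTRY[name]()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, outdir / f"{name}-spectra.csv")
        write_nitrogen(nitrogen, outdir / f"{name}-nitrogen.csv")
        truth = [
            {"center_nm": b.center_nm, "width_nm": b.width_nm, "sensitivity": b.sensitivity}
            for b in bands
        ]
        (outdir / f"{name}-bands.json").write_text(json.dumps(truth, indent=2) + "\n")
    return spectra, nitrogen, bands
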