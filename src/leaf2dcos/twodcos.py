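"""Generalized two-dimensional correlation spectroscopy (2DCOS).

A series of m spectra, ordered by an external perturbation (here the leaf
nitrogen content), is mean-centered into dynamic spectra ỹ(v, t). Two maps
spread the covariation over a wavelength × wavelength plane:

    synchronous   ø(v1, v2) = ỹ(v1)ᵀ ỹ(v2) / (m − 1)
    asynchronous  ψ(v1, v2) = ỹ(v1)ᵀ N ỹ(v2) / (m − 1)

where N is the Hilbert–Noda matrix, N[j, k] = 1 / (π (k − j)) for j ≠ k and
0 on the diagonal. ø is symmetric with per-wavelength variances on its
diagonal; ψ is antisymmetric with a zero diagonal and vanishes whenever the
dynamics are perfectly in phase (rank-1 across the perturbation axis).

Auto-peaks (diagonal maxima of ø) mark perturbation-sensitive wavebands;
cross-peak signs in ø and ψ encode Noda's sequential-order rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import NitrogenTable, SpectrumSet
from .regions import Region, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class DynamicSpectra:
    """Perturbation-ordered, reference-subtracted spectra.

    Rows are sorted by ascending perturbation value; ``values[t, v]`` is the
    observed spectrum minus the reference at wavelength ``v``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray  # (m, w)
    reference: np.ndarray  # (w,)
    perturbation: np.ndarray  # (m,) ascending
    sample_ids: list[str]

    @property
    def m(self) -> int:
        return self.values.shape[0]


def dynamic_spectra(
    spectra: SpectrumSet,
    nitrogen: NitrogenTable,
    window: RegionSet | None = None,
    reference: str | np.ndarray = "mean",
) -> DynamicSpectra:
    """Build the dynamic spectra for a wavelength window.

    The perturbation axis is the sample series sorted by ascending nitrogen;
    ties keep the stable order of the sample ids (logged). Reference is the
    mean spectrum over the analysis set unless a custom spectrum is passed.
    """
    if spectra.n_samples < 2:
        raise ValueError("need >= 2 spectra (m >= 2)")
    t = nitrogen.aligned_to(spectra.sample_ids)
    order = np.argsort(t, kind="stable")
    if np.unique(t).size < t.size:
        logger.info("tied nitrogen values; stable order by sample id used")
    if window is not None and len(window) > 0:
        cols = [spectra.index_of(w) for w in window.wavelengths()]
        wl = spectra.wavelengths_nm[cols]
        X = spectra.reflectance[:, cols]
    else:
        wl = spectra.wavelengths_nm.copy()
        X = spectra.reflectance
    X = X[order]
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean' or a custom spectrum array")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (wl.size,):
            raise ValueError("custom reference length does not match window")
    return DynamicSpectra(
        wavelengths_nm=wl,
        values=X - ref,
        reference=ref,
        perturbation=t[order],
        sample_ids=[spectra.sample_ids[i] for i in order],
    )


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """Discrete Hilbert–Noda matrix: N[j,k] = 1/(π(k−j)), zero diagonal."""
    if m < 1:
        raise ValueError("m must be >= 1")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    N[j == k] = 0.0
    return N


def synchronous_map(dyn: DynamicSpectra) -> np.ndarray:
    """ø = ỹᵀ ỹ / (m − 1): the covariance-like in-phase map."""
    if dyn.m < 2:
        raise ValueError("m must be >= 2")
    Y = dyn.values
    return (Y.T @ Y) / (dyn.m - 1)


def asynchronous_map(dyn: DynamicSpectra) -> np.ndarray:
    """ψ = ỹᵀ N ỹ / (m − 1): the out-of-phase map (antisymmetric)."""
    if dyn.m < 2:
        raise ValueError("m must be >= 2")
    Y = dyn.values
    N = hilbert_noda_matrix(dyn.m)
    return (Y.T @ (N @ Y)) / (dyn.m - 1)


@dataclass
class CorrelationMaps:
    wavelengths_nm: np.ndarray
    sync: np.ndarray
    async_: np.ndarray

    @classmethod
    def from_dynamic(cls, dyn: DynamicSpectra) -> "CorrelationMaps":
        return cls(dyn.wavelengths_nm.copy(), synchronous_map(dyn), asynchronous_map(dyn))

    def to_csv(self, sync_path, async_path) -> None:
        import pandas as pd

        wl = self.wavelengths_nm
        for mat, path in ((self.sync, sync_path), (self.async_, async_path)):
            pd.DataFrame(mat, index=wl, columns=wl).to_csv(path, float_format="%.10g")


@dataclass
class AutoPeak:
    band: Region
    center_nm: int
    intensity: float


@dataclass
class CrossPeak:
    band1: Region  # higher-wavelength side (v1)
    band2: Region  # lower-wavelength side (v2)
    v1_nm: int
    v2_nm: int
    sync_sign: int
    async_sign: int
    sync_value: float
    async_value: float
    order: str  # sequential-order verdict for v1 relative to v2


def _diagonal_peaks(d: np.ndarray, prominence: float) -> list[int]:
    """Prominent local maxima of the sync diagonal, endpoints included.

    Padding with a sub-minimum sentinel lets boundary maxima count; the
    prominence filter discards noise ripple riding on a band's shoulder.
    """
    from scipy.signal import find_peaks

    padded = np.concatenate([[d.min() - 1.0], d, [d.min() - 1.0]])
    idx, _ = find_peaks(padded, prominence=prominence)
    return [int(i - 1) for i in idx]


def detect_autopeaks(
    maps: CorrelationMaps, n_levels: int = 8, min_prominence_fraction: float = 0.05
) -> list[AutoPeak]:
    """Auto-peaks of the synchronous diagonal with contour-derived band extents.

    Local maxima of diag(ø) whose height or topographic prominence falls
    below ``min_prominence_fraction`` of the diagonal's range are treated as
    noise ripple and dropped. Each surviving peak's band is the contiguous
    diagonal stretch at or above the lowest of ``n_levels`` equally spaced
    contour levels whose stretch still encloses only that peak — the widest
    contour that isolates it from its neighbours.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    d = np.diag(maps.sync)
    wl = maps.wavelengths_nm
    dmax = d.max(initial=0.0)
    if dmax <= 0 or np.allclose(d, d[0]):
        return []
    cand = [
        i
        for i in _diagonal_peaks(d, prominence=min_prominence_fraction * np.ptp(d))
        if d[i] >= min_prominence_fraction * dmax
    ]
    if not cand:
        return []
    # contour levels equally spaced over the diagonal's range, as drawn on
    # an n-level contour map
    levels = np.linspace(d.min(), dmax, n_levels + 1)[1:]  # exclude the floor
    peaks: list[AutoPeak] = []
    others = set(cand)
    for i in cand:
        best: tuple[int, int] | None = None
        for level in sorted(levels, reverse=True):
            if d[i] < level:
                continue
            lo = i
            while lo > 0 and d[lo - 1] >= level:
                lo -= 1
            hi = i
            while hi + 1 < d.size and d[hi + 1] >= level:
                hi += 1
            if any(lo <= j <= hi for j in others if j != i):
                break  # lower levels only widen the stretch further
            best = (lo, hi)
        if best is None:
            best = (i, i)
        peaks.append(
            AutoPeak(
                band=Region(int(wl[best[0]]), int(wl[best[1]])),
                center_nm=int(wl[i]),
                intensity=float(d[i]),
            )
        )
    peaks.sort(key=lambda p: p.band.lo)
    return peaks


def sequential_order(sync_sign: int, async_sign: int, v1_gt_v2: bool = True) -> str:
    """Noda's rules for the change order of v1 vs v2 (v1 > v2 convention).

    Same nonzero signs in both maps → v1 changes before v2; opposite nonzero
    signs → after; zero asynchronous intensity → simultaneous (in phase);
    zero synchronous with nonzero asynchronous → indeterminate.
    """
    if async_sign == 0:
        return "simultaneous"
    if sync_sign == 0:
        return "indeterminate"
    same = (sync_sign > 0) == (async_sign > 0)
    if not v1_gt_v2:
        same = not same
    return "before" if same else "after"


def detect_crosspeaks(
    maps: CorrelationMaps,
    auto_peaks: list[AutoPeak],
    threshold_fraction: float = 0.2,
) -> list[CrossPeak]:
    """Off-diagonal extrema linking pairs of auto-peak bands.

    For each unordered pair of auto-peak bands, the off-diagonal extremum of
    |ø| within the rectangle (band_hi × band_lo) is located; it is reported
    when it exceeds ``threshold_fraction`` of the global off-diagonal |ø|
    maximum, together with the sync/async signs at the extremum and the
    sequential-order verdict. v1 is the higher-wavelength band.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if len(auto_peaks) < 2:
        return []
    wl = maps.wavelengths_nm
    idx = {int(w): i for i, w in enumerate(wl)}
    off = np.abs(maps.sync).copy()
    np.fill_diagonal(off, 0.0)
    global_max = off.max()
    if global_max <= 0:
        return []
    out: list[CrossPeak] = []
    for a in range(len(auto_peaks)):
        for b in range(a + 1, len(auto_peaks)):
            p_lo, p_hi = auto_peaks[a], auto_peaks[b]  # sorted by lo
            rows = [idx[w] for w in range(p_hi.band.lo, p_hi.band.hi + 1) if w in idx]
            cols = [idx[w] for w in range(p_lo.band.lo, p_lo.band.hi + 1) if w in idx]
            sub = np.abs(maps.sync[np.ix_(rows, cols)])
            k = np.unravel_index(int(np.argmax(sub)), sub.shape)
            i, j = rows[k[0]], cols[k[1]]
            if np.abs(maps.sync[i, j]) < threshold_fraction * global_max:
                continue
            s_val = float(maps.sync[i, j])
            a_val = float(maps.async_[i, j])
            # an asynchronous intensity that does not rise above the map's
            # own peak scale carries no phase information; call it zero
            # (in-phase) rather than reading a sign off noise
            a_scale = np.abs(maps.async_).max()
            s_sign = int(np.sign(s_val))
            a_sign = (
                0
                if a_scale == 0 or abs(a_val) < threshold_fraction * a_scale
                else int(np.sign(a_val))
            )
            out.append(
                CrossPeak(
                    band1=p_hi.band,
                    band2=p_lo.band,
                    v1_nm=int(wl[i]),
                    v2_nm=int(wl[j]),
                    sync_sign=s_sign,
                    async_sign=a_sign,
                    sync_value=s_val,
                    async_value=a_val,
                    order=sequential_order(s_sign, a_sign, v1_gt_v2=True),
                )
            )
    return out


def select_bands(auto_peaks: list[AutoPeak]) -> RegionSet:
    """Sensitive wavebands = auto-peak band intervals, merged if overlapping."""
    if not auto_peaks:
        raise ValueError("no sensitive bands found")
    return RegionSet.merged([(p.band.lo, p.band.hi) for p in auto_peaks])


def plot_contours(maps: CorrelationMaps, path, n_levels: int = 8) -> None:
    """Side-by-side sync/async contour plot (n_levels levels) saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wl = maps.wavelengths_nm
    fig, axes = plt.subplots(1, 2, figsize=(11, 5), constrained_layout=True)
    for ax, mat, title in (
        (axes[0], maps.sync, "synchronous"),
        (axes[1], maps.async_, "asynchronous"),
    ):
        cs = ax.contour(wl, wl, mat, levels=n_levels, cmap="RdBu_r")
        ax.set_xlabel("wavelength $v_2$ / nm")
        ax.set_ylabel("wavelength $v_1$ / nm")
        ax.set_title(title)
        fig.colorbar(cs, ax=ax, shrink=0.85)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def peak_table_tsv(auto_peaks: list[AutoPeak], cross_peaks: list[CrossPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\taxis1_nm\taxis2_nm\tsync_sign\tasync_sign\torder\tintensity\n")
        for p in auto_peaks:
            fh.write(f"auto\t{p.band}\t{p.band}\t+\t0\tsimultaneous\t{p.intensity:.6g}\n")
        for c in cross_peaks:
            s = {1: "+", -1: "-", 0: "0"}
            fh.write(
                f"cross\t{c.band1}\t{c.band2}\t{s[c.sync_sign]}\t{s[c.async_sign]}"
                f"\t{c.order}\t{c.sync_value:.6g}\n"
            )
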