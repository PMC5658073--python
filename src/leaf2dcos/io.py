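"""Reading, validation and summary of leaf reflectance spectra and nitrogen tables.

The canonical spectral layout is a wide table: column 1 holds the wavelength
in nm (350–2500, 1 nm step), each remaining column is one leaf sample.
Reflectance is unitless in [0, 1]. Nitrogen is stored in g·kg⁻¹ of dry
matter; ``unit_scale`` converts whatever unit a file uses into g·kg⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GRID_MIN_NM = 350
GRID_MAX_NM = 2500
GRID_STEP_NM = 1


class GridError(ValueError):
    """Wavelength grid violates the 350–2500 nm / 1 nm contract."""


@dataclass
class SpectrumSet:
    """Reflectance matrix over a uniform 1 nm wavelength grid.

    Attributes
    ----------
    wavelengths_nm : (w,) int array, strictly increasing, 1 nm step
    reflectance : (n_samples, w) float array, finite, >= 0
    sample_ids : list of unique labels, one per row
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=int)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        validate_grid(self.wavelengths_nm)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D [sample x wavelength]")
        n, w = self.reflectance.shape
        if w != self.wavelengths_nm.size:
            raise ValueError(
                f"reflectance has {w} wavelength columns but grid has "
                f"{self.wavelengths_nm.size}"
            )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match reflectance rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance values")
        if np.any(self.reflectance < 0):
            raise ValueError("negative reflectance values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    def index_of(self, wavelength_nm: int) -> int:
        lo = int(self.wavelengths_nm[0])
        if not lo <= wavelength_nm <= int(self.wavelengths_nm[-1]):
            raise KeyError(f"wavelength {wavelength_nm} nm outside grid")
        return wavelength_nm - lo

    def window(self, lo_nm: int, hi_nm: int) -> "SpectrumSet":
        """Closed-interval wavelength slice, grid contract preserved."""
        i, j = self.index_of(lo_nm), self.index_of(hi_nm)
        return SpectrumSet(
            self.wavelengths_nm[i : j + 1],
            self.reflectance[:, i : j + 1],
            list(self.sample_ids),
        )


@dataclass
class NitrogenTable:
    """Per-sample nitrogen content, canonically in g·kg⁻¹."""

    sample_ids: list[str]
    nitrogen_g_per_kg: np.ndarray
    unit_scale: float = 1.0  # factor applied to the stored file values

    def __post_init__(self) -> None:
        self.nitrogen_g_per_kg = np.asarray(self.nitrogen_g_per_kg, dtype=float)
        if len(self.sample_ids) != self.nitrogen_g_per_kg.size:
            raise ValueError("one nitrogen value per sample id required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(~np.isfinite(self.nitrogen_g_per_kg)) or np.any(
            self.nitrogen_g_per_kg <= 0
        ):
            raise ValueError("nitrogen values must be positive and finite")

    def aligned_to(self, ids: list[str]) -> np.ndarray:
        """Nitrogen values reordered to match ``ids`` (1:1 required)."""
        lookup = dict(zip(self.sample_ids, self.nitrogen_g_per_kg))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"no nitrogen value for sample(s): {missing[:5]}")
        return np.array([lookup[i] for i in ids], dtype=float)


@dataclass
class SampleStats:
    n: int
    maximum: float
    minimum: float
    mean: float
    sd: float  # n-1 divisor

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "maximum": self.maximum,
            "minimum": self.minimum,
            "mean": self.mean,
            "sd": self.sd,
        }


def validate_grid(wavelengths: np.ndarray) -> None:
    w = np.asarray(wavelengths)
    if w.size == 0:
        raise GridError("empty wavelength grid")
    if w.size > 1:
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if np.any(steps != GRID_STEP_NM):
            raise GridError(
                "non-uniform/unsupported grid: expected 1 nm step, "
                f"found steps {sorted(set(int(s) for s in steps))[:5]}"
            )
    if w[0] < GRID_MIN_NM or w[-1] > GRID_MAX_NM:
        raise GridError(
            f"grid [{int(w[0])}, {int(w[-1])}] nm outside {GRID_MIN_NM}-{GRID_MAX_NM} nm"
        )


def _read_table(path: str | Path, fmt: str | None) -> pd.DataFrame:
    """Read CSV/XLSX with header row preserved verbatim (no name mangling)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xls" if path.suffix.lower() in {".xls", ".xlsx"} else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path, header=None, dtype=str)
    elif fmt == "xls":
        if path.suffix.lower() == ".xls":
            raise ValueError(
                "legacy binary .xls needs the xlrd reader, which is not "
                "installed; convert the sheet to .xlsx or CSV"
            )
        raw = pd.read_excel(path, engine="openpyxl", header=None, dtype=str)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'xls'")
    header = [str(c) for c in raw.iloc[0]]
    df = raw.iloc[1:].reset_index(drop=True)
    df.columns = pd.Index(range(len(header)))
    return df, header


def read_spectra(path: str | Path, format: str | None = None) -> SpectrumSet:
    """Read a wide spectra table (wavelength column + one column per sample).

    Rows whose wavelength falls outside 350–2500 nm are rejected with a
    warning; any non-numeric cell, duplicate sample id or non-1-nm grid is a
    hard error.
    """
    df, header = _read_table(path, format)
    if len(header) < 2:
        raise ValueError("spectra table needs a wavelength column plus >=1 sample")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in header")
    wl_raw = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if wl_raw.isna().any():
        bad = df.index[wl_raw.isna()][0]
        raise ValueError(f"non-numeric wavelength in row {bad}")
    inside = (wl_raw >= GRID_MIN_NM) & (wl_raw <= GRID_MAX_NM)
    if not inside.all():
        warnings.warn(
            f"rejected {(~inside).sum()} row(s) outside "
            f"{GRID_MIN_NM}-{GRID_MAX_NM} nm",
            stacklevel=2,
        )
        df = df.loc[inside.values]
        wl_raw = wl_raw[inside]
    values = np.empty((df.shape[0], len(sample_ids)))
    for j, name in enumerate(sample_ids):
        num = pd.to_numeric(df.iloc[:, j + 1], errors="coerce")
        if num.isna().any():
            row = df.index[num.isna()][0]
            raise ValueError(f"non-numeric cell at row {row}, column {name!r}")
        # astype(float) parses via strtod and round-trips doubles exactly;
        # to_numeric's fast path can drop the last ulp
        values[:, j] = df.iloc[:, j + 1].astype(float).values
    return SpectrumSet(wl_raw.values.astype(int), values.T, sample_ids)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Wide-CSV writer; round-trips with :func:`read_spectra` at full precision."""
    df = pd.DataFrame(
        spectra.reflectance.T,
        columns=spectra.sample_ids,
    )
    df.insert(0, "wavelength_nm", spectra.wavelengths_nm)
    df.to_csv(path, index=False)  # default str() repr round-trips doubles exactly


def read_nitrogen(
    path: str | Path, unit_scale: float = 1.0, format: str | None = None
) -> NitrogenTable:
    """Read a two-column (id, value) nitrogen table; values x unit_scale → g·kg⁻¹."""
    df, header = _read_table(path, format)
    if len(header) < 2:
        raise ValueError("nitrogen table needs two columns (id, value)")
    ids = [str(v) for v in df.iloc[:, 0]]
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        raise ValueError(
            f"non-numeric nitrogen value for id "
            f"{ids[int(np.argmax(vals.isna().values))]!r}"
        )
    exact = df.iloc[:, 1].astype(float).values
    return NitrogenTable(ids, exact * float(unit_scale), unit_scale=float(unit_scale))


def write_nitrogen(table: NitrogenTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, "nitrogen_g_per_kg": table.nitrogen_g_per_kg}
    ).to_csv(path, index=False)


def nitrogen_stats(
    table: NitrogenTable, subset: list[str] | None = None
) -> SampleStats:
    """Descriptive statistics (n−1 sd) over all samples or a named subset."""
    if subset is None:
        vals = table.nitrogen_g_per_kg
    else:
        if len(subset) == 0:
            raise ValueError("empty subset")
        vals = table.aligned_to(list(subset))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SampleStats(
        n=int(vals.size),
        maximum=float(vals.max()),
        minimum=float(vals.min()),
        mean=float(vals.mean()),
        sd=sd,
    )


def group_mean_spectra(
    spectra: SpectrumSet,
    nitrogen: NitrogenTable,
    thresholds: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Mean spectrum per nitrogen group: <= t1, (t1, t2), >= t2 (g·kg⁻¹).

    Empty groups are omitted with a warning rather than raising, so a
    skewed cohort still yields the populated group means.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be ascending")
    n = nitrogen.aligned_to(spectra.sample_ids)
    masks = {
        f"low (<= {t1:g})": n <= t1,
        f"mid ({t1:g}-{t2:g})": (n > t1) & (n < t2),
        f"high (>= {t2:g})": n >= t2,
    }
    out: dict[str, np.ndarray] = {}
    for name, mask in masks.items():
        if not mask.any():
            warnings.warn(f"group {name!r} is empty; omitted", stacklevel=2)
            continue
        out[name] = spectra.reflectance[mask].mean(axis=0)
    return out
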