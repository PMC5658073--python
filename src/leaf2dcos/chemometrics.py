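"""Band features (Rx/Sx) and calibration/validation of PLSR and ν-SVR models.

For each selected sensitive waveband, two characteristic parameters are
computed per sample: Rx, the maximum reflectance within the band, and Sx,
the total (summed) reflectance over the band's integer-nm wavelengths.
Nitrogen is regressed on one feature family at a time with partial least
squares regression (NIPALS, via scikit-learn) or ν-support-vector
regression (RBF kernel, libsvm via scikit-learn), on a random
calibration/validation split.

Fitting happens on the g·(100 g)⁻¹ nitrogen scale (g·kg⁻¹ / 10) — the
native scale of the fixed SVR hyperparameters and of the linear-model
coefficients this package reports — while all metrics are returned in
g·kg⁻¹. R² is invariant under this common rescaling; RMSE scales by 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import NuSVR

from .io import NitrogenTable, SpectrumSet
from .regions import RegionSet

#: models are fitted on nitrogen x FIT_SCALE (g/kg -> g/100g)
FIT_SCALE = 0.1


@dataclass
class FeatureTable:
    """Per-sample Rx/Sx features over an ordered set of bands."""

    sample_ids: list[str]
    bands: RegionSet
    rx: np.ndarray  # (n_samples, n_bands) max reflectance per band
    sx: np.ndarray  # (n_samples, n_bands) summed reflectance per band

    def family(self, which: str) -> np.ndarray:
        if which == "rx":
            return self.rx
        if which == "sx":
            return self.sx
        raise ValueError("feature family must be 'rx' or 'sx'")

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, b in enumerate(self.bands):
            cols[f"Rx_{b.lo}_{b.hi}"] = self.rx[:, j]
        for j, b in enumerate(self.bands):
            cols[f"Sx_{b.lo}_{b.hi}"] = self.sx[:, j]
        return pd.DataFrame(cols, index=self.sample_ids)


def compute_features(spectra: SpectrumSet, bands: RegionSet) -> FeatureTable:
    """Rx = max, Sx = sum of reflectance over each band's closed nm interval."""
    if not bands:
        raise ValueError("empty band set")
    n = spectra.n_samples
    rx = np.empty((n, len(bands)))
    sx = np.empty((n, len(bands)))
    for j, b in enumerate(bands):
        i0, i1 = spectra.index_of(b.lo), spectra.index_of(b.hi)
        block = spectra.reflectance[:, i0 : i1 + 1]
        rx[:, j] = block.max(axis=1)
        sx[:, j] = block.sum(axis=1)
    return FeatureTable(list(spectra.sample_ids), bands, rx, sx)


@dataclass
class SplitSpec:
    calibration_ids: list[str]
    validation_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


def make_split(ids: list[str], ratio: float = 0.75, seed: int = 0) -> SplitSpec:
    """Uniform random partition of ids into calibration/validation."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(ids)
    n_cal = int(round(n * ratio))
    if n_cal < 2 or n - n_cal < 2:
        raise ValueError("need at least 2 samples on each side of the split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = sorted(perm[:n_cal])
    val = sorted(perm[n_cal:])
    return SplitSpec([ids[i] for i in cal], [ids[i] for i in val], seed)


@dataclass
class FitMetrics:
    r2_cal: float
    rmse_cal: float  # g/kg
    r2_val: float
    rmse_val: float  # g/kg

    def as_dict(self) -> dict:
        return {
            "r2_cal": self.r2_cal,
            "rmse_cal": self.rmse_cal,
            "r2_val": self.r2_val,
            "rmse_val": self.rmse_val,
        }


@dataclass
class PlsrModel:
    """Fitted PLSR collapsed to its explicit linear form (on the fit scale)."""

    intercept: float
    coefficients: np.ndarray  # one per feature
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted nitrogen on the fit scale (g/100g)."""
        return self.intercept + np.asarray(X) @ self.coefficients

    def equation(self, names: list[str] | None = None) -> str:
        names = names or [f"x{i + 1}" for i in range(self.coefficients.size)]
        terms = "".join(
            f" {'-' if c < 0 else '+'} {abs(c):.3f}·{n}"
            for c, n in zip(self.coefficients, names)
        )
        return f"y = {self.intercept:.3f}{terms}"


@dataclass
class SvrConfig:
    """ν-SVR hyperparameters (libsvm naming); defaults are the fixed set
    used for leaf-nitrogen estimation, no search."""

    kernel: str = "rbf"
    degree: int = 3
    gamma: float = 0.5
    coef0: float = 0.001
    nu: float = 0.5
    epsilon_termination: float = 0.001  # optimizer tolerance
    cache_mb: float = 100.0
    cost: float = 1.0
    shrinking: bool = True
    probability: bool = True  # accepted; no effect on regression point predictions
    loss_p: float = 0.01  # epsilon-SVR loss width; unused by nu-SVR
    scale_features: bool = False  # optional min-max scaling switch

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be positive")


def evaluate(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """R² (about the observed mean) and RMSE.

    Zero variance in the observed values leaves R² undefined; it is
    returned as NaN with a warning, RMSE is still reported.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal non-empty lengths")
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((observed - observed.mean()) ** 2))
    if sstot == 0:
        warnings.warn("zero variance in observed values; R² undefined", stacklevel=2)
        return float("nan"), rmse
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return r2, rmse


def _split_arrays(
    features: FeatureTable,
    nitrogen: NitrogenTable,
    split: SplitSpec,
    family: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X = features.family(family)
    pos = {s: i for i, s in enumerate(features.sample_ids)}
    ic = [pos[s] for s in split.calibration_ids]
    iv = [pos[s] for s in split.validation_ids]
    y = nitrogen.aligned_to(features.sample_ids)
    return X[ic], y[ic], X[iv], y[iv]


def _metrics(model_predict, Xc, yc, Xv, yv) -> FitMetrics:
    """Metrics in g/kg from a predictor operating on the fit scale."""
    pc = np.asarray(model_predict(Xc)).ravel() / FIT_SCALE
    pv = np.asarray(model_predict(Xv)).ravel() / FIT_SCALE
    r2c, rmsec = evaluate(pc, yc)
    r2v, rmsev = evaluate(pv, yv)
    return FitMetrics(r2c, rmsec, r2v, rmsev)


def fit_plsr(
    features: FeatureTable,
    nitrogen: NitrogenTable,
    split: SplitSpec,
    components: int = 2,
    family: str = "rx",
) -> tuple[PlsrModel, FitMetrics]:
    """Partial least squares regression on the calibration split.

    The fitted latent-variable model is collapsed to its equivalent
    intercept + linear coefficients. If the requested number of components
    exceeds the rank of the centered calibration features it is reduced
    with a warning.
    """
    if components < 1:
        raise ValueError("components must be >= 1")
    Xc, yc, Xv, yv = _split_arrays(features, nitrogen, split, family)
    if Xc.shape[0] <= components:
        raise ValueError("calibration set must be larger than component count")
    rank = np.linalg.matrix_rank(Xc - Xc.mean(axis=0))
    k = min(components, Xc.shape[1])
    if rank < k:
        warnings.warn(
            f"feature rank {rank} < requested components {k}; reduced", stacklevel=2
        )
        k = max(int(rank), 1)
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(Xc, yc * FIT_SCALE)
    coefs = np.asarray(pls.coef_).reshape(-1)
    # collapse the centered latent form to y = b0 + x·b: sklearn's
    # intercept_ is the training-target mean, taken about centered X
    x_mean = Xc.mean(axis=0)
    intercept = float(np.asarray(pls.intercept_).reshape(-1)[0] - x_mean @ coefs)
    model = PlsrModel(intercept=intercept, coefficients=coefs, n_components=k)
    return model, _metrics(model.predict, Xc, yc, Xv, yv)


def fit_svr(
    features: FeatureTable,
    nitrogen: NitrogenTable,
    split: SplitSpec,
    config: SvrConfig | None = None,
    family: str = "sx",
):
    """ν-SVR (RBF) on the calibration split; deterministic given data+config."""
    config = config or SvrConfig()
    Xc, yc, Xv, yv = _split_arrays(features, nitrogen, split, family)
    if not (np.all(np.isfinite(Xc)) and np.all(np.isfinite(Xv))):
        raise ValueError("non-finite feature values")
    lo, span = None, None
    if config.scale_features:
        lo = Xc.min(axis=0)
        span = np.where(Xc.max(axis=0) - lo == 0, 1.0, Xc.max(axis=0) - lo)
        Xc = (Xc - lo) / span
        Xv = (Xv - lo) / span
    if np.ptp(yc) == 0:
        warnings.warn("constant calibration target; model predicts the constant",
                      stacklevel=2)
    svr = NuSVR(
        kernel=config.kernel,
        degree=config.degree,
        gamma=config.gamma,
        coef0=config.coef0,
        nu=config.nu,
        C=config.cost,
        tol=config.epsilon_termination,
        cache_size=config.cache_mb,
        shrinking=config.shrinking,
    )
    svr.fit(Xc, yc * FIT_SCALE)
    return svr, _metrics(svr.predict, Xc, yc, Xv, yv)


def compare_models(metric_sets: list[tuple[str, FitMetrics]]) -> list[tuple[str, FitMetrics]]:
    """Rank by validation R² (desc), ties by validation RMSE (asc); stable."""
    if len(metric_sets) < 2:
        raise ValueError("need >= 2 metric sets to rank")
    return sorted(
        metric_sets, key=lambda kv: (-kv[1].r2_val, kv[1].rmse_val)
    )


def split_family_metrics(
    features: FeatureTable,
    nitrogen: NitrogenTable,
    seeds: list[int],
    ratio: float = 0.75,
    components: int = 2,
    svr_config: SvrConfig | None = None,
    models: tuple[str, ...] = ("plsr", "svr"),
    families: tuple[str, ...] = ("rx", "sx"),
) -> dict[str, dict]:
    """Mean ± sd metrics over a family of random splits, per model × feature.

    The reference split of a single random draw is unknowable, so model
    quality is summarised distributionally over seeded splits.
    """
    out: dict[str, dict] = {}
    per_seed: dict[str, list[FitMetrics]] = {}
    for seed in seeds:
        split = make_split(features.sample_ids, ratio=ratio, seed=seed)
        for fam in families:
            for model in models:
                if model == "plsr":
                    _, m = fit_plsr(features, nitrogen, split, components, family=fam)
                elif model == "svr":
                    _, m = fit_svr(features, nitrogen, split, svr_config, family=fam)
                else:
                    raise ValueError(f"unknown model {model!r}")
                per_seed.setdefault(f"{model}_{fam}", []).append(m)
    for key, ms in per_seed.items():
        arr = np.array([[m.r2_cal, m.rmse_cal, m.r2_val, m.rmse_val] for m in ms])
        mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=1) if len(ms) > 1 else np.zeros(4)
        out[key] = {
            "n_splits": len(ms),
            "mean": dict(zip(("r2_cal", "rmse_cal", "r2_val", "rmse_val"), mean.tolist())),
            "sd": dict(zip(("r2_cal", "rmse_cal", "r2_val", "rmse_val"), sd.tolist())),
        }
    return out
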