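"""End-to-end orchestration: screen → 2DCOS → bands → features → models → report.

Stages write their artifacts (TSV/CSV/JSON) into one run directory, and the
final machine-readable report carries the selected bands, per-model metric
distributions over the seeded split family, and provenance (config hash,
seeds, package version). Every number in the human-readable summary is
recomputable from the stage artifacts stored alongside it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chemometrics import (
    SvrConfig,
    compute_features,
    split_family_metrics,
)
from .io import (
    NitrogenTable,
    SpectrumSet,
    nitrogen_stats,
    read_nitrogen,
    read_spectra,
)
from .regions import DEFAULT_EXCLUSIONS, RegionSet
from .screening import apply_exclusions, correlation_profile, significant_regions
from .synthetic import SyntheticConfig, simulate_dataset
from .twodcos import (
    CorrelationMaps,
    detect_autopeaks,
    detect_crosspeaks,
    dynamic_spectra,
    peak_table_tsv,
    select_bands,
)


@dataclass
class PipelineConfig:
    """Round-trippable run configuration (YAML)."""

    spectra_path: str | None = None
    nitrogen_path: str | None = None
    unit_scale: float = 1.0
    synthetic: bool = False
    synthetic_seed: int = 20170
    alpha: float = 0.01
    min_run: int = 5
    exclusions: list[tuple[int, int]] = field(
        default_factory=lambda: [(r.lo, r.hi) for r in DEFAULT_EXCLUSIONS]
    )
    window: list[tuple[int, int]] | None = None  # None → screened regions
    n_levels: int = 8
    threshold_fraction: float = 0.2
    split_ratio: float = 0.75
    seeds: list[int] = field(default_factory=lambda: list(range(50)))
    models: list[str] = field(default_factory=lambda: ["plsr", "svr"])
    families: list[str] = field(default_factory=lambda: ["rx", "sx"])
    plsr_components: int = 2
    output_dir: str = "runs/latest"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(cfg: PipelineConfig) -> tuple[SpectrumSet, NitrogenTable]:
    if cfg.synthetic:
        spectra, nitrogen, _ = simulate_dataset(SyntheticConfig(seed=cfg.synthetic_seed))
        return spectra, nitrogen
    if not cfg.spectra_path or not cfg.nitrogen_path:
        raise ValueError("either synthetic=true or both input paths are required")
    return (
        read_spectra(cfg.spectra_path),
        read_nitrogen(cfg.nitrogen_path, unit_scale=cfg.unit_scale),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, persist artifacts, return (and write) the report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seeds": list(cfg.seeds),
    }

    stage = "load"
    try:
        spectra, nitrogen = _load_inputs(cfg)
        report["n_samples"] = spectra.n_samples
        report["nitrogen_stats"] = nitrogen_stats(nitrogen).as_dict()

        stage = "screen"
        profile = correlation_profile(spectra, nitrogen)
        profile.to_tsv(outdir / "correlation_profile.tsv")
        sig = significant_regions(profile, alpha=cfg.alpha, min_run=cfg.min_run)
        kept = apply_exclusions(sig, RegionSet(cfg.exclusions), min_run=cfg.min_run)
        sig.to_tsv(outdir / "significant_regions.tsv")
        kept.to_tsv(outdir / "screened_regions.tsv")
        wl_ext, r_ext = profile.extreme(within=kept) if kept else profile.extreme()
        report["screening"] = {
            "significant_regions": [(r.lo, r.hi) for r in sig],
            "screened_regions": [(r.lo, r.hi) for r in kept],
            "extreme_r": r_ext,
            "extreme_wavelength_nm": wl_ext,
        }

        stage = "corr2d"
        window = RegionSet(cfg.window) if cfg.window else kept
        if not window:
            raise ValueError("empty analysis window after screening/exclusions")
        dyn = dynamic_spectra(spectra, nitrogen, window=window)
        maps = CorrelationMaps.from_dynamic(dyn)
        maps.to_csv(outdir / "synchronous_map.csv", outdir / "asynchronous_map.csv")

        stage = "bands"
        autos = detect_autopeaks(maps, n_levels=cfg.n_levels)
        crosses = detect_crosspeaks(maps, autos, threshold_fraction=cfg.threshold_fraction)
        peak_table_tsv(autos, crosses, outdir / "peak_table.tsv")
        bands = select_bands(autos)
        bands.to_tsv(outdir / "sensitive_bands.tsv")
        report["bands"] = {
            "auto_peaks": [
                {"band": (p.band.lo, p.band.hi), "center_nm": p.center_nm,
                 "intensity": p.intensity}
                for p in autos
            ],
            "cross_peaks": [
                {"band1": (c.band1.lo, c.band1.hi), "band2": (c.band2.lo, c.band2.hi),
                 "sync_sign": c.sync_sign, "async_sign": c.async_sign, "order": c.order}
                for c in crosses
            ],
            "selected": [(r.lo, r.hi) for r in bands],
        }

        if cfg.models:
            stage = "features"
            features = compute_features(spectra, bands)
            features.to_frame().to_csv(outdir / "features.tsv", sep="\t")

            stage = "fit"
            report["models"] = split_family_metrics(
                features,
                nitrogen,
                seeds=list(cfg.seeds),
                ratio=cfg.split_ratio,
                components=cfg.plsr_components,
                svr_config=SvrConfig(),
                models=tuple(cfg.models),
                families=tuple(cfg.families),
            )
        else:
            report["models"] = {}
    except Exception as exc:  # keep partial artifacts, name the stage
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def report_summary(report_path: str | Path) -> str:
    """Human-readable model × feature table from a stored report."""
    data = json.loads(Path(report_path).read_text())
    if "bands" not in data:
        raise ValueError("malformed report: missing 'bands'")
    lines = []
    sel = ", ".join(f"{lo}-{hi} nm" for lo, hi in data["bands"]["selected"])
    lines.append(f"selected sensitive bands: {sel}")
    models = data.get("models", {})
    if models:
        rows = sorted(
            models.items(),
            key=lambda kv: (-kv[1]["mean"]["r2_val"], kv[1]["mean"]["rmse_val"]),
        )
        header = (
            f"{'model':<10}{'R2_cal':>14}{'RMSE_cal':>14}{'R2_val':>14}{'RMSE_val':>14}"
        )
        lines.append(header)
        for name, stats in rows:
            mean, sd = stats["mean"], stats["sd"]
            lines.append(
                f"{name:<10}"
                + "".join(
                    f"{mean[k]:>8.3f}±{sd[k]:<5.3f}"
                    for k in ("r2_cal", "rmse_cal", "r2_val", "rmse_val")
                )
            )
        lines.append(f"(mean ± sd over {next(iter(models.values()))['n_splits']} splits;"
                     " RMSE in g·kg⁻¹)")
    return "\n".join(lines)
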