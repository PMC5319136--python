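"""End-to-end orchestration: scans → densitograms → metrics → comparison.

``analyze_scan`` runs the single-scan chain (project → calibrate →
quantize → detect maxima → grid → MAR → metrics) and is the unit every
driver, test and experiment builds on.  ``run_pipeline`` wires a whole
simulated cohort through it and writes the standard result bundle:

* ``metrics.csv`` — one row per subject × timepoint × view,
* ``comparison.csv`` / ``coordinates.csv`` — the Table-1-style paired
  summary (t1 mean (SD), t2 mean (SD), p) and the maxima-location tests,
* ``densitograms/*.png`` — false-colour renderings (optional),
* ``provenance.json`` — config hash, seed, package/library versions.

Given the same config and seed the bundle is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationFit, apply_calibration, fit_calibration
from .cohort import JointMetrics, PairedCohortResult, compare_paired, metrics_to_frame, summarize_joint
from .densitometry import (
    DEFAULT_WINDOW_HU,
    GridFrame,
    MarResult,
    MaximumRegion,
    QuantizedDensitogram,
    compute_mar,
    detect_maxima,
    quantize,
    to_grid,
)
from .errors import ConfigError
from .projection import Densitogram, ViewSpec, default_views, project_mip
from .synthetic import Cohort, SyntheticSpec, default_spec, generate_cohort, phantom_spec_for
from .volume import BoneMask, CtVolume

__all__ = ["RunConfig", "ScanAnalysis", "PipelineResult", "analyze_scan", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a simulated end-to-end run."""

    n_subjects: int = 10
    growth_factor: float = 1.15
    seed: int = 0
    spec: SyntheticSpec | None = None        # None → default_spec()
    mip_depth: float = 1.5                   # mm
    window: tuple[float, float] = DEFAULT_WINDOW_HU
    min_area: int = 3
    connectivity: int = 8
    grid_units: int = 30
    alpha: float = 0.05
    render: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.mip_depth <= 0:
            raise ConfigError("mip_depth must be positive")
        if not self.window[1] > self.window[0]:
            raise ConfigError("quantization window must have lower < upper")
        if self.grid_units < 2:
            raise ConfigError("grid_units must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class ScanAnalysis:
    """Everything derived from one scan in one view."""

    densitogram: Densitogram
    quantized: QuantizedDensitogram
    maxima: list[MaximumRegion]
    frame: GridFrame
    mar: MarResult
    metrics: JointMetrics


def analyze_scan(
    volume: CtVolume,
    mask: BoneMask,
    view: ViewSpec,
    fit: CalibrationFit,
    window: tuple[float, float] = DEFAULT_WINDOW_HU,
    min_area: int = 3,
    connectivity: int = 8,
    grid_units: int = 30,
) -> ScanAnalysis:
    """Single-scan chain: MIP → calibrate → quantize → maxima → grid → MAR."""
    dg = project_mip(volume, mask, view)
    dg.values_density = apply_calibration(dg.values_hu, fit)
    q = quantize(dg, window)
    maxima = detect_maxima(q, min_area=min_area, connectivity=connectivity)
    frame = GridFrame.from_surface_mask(dg.surface_mask, n_units=grid_units)
    for reg in maxima:
        reg.centroid_grid = to_grid(reg, frame)
        reg.peak_grid = frame.pixel_to_grid(*reg.peak_px)
    mar = compute_mar(maxima, dg.surface_mask)
    metrics = summarize_joint(dg, q, mar, fit)
    return ScanAnalysis(dg, q, maxima, frame, mar, metrics)


@dataclass
class PipelineResult:
    cohort: Cohort
    metrics: pd.DataFrame
    comparison: PairedCohortResult
    analyses: dict = field(default_factory=dict)   # (subject, tp, view) → ScanAnalysis
    fits: dict = field(default_factory=dict)       # (subject, tp) → CalibrationFit
    paths: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a paired cohort and push every scan through the full chain."""
    config.validate()
    spec = config.spec if config.spec is not None else default_spec()
    views = default_views(mip_depth=config.mip_depth)
    cohort = generate_cohort(config.n_subjects, config.growth_factor, spec, config.seed)
    phantom = phantom_spec_for(spec)

    analyses: dict = {}
    fits: dict = {}
    all_metrics: list[JointMetrics] = []
    for sid, tp, scan in cohort.scans():
        fit = fit_calibration(scan.volume, phantom)
        fits[(sid, tp)] = fit
        for view in views:
            an = analyze_scan(
                scan.volume,
                scan.mask,
                view,
                fit,
                window=config.window,
                min_area=config.min_area,
                connectivity=config.connectivity,
                grid_units=config.grid_units,
            )
            analyses[(sid, tp, view.name)] = an
            all_metrics.append(an.metrics)

    comparison = compare_paired(all_metrics, alpha=config.alpha)
    metrics_df = metrics_to_frame(all_metrics)
    result = PipelineResult(cohort, metrics_df, comparison, analyses, fits)

    if config.out_dir is not None:
        result.paths = _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    metrics_path = out / "metrics.csv"
    result.metrics.to_csv(metrics_path, index=False, float_format="%.6f")
    paths["metrics"] = metrics_path

    cmp_path = out / "comparison.csv"
    result.comparison.table.to_csv(cmp_path, index=False, float_format="%.6f")
    paths["comparison"] = cmp_path

    coord_path = out / "coordinates.csv"
    result.comparison.coordinates.to_csv(coord_path, index=False, float_format="%.6f")
    paths["coordinates"] = coord_path

    prov = {
        "tool": "ctoam",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "growth_factor": config.growth_factor,
        "numpy": np.__version__,
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    paths["provenance"] = prov_path

    if config.render:
        from .render import save_densitogram_png

        png_dir = out / "densitograms"
        png_dir.mkdir(exist_ok=True)
        for (sid, tp, view), an in result.analyses.items():
            p = png_dir / f"{sid}_{tp}_{view}.png"
            save_densitogram_png(an.densitogram, p)
        paths["densitograms"] = png_dir
    return paths
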