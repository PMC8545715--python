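"""End-to-end orchestration: inputs → segmentation → metrics → curves →
multifractal spectra → isotropy/homogeneity report.

Each sample is either a synthetic phantom or a TIFF volume on disk.  The
run writes every artifact (mask, metrics, per-axis curves and spectra,
isotropy report) plus a manifest recording all parameters and seeds, so a
rerun from the manifest alone is bit-identical.
"""
from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import volio
from .curves import FrequencyCurve, pore_frequency_curve, slice_porosity_range
from .errors import DegenerateInputError, InvalidParameterError, PoretomoError
from .metrics import (
    DEFAULT_MIN_PORE_VOLUME_VOX,
    DEFAULT_PORE_CONNECTIVITY,
    DEFAULT_SMALL_PORE_CUTOFF_VOX,
    PoreMetrics,
    compute_pore_metrics,
)
from .multifractal import (
    MultifractalConfig,
    MultifractalSpectrum,
    SpectrumDescriptors,
    run_multifractal,
)
from .phantoms import PhantomSpec, generate_phantom
from .segmentation import SegmentationConfig, crop_center_roi, segment_volume
from .volumes import BinaryVolume, DEFAULT_VOXEL_EDGE_UM

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInput",
    "PipelineConfig",
    "IsotropyThresholds",
    "IsotropyReport",
    "SampleReport",
    "run_pipeline",
    "aggregate_samples",
    "load_config",
    "config_from_dict",
]

#: Descriptors compared pairwise across axes for the isotropy verdict.
#: Asymmetry is reported but excluded: it is a ratio of near-zero spans and
#: numerically unstable for the degenerate spectra of homogeneous media.
_VERDICT_DESCRIPTORS = ("width", "d0_minus_d2", "d_qmin_minus_d_qmax")


@dataclass(frozen=True)
class IsotropyThresholds:
    """Artifact verdict thresholds (not derived from any measurement)."""

    homogeneous_width_max: float = 0.15
    isotropic_pairwise_max: float = 0.10


@dataclass(frozen=True)
class SampleInput:
    """One sample: a phantom recipe or a TIFF volume on disk."""

    name: str
    group: str = ""
    phantom: PhantomSpec | None = None
    tiff_path: str | None = None
    tiff_layout: str = "multipage"
    tiff_is_mask: bool = False

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.tiff_path is None):
            raise InvalidParameterError(
                f"sample {self.name!r}: exactly one of phantom or tiff_path required"
            )


@dataclass(frozen=True)
class PipelineConfig:
    samples: tuple[SampleInput, ...]
    segmentation: SegmentationConfig = SegmentationConfig()
    pore_connectivity: int = DEFAULT_PORE_CONNECTIVITY
    min_pore_volume_vox: int = DEFAULT_MIN_PORE_VOLUME_VOX
    small_pore_cutoff_vox: int = DEFAULT_SMALL_PORE_CUTOFF_VOX
    multifractal: MultifractalConfig = MultifractalConfig()
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM
    thresholds: IsotropyThresholds = IsotropyThresholds()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise InvalidParameterError("config needs at least one sample")


@dataclass(frozen=True)
class AxisCurveSummary:
    axis: int
    mean_count: float
    sd_count: float
    min_slice_porosity: float
    max_slice_porosity: float


@dataclass(frozen=True)
class IsotropyReport:
    """Cross-axis comparison of spectra and curve statistics for one sample."""

    descriptors: tuple[SpectrumDescriptors, SpectrumDescriptors, SpectrumDescriptors]
    curve_summaries: tuple[AxisCurveSummary, AxisCurveSummary, AxisCurveSummary]
    pairwise_differences: dict[str, float]
    homogeneous: bool
    isotropic: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "descriptors": [d.to_dict() for d in self.descriptors],
            "curve_summaries": [asdict(c) for c in self.curve_summaries],
            "pairwise_differences": self.pairwise_differences,
            "homogeneous": self.homogeneous,
            "isotropic": self.isotropic,
        }


@dataclass(frozen=True)
class SampleReport:
    name: str
    group: str
    metrics: PoreMetrics
    curves: tuple[FrequencyCurve, FrequencyCurve, FrequencyCurve]
    spectra: tuple[MultifractalSpectrum, MultifractalSpectrum, MultifractalSpectrum]
    isotropy: IsotropyReport


def _isotropy_report(
    curves: tuple[FrequencyCurve, ...],
    spectra: tuple[MultifractalSpectrum, ...],
    thresholds: IsotropyThresholds,
) -> IsotropyReport:
    descriptors = tuple(s.descriptors() for s in spectra)
    summaries = []
    for curve in curves:
        lo, hi = slice_porosity_range(curve)
        summaries.append(
            AxisCurveSummary(
                axis=curve.axis,
                mean_count=float(curve.counts.mean()),
                sd_count=float(curve.counts.std(ddof=1)),
                min_slice_porosity=lo,
                max_slice_porosity=hi,
            )
        )
    pairwise: dict[str, float] = {}
    names = ("width", "asymmetry", "d0_minus_d2", "d_qmin_minus_d_qmax")
    for name in names:
        values = [getattr(d, name) for d in descriptors]
        diffs = [
            abs(values[a] - values[b]) for a, b in ((0, 1), (0, 2), (1, 2))
        ]
        pairwise[name] = float(max(diffs))
    homogeneous = all(
        d.width < thresholds.homogeneous_width_max for d in descriptors
    )
    verdict_diffs = [pairwise[n] for n in _VERDICT_DESCRIPTORS]
    isotropic = all(
        math.isfinite(v) and v < thresholds.isotropic_pairwise_max
        for v in verdict_diffs
    )
    return IsotropyReport(
        descriptors=descriptors,  # type: ignore[arg-type]
        curve_summaries=tuple(summaries),  # type: ignore[arg-type]
        pairwise_differences=pairwise,
        homogeneous=homogeneous,
        isotropic=isotropic,
    )


def _load_sample_volume(sample: SampleInput, config: PipelineConfig) -> BinaryVolume:
    if sample.phantom is not None:
        binary = generate_phantom(sample.phantom)
        if config.segmentation.roi_edge_vox is not None:
            binary = crop_center_roi(binary, config.segmentation.roi_edge_vox)
        return binary
    if sample.tiff_is_mask:
        binary = volio.read_mask(
            sample.tiff_path, sample.tiff_layout, config.voxel_edge_um
        )
        if config.segmentation.roi_edge_vox is not None:
            binary = crop_center_roi(binary, config.segmentation.roi_edge_vox)
        return binary
    gray = volio.read_volume(
        sample.tiff_path, sample.tiff_layout, config.voxel_edge_um
    )
    return segment_volume(gray, config.segmentation)


def analyze_sample(sample: SampleInput, config: PipelineConfig) -> SampleReport:
    """Run the per-sample chain without touching the filesystem outputs."""
    t0 = time.perf_counter()
    binary = _load_sample_volume(sample, config)
    logger.info("[%s] volume %s ready (%.2fs)", sample.name, binary.shape, time.perf_counter() - t0)
    metrics = compute_pore_metrics(
        binary,
        connectivity=config.pore_connectivity,
        min_pore_volume_vox=config.min_pore_volume_vox,
        small_pore_cutoff_vox=config.small_pore_cutoff_vox,
    )
    curves = tuple(pore_frequency_curve(binary, axis) for axis in range(3))
    spectra = tuple(run_multifractal(c, config.multifractal) for c in curves)
    isotropy = _isotropy_report(curves, spectra, config.thresholds)
    logger.info("[%s] analysis done (%.2fs)", sample.name, time.perf_counter() - t0)
    return SampleReport(
        name=sample.name,
        group=sample.group,
        metrics=metrics,
        curves=curves,  # type: ignore[arg-type]
        spectra=spectra,  # type: ignore[arg-type]
        isotropy=isotropy,
    )


def _config_to_dict(config: PipelineConfig) -> dict[str, Any]:
    out = asdict(config)
    out["samples"] = [asdict(s) for s in config.samples]
    for s_dict, s in zip(out["samples"], config.samples):
        if s.phantom is not None:
            s_dict["phantom"]["shape"] = list(s.phantom.shape)
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> list[SampleReport]:
    """Analyze every configured sample and write all artifacts to ``outdir``.

    The manifest (``manifest.json``) records the full configuration, every
    written file, and the number of multifractal analyses performed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: list[SampleReport] = []
    artifacts: list[str] = []  # paths relative to outdir, so reruns compare equal
    for sample in config.samples:
        report = analyze_sample(sample, config)
        reports.append(report)
        sdir = outdir / sample.name
        sdir.mkdir(parents=True, exist_ok=True)
        with open(sdir / "metrics.json", "w") as fh:
            json.dump(report.metrics.to_dict(), fh, indent=2)
        artifacts.append(f"{sample.name}/metrics.json")
        for axis in range(3):
            report.curves[axis].to_csv(sdir / f"curve_axis{axis}.csv")
            report.spectra[axis].to_csv(sdir / f"spectrum_axis{axis}.csv")
            artifacts += [
                f"{sample.name}/curve_axis{axis}.csv",
                f"{sample.name}/spectrum_axis{axis}.csv",
            ]
        with open(sdir / "isotropy.json", "w") as fh:
            json.dump(report.isotropy.to_dict(), fh, indent=2)
        artifacts.append(f"{sample.name}/isotropy.json")
    manifest = {
        "config": _config_to_dict(config),
        "n_samples": len(reports),
        "n_multifractal_analyses": sum(len(r.spectra) for r in reports),
        "analyses": [
            {"sample": r.name, "axis": axis}
            for r in reports
            for axis in range(3)
        ],
        "artifacts": sorted(artifacts),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return reports


def aggregate_samples(
    metrics: list[PoreMetrics] | list[dict],
    groups: list[str] | None = None,
) -> dict[str, Any]:
    """Cohort summary: mean and sample SD (n−1) per metric, overall and by group.

    With a single report the SD is reported as NaN.
    """
    if not metrics:
        raise DegenerateInputError("no sample reports to aggregate")
    records = [m.to_dict() if isinstance(m, PoreMetrics) else dict(m) for m in metrics]
    if groups is None:
        groups = [str(r.get("group", "")) for r in records]
    if len(groups) != len(records):
        raise InvalidParameterError("groups must match metrics in length")
    numeric_keys = [
        k
        for k in records[0]
        if isinstance(records[0][k], (int, float)) and not isinstance(records[0][k], bool)
    ]

    def _summary(rows: list[dict]) -> dict[str, dict[str, float]]:
        out = {}
        for key in numeric_keys:
            vals = np.array([float(r[key]) for r in rows])
            out[key] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
            }
        return out

    by_group: dict[str, dict] = {}
    for g in sorted(set(groups)):
        rows = [r for r, gg in zip(records, groups) if gg == g]
        by_group[g] = _summary(rows)
    return {"overall": _summary(records), "by_group": by_group}


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from parsed YAML/JSON."""
    samples = []
    for s in data.get("samples", []):
        phantom = None
        if "phantom" in s and s["phantom"] is not None:
            p = dict(s["phantom"])
            p["shape"] = tuple(int(v) for v in p["shape"])
            phantom = PhantomSpec(**p)
        samples.append(
            SampleInput(
                name=s["name"],
                group=s.get("group", ""),
                phantom=phantom,
                tiff_path=s.get("tiff_path"),
                tiff_layout=s.get("tiff_layout", "multipage"),
                tiff_is_mask=bool(s.get("tiff_is_mask", False)),
            )
        )
    seg = SegmentationConfig(**data.get("segmentation", {}))
    mfa = MultifractalConfig(**data.get("multifractal", {}))
    thresholds = IsotropyThresholds(**data.get("thresholds", {}))
    kwargs = {
        k: data[k]
        for k in (
            "pore_connectivity",
            "min_pore_volume_vox",
            "small_pore_cutoff_vox",
            "voxel_edge_um",
            "seed",
        )
        if k in data
    }
    return PipelineConfig(
        samples=tuple(samples),
        segmentation=seg,
        multifractal=mfa,
        thresholds=thresholds,
        **kwargs,
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML or JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: expected a mapping at top level")
    return config_from_dict(data)
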