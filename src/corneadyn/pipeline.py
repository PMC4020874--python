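"""End-to-end analysis pipeline and its configuration.

Stage order: median filtration -> outer-edge detection -> contour
repair/validation/smoothing -> relative deformation -> eyeball/cornea
separation -> fast dynamics -> pattern, features and (optionally)
classification.  The pipeline itself contains no randomness: re-running
the same configuration on the same input reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edge_extraction as ee
from . import fast_dynamics as fd
from . import features_classes as fc
from . import separation as sep
from .io_sequences import (
    ConfigError,
    ContourError,
    ImageSequence,
    Map2D,
    read_sequence,
    write_map,
)

__all__ = ["PipelineConfig", "AnalysisResult", "run_pipeline", "analyze_sequence"]

log = logging.getLogger("corneadyn")


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline in one (JSON-round-trippable) place."""

    edge: ee.EdgeParams = field(default_factory=ee.EdgeParams)
    edge_method: str = "canny"  # canny | otsu
    border_band: int = 1
    se2: tuple[int, int] = fd.SE2_DEFAULT
    bands: tuple[tuple[int, int], tuple[int, int]] | None = None
    region_i_max_hz: float = fd.REGION_I_MAX_HZ
    region_ii_hz: tuple[float, float | None] = fd.REGION_II_HZ
    w2_harmonics: tuple[int, int] = fc.W2_HARMONIC_RANGE
    w3_threshold: float = 0.8
    frame_interval_s: float | None = None  # None -> use the sequence's own
    strict_validity: bool = True
    write_intermediate: bool = False

    def __post_init__(self) -> None:
        if self.edge_method not in ("canny", "otsu"):
            raise ConfigError(f"edge_method must be 'canny' or 'otsu', got {self.edge_method!r}")
        if not 0 < self.w3_threshold <= 1:
            raise ConfigError("w3_threshold must lie in (0, 1]")

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        edge_payload = payload.pop("edge", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if edge_payload is not None:
            edge_known = {f.name for f in dataclasses.fields(ee.EdgeParams)}
            edge_unknown = set(edge_payload) - edge_known
            if edge_unknown:
                raise ConfigError(f"unknown edge config keys: {sorted(edge_unknown)}")
            edge_payload = {
                k: tuple(v) if isinstance(v, list) else v for k, v in edge_payload.items()
            }
            payload["edge"] = ee.EdgeParams(**edge_payload)
        for key in ("se2", "region_ii_hz", "w2_harmonics"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        if payload.get("bands") is not None:
            payload["bands"] = tuple(tuple(b) for b in payload["bands"])
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class AnalysisResult:
    """Everything the pipeline measures for one eye."""

    contour_raw: Map2D
    contour: Map2D
    validity_raw: ee.ContourValidity
    validity: ee.ContourValidity
    decomposition: sep.DeformationDecomposition
    fast: fd.FastDynamics
    L_V: Map2D
    L_delta: Map2D
    features: fc.FeatureVector
    max_deflection_px: float
    frame_interval_s: float
    timings_s: dict[str, float]
    class_label: int | None = None


def analyze_sequence(seq: ImageSequence, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run every analysis stage on an in-memory sequence."""
    config = config or PipelineConfig()
    dt = config.frame_interval_s or seq.frame_interval_s
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    filtered = ee.median_filter_3d(seq, config.edge.median_mask)
    timings["median_filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    detector = ee.extract_edge_canny if config.edge_method == "canny" else ee.extract_edge_otsu
    # detect on the filtered data for robustness; refine sub-pixel positions
    # on the raw frames, free of the median filter's motion bias
    contour_raw = detector(filtered, config.edge, refine_on=seq)
    timings["edge_extraction"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    validity_raw = ee.validate_contour(contour_raw, config.edge)
    contour = ee.smooth_contour(ee.interpolate_missing(contour_raw), config.edge.contour_median_mask)
    validity = ee.validate_contour(contour, config.edge)
    if config.strict_validity and not validity.ok:
        raise ContourError(
            f"contour failed the validity rule: {validity.n_discontinuities} missing "
            f"columns, max interframe jump {validity.max_interframe_jump:.1f} px "
            f"(limit {validity.max_jump_px} px)"
        )
    timings["contour_validation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    decomposition = sep.separate_eyeball(sep.relative_deformation(contour), config.border_band)
    timings["separation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fast = fd.compute_fast_dynamics(
        decomposition.L_TR, dt, config.se2, config.bands,
        config.region_i_max_hz, config.region_ii_hz,
    )
    timings["fast_dynamics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    l_v = fc.build_pattern(decomposition.L_TO, decomposition.L_TR, config.se2)
    l_delta = fc.pattern_error(decomposition.L_T, l_v)
    features = fc.FeatureVector(
        w1=fc.feature_w1(l_delta),
        w2=fc.feature_w2(fast.F_QL, fast.F_QR, config.w2_harmonics),
        w3=fc.feature_w3(fast.comp_II_L, fast.comp_II_R, config.w3_threshold),
    )
    timings["features"] = time.perf_counter() - t0

    return AnalysisResult(
        contour_raw=contour_raw,
        contour=contour,
        validity_raw=validity_raw,
        validity=validity,
        decomposition=decomposition,
        fast=fast,
        L_V=l_v,
        L_delta=l_delta,
        features=features,
        max_deflection_px=sep.max_deflection(decomposition.L_TR),
        frame_interval_s=dt,
        timings_s=timings,
    )


def _write_outputs(result: AnalysisResult, config: PipelineConfig, out_dir: Path, eye_id: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    features = pd.DataFrame(
        [
            {
                "eye_id": eye_id,
                "w1": result.features.w1,
                "w2": result.features.w2,
                "w3": result.features.w3,
                "w3_ms": result.features.w3_ms(result.frame_interval_s),
                "max_deflection_px": result.max_deflection_px,
                "class": result.class_label if result.class_label is not None else "",
            }
        ]
    )
    features.to_csv(out_dir / "features.csv", index=False)
    report = {
        "eye_id": eye_id,
        "features": {"w1": result.features.w1, "w2": result.features.w2, "w3": result.features.w3},
        "w3_ms": result.features.w3_ms(result.frame_interval_s),
        "max_deflection_px": result.max_deflection_px,
        "class": result.class_label,
        "frame_interval_s": result.frame_interval_s,
        "contour_validity": {
            "raw": dataclasses.asdict(result.validity_raw),
            "final": dataclasses.asdict(result.validity),
        },
        "timings_s": result.timings_s,
        "config": config.to_dict(),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    if config.write_intermediate:
        write_map(result.contour, out_dir / "contour.csv")
        write_map(result.decomposition.L_T, out_dir / "L_T.csv")
        write_map(result.decomposition.L_TO, out_dir / "L_TO.csv")
        write_map(result.decomposition.L_TR, out_dir / "L_TR.csv")
        write_map(result.fast.L_Q, out_dir / "L_Q.csv")
        write_map(result.L_delta, out_dir / "L_delta.csv")
        n_cols = result.decomposition.L_T.shape[0]
        times = np.arange(result.fast.L_QL.size) * result.frame_interval_s
        centre = pd.DataFrame(
            {
                "frame": np.arange(result.fast.L_QL.size),
                "time_s": times,
                "L_T": result.decomposition.L_T.values[n_cols // 2, :],
                "L_TO": result.decomposition.L_TO.values[n_cols // 2, :],
                "L_TR": result.decomposition.L_TR.values[n_cols // 2, :],
            }
        )
        centre.to_csv(out_dir / "centerline.csv", index=False)
        spectra = pd.DataFrame(
            {
                "bin": np.arange(result.fast.freqs_hz.size),
                "freq_hz": result.fast.freqs_hz,
                "magnitude_L": result.fast.F_QL,
                "magnitude_R": result.fast.F_QR,
            }
        )
        spectra.to_csv(out_dir / "spectra.csv", index=False)


def run_pipeline(
    source: ImageSequence | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    tree: "fc.DecisionTree | None" = None,
    eye_id: str | None = None,
) -> AnalysisResult:
    """Analyse a sequence (path or in-memory), optionally classify and write reports.

    On contour-validity failure a :class:`ContourError` propagates after the
    raw contour map has been dumped to ``out_dir`` for diagnosis (when an
    output directory is given).
    """
    config = config or PipelineConfig()
    if isinstance(source, (str, Path)):
        eye_id = eye_id or Path(source).stem
        seq = read_sequence(source)
    else:
        eye_id = eye_id or "sequence"
        seq = source
    log.info("analysing %s: dims %s", eye_id, seq.dims)
    try:
        result = analyze_sequence(seq, config)
    except ContourError:
        if out_dir is not None:
            dump = Path(out_dir)
            dump.mkdir(parents=True, exist_ok=True)
            detector = ee.extract_edge_canny if config.edge_method == "canny" else ee.extract_edge_otsu
            raw = detector(ee.median_filter_3d(seq, config.edge.median_mask), config.edge)
            write_map(raw, dump / "contour_invalid.csv")
            log.error("contour validity failure; raw contour dumped to %s", dump)
        raise
    if tree is not None:
        result.class_label = fc.classify(tree, result.features)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir), eye_id)
    return result
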