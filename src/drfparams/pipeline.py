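"""End-to-end biplane pipeline: contours -> axes -> landmarks -> parameters.

Single-case mode fails fast inside a stage but always returns a
CaseResult (with the error recorded and partial outputs preserved);
batch mode is fail-soft per case.
"""

from __future__ import annotations

import csv
import json
import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .axis_fitting import AxisFitConfig, AxisLine, fit_axis, sample_interior_points
from .contour_extraction import ContourConfig, extract_part_contour
from .landmark_detection import (
    LandmarkSet,
    RotatingLineConfig,
    detect_rim_pair,
    detect_ST,
    detect_UBR,
    detect_UH,
)
from .mask_io import LabelMask, View, read_label_mask, read_metadata
from .radiographic_params import RadiographicParams, assemble_params

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    contour: ContourConfig = field(default_factory=ContourConfig)
    axis: AxisFitConfig = field(default_factory=AxisFitConfig)
    rotating: RotatingLineConfig = field(default_factory=RotatingLineConfig)
    spacing: float | None = None
    emit_overlays: bool = False
    log_level: str = "WARNING"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            contour=ContourConfig(**raw.get("contour", {})),
            axis=AxisFitConfig(**raw.get("axis", {})),
            rotating=RotatingLineConfig(**raw.get("rotating", {})),
            spacing=raw.get("spacing"),
            emit_overlays=bool(raw.get("emit_overlays", False)),
            log_level=raw.get("log_level", "WARNING"),
        )


@dataclass
class CaseResult:
    params: RadiographicParams | None = None
    landmarks: LandmarkSet | None = None
    ap_axis: AxisLine | None = None
    lat_axis: AxisLine | None = None
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict() if self.params else None,
            "landmarks": self.landmarks.to_dict() if self.landmarks else None,
            "ap_axis": self.ap_axis.to_dict() if self.ap_axis else None,
            "lat_axis": self.lat_axis.to_dict() if self.lat_axis else None,
            "timings": {k: round(v, 6) for k, v in self.timings.items()},
            "warnings": list(self.warnings),
            "error": self.error,
        }


def _axis_cfg_for(cfg: AxisFitConfig, view: str, part: str) -> AxisFitConfig:
    """Derive a per-part seed so sampling is reproducible and decorrelated."""
    tag = zlib.crc32(f"{view}/{part}".encode())
    ss = np.random.SeedSequence([cfg.seed, tag])
    child = int(ss.generate_state(1)[0])
    return AxisFitConfig(n_points=cfg.n_points, seed=child, alpha=cfg.alpha,
                         max_iter=cfg.max_iter, tol=cfg.tol,
                         backtracking=cfg.backtracking)


def _part_axis(mask: LabelMask, part: str, cfg: PipelineConfig) -> AxisLine:
    contour = extract_part_contour(mask, part, cfg.contour)
    acfg = _axis_cfg_for(cfg.axis, mask.view.value, part)
    pts = sample_interior_points(contour, acfg)
    return fit_axis(pts, acfg)


def run_case(ap: LabelMask, lat: LabelMask, cfg: PipelineConfig | None = None) -> CaseResult:
    """Contour -> axis -> landmarks -> parameters for one biplane pair."""
    cfg = cfg or PipelineConfig()
    result = CaseResult()
    t0 = time.perf_counter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ap_distal = extract_part_contour(ap, "distal_radius", cfg.contour)
            ulna_contour = extract_part_contour(ap, "ulna", cfg.contour)
            lat_distal = extract_part_contour(lat, "distal_radius", cfg.contour)
            result.timings["contours"] = time.perf_counter() - t0

            t1 = time.perf_counter()
            ap_axis = _part_axis(ap, "ulna", cfg)
            lat_axis = _part_axis(lat, "proximal_radius", cfg)
            result.ap_axis, result.lat_axis = ap_axis, lat_axis
            result.timings["axes"] = time.perf_counter() - t1

            t2 = time.perf_counter()
            st = detect_ST(ap_distal)
            ubr = detect_UBR(ap_distal, st, ap_axis, cfg.rotating)
            uh, ul_ubr = detect_UH(ulna_contour, ap_axis, cfg.rotating)
            dj, vjb, displacement = detect_rim_pair(lat_distal, lat_axis, cfg.rotating)
            result.landmarks = LandmarkSet(
                ST=tuple(st), UBR=tuple(ubr), UH=tuple(uh), ul_UBR=tuple(ul_ubr),
                DJ=tuple(dj), VJB=tuple(vjb), displacement=displacement,
            )
            result.timings["landmarks"] = time.perf_counter() - t2

            t3 = time.perf_counter()
            result.params = assemble_params(result.landmarks, ap_axis, lat_axis,
                                            spacing=cfg.spacing)
            result.timings["params"] = time.perf_counter() - t3
        result.warnings.extend(str(w.message) for w in caught)
        if result.params is not None:
            result.warnings.extend(result.params.warnings)
    except (ValueError, KeyError) as exc:
        result.error = str(exc)
    result.timings["total"] = time.perf_counter() - t0
    return result


def discover_cases(case_dir) -> list[dict]:
    """Find paired <stem>_ap.png / <stem>_lat.png masks with optional sidecars."""
    case_dir = Path(case_dir)
    cases = []
    for ap_path in sorted(case_dir.glob("*_ap.png")):
        stem = ap_path.name[: -len("_ap.png")]
        lat_path = case_dir / f"{stem}_lat.png"
        if not lat_path.exists():
            log.warning("skipping unpaired case %s (no LAT mask)", stem)
            continue
        meta_path = case_dir / f"{stem}_meta.json"
        truth_path = case_dir / f"{stem}_truth.json"
        cases.append({
            "stem": stem, "ap": ap_path, "lat": lat_path,
            "meta": meta_path if meta_path.exists() else None,
            "truth": truth_path if truth_path.exists() else None,
        })
    return cases


_PARAM_KEYS = ("RA_deg", "RL", "UV", "PT_deg")


def run_batch(case_dir, cfg: PipelineConfig | None = None,
              out_dir=None) -> dict:
    """Process a directory of paired masks; emit per-case JSON and a CSV table.

    When truth sidecars exist, the summary carries signed errors with
    per-parameter mean and SD.  Corrupt or failing cases are skipped
    with a record, never abort the batch.
    """
    cfg = cfg or PipelineConfig()
    cases = discover_cases(case_dir)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    errors: dict[str, list[float]] = {k: [] for k in _PARAM_KEYS}
    n_failed = 0
    for case in cases:
        meta = read_metadata(case["meta"]) if case["meta"] else {}
        try:
            ap = read_label_mask(case["ap"], View.AP, meta)
            lat = read_label_mask(case["lat"], View.LAT, meta)
            result = run_case(ap, lat, cfg)
        except (ValueError, KeyError, OSError) as exc:
            result = CaseResult(error=str(exc))
        if out_dir:
            (out_dir / f"{case['stem']}_result.json").write_text(
                json.dumps(result.to_dict(), indent=2))
        row = {"case": case["stem"], "error": result.error or ""}
        if result.params:
            row.update({k: getattr(result.params, k) for k in _PARAM_KEYS})
            if case["truth"]:
                truth = json.loads(Path(case["truth"]).read_text())
                tp = truth["params"]
                for k in _PARAM_KEYS:
                    err = getattr(result.params, k) - tp[k]
                    row[f"err_{k}"] = err
                    errors[k].append(err)
        else:
            n_failed += 1
        rows.append(row)
    summary = {
        "n_cases": len(rows),
        "n_failed": n_failed,
        "error_mean": {k: float(np.mean(v)) for k, v in errors.items() if v},
        "error_sd": {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                     for k, v in errors.items() if v},
    }
    if out_dir and rows:
        fieldnames = sorted({key for r in rows for key in r},
                            key=lambda k: (k != "case", k))
        with open(out_dir / "batch.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    if not rows:
        log.warning("no cases found in %s", case_dir)
    return summary


def render_overlay(mask: LabelMask, result: CaseResult, path) -> None:
    """Debug overlay: mask, detected landmarks and axes (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mask.pixels, cmap="tab10", interpolation="nearest")
    if result.landmarks:
        for name, p in result.landmarks.to_dict().items():
            if isinstance(p, list):
                ax.plot(p[0], p[1], "r+", markersize=10)
                ax.annotate(name, p, color="white", fontsize=8)
    for axis in (result.ap_axis, result.lat_axis):
        if axis is not None:
            a = axis.anchor()
            d = axis.direction_distal()
            ts = np.array([-600, 600])
            ax.plot(a[0] + ts * d[0], a[1] + ts * d[1], "y-", linewidth=0.8)
    ax.set_xlim(0, mask.pixels.shape[1])
    ax.set_ylim(mask.pixels.shape[0], 0)
    if result.params:
        ax.set_title(", ".join(f"{k}={getattr(result.params, k):.1f}" for k in _PARAM_KEYS))
    fig.savefig(path, dpi=120)
    plt.close(fig)
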