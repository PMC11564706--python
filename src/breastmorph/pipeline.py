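"""End-to-end case analysis: load → split → landmarks → metrics → quadrants
→ hulls, with a versioned JSON-serializable report and an exit-code
taxonomy for batch use.

All randomness lives in phantom generation; the analysis path is
deterministic, so repeated runs on identical inputs yield byte-identical
reports (no timestamps are embedded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .hulls import multicentric_hulls, unicentric_hull
from .labelmap import LabelMap, TissueSchema, load_labelmap, side_subvolume
from .landmarks import LandmarkNotFoundError, NippleParams, build_breast_box, locate_nipple
from .metrics import EmptyMaskError, tumor_metrics_report
from .quadrants import assign_quadrants, balance_plane

__all__ = ["RunConfig", "EXIT_CODES", "run_case", "run_case_from_map"]

REPORT_SCHEMA_VERSION = 1

EXIT_CODES = {"success": 0, "no-tumor": 2, "landmark-failure": 3, "io-error": 4}


@dataclass
class RunConfig:
    input_path: str | None = None
    schema_path: str | None = None
    sides: tuple = ("left", "right")
    nipple_params: NippleParams = field(default_factory=NippleParams)
    margins_mm: tuple = (10.0,)
    hull_mode: str = "multicentric"
    connectivity: str = "face"
    midline: int | None = None

    def __post_init__(self) -> None:
        for m in self.margins_mm:
            if not 0 <= m <= 20:
                raise ValueError(f"margin {m} mm outside [0, 20]")
        if self.hull_mode not in ("unicentric", "multicentric", "both"):
            raise ValueError(f"unknown hull mode {self.hull_mode!r}")

    def echo(self) -> dict:
        return {
            "input_path": self.input_path,
            "schema_path": self.schema_path,
            "sides": list(self.sides),
            "nipple_params_mm": {
                "neighborhood_radius": self.nipple_params.neighborhood_radius_mm,
                "posterior_offset": self.nipple_params.posterior_offset_mm,
            },
            "margins_mm": [float(m) for m in self.margins_mm],
            "hull_mode": self.hull_mode,
            "connectivity": self.connectivity,
            "midline": self.midline,
        }


def _hull_summaries(sub, margins, mode, connectivity):
    tumor = sub.tissue_mask("tumor")
    out = []
    for margin in margins:
        entry = {"margin_mm": float(margin)}
        if mode in ("multicentric", "both"):
            hulls = multicentric_hulls(
                tumor, sub.spacing_mm, margin, connectivity, sub.origin_mm
            )
            entry["multicentric"] = {
                "n_hulls": len(hulls),
                "merged": any(len(h.component_ids) > 1 for h in hulls),
                "volumes_mm3": [round(h.volume_mm3, 1) for h in hulls],
            }
        if mode in ("unicentric", "both"):
            uh = unicentric_hull(tumor, sub.spacing_mm, margin, sub.origin_mm)
            entry["unicentric"] = {"volume_mm3": round(uh.volume_mm3, 1)}
        out.append(entry)
    return out


def run_case_from_map(labelmap: LabelMap, config: RunConfig) -> dict:
    """Analyze one loaded label map; returns the CaseReport dict."""
    report = {
        "tool": "breastmorph",
        "version": __version__,
        "report_schema_version": REPORT_SCHEMA_VERSION,
        "config": config.echo(),
        "sides": {},
        "warnings": [],
        "status": "success",
    }
    statuses = []
    for side in config.sides:
        side_report: dict = {}
        report["sides"][side] = side_report
        try:
            nipple = locate_nipple(labelmap, side, config.nipple_params, config.midline)
            box = build_breast_box(labelmap, side, config.midline)
        except LandmarkNotFoundError as exc:
            report["warnings"].append(f"{side}: {exc}")
            statuses.append("landmark-failure")
            continue
        side_report["nipple_mm"] = [round(v, 2) for v in nipple]
        side_report["breast_box"] = box.to_dict()
        if box.fallback:
            report["warnings"].append(f"{side}: breast box used tight-bounds fallback")

        sub = side_subvolume(labelmap, side, config.midline)
        if not sub.tissue_mask("tumor").any():
            report["warnings"].append(f"{side}: no tumor voxels")
            statuses.append("no-tumor")
            continue
        try:
            metrics = tumor_metrics_report(
                labelmap, side, nipple, box, config.connectivity, config.midline
            )
            side_report["tumor_metrics"] = metrics.to_dict()
            angle, plane = balance_plane(labelmap, side, nipple, box, midline=config.midline)
            quad = assign_quadrants(labelmap, side, nipple, plane, midline=config.midline)
            side_report["quadrants"] = quad.to_dict()
            if not plane.balanced:
                report["warnings"].append(f"{side}: balance plane residual above tolerance")
            side_report["hulls"] = _hull_summaries(
                sub, config.margins_mm, config.hull_mode, config.connectivity
            )
            statuses.append("success")
        except EmptyMaskError as exc:
            report["warnings"].append(f"{side}: {exc}")
            statuses.append("no-tumor")

    if "success" not in statuses and statuses:
        report["status"] = (
            "landmark-failure" if "landmark-failure" in statuses else "no-tumor"
        )
    elif "no-tumor" in statuses or "landmark-failure" in statuses:
        # partial: some side succeeded
        report["status"] = "success"
    return report


def run_case(config: RunConfig) -> dict:
    """Load the configured input and analyze it."""
    if config.input_path is None:
        raise ValueError("run_case requires an input path")
    schema = (
        TissueSchema.from_json(config.schema_path)
        if config.schema_path
        else TissueSchema.default()
    )
    try:
        labelmap = load_labelmap(config.input_path, schema)
    except (OSError, ValueError) as exc:
        return {
            "tool": "breastmorph",
            "version": __version__,
            "report_schema_version": REPORT_SCHEMA_VERSION,
            "config": config.echo(),
            "sides": {},
            "warnings": [f"io: {exc}"],
            "status": "io-error",
        }
    return run_case_from_map(labelmap, config)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
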