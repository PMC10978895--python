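"""Batch analysis of whole assemblages and summary statistics.

Processes every mesh in a directory through the full pipeline, writing a
per-segment CSV, a per-artifact CSV, a summary JSON (including the pooled
angle distribution and its trough-derived sharp/blunt threshold) and a
processing log. Individual failures are logged and skipped so one corrupt
scan cannot abort an assemblage run.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .metrics import ThresholdResult, sharp_threshold
from .pipeline import ArtifactAnalysis, analyze_path

logger = logging.getLogger(__name__)

__all__ = ["BatchResult", "run_batch", "summarize_assemblage"]

MESH_SUFFIXES = (".obj", ".ply", ".stl", ".wrl", ".vrml")


@dataclass
class BatchResult:
    """Outcome of an assemblage run."""

    status: str  # "ok" | "partial" | "empty"
    analyses: dict[str, ArtifactAnalysis] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    segment_table: pd.DataFrame | None = None
    artifact_table: pd.DataFrame | None = None


def summarize_assemblage(
    analyses: dict[str, ArtifactAnalysis],
    threshold_kde_floor_deg: float = 2.0,
) -> dict:
    """Assemblage-level aggregation of per-artifact reports.

    Includes segment-count proportions, the pooled segment-angle
    distribution with its data-driven trough threshold (when at least 30
    segments are pooled and the distribution is bimodal), the mean percent
    of sharp perimeter with a normal-approximation 95% CI, and
    concavity-label proportions.
    """
    reports = [a.report for a in analyses.values()]
    if not reports:
        return {}
    seg_counts = pd.Series([r.n_segments for r in reports])
    count_props = (
        seg_counts.value_counts(normalize=True).sort_index().to_dict()
    )
    pooled = np.concatenate(
        [[s.mean_angle for s in r.segments] for r in reports]
    )
    threshold: ThresholdResult | None = None
    if pooled.size >= 30:
        threshold = sharp_threshold(
            pooled, threshold_kde_floor_deg=threshold_kde_floor_deg
        )
    pct = np.array([r.percent_sharp_perimeter for r in reports])
    ci = 1.96 * pct.std(ddof=1) / np.sqrt(len(pct)) if len(pct) > 1 else 0.0
    labels = pd.Series(
        [s.concavity_label for r in reports for s in r.segments]
    )
    label_props = labels.value_counts(normalize=True).to_dict()
    return {
        "n_artifacts": len(reports),
        "n_segments_total": int(seg_counts.sum()),
        "segments_per_artifact_mean": float(seg_counts.mean()),
        "segment_count_proportions": {int(k): float(v) for k, v in count_props.items()},
        "n_sharp_segments_total": int(
            sum(r.n_sharp_edges for r in reports)
        ),
        "pct_artifacts_with_blunt_perimeter": float(
            100.0
            * np.mean([r.percent_sharp_perimeter < 100.0 - 1e-9 for r in reports])
        ),
        "pct_artifacts_multi_edge": float(
            100.0 * np.mean([r.n_sharp_edges > 1 for r in reports])
        ),
        "percent_sharp_mean": float(pct.mean()),
        "percent_sharp_ci95": float(ci),
        "pooled_trough_deg": threshold.trough_deg if threshold else None,
        "pooled_threshold_rounded_deg": threshold.rounded_deg
        if threshold
        else None,
        "pooled_unimodal": threshold.unimodal if threshold else None,
        "concavity_label_proportions": {
            str(k): float(v) for k, v in label_props.items()
        },
    }


def run_batch(
    input_dir: str | Path,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> BatchResult:
    """Analyze every mesh file in ``input_dir``; write tables and summary.

    Returns a :class:`BatchResult` with status "ok" when every file
    processed, "partial" when some failed (failures are logged, not
    fatal). An empty input directory raises ``FileNotFoundError``.
    """
    cfg = config or RunConfig()
    input_dir = Path(input_dir)
    paths = sorted(
        p
        for p in input_dir.iterdir()
        if p.suffix.lower() in MESH_SUFFIXES and p.is_file()
    )
    if not paths:
        raise FileNotFoundError(f"no mesh files found in {input_dir}")

    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    analyses: dict[str, ArtifactAnalysis] = {}
    failures: dict[str, str] = {}
    timings: dict[str, float] = {}
    for path in paths:
        t0 = time.perf_counter()
        try:
            analyses[path.stem] = analyze_path(path, config=cfg)
        except Exception as exc:
            failures[path.name] = f"{type(exc).__name__}: {exc}"
            logger.warning("skipping %s: %s", path.name, exc)
            logger.debug("%s", traceback.format_exc())
        timings[path.name] = time.perf_counter() - t0

    summary = summarize_assemblage(
        analyses, threshold_kde_floor_deg=cfg.threshold_kde_floor_deg
    )
    summary["failures"] = failures
    status = "ok" if not failures else ("partial" if analyses else "empty")

    segment_table = (
        pd.concat(
            [a.report.segment_frame() for a in analyses.values()],
            ignore_index=True,
        )
        if analyses
        else pd.DataFrame()
    )
    artifact_table = pd.DataFrame(
        [a.report.summary_row() for a in analyses.values()]
    )

    if out:
        segment_table.to_csv(
            out / "segments.csv", index=False, float_format="%.6g"
        )
        artifact_table.to_csv(
            out / "artifacts.csv", index=False, float_format="%.6g"
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        cfg.to_json(out / "config.json")
        with open(out / "run.log", "w") as fh:
            for name, dt in timings.items():
                state = "fail" if name in failures else "ok"
                fh.write(f"{name}\t{state}\t{dt:.2f}s\n")
    return BatchResult(
        status=status,
        analyses=analyses,
        failures=failures,
        summary=summary,
        segment_table=segment_table,
        artifact_table=artifact_table,
    )
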