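"""Diagnostic figures: angle-colored outlines and profile/segmentation plots."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["plot_artifact"]


def plot_artifact(analysis, out_prefix: str | Path) -> list[Path]:
    """Write two figures for one analyzed artifact.

    1. ``<prefix>_outline.png`` — plan-view outline colored by edge angle,
       with crosses at change points;
    2. ``<prefix>_profile.png`` — arc length vs edge angle with change
       points (vertical lines) and per-segment means (horizontal lines).

    Returns the written paths; if matplotlib is unavailable the plots are
    skipped with a warning.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - backend present in tests
        logger.warning("plotting skipped: %s", exc)
        return []

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    outline = analysis.outline
    profile = analysis.profile
    seg = analysis.segmentation
    written = []

    fig, ax = plt.subplots(figsize=(5, 6))
    pts = outline.coords
    sc = ax.scatter(
        pts[:, 0], pts[:, 1], c=profile.angle, cmap="viridis", s=4,
        vmin=0, vmax=180,
    )
    for b in seg.breakpoints:
        ax.plot(pts[b, 0], pts[b, 1], "rx", markersize=10, markeredgewidth=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"{analysis.report.artifact_id}: edge angle")
    fig.colorbar(sc, ax=ax, label="edge angle (deg)")
    path = out_prefix.parent / f"{out_prefix.name}_outline.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(outline.arc_pos, profile.angle, "k-", linewidth=0.8)
    for b in seg.breakpoints:
        ax.axvline(outline.arc_pos[b], color="r", linewidth=1)
    for (a, b), mean in zip(seg.segment_slices(), seg.segment_means):
        stop = outline.arc_pos[b - 1] if b <= outline.n else outline.arc_pos[-1]
        ax.hlines(mean, outline.arc_pos[a], stop, color="b", linewidth=1.5)
    ax.set_xlabel("arc length (length units)")
    ax.set_ylabel("edge angle (deg)")
    ax.set_title(
        f"{analysis.report.artifact_id}: {seg.chosen_k} change points"
    )
    fig.tight_layout()
    path = out_prefix.parent / f"{out_prefix.name}_profile.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
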