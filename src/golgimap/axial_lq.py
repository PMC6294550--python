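"""Axial localization quotient (LQ).

The LQ places a marker's fluorescence centroid on the cis->trans axis
defined per mini-stack by the GM130 (cis) and GalT (trans) reference
centroids, normalized so GM130 maps to 0.00 and GalT to 1.00.  It is the
scalar projection of the marker's displacement from GM130 onto the axis,
divided by the axis length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image_core import Point

DEFAULT_MIN_AXIS_PX = 3.0
DEFAULT_PLAUSIBLE_RANGE = (-3.0, 3.0)


class LQError(ValueError):
    pass


@dataclass
class LQRecord:
    stack_id: str
    centroid_marker: Point
    centroid_gm130: Point
    centroid_galt: Point
    lq: float
    axis_length_px: float
    accepted: bool = True
    reject_reason: str = ""
    flagged: bool = False


@dataclass
class LQSummary:
    channel: str
    mean_lq: float
    sem: float | None
    n: int
    n_rejected: int = 0


def compute_lq(
    marker: Point,
    gm130: Point,
    galt: Point,
    min_axis_px: float = DEFAULT_MIN_AXIS_PX,
    plausible_range: tuple[float, float] = DEFAULT_PLAUSIBLE_RANGE,
    stack_id: str = "",
) -> LQRecord:
    """LQ of one mini-stack from its three centroids.

    ``lq = ((marker - gm130) . (galt - gm130)) / |galt - gm130|^2`` so a
    marker at GM130 scores 0.00 and one at GalT scores 1.00.  Stacks whose
    GM130->GalT axis is shorter than ``min_axis_px`` are rejected (short
    axes amplify centroid noise); LQs outside ``plausible_range`` are
    flagged but kept.
    """
    ax = np.array([galt.x - gm130.x, galt.y - gm130.y])
    axis_len = float(np.hypot(*ax))
    if axis_len < min_axis_px:
        return LQRecord(
            stack_id, marker, gm130, galt,
            lq=float("nan"), axis_length_px=axis_len,
            accepted=False,
            reject_reason=f"axis {axis_len:.2f} px < min_axis_px {min_axis_px}",
        )
    disp = np.array([marker.x - gm130.x, marker.y - gm130.y])
    lq = float(disp @ ax / (axis_len**2))
    lo, hi = plausible_range
    return LQRecord(
        stack_id, marker, gm130, galt,
        lq=lq, axis_length_px=axis_len,
        accepted=True, flagged=not (lo <= lq <= hi),
    )


def summarize_lq(records: Sequence[LQRecord], channel: str = "") -> LQSummary:
    """Mean, SEM (= sd/sqrt(n)) and n over accepted records."""
    accepted = [r.lq for r in records if r.accepted]
    n_rejected = sum(1 for r in records if not r.accepted)
    if not accepted:
        raise LQError("no accepted LQ records to summarize")
    n = len(accepted)
    vals = np.asarray(accepted, dtype=float)
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
    return LQSummary(channel=channel, mean_lq=float(vals.mean()), sem=sem, n=n,
                     n_rejected=n_rejected)


# ---------------------------------------------------------------------------
# CSV-facing helpers
# ---------------------------------------------------------------------------

def lq_from_centroid_table(
    df: pd.DataFrame,
    marker_channel: str,
    gm130_channel: str = "gm130",
    galt_channel: str = "galt",
    min_axis_px: float = DEFAULT_MIN_AXIS_PX,
) -> list[LQRecord]:
    """Compute per-stack LQs from a long-format centroid table.

    Expects columns ``stack_id, channel, x, y``; stacks missing any of the
    three channels are skipped.
    """
    for col in ("stack_id", "channel", "x", "y"):
        if col not in df.columns:
            raise LQError(f"centroid table missing column {col!r}")
    records = []
    for stack_id, grp in df.groupby("stack_id", sort=True):
        by_channel = {row["channel"]: Point(row["x"], row["y"]) for _, row in grp.iterrows()}
        if not all(c in by_channel for c in (marker_channel, gm130_channel, galt_channel)):
            continue
        records.append(
            compute_lq(
                by_channel[marker_channel],
                by_channel[gm130_channel],
                by_channel[galt_channel],
                min_axis_px=min_axis_px,
                stack_id=str(stack_id),
            )
        )
    return records


def records_to_frame(records: Iterable[LQRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stack_id": r.stack_id,
                "lq": r.lq,
                "axis_length_px": r.axis_length_px,
                "accepted": r.accepted,
                "flagged": r.flagged,
                "reject_reason": r.reject_reason,
                "marker_x": r.centroid_marker.x,
                "marker_y": r.centroid_marker.y,
                "gm130_x": r.centroid_gm130.x,
                "gm130_y": r.centroid_gm130.y,
                "galt_x": r.centroid_galt.x,
                "galt_y": r.centroid_galt.y,
            }
            for r in records
        ]
    )


def summary_to_frame(summaries: Iterable[LQSummary]) -> pd.DataFrame:
    """Table-style summary: Name, LQ, N, SEM."""
    return pd.DataFrame(
        [
            {
                "Name": s.channel,
                "LQ": s.mean_lq,
                "N": s.n,
                "SEM": s.sem if s.sem is not None else np.nan,
            }
            for s in summaries
        ]
    )
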