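"""Lateral-localization core: gyradius normalization, centroid alignment,
en-face averaging, radial mean profiles and half-max radius/diameter
extraction.

The pipeline mirrors the standard mini-stack averaging workflow: each
background-subtracted square crop is rescaled isotropically so the
reference (rim marker) channel has a gyradius of exactly 100 px, embedded
into a 701x701 canvas, translated so the reference fluorescence centroid
sits at (350, 350), and averaged per pixel across stacks.  Radial mean
profiles are taken over unit-width annuli for radii 1..350 px, and a
marker's radius is the half-maximum position on the outer slope of its
profile, normalized by the reference channel's radius from the same
averaged set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_core import (
    ImageError,
    MultiChannelImage,
    Point,
    center_of_mass,
    line_profile,
)

CANVAS_SIZE = 701
CANVAS_CENTER = 350.0  # (350, 350) is the center pixel of the 701x701 canvas
TARGET_GYRADIUS = 100.0
PROFILE_MAX_RADIUS = 350


class AnalysisError(ValueError):
    """Raised when a measurement cannot be made on the given input."""


@dataclass
class MiniStack:
    """A square, background-subtracted multi-channel crop of one mini-stack."""

    image: MultiChannelImage
    reference_channel: str
    stack_id: str = ""

    def __post_init__(self) -> None:
        h, w = self.image.shape
        if h != w:
            raise AnalysisError(f"mini-stack image must be square, got {w}x{h}")
        ref = self.image.channel(self.reference_channel)
        if ref.sum() <= 0:
            raise AnalysisError("reference channel has zero total intensity")


@dataclass
class NormalizedMiniStack:
    """A mini-stack rescaled to reference gyradius 100 px on a 701x701 canvas."""

    image: MultiChannelImage
    reference_channel: str
    scale_factor: float
    reference_gyradius_px: float
    shift_px: tuple[float, float] = (0.0, 0.0)
    stack_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != (CANVAS_SIZE, CANVAS_SIZE):
            raise AnalysisError(
                f"normalized canvas must be {CANVAS_SIZE}x{CANVAS_SIZE}, got {self.image.shape}"
            )


@dataclass
class EnFaceAverage:
    image: MultiChannelImage
    n: int
    stack_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise AnalysisError("average requires n >= 1")
        if self.stack_ids and len(self.stack_ids) != self.n:
            raise AnalysisError("stack_ids length must equal n")


@dataclass
class RadialProfile:
    """Radial mean intensity vs integer radius 1..350 px about a centroid."""

    radii_px: np.ndarray
    values: dict[str, np.ndarray]
    center: Point
    pixel_size_nm: float
    mode: str = "annular"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.radii_px = np.asarray(self.radii_px)
        if np.any(np.diff(self.radii_px) <= 0):
            raise AnalysisError("radii must be strictly increasing")
        for name, v in self.values.items():
            if len(v) != len(self.radii_px):
                raise AnalysisError(f"channel {name!r} length mismatch")

    def normalize(self) -> "RadialProfile":
        out = {}
        for name, v in self.values.items():
            m = v.max()
            out[name] = v / m if m > 0 else v.copy()
        return RadialProfile(
            self.radii_px.copy(), out, self.center, self.pixel_size_nm, self.mode, True
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "radius_px": self.radii_px,
            "radius_nm": self.radii_px * self.pixel_size_nm,
        }
        data.update(self.values)
        return pd.DataFrame(data)


@dataclass
class MarkerRadius:
    channel_name: str
    radius_px: float
    radius_normalized: float
    peak_radius_px: float
    half_max_value: float
    stack_id: str = ""


# ---------------------------------------------------------------------------
# Gyradius
# ---------------------------------------------------------------------------

def gyradius(channel: np.ndarray, center: Point) -> float:
    """Intensity-weighted RMS distance of all pixels from ``center`` (px).

    ``sqrt(sum_i I_i * r_i^2 / sum_i I_i)`` with r_i the Euclidean distance
    of pixel i's center to ``center``; every pixel of the image contributes.
    Equals the radius for an ideal thin ring.
    """
    arr = np.asarray(channel, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise AnalysisError("gyradius: zero total intensity")
    ys, xs = np.indices(arr.shape)
    r2 = (xs - center.x) ** 2 + (ys - center.y) ** 2
    return float(np.sqrt((arr * r2).sum() / total))


# ---------------------------------------------------------------------------
# Normalize / align / average
# ---------------------------------------------------------------------------

def normalize_ministack(
    ms: MiniStack,
    normalize_intensity: bool = True,
    interp_order: int = 1,
    max_clipped_fraction: float = 0.05,
) -> NormalizedMiniStack:
    """Rescale all channels so the reference gyradius is 100 px, on a 701x701 canvas.

    The isotropic scale factor is ``100 / gyradius(reference)``, applied
    identically to every channel about the input image center; the scaled
    image is embedded centrally in the 701x701 canvas.  When
    ``normalize_intensity`` is on, each channel is divided by its pixel sum
    so stacks contribute equal weight to subsequent averaging.
    """
    ref = ms.image.channel(ms.reference_channel)
    ref_centroid = center_of_mass(ref)
    g = gyradius(ref, ref_centroid)
    if g <= 0:
        raise AnalysisError("reference gyradius is zero; cannot normalize")
    s = TARGET_GYRADIUS / g
    h, w = ms.image.shape
    in_center = ((w - 1) / 2.0, (h - 1) / 2.0)  # (x, y)

    # output -> input mapping: in = in_center + (out - 350) / s
    matrix = np.array([[1.0 / s, 0.0], [0.0, 1.0 / s]])
    offset = np.array(
        [
            in_center[1] - CANVAS_CENTER / s,  # row (y)
            in_center[0] - CANVAS_CENTER / s,  # col (x)
        ]
    )
    out_channels: dict[str, np.ndarray] = {}
    for name, arr in ms.image.channels.items():
        scaled = ndimage.affine_transform(
            arr,
            matrix,
            offset=offset,
            output_shape=(CANVAS_SIZE, CANVAS_SIZE),
            order=interp_order,
            mode="constant",
            cval=0.0,
        )
        scaled = np.clip(scaled, 0.0, None)
        in_sum = arr.sum()
        if in_sum > 0:
            clipped = 1.0 - scaled.sum() / (in_sum * s * s)
            if clipped > max_clipped_fraction:
                raise AnalysisError(
                    f"channel {name!r}: {clipped:.1%} of intensity falls outside the "
                    f"{CANVAS_SIZE}x{CANVAS_SIZE} canvas after scaling by {s:.3g}"
                )
        if normalize_intensity:
            total = scaled.sum()
            if total > 0:
                scaled = scaled / total
        out_channels[name] = scaled

    out_img = MultiChannelImage(
        out_channels,
        ms.image.pixel_size_nm / s,  # physical size per canvas pixel
        ms.image.provenance
        + [f"normalize_ministack(scale={s:.6g}, ref={ms.reference_channel})"],
    )
    out_ref_g = gyradius(
        out_img.channel(ms.reference_channel),
        center_of_mass(out_img.channel(ms.reference_channel)),
    )
    return NormalizedMiniStack(
        image=out_img,
        reference_channel=ms.reference_channel,
        scale_factor=s,
        reference_gyradius_px=out_ref_g,
        stack_id=ms.stack_id,
    )


def align_ministack(
    nms: NormalizedMiniStack,
    interp_order: int = 1,
    max_clipped_fraction: float = 0.05,
    tol_px: float = 0.05,
    max_iter: int = 3,
) -> NormalizedMiniStack:
    """Translate all channels rigidly so the reference centroid is (350, 350).

    One common sub-pixel shift, measured on the reference channel, is
    applied to every channel so inter-channel geometry is preserved.
    """
    channels = {k: v for k, v in nms.image.channels.items()}
    total_shift = np.zeros(2)  # (dx, dy)
    for _ in range(max_iter):
        c = center_of_mass(channels[nms.reference_channel])
        d = np.array([CANVAS_CENTER - c.x, CANVAS_CENTER - c.y])
        if np.hypot(*d) <= tol_px:
            break
        for name, arr in channels.items():
            before = arr.sum()
            shifted = ndimage.shift(
                arr, (d[1], d[0]), order=interp_order, mode="constant", cval=0.0
            )
            shifted = np.clip(shifted, 0.0, None)
            if before > 0 and 1.0 - shifted.sum() / before > max_clipped_fraction:
                raise AnalysisError(
                    f"channel {name!r}: shift ({d[0]:.1f}, {d[1]:.1f}) pushes signal "
                    "off the canvas"
                )
            channels[name] = shifted
        total_shift += d
    out_img = MultiChannelImage(
        channels,
        nms.image.pixel_size_nm,
        nms.image.provenance
        + [f"align_ministack(shift=({total_shift[0]:.3f},{total_shift[1]:.3f}))"],
    )
    return NormalizedMiniStack(
        image=out_img,
        reference_channel=nms.reference_channel,
        scale_factor=nms.scale_factor,
        reference_gyradius_px=nms.reference_gyradius_px,
        shift_px=(float(total_shift[0]), float(total_shift[1])),
        stack_id=nms.stack_id,
    )


def average_ministacks(aligned: Sequence[NormalizedMiniStack]) -> EnFaceAverage:
    """Per-pixel, per-channel arithmetic mean across aligned stacks."""
    aligned = list(aligned)
    if not aligned:
        raise AnalysisError("no aligned mini-stacks to average")
    names = aligned[0].image.channel_names
    for a in aligned[1:]:
        if a.image.channel_names != names:
            raise AnalysisError(
                f"channel sets differ: {names} vs {a.image.channel_names}"
            )
    out = {
        name: np.mean(np.stack([a.image.channels[name] for a in aligned]), axis=0)
        for name in names
    }
    img = MultiChannelImage(
        out,
        aligned[0].image.pixel_size_nm,
        [f"average_ministacks(n={len(aligned)})"],
    )
    return EnFaceAverage(
        image=img,
        n=len(aligned),
        stack_ids=[a.stack_id for a in aligned],
    )


# ---------------------------------------------------------------------------
# Radial profile and half-max extraction
# ---------------------------------------------------------------------------

def radial_mean_profile(
    image: MultiChannelImage,
    center: Point,
    mode: str = "annular",
    max_radius: int = PROFILE_MAX_RADIUS,
) -> RadialProfile:
    """Radial mean intensity for radii 1..``max_radius`` px about ``center``.

    ``annular`` (default) averages pixels whose center distance lies in
    [r-0.5, r+0.5); ``cumulative`` averages all pixels within distance r.
    """
    h, w = image.shape
    if not (-0.5 <= center.x <= w - 0.5 and -0.5 <= center.y <= h - 0.5):
        raise AnalysisError("profile center lies outside the image")
    if mode not in ("annular", "cumulative"):
        raise AnalysisError(f"unknown profile mode {mode!r}")
    ys, xs = np.indices((h, w))
    d = np.hypot(xs - center.x, ys - center.y)
    radii = np.arange(1, max_radius + 1)
    values: dict[str, np.ndarray] = {}
    if mode == "annular":
        # bin r <- [r-0.5, r+0.5)
        bins = np.floor(d + 0.5).astype(int).ravel()
        nbins = max_radius + 1
        valid = bins <= max_radius
        counts = np.bincount(bins[valid], minlength=nbins)
        for name, arr in image.channels.items():
            sums = np.bincount(bins[valid], weights=arr.ravel()[valid], minlength=nbins)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            values[name] = means[1 : max_radius + 1]
    else:
        order = np.argsort(d.ravel())
        d_sorted = d.ravel()[order]
        edges = np.searchsorted(d_sorted, radii + 1e-9, side="right")
        for name, arr in image.channels.items():
            csum = np.concatenate([[0.0], np.cumsum(arr.ravel()[order])])
            means = np.where(edges > 0, csum[edges] / np.maximum(edges, 1), 0.0)
            values[name] = means
    return RadialProfile(radii, values, center, image.pixel_size_nm, mode)


def _outward_half_max_crossing(
    positions: np.ndarray, values: np.ndarray, peak_idx: int, direction: int = 1
) -> tuple[float, float]:
    """First half-max crossing outward of the peak, linearly interpolated.

    Returns ``(position, half_max_value)``.  A sample exactly at half-max
    followed by smaller values resolves to that sample's position (the
    interpolation is exact there), matching the outermost-plateau rule.
    """
    half = values[peak_idx] / 2.0
    i = peak_idx
    last = len(values) - 1 if direction > 0 else 0
    while i != last:
        j = i + direction
        if values[j] < half:
            # interpolate between i (>= half) and j (< half)
            vi, vj = values[i], values[j]
            frac = (vi - half) / (vi - vj)
            pos = positions[i] + frac * (positions[j] - positions[i])
            return float(pos), float(half)
        i = j
    raise AnalysisError(
        "outer slope not resolved: profile never falls below half-max in range"
    )


def extract_marker_radius(
    profile: RadialProfile,
    channel: str,
    reference_radius_px: float | None = None,
    stack_id: str = "",
) -> MarkerRadius:
    """Half-max outer-slope radius of a channel's radial profile.

    The radius is the first crossing of half the global maximum outward of
    the peak, linearly interpolated between integer radii.  When
    ``reference_radius_px`` is given the normalized radius (fraction of the
    reference marker's radius) is also reported; otherwise it is NaN.
    """
    if channel not in profile.values:
        raise AnalysisError(f"channel {channel!r} not in profile")
    v = np.asarray(profile.values[channel], dtype=float)
    if v.max() <= 0:
        raise AnalysisError(f"channel {channel!r} profile is empty")
    peak_idx = int(np.argmax(v))
    radius_px, half = _outward_half_max_crossing(
        np.asarray(profile.radii_px, dtype=float), v, peak_idx, direction=1
    )
    if reference_radius_px is not None:
        if reference_radius_px <= 0:
            raise AnalysisError("reference radius must be > 0")
        normalized = radius_px / reference_radius_px
    else:
        normalized = float("nan")
    return MarkerRadius(
        channel_name=channel,
        radius_px=radius_px,
        radius_normalized=normalized,
        peak_radius_px=float(profile.radii_px[peak_idx]),
        half_max_value=half,
        stack_id=stack_id,
    )


def extract_all_radii(
    profile: RadialProfile, reference_channel: str, stack_id: str = ""
) -> list[MarkerRadius]:
    """Half-max radii for every channel, normalized to the reference channel."""
    ref = extract_marker_radius(profile, reference_channel, stack_id=stack_id)
    ref = MarkerRadius(
        ref.channel_name, ref.radius_px, 1.0, ref.peak_radius_px, ref.half_max_value, stack_id
    )
    out = [ref]
    for name in profile.values:
        if name == reference_channel:
            continue
        out.append(
            extract_marker_radius(
                profile, name, reference_radius_px=ref.radius_px, stack_id=stack_id
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ring diameter from line profiles
# ---------------------------------------------------------------------------

def _diameter_single_angle(
    image: MultiChannelImage,
    channel: str,
    center: Point,
    angle_deg: float,
    width_px: int,
) -> float:
    h, w = image.shape
    th = np.radians(angle_deg)
    ux, uy = np.cos(th), np.sin(th)
    # longest half-length that keeps both endpoints inside the image
    lims = []
    for u, c, n in ((ux, center.x, w), (uy, center.y, h)):
        if abs(u) > 1e-12:
            lims.append(min((c - 0) / abs(u), (n - 1 - c) / abs(u)))
    half_len = float(min(lims))
    if half_len < 2:
        raise AnalysisError("line through center too short to span the ring")
    start = Point(center.x - half_len * ux, center.y - half_len * uy)
    end = Point(center.x + half_len * ux, center.y + half_len * uy)
    series = line_profile(
        MultiChannelImage({channel: image.channel(channel)}, image.pixel_size_nm),
        start,
        end,
        width_px=width_px,
    )
    v = series.values[channel]
    pos = series.positions_px - half_len  # signed distance from center
    mid = int(np.argmin(np.abs(pos)))
    left, right = v[: mid + 1], v[mid:]
    if left.max() <= 0 or right.max() <= 0:
        raise AnalysisError("fewer than two flanking peaks on the line profile")
    li = int(np.argmax(left))
    ri = mid + int(np.argmax(right))
    if li == mid or ri == mid:
        raise AnalysisError("fewer than two flanking peaks on the line profile")
    # outer slope: away from the center on each side
    lpos, _ = _outward_half_max_crossing(series.positions_px, v, li, direction=-1)
    rpos, _ = _outward_half_max_crossing(series.positions_px, v, ri, direction=+1)
    return float(rpos - lpos)


def measure_ring_diameter(
    image: MultiChannelImage,
    channel: str,
    center: Point,
    angle_deg: float | None = None,
    width_px: int = 1,
    n_angles: int = 36,
) -> tuple[float, float]:
    """Ring diameter from the outer half-max points of a line profile.

    A line is drawn through ``center``; the two local maxima flanking the
    center are located and, for each, the half-maximum crossing on its outer
    slope (away from the center) is found by linear interpolation.  The
    diameter is the distance between the two crossings.  With
    ``angle_deg=None`` the mean over ``n_angles`` evenly spaced angles is
    returned.  Returns ``(diameter_px, diameter_nm)``.
    """
    if angle_deg is not None:
        d_px = _diameter_single_angle(image, channel, center, angle_deg, width_px)
    else:
        angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
        d_px = float(
            np.mean(
                [
                    _diameter_single_angle(image, channel, center, a, width_px)
                    for a in angles
                ]
            )
        )
    return d_px, d_px * image.pixel_size_nm


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_radii(
    records: Sequence[MarkerRadius],
    lq_table: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Per-channel mean/SEM/n of normalized radius, joined with LQ values.

    ``lq_table`` maps channel name -> LQ (dict, or a DataFrame with
    ``channel``/``lq`` columns).  Channels missing from the table are kept
    and flagged with ``lq_missing=True`` rather than dropped.
    """
    if not records:
        raise AnalysisError("no marker radius records to summarize")
    df = pd.DataFrame(
        [
            {
                "channel": r.channel_name,
                "radius_normalized": r.radius_normalized,
                "radius_px": r.radius_px,
            }
            for r in records
        ]
    )
    rows = []
    for channel, grp in df.groupby("channel", sort=False):
        vals = grp["radius_normalized"].to_numpy()
        n = len(vals)
        rows.append(
            {
                "channel": channel,
                "normalized_radius_mean": float(np.mean(vals)),
                "normalized_radius_sem": float(np.std(vals, ddof=1) / np.sqrt(n))
                if n >= 2
                else np.nan,
                "n": n,
            }
        )
    out = pd.DataFrame(rows)
    lq_map: dict[str, float] = {}
    if lq_table is not None:
        if isinstance(lq_table, pd.DataFrame):
            lq_map = dict(zip(lq_table["channel"], lq_table["lq"]))
        else:
            lq_map = dict(lq_table)
    out["lq"] = [lq_map.get(c, np.nan) for c in out["channel"]]
    out["lq_missing"] = [c not in lq_map for c in out["channel"]]
    return out


def plot_radius_vs_lq(summary: pd.DataFrame, path) -> None:
    """Scatter of normalized radius (y) against LQ (x), one point per channel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sub = summary[~summary["lq_missing"]]
    ax.errorbar(
        sub["lq"],
        sub["normalized_radius_mean"],
        yerr=sub["normalized_radius_sem"],
        fmt="o",
        capsize=3,
    )
    for _, row in sub.iterrows():
        ax.annotate(row["channel"], (row["lq"], row["normalized_radius_mean"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("LQ")
    ax.set_ylabel("normalized radius")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
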