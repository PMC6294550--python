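"""Image I/O and shared low-level measurements.

Coordinate convention used throughout the package: 0-based pixel indices,
pixel centers at integer coordinates, ``x`` = column, ``y`` = row.  Points
are ``(x, y)`` pairs.  Arrays are indexed ``[y, x]``.  Every sub-pixel read
uses bilinear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


class ImageError(ValueError):
    """Raised for invalid image inputs or operations."""


@dataclass(frozen=True)
class Point:
    """A pixel-coordinate point (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ImageError(f"Point coordinates must be finite, got {(self.x, self.y)}")

    def as_xy(self) -> tuple[float, float]:
        return (float(self.x), float(self.y))


@dataclass
class MultiChannelImage:
    """An ordered set of equally shaped 2D channels with a physical pixel size.

    Parameters
    ----------
    channels
        Ordered mapping channel name -> 2D float array (``[y, x]`` indexing).
    pixel_size_nm
        Physical pixel size in nanometres.
    provenance
        Free-form processing log; operations append one entry each.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageError("MultiChannelImage needs at least one channel")
        if not self.pixel_size_nm > 0:
            raise ImageError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        shapes = set()
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ImageError(f"channel {name!r} is not 2D (shape {arr.shape})")
            if not np.all(np.isfinite(arr)):
                raise ImageError(f"channel {name!r} contains non-finite values")
            shapes.add(arr.shape)
            clean[name] = arr
        if len(shapes) > 1:
            raise ImageError(f"channels have mismatched shapes: {sorted(shapes)}")
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.keys())

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ImageError(
                f"channel {name!r} not found; available: {self.channel_names}"
            ) from None

    def copy_with(
        self,
        channels: Mapping[str, np.ndarray] | None = None,
        note: str | None = None,
    ) -> "MultiChannelImage":
        new_channels = dict(channels) if channels is not None else {
            k: v.copy() for k, v in self.channels.items()
        }
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return MultiChannelImage(new_channels, self.pixel_size_nm, prov)


@dataclass
class ProfileSeries:
    """Intensity samples along a line, one series per channel.

    ``positions_px`` are distances (px) along the sampled segment, strictly
    increasing at unit spacing.
    """

    positions_px: np.ndarray
    values: dict[str, np.ndarray]
    pixel_size_nm: float
    width_px: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if np.any(np.diff(self.positions_px) <= 0):
            raise ImageError("profile positions must be strictly increasing")
        n = len(self.positions_px)
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if len(v) != n:
                raise ImageError(f"channel {name!r} length {len(v)} != positions {n}")
            self.values[name] = v

    @property
    def positions_nm(self) -> np.ndarray:
        return self.positions_px * self.pixel_size_nm

    def normalize(self) -> "ProfileSeries":
        """Return a copy with each channel scaled to a maximum of 1."""
        out = {}
        for name, v in self.values.items():
            m = v.max()
            out[name] = v / m if m > 0 else v.copy()
        return ProfileSeries(
            self.positions_px.copy(), out, self.pixel_size_nm, self.width_px, True
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"position_px": self.positions_px, "position_nm": self.positions_nm}
        data.update(self.values)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_image(img: MultiChannelImage, path) -> None:
    """Write a MultiChannelImage as a multi-page float32 TIFF.

    Channel order and pixel size are stored in the ImageDescription tag as
    JSON so that :func:`read_image` round-trips losslessly.
    """
    stack = np.stack([img.channels[name] for name in img.channel_names]).astype(
        np.float32
    )
    meta = {
        "channel_names": img.channel_names,
        "pixel_size_nm": img.pixel_size_nm,
        "provenance": img.provenance,
    }
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))


def read_image(
    path,
    pixel_size_nm: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> MultiChannelImage:
    """Read a (multi-channel) TIFF.

    Pixel size and channel names come from the embedded JSON metadata when
    present; otherwise they must be supplied.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ImageError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    names = list(channel_names or meta.get("channel_names") or [])
    if not names:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    if len(names) != arr.shape[0]:
        raise ImageError(
            f"{path}: {arr.shape[0]} channel pages but {len(names)} channel names"
        )
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ImageError(
            f"{path}: pixel size not in TIFF metadata; pass pixel_size_nm= or set it "
            "in the run config"
        )
    prov = list(meta.get("provenance", [])) + [f"read_image({path})"]
    return MultiChannelImage(
        {name: arr[i].astype(float) for i, name in enumerate(names)},
        float(px),
        prov,
    )


# ---------------------------------------------------------------------------
# Basic operations
# ---------------------------------------------------------------------------

def max_intensity_projection(
    slices: Sequence[MultiChannelImage],
) -> MultiChannelImage:
    """Per-pixel, per-channel maximum across a stack of congruent slices."""
    slices = list(slices)
    if not slices:
        raise ImageError("empty stack: nothing to project")
    first = slices[0]
    names = first.channel_names
    for s in slices[1:]:
        if s.channel_names != names or s.shape != first.shape:
            raise ImageError("slices must share channel names and shapes")
    out = {
        name: np.max(np.stack([s.channels[name] for s in slices]), axis=0)
        for name in names
    }
    return first.copy_with(out, note=f"max_intensity_projection(n={len(slices)})")


def subtract_background(
    img: MultiChannelImage,
    method: str = "border_median",
    border_px: int = 3,
    ball_radius: float | None = None,
) -> MultiChannelImage:
    """Subtract a per-channel background estimate; negatives clamp to 0.

    ``border_median`` subtracts the median of a ``border_px``-wide frame
    (constant estimate).  ``rolling_ball`` uses skimage's rolling-ball
    algorithm with ``ball_radius`` px.
    """
    if method not in ("border_median", "rolling_ball"):
        raise ImageError(f"unknown background method {method!r}")
    out = {}
    for name, arr in img.channels.items():
        if method == "border_median":
            b = border_px
            border = np.concatenate(
                [
                    arr[:b, :].ravel(),
                    arr[-b:, :].ravel(),
                    arr[b:-b, :b].ravel(),
                    arr[b:-b, -b:].ravel(),
                ]
            )
            bg = np.median(border)
        else:
            if ball_radius is None or ball_radius <= 0:
                raise ImageError("rolling_ball requires ball_radius > 0")
            from skimage import restoration

            bg = restoration.rolling_ball(arr, radius=ball_radius)
        out[name] = np.clip(arr - bg, 0.0, None)
    note = f"subtract_background(method={method}, border_px={border_px}, ball_radius={ball_radius})"
    return img.copy_with(out, note=note)


def crop_square(
    img: MultiChannelImage,
    center: Point,
    side_px: int,
    pad: bool = False,
) -> MultiChannelImage:
    """Integer-aligned square crop of ``side_px`` around ``center``.

    Out-of-bounds crops raise unless ``pad`` is set, in which case missing
    pixels are zero-filled.
    """
    if side_px < 1:
        raise ImageError("side_px must be >= 1")
    h, w = img.shape
    x0 = int(round(center.x)) - side_px // 2
    y0 = int(round(center.y)) - side_px // 2
    x1, y1 = x0 + side_px, y0 + side_px
    if not pad and (x0 < 0 or y0 < 0 or x1 > w or y1 > h):
        raise ImageError(
            f"crop [{x0}:{x1}, {y0}:{y1}] out of bounds for {w}x{h} image "
            "(enable pad=True to zero-fill)"
        )
    out = {}
    for name, arr in img.channels.items():
        dst = np.zeros((side_px, side_px), dtype=float)
        sy0, sy1 = max(y0, 0), min(y1, h)
        sx0, sx1 = max(x0, 0), min(x1, w)
        if sy1 > sy0 and sx1 > sx0:
            dst[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = arr[sy0:sy1, sx0:sx1]
        out[name] = dst
    return img.copy_with(
        out, note=f"crop_square(center=({center.x},{center.y}), side={side_px})"
    )


def center_of_mass(channel: np.ndarray) -> Point:
    """Fluorescence centroid: intensity-weighted mean pixel position.

    Returns ``(sum(I*x)/sum(I), sum(I*y)/sum(I))`` with pixel centers at
    integer coordinates.
    """
    arr = np.asarray(channel, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ImageError("center_of_mass: channel has zero (or negative) total intensity")
    ys, xs = np.indices(arr.shape)
    return Point(float((arr * xs).sum() / total), float((arr * ys).sum() / total))


def line_profile(
    img: MultiChannelImage,
    start: Point,
    end: Point,
    width_px: int = 1,
    normalize: bool = False,
) -> ProfileSeries:
    """Sample intensities along a (thick) line at 1-px spacing.

    At each position along the segment the intensity is averaged across
    ``width_px`` bilinear samples spaced 1 px apart perpendicular to the
    line.  Width 1 along an integer row/column reproduces the raw pixels.
    """
    if width_px < 1:
        raise ImageError("width_px must be >= 1")
    dx, dy = end.x - start.x, end.y - start.y
    length = float(np.hypot(dx, dy))
    if length == 0:
        raise ImageError("line_profile: start and end coincide")
    ux, uy = dx / length, dy / length  # along-line unit vector
    px_, py_ = -uy, ux  # perpendicular unit vector
    t = np.arange(0.0, np.floor(length) + 1.0)  # 1-px spacing incl. endpoints
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    xs = start.x + t[:, None] * ux + offsets[None, :] * px_
    ys = start.y + t[:, None] * uy + offsets[None, :] * py_
    h, w = img.shape
    if xs.max() < -0.5 or ys.max() < -0.5 or xs.min() > w - 0.5 or ys.min() > h - 0.5:
        raise ImageError("line_profile: segment lies fully outside the image")
    coords = np.stack([ys.ravel(), xs.ravel()])
    values = {}
    for name, arr in img.channels.items():
        samp = ndimage.map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)
        values[name] = samp.reshape(xs.shape).mean(axis=1)
    series = ProfileSeries(t, values, img.pixel_size_nm, width_px)
    return series.normalize() if normalize else series


def roi_total_intensity(
    channel: np.ndarray,
    roi_center: Point,
    roi_radius_px: float,
    bg_annulus: tuple[float, float] | None = None,
    bg_stat: str = "median",
    clamp: bool = False,
) -> float:
    """Background-corrected total intensity of a circular ROI.

    Sums pixels whose centers fall inside the circle, then subtracts
    ``(per-pixel background from the annulus) * ROI pixel count``.  The
    annulus is ``(inner_radius, outer_radius)`` in px; ``None`` skips
    background correction.
    """
    arr = np.asarray(channel, dtype=float)
    h, w = arr.shape
    if not (-0.5 <= roi_center.x <= w - 0.5 and -0.5 <= roi_center.y <= h - 0.5):
        raise ImageError("roi_total_intensity: ROI center outside image")
    ys, xs = np.indices(arr.shape)
    d = np.hypot(xs - roi_center.x, ys - roi_center.y)
    inside = d <= roi_radius_px
    if not inside.any():
        inside = d == d.min()  # degenerate radius: nearest single pixel
    total = float(arr[inside].sum())
    if bg_annulus is not None:
        r_in, r_out = bg_annulus
        if r_out <= r_in:
            raise ImageError("annulus outer radius must exceed inner radius")
        ann = (d > r_in) & (d <= r_out)
        if not ann.any():
            raise ImageError("background annulus contains no pixels")
        bg_pix = np.median(arr[ann]) if bg_stat == "median" else float(arr[ann].mean())
        total -= bg_pix * int(inside.sum())
    if clamp:
        total = max(total, 0.0)
    return total
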