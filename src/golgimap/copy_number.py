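"""Copy-number estimation against an in-cell fluorescence standard.

A punctum's copy number is its background-subtracted total ROI intensity
divided by that of a standard of known stoichiometry (a nuclear pore
carrying ~16 GFP copies), scaled by the fluorophore's brightness relative
to GFP: ``copies = (copies_per_standard / relative_brightness) * I_punctum / I_standard``.
For GFP this is 16x the intensity ratio; for moxGFP (1.47x brighter than
EGFP) the prefactor is 16/1.47 ~= 10.9.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .image_core import MultiChannelImage, Point, roi_total_intensity


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class FluorophoreStandard:
    """A fluorescence standard of known copy number and relative brightness."""

    name: str = "GFP-Nup133"
    copies_per_standard: float = 16.0
    relative_brightness_vs_gfp: float = 1.0

    def __post_init__(self) -> None:
        if not self.copies_per_standard > 0:
            raise CalibrationError("copies_per_standard must be > 0")
        if not self.relative_brightness_vs_gfp > 0:
            raise CalibrationError("relative_brightness_vs_gfp must be > 0")

    @property
    def prefactor(self) -> float:
        """Copies per unit intensity ratio (16 for GFP, ~10.9 for moxGFP)."""
        return self.copies_per_standard / self.relative_brightness_vs_gfp


GFP_STANDARD = FluorophoreStandard("GFP-Nup133", 16.0, 1.0)
MOXGFP_STANDARD = FluorophoreStandard("GFP-Nup133 (moxGFP target)", 16.0, 1.47)


@dataclass
class CopyNumberRecord:
    punctum_id: str
    i_punctum: float
    i_standard: float
    copies: float


@dataclass
class StandardCalibration:
    mean_intensity: float
    sem: float | None
    n: int
    imaging_config_hash: str = ""


def estimate_copies(
    i_punctum: float,
    i_standard: float,
    standard: FluorophoreStandard = GFP_STANDARD,
    punctum_id: str = "",
) -> CopyNumberRecord:
    """Copy number of one punctum from the intensity ratio to the standard."""
    if i_standard <= 0:
        raise CalibrationError("standard intensity must be > 0")
    if i_punctum < 0:
        raise CalibrationError(
            "negative punctum intensity; background subtraction should have clamped it"
        )
    copies = standard.prefactor * i_punctum / i_standard
    return CopyNumberRecord(punctum_id, float(i_punctum), float(i_standard), float(copies))


def calibrate_standard(
    images: Sequence[MultiChannelImage],
    channel: str,
    roi_centers: Sequence[Sequence[Point]],
    roi_radius_px: float,
    bg_annulus: tuple[float, float] | None = None,
    imaging_config: dict | None = None,
) -> StandardCalibration:
    """Aggregate per-pore ROI intensities into the standard's I value.

    ``roi_centers[i]`` lists the pore ROI centers for ``images[i]``.  The
    mean over all pores is used as the standard intensity downstream; SEM
    and n are reported alongside.  ``imaging_config`` is hashed and recorded
    so that standard and sample acquisitions can be checked for identical
    imaging settings.
    """
    if len(images) != len(roi_centers):
        raise CalibrationError("need one ROI-center list per image")
    intensities: list[float] = []
    for img, centers in zip(images, roi_centers):
        arr = img.channel(channel)
        for c in centers:
            intensities.append(
                roi_total_intensity(
                    arr, c, roi_radius_px, bg_annulus=bg_annulus, clamp=True
                )
            )
    if not intensities:
        raise CalibrationError("no measurable standard ROIs")
    vals = np.asarray(intensities, dtype=float)
    n = len(vals)
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
    cfg_hash = ""
    if imaging_config is not None:
        cfg_hash = hashlib.sha256(
            json.dumps(imaging_config, sort_keys=True).encode()
        ).hexdigest()[:16]
    return StandardCalibration(float(vals.mean()), sem, n, cfg_hash)


def records_to_frame(records: Sequence[CopyNumberRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "punctum_id": r.punctum_id,
                "i_punctum": r.i_punctum,
                "i_standard": r.i_standard,
                "copies": r.copies,
            }
            for r in records
        ]
    )


def summarize_copies(records: Sequence[CopyNumberRecord]) -> dict:
    """Mean +/- SEM copy number over a set of puncta."""
    if not records:
        raise CalibrationError("no copy-number records")
    vals = np.asarray([r.copies for r in records], dtype=float)
    n = len(vals)
    return {
        "copies_mean": float(vals.mean()),
        "copies_sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan,
        "n": n,
    }
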