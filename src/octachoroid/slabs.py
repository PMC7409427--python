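"""Depth quantization and single-pixel en-face slab extraction.

All depths are micrometres beneath Bruch membrane (BM), positive downward,
0 = BM itself.  The device samples the axial direction every
``axial_step`` um (2.6 um for the swept-source instrument emulated here),
so a nominal depth is first snapped to the nearest multiple of the step:
nominal 50 um becomes 49.4, 100 becomes 98.8, ... 550 becomes 551.2.
A single-pixel slab at depth d is the one voxel per A-scan at exactly
BM + d; no axial averaging is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import EyeRecord, VolumePair

__all__ = [
    "DepthSchedule",
    "ImagePair",
    "quantize_depth",
    "fixed_schedule",
    "percentile_schedule",
    "percentile_depths",
    "extract_slab",
    "eligible_at_depth",
    "PERCENTILE_FRACTIONS",
]

#: Percentile-series fractions of the subfoveal choroidal thickness.
PERCENTILE_FRACTIONS = (0.125, 0.25, 0.375, 0.50, 0.625, 0.75, 0.875)


@dataclass(frozen=True)
class DepthSchedule:
    """A series of nominal depths: fixed (um) or percentile (fraction of SCT)."""

    kind: str                        # "fixed" | "percentile"
    nominal_values: tuple[float, ...]
    axial_step: float = 2.6

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "percentile"):
            raise ValueError(f"kind must be 'fixed' or 'percentile', got {self.kind!r}")
        vals = self.nominal_values
        if any(v <= 0 for v in vals) or any(
            b <= a for a, b in zip(vals, vals[1:])
        ):
            raise ValueError("nominal values must be positive and strictly increasing")

    def labels(self) -> tuple[str, ...]:
        if self.kind == "fixed":
            return tuple(f"{v:g}" for v in self.nominal_values)
        return tuple(f"{100 * v:g}%" for v in self.nominal_values)


def fixed_schedule(axial_step: float = 2.6) -> DepthSchedule:
    """The 50..550 um, 50-um-interval fixed-depth series."""
    return DepthSchedule(
        kind="fixed",
        nominal_values=tuple(float(d) for d in range(50, 551, 50)),
        axial_step=axial_step,
    )


def percentile_schedule(axial_step: float = 2.6) -> DepthSchedule:
    """The 12.5..87.5 %SCT, 12.5-point-interval percentile series."""
    return DepthSchedule(
        kind="percentile", nominal_values=PERCENTILE_FRACTIONS, axial_step=axial_step
    )


@dataclass
class ImagePair:
    """One OCTA en-face image and its en-face OCT counterpart at one depth."""

    octa_image: np.ndarray
    oct_image: np.ndarray
    eye_id: str
    nominal_depth: float | str      # um, or a percentile label
    actual_depth: float             # um beneath BM, on the axial grid

    def __post_init__(self) -> None:
        if self.octa_image.shape != self.oct_image.shape:
            raise ValueError(
                "octa_image and oct_image shapes differ: "
                f"{self.octa_image.shape} vs {self.oct_image.shape}"
            )


def quantize_depth(nominal: float, axial_step: float) -> float:
    """Snap a nominal depth to the nearest multiple of the axial step.

    Ties (nominal exactly halfway between two grid depths) round up, i.e.
    to the deeper slab.  quantize_depth(50, 2.6) == 49.4.
    """
    if nominal <= 0:
        raise ValueError(f"nominal depth must be > 0, got {nominal}")
    if axial_step <= 0:
        raise ValueError(f"axial_step must be > 0, got {axial_step}")
    # small eps so a ratio a hair under an exact half (float error) still
    # rounds up like the true tie would
    k = math.floor(nominal / axial_step + 0.5 + 1e-9)
    return k * axial_step


def percentile_depths(sct: float, axial_step: float = 2.6) -> list[float]:
    """Quantized depths at 12.5, 25, ... 87.5 % of the SCT beneath BM."""
    if sct <= axial_step * 8:
        raise ValueError(
            f"sct={sct} too small to separate the seven percentile levels "
            f"at axial_step={axial_step}"
        )
    depths = [quantize_depth(f * sct, axial_step) for f in PERCENTILE_FRACTIONS]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError(
            f"sct={sct} too small: percentile levels collapse onto the same slab"
        )
    return depths


def extract_slab(
    pair_volume: VolumePair, actual_depth: float, eye_id: str = ""
) -> ImagePair:
    """BM-referenced single-pixel slab pair at ``actual_depth`` um.

    For each A-scan (x, y), takes the single voxel at
    ``bm_depth_map(x, y) + actual_depth`` from both volumes.
    """
    step = pair_volume.axial_step
    k = actual_depth / step
    k_int = int(round(k))
    if abs(k - k_int) > 1e-6:
        raise ValueError(
            f"actual_depth={actual_depth} is not on the axial grid (step {step})"
        )
    offsets = np.round(pair_volume.bm_depth_map / step).astype(int)
    idx = offsets + k_int
    max_valid = (pair_volume.n_pages - 1 - int(offsets.max())) * step
    if idx.min() < 0 or idx.max() >= pair_volume.n_pages:
        raise ValueError(
            f"depth {actual_depth} um beyond volume extent; "
            f"maximum valid depth is {max_valid:.1f} um"
        )
    ny, nx = pair_volume.grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    octa = pair_volume.octa_volume[idx, yy, xx]
    oct_ = pair_volume.oct_volume[idx, yy, xx]
    return ImagePair(
        octa_image=octa,
        oct_image=oct_,
        eye_id=eye_id,
        nominal_depth=actual_depth,
        actual_depth=actual_depth,
    )


def eligible_at_depth(eye: EyeRecord, actual_depth: float) -> bool:
    """Whether a slab at ``actual_depth`` still lies within the choroid.

    A slab deeper than the eye's SCT sits below the chorioscleral interface
    and is excluded from per-depth aggregates.
    """
    return actual_depth <= eye.sct
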