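"""OCTA vs en-face OCT agreement: similarity, comparison maps, per-depth
profiles and optimal-depth selection.

Similarity between a binarized OCTA image and its binarized en-face OCT
counterpart is the percentage of pixels on which the two masks agree.  The
four-colour comparison map classifies each pixel as white (white in both),
black (black in both), green (white on OCTA, black on OCT) or red (black
on OCTA, white on OCT).

Whether an OCTA slab "displays choroidal vessels" is decided by an
explicit three-criterion rule (a reproducible surrogate for the subjective
grading such judgements usually receive): the binarized OCTA black
fraction must be in a plausible range, the similarity with the en-face OCT
must be high, and the black connected components must be stripe-sized
rather than granular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .binarize import BinaryImage, binarize
from .slabs import ImagePair

__all__ = [
    "ComparisonMap",
    "DepthProfileRow",
    "DisplayCriteria",
    "Measurement",
    "similarity",
    "comparison_map",
    "displays_vessels",
    "evaluate_pair",
    "depth_profile",
    "select_optimal_depth",
    "CATEGORY_COLORS",
]

# category codes
BOTH_WHITE, BOTH_BLACK, OCTA_WHITE_OCT_BLACK, OCTA_BLACK_OCT_WHITE = 0, 1, 2, 3

#: RGB rendering of the four categories: white, black, green, red.
CATEGORY_COLORS = {
    BOTH_WHITE: (255, 255, 255),
    BOTH_BLACK: (0, 0, 0),
    OCTA_WHITE_OCT_BLACK: (0, 255, 0),
    OCTA_BLACK_OCT_WHITE: (255, 0, 0),
}

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def _mask_of(a) -> np.ndarray:
    return a.mask if isinstance(a, BinaryImage) else np.asarray(a, bool)


def similarity(a, b) -> float:
    """Percentage of matched pixels between two binary masks, in [0, 100]."""
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    return 100.0 * float((ma == mb).mean())


@dataclass
class ComparisonMap:
    """Per-pixel four-way agreement classification."""

    categories: np.ndarray          # uint8 codes 0..3

    def counts(self) -> dict[int, int]:
        c = np.bincount(self.categories.ravel(), minlength=4)
        return {k: int(c[k]) for k in range(4)}

    def to_rgb(self) -> np.ndarray:
        lut = np.zeros((4, 3), np.uint8)
        for k, rgb in CATEGORY_COLORS.items():
            lut[k] = rgb
        return lut[self.categories]

    def similarity(self) -> float:
        c = self.counts()
        total = self.categories.size
        return 100.0 * (c[BOTH_WHITE] + c[BOTH_BLACK]) / total


def comparison_map(octa, oct_) -> ComparisonMap:
    """Four-colour comparison of binarized OCTA (a) vs en-face OCT (b)."""
    ma, mb = _mask_of(octa), _mask_of(oct_)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    cats = np.full(ma.shape, BOTH_WHITE, np.uint8)
    cats[ma & mb] = BOTH_BLACK
    cats[~ma & mb] = OCTA_WHITE_OCT_BLACK
    cats[ma & ~mb] = OCTA_BLACK_OCT_WHITE
    return ComparisonMap(categories=cats)


@dataclass(frozen=True)
class DisplayCriteria:
    """Cutoffs of the automated vessel-display rule.

    ``min_median_component_px`` is expressed at the native 300 x 300 en-face
    grid (90 000 pixels) and scaled proportionally for other grid sizes.
    """

    black_fraction_range: tuple[float, float] = (10.0, 90.0)   # percent
    min_similarity: float = 70.0                               # percent
    min_median_component_px: float = 20.0                      # px at 300x300
    reference_pixels: int = 300 * 300


def _median_black_component_area(mask: np.ndarray) -> float:
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return 0.0
    areas = np.bincount(labels.ravel())[1:]
    return float(np.median(areas))


def displays_vessels(
    pair: ImagePair, criteria: DisplayCriteria = DisplayCriteria()
) -> bool:
    """Automated vessel-display decision for one OCTA / en-face OCT pair.

    True iff (i) the binarized OCTA black fraction lies in
    ``black_fraction_range``; (ii) the similarity between the binarized
    OCTA and en-face OCT images is at least ``min_similarity``; and
    (iii) the median 8-connected black component is stripe-sized
    (>= ``min_median_component_px`` scaled to the image area), ruling out
    choriocapillaris granularity and pure noise.
    """
    octa_bin = binarize(pair.octa_image)
    oct_bin = binarize(pair.oct_image)
    black_pct = 100.0 * octa_bin.black_fraction
    lo, hi = criteria.black_fraction_range
    if not lo <= black_pct <= hi:
        return False
    if similarity(octa_bin, oct_bin) < criteria.min_similarity:
        return False
    scale = pair.octa_image.size / criteria.reference_pixels
    if _median_black_component_area(octa_bin.mask) < criteria.min_median_component_px * scale:
        return False
    return True


@dataclass(frozen=True)
class Measurement:
    """One eye's evaluation at one scheduled depth."""

    eye_id: str
    label: str
    displays: bool
    similarity_pct: float


def evaluate_pair(
    pair: ImagePair, label: str, criteria: DisplayCriteria = DisplayCriteria()
) -> Measurement:
    """Binarize both modalities and evaluate display + similarity."""
    octa_bin = binarize(pair.octa_image)
    oct_bin = binarize(pair.oct_image)
    return Measurement(
        eye_id=pair.eye_id,
        label=label,
        displays=displays_vessels(pair, criteria),
        similarity_pct=similarity(octa_bin, oct_bin),
    )


@dataclass
class DepthProfileRow:
    """Per-depth aggregate across eligible eyes."""

    depth_label: str
    n_eyes: int
    n_displaying: int
    similarity_mean: float          # nan when n_eyes == 0
    similarity_sd: float | None     # sample SD; None when n_eyes < 2

    @property
    def display_fraction(self) -> float:
        return self.n_displaying / self.n_eyes if self.n_eyes else 0.0


def depth_profile(
    measurements: Iterable[Measurement], labels: Sequence[str]
) -> list[DepthProfileRow]:
    """Aggregate per-eye measurements into rows, one per scheduled depth.

    Eligibility is implicit: an eye with no measurement at a label simply
    does not contribute to that row.  SDs are sample SDs (ddof = 1),
    undefined (None) for single-eye rows.
    """
    by_label: dict[str, list[Measurement]] = {lab: [] for lab in labels}
    for m in measurements:
        if m.label in by_label:
            by_label[m.label].append(m)
    rows: list[DepthProfileRow] = []
    for lab in labels:
        ms = by_label[lab]
        if not ms:
            rows.append(DepthProfileRow(lab, 0, 0, math.nan, None))
            continue
        sims = np.array([m.similarity_pct for m in ms])
        sd = float(np.std(sims, ddof=1)) if len(ms) >= 2 else None
        rows.append(
            DepthProfileRow(
                depth_label=lab,
                n_eyes=len(ms),
                n_displaying=sum(m.displays for m in ms),
                similarity_mean=float(sims.mean()),
                similarity_sd=sd,
            )
        )
    return rows


def select_optimal_depth(profile: Sequence[DepthProfileRow]) -> str | None:
    """Depth with the best vessel display, then similarity, then shallowness.

    Rows are assumed ordered shallow to deep.  Maximizes
    (display fraction, mean similarity) lexicographically; ties go to the
    shallower depth.  Returns None when no row displays vessels at all.
    """
    if not profile:
        raise ValueError("profile is empty")
    best: DepthProfileRow | None = None
    for row in profile:
        if row.n_eyes == 0 or row.n_displaying == 0:
            continue
        if best is None:
            best = row
            continue
        key_row = (row.display_fraction, row.similarity_mean)
        key_best = (best.display_fraction, best.similarity_mean)
        if key_row > key_best:
            best = row
    return best.depth_label if best is not None else None
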