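"""Image-quality and artefact exclusion of a cohort roster.

An eye is excluded when its device image score is below 50, when any of
the six named artefacts (banding, blink, vessel doubling, stretching, out
of window, crisscross) is flagged, or when it carries two or more motion
artefacts wider than a primary branch vein.  One reason is logged per
excluded eye, checked in that priority order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .phantom import ARTEFACT_KINDS, EyeRecord

__all__ = ["ExclusionEntry", "apply_exclusions", "SCORE_CUTOFF", "MOTION_CUTOFF"]

SCORE_CUTOFF = 50.0
MOTION_CUTOFF = 2


@dataclass(frozen=True)
class ExclusionEntry:
    eye_id: str
    reason: str


def _exclusion_reason(eye: EyeRecord) -> str | None:
    if eye.image_score < SCORE_CUTOFF:
        return "image_score_below_50"
    for kind in ARTEFACT_KINDS:     # fixed order so the logged reason is stable
        if kind in eye.artefact_flags:
            return f"artefact_{kind}"
    if eye.wide_motion_artefact_count >= MOTION_CUTOFF:
        return "wide_motion_artefacts_ge_2"
    return None


def apply_exclusions(
    roster: Sequence[EyeRecord],
) -> tuple[list[EyeRecord], list[ExclusionEntry]]:
    """Split a roster into included eyes and an exclusion log.

    Order is preserved; included and excluded eyes partition the roster.
    Re-running on the included set excludes nothing.
    """
    if not roster:
        raise ValueError("roster is empty")
    included: list[EyeRecord] = []
    log: list[ExclusionEntry] = []
    for eye in roster:
        reason = _exclusion_reason(eye)
        if reason is None:
            included.append(eye)
        else:
            log.append(ExclusionEntry(eye_id=eye.eye_id, reason=reason))
    return included, log
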