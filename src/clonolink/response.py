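"""Treatment-response classification from tumor-volume courses.

Each treated mouse carries a time series of tumor volumes (mm^3, computed
upstream as length x width^2 / 2).  The relative change in tumor volume

    RCTV = (TV_n - TV_0) / TV_0

between the start of treatment (t0) and the endpoint (tn) classifies the
mouse as a responder (RCTV < 0), slow progressor (0 <= RCTV <= 1.5) or
non-responder (RCTV > 1.5).  An RCTV of exactly 0 — a tumor that neither
shrank nor grew — is assigned to the slow-progressor class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

RESPONDER = "R"
SLOW_PROGRESSOR = "SP"
NON_RESPONDER = "NR"


@dataclass(frozen=True)
class TumorCourse:
    """Tumor-volume time series for one mouse."""

    mouse_id: str
    days: tuple
    volumes: tuple
    t0_index: int = 0
    tn_index: int = -1

    def __post_init__(self):
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must have equal length")
        if len(self.days) < 2:
            raise ValueError("a course needs at least two time points")
        n = len(self.days)
        t0 = self.t0_index % n
        tn = self.tn_index % n
        if t0 >= tn:
            raise ValueError("t0 must precede tn")


@dataclass(frozen=True)
class ResponseCall:
    mouse_id: str
    rctv: float
    response_class: str


def rctv(tv0: float, tvn: float) -> float:
    """Relative change in tumor volume, (TVn - TV0) / TV0."""
    if tv0 <= 0:
        raise ValueError(f"baseline tumor volume must be positive, got {tv0}")
    return (tvn - tv0) / tv0


def classify_rctv(value: float) -> str:
    if value < 0:
        return RESPONDER
    if value <= 1.5:
        return SLOW_PROGRESSOR
    return NON_RESPONDER


def classify_response(course: TumorCourse) -> ResponseCall:
    """Classify a mouse as R / SP / NR from its tumor-volume course."""
    tv0 = course.volumes[course.t0_index]
    tvn = course.volumes[course.tn_index]
    value = rctv(tv0, tvn)
    return ResponseCall(
        mouse_id=course.mouse_id, rctv=value, response_class=classify_rctv(value)
    )
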