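"""NIPS ground-truth scoring and procedure-video epoch segmentation.

The Neonatal Infant Pain Scale (NIPS) rates six indicators — facial
expression, cry, breathing pattern, arm movement, leg movement and state of
arousal. Every indicator is binary except cry, which has three categories
(0, 1, 2), so the total ranges from 0 to 7. An epoch is labelled *pain* when
its total reaches 3, and severity splits the scale into no pain (0–2),
moderate pain (3–4) and severe pain (>4).

A procedure recording is cut into seven epochs: a baseline window of up to
five minutes before the procedure (T0), the procedure itself (T1), and five
successive one-minute windows after its completion (T2–T6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

__all__ = [
    "NipsIndicators",
    "EpochPlan",
    "EPOCH_IDS",
    "nips_total",
    "pain_label",
    "severity",
    "segment_epochs",
    "epoch_frames",
]

EPOCH_IDS = ("T0", "T1", "T2", "T3", "T4", "T5", "T6")

_BINARY_FIELDS = ("facial_expression", "breathing", "arms", "legs", "arousal")


@dataclass(frozen=True)
class NipsIndicators:
    """One NIPS rating: five binary indicators plus the 3-category cry."""

    facial_expression: int
    cry: int
    breathing: int
    arms: int
    legs: int
    arousal: int

    def __post_init__(self) -> None:
        for name in _BINARY_FIELDS:
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValueError(f"NIPS indicator {name!r} must be 0 or 1, got {value!r}")
        if self.cry not in (0, 1, 2):
            raise ValueError(f"NIPS indicator 'cry' must be 0, 1 or 2, got {self.cry!r}")

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def nips_total(ind: NipsIndicators) -> int:
    """Total NIPS score: the sum of all six indicator scores (0–7)."""
    return sum(getattr(ind, f.name) for f in fields(ind))


def _check_score(score: int) -> int:
    score = int(score)
    if not 0 <= score <= 7:
        raise ValueError(f"NIPS total must lie in [0, 7], got {score}")
    return score


def pain_label(score: int) -> str:
    """Binary label from the NIPS total: ``pain`` for 3–7, ``no_pain`` for 0–2."""
    return "pain" if _check_score(score) >= 3 else "no_pain"


def severity(score: int) -> str:
    """Severity group: ``none`` (0–2), ``moderate`` (3–4) or ``severe`` (>4)."""
    score = _check_score(score)
    if score <= 2:
        return "none"
    if score <= 4:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class EpochPlan:
    """Seven half-open intervals ``[start, end)`` in seconds, keyed T0–T6."""

    intervals: dict[str, tuple[float, float]]
    truncated: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.intervals) != EPOCH_IDS:
            raise ValueError("EpochPlan requires exactly the seven epochs T0..T6 in order")
        prev_end = None
        for eid, (start, end) in self.intervals.items():
            if end < start:
                raise ValueError(f"epoch {eid} has end < start: [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"epoch {eid} overlaps the preceding epoch")
            prev_end = end


def segment_epochs(procedure_start: float, procedure_end: float, video_duration: float) -> EpochPlan:
    """Cut a recording into the seven analysis epochs around a painful procedure.

    T0 covers up to 300 s of baseline immediately before the procedure,
    T1 is the procedure interval itself, and T2–T6 are successive 60-s
    windows after completion, truncated (and flagged) at the end of the
    video. Exactly seven intervals are always returned.
    """
    if not 0 <= procedure_start < procedure_end <= video_duration:
        raise ValueError(
            "require 0 <= procedure_start < procedure_end <= video_duration, got "
            f"start={procedure_start}, end={procedure_end}, duration={video_duration}"
        )
    intervals: dict[str, tuple[float, float]] = {}
    truncated: dict[str, bool] = {}

    t0_start = max(0.0, procedure_start - 300.0)
    intervals["T0"] = (t0_start, procedure_start)
    truncated["T0"] = procedure_start - 300.0 < 0.0

    intervals["T1"] = (procedure_start, procedure_end)
    truncated["T1"] = False

    cursor = procedure_end
    for eid in EPOCH_IDS[2:]:
        start = min(cursor, video_duration)
        end = min(cursor + 60.0, video_duration)
        intervals[eid] = (start, end)
        truncated[eid] = end < cursor + 60.0
        cursor += 60.0
    return EpochPlan(intervals=intervals, truncated=truncated)


def epoch_frames(plan: EpochPlan, epoch_id: str, fs: float) -> tuple[int, int]:
    """Map one epoch interval to frame indices as ``[floor(start*fs), floor(end*fs))``."""
    if epoch_id not in plan.intervals:
        raise KeyError(f"unknown epoch {epoch_id!r}")
    start, end = plan.intervals[epoch_id]
    import math

    return math.floor(start * fs), math.floor(end * fs)
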