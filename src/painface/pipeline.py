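"""End-to-end feature extraction: from a landmark sequence (and optionally a
frame stack) to the four named per-video feature streams.

* ``DG_DisFace`` (528 = 16 × 3 × 11): temporal descriptors of the eleven
  facial-deformation distances.
* ``DG_DisPose`` (384 = 16 × 3 × 8): temporal descriptors of the eight
  boundary-to-component head-pose distances.
* ``DA_Gradient`` (1488 = 16 × 3 × 31): temporal descriptors of the 31
  per-RAP mean gradient magnitudes.
* ``DA_LBP-TOP`` (5487 = 177 × 31): spatio-temporal texture histograms.

The two appearance streams need the frame stack; the geometric streams need
only landmarks.
"""

from __future__ import annotations

import numpy as np

from . import facemap, geometry, temporal, texture
from .data import FrameStack, LandmarkSequence, PainInstance, SubjectRecord, STREAM_NAMES

__all__ = ["extract_streams", "stream_feature_names", "STREAM_NAMES", "build_instances"]

_GEOMETRIC = ("DG_DisFace", "DG_DisPose")


def extract_streams(
    seq: LandmarkSequence,
    stack: FrameStack | None = None,
    streams: tuple[str, ...] = STREAM_NAMES,
    mapping: dict | None = None,
    rap_indices: list[int] | None = None,
) -> dict[str, np.ndarray]:
    """Compute the requested feature streams for one video."""
    unknown = set(streams) - set(STREAM_NAMES)
    if unknown:
        raise ValueError(f"unknown streams {sorted(unknown)}; valid: {STREAM_NAMES}")
    if stack is None and any(s.startswith("DA_") for s in streams):
        raise ValueError("appearance streams require a frame stack")

    out: dict[str, np.ndarray] = {}
    if any(s in _GEOMETRIC for s in streams):
        deform, pose = geometry.geometry_signals(seq, mapping)
        if "DG_DisFace" in streams:
            out["DG_DisFace"] = temporal.build_stream(deform)
        if "DG_DisPose" in streams:
            out["DG_DisPose"] = temporal.build_stream(pose)
    if "DA_Gradient" in streams:
        grads = texture.gradient_signals(stack, seq, rap_indices)
        out["DA_Gradient"] = temporal.build_stream(grads)
    if "DA_LBP-TOP" in streams:
        out["DA_LBP-TOP"] = texture.video_appearance(stack, seq, rap_indices)
    return {s: out[s] for s in streams}


def stream_feature_names(stream: str, rap_indices: list[int] | None = None) -> list[str]:
    """Per-feature names of one stream, matching extract_streams' layout."""
    rap = list(rap_indices if rap_indices is not None else facemap.DEFAULT_RAP_INDICES)
    if stream == "DG_DisFace":
        return temporal.stream_feature_names(list(facemap.DEFORMATION_NAMES))
    if stream == "DG_DisPose":
        return temporal.stream_feature_names(list(facemap.POSE_NAMES))
    if stream == "DA_Gradient":
        return temporal.stream_feature_names([f"rap{i}" for i in rap])
    if stream == "DA_LBP-TOP":
        return texture.lbp_top_feature_names(rap)
    raise ValueError(f"unknown stream {stream!r}; valid: {STREAM_NAMES}")


def build_instances(
    records,
    streams: tuple[str, ...] = STREAM_NAMES,
    mapping: dict | None = None,
    rap_indices: list[int] | None = None,
) -> list[PainInstance]:
    """Turn cohort records (sequence, stack, subject, epoch, NIPS) into PainInstances.

    Each record needs attributes ``sequence``, ``frames`` (may be None for
    geometry-only work), ``subject`` (:class:`SubjectRecord`), ``epoch_id``
    and ``nips_score``.
    """
    instances = []
    for rec in records:
        feats = extract_streams(
            rec.sequence, rec.frames, streams=streams, mapping=mapping, rap_indices=rap_indices
        )
        instances.append(
            PainInstance(
                subject=rec.subject,
                epoch_id=rec.epoch_id,
                streams=feats,
                nips_score=rec.nips_score,
            )
        )
    return instances
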