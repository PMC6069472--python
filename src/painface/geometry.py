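"""Per-frame geometric facial features and hemiface feature selection.

Two families of Euclidean distances are read off each landmark frame:

* eleven *deformation* distances tracking the pain-relevant facial actions
  (brow lowering, eye squeeze, mouth stretch): eyebrow–eye, eyelid opening,
  eyebrow–mouth, eye–mouth on both sides, plus nose–mouth and the mouth
  width and height;
* eight *head-pose* distances from the left/right face boundary to the
  brows, eyes, nose and mouth — lateral head shake shows up as an
  antisymmetric change between the two sides.

Every distance is the Euclidean distance between the centroids of two
configured landmark groups, which makes each measure robust to single-point
jitter and keeps the whole geometry layer re-configurable for a different
landmark ordering.
"""

from __future__ import annotations

import numpy as np

from . import facemap, temporal
from .data import LandmarkFrame, LandmarkSequence
from .facemap import ConfigError

__all__ = [
    "compute_deformation",
    "compute_pose",
    "geometry_signals",
    "hemiface_select",
    "hemiface_mask",
    "feature_side",
]

_SIDES = ("left", "right", "whole")


def _centroid(points: np.ndarray, indices: list[int]) -> np.ndarray:
    return points[np.asarray(indices, dtype=int)].mean(axis=0)


def _distances(frame: LandmarkFrame, mapping: dict, section: str) -> dict[str, float]:
    groups = mapping["groups"]
    out: dict[str, float] = {}
    for name, pair in mapping[section].items():
        try:
            ga, gb = (groups[g] for g in pair)
        except KeyError as exc:
            raise ConfigError(f"distance {name!r} refers to undefined group {exc.args[0]!r}") from exc
        out[name] = float(np.linalg.norm(_centroid(frame.points, ga) - _centroid(frame.points, gb)))
    return out


def compute_deformation(frame: LandmarkFrame, mapping: dict | None = None) -> dict[str, float]:
    """The 11 facial-deformation distances of one frame, keyed by name."""
    return _distances(frame, mapping or facemap.DEFAULT_MAPPING, "deformation")


def compute_pose(frame: LandmarkFrame, mapping: dict | None = None) -> dict[str, float]:
    """The 8 boundary-to-component head-pose distances of one frame."""
    return _distances(frame, mapping or facemap.DEFAULT_MAPPING, "pose")


def geometry_signals(
    seq: LandmarkSequence, mapping: dict | None = None
) -> tuple[dict[str, temporal.TemporalSignal], dict[str, temporal.TemporalSignal]]:
    """Per-video temporal signals for all 19 geometric distances.

    Returns ``(deformation_signals, pose_signals)``: 11 + 8 named
    TemporalSignals of length equal to the frame count, carrying the
    sequence's sampling rate.
    """
    mapping = mapping or facemap.DEFAULT_MAPPING
    deform_rows: list[dict[str, float]] = []
    pose_rows: list[dict[str, float]] = []
    for frame in seq.frames:
        try:
            deform_rows.append(_distances(frame, mapping, "deformation"))
            pose_rows.append(_distances(frame, mapping, "pose"))
        except ConfigError:
            raise
        except Exception as exc:
            raise ValueError(f"frame {frame.frame_index}: {exc}") from exc

    def to_signals(rows: list[dict[str, float]]) -> dict[str, temporal.TemporalSignal]:
        names = list(rows[0])
        return {
            name: temporal.make_signal(name, np.asarray([r[name] for r in rows]), seq.fs)
            for name in names
        }

    return to_signals(deform_rows), to_signals(pose_rows)


def feature_side(feature_name: str) -> str:
    """Hemiface side ('left', 'right' or 'mid') of one feature name.

    The prefix before the first ``|`` is either a distance-signal name
    (``d_ebl|s|max``) or a RAP patch tag (``rap22|XY|05``).
    """
    prefix = feature_name.split("|", 1)[0]
    if prefix.startswith("rap"):
        idx = int(prefix[3:])
        try:
            return facemap.RAP_SIDES[idx]
        except KeyError as exc:
            raise ConfigError(f"no hemiface side configured for landmark {idx}") from exc
    try:
        return facemap.DISTANCE_SIDES[prefix]
    except KeyError as exc:
        raise ConfigError(f"no hemiface side configured for signal {prefix!r}") from exc


def hemiface_select(feature_names: list[str], side: str) -> list[str]:
    """Subset of feature names belonging to one hemiface.

    ``left`` keeps left-side and midline features, ``right`` the mirror set,
    ``whole`` everything. Midline features (nose–mouth geometry, mouth
    width/height, midline patches) belong to both hemifaces, so
    left ∪ right covers every lateral feature once and midline features
    twice.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")
    if side == "whole":
        return list(feature_names)
    keep = {side, "mid"}
    return [name for name in feature_names if feature_side(name) in keep]


def hemiface_mask(feature_names: list[str], side: str) -> np.ndarray:
    """Boolean mask over *feature_names* implementing :func:`hemiface_select`."""
    selected = set(hemiface_select(feature_names, side))
    return np.asarray([name in selected for name in feature_names], dtype=bool)
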