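"""Core domain containers and on-disk formats.

Landmark sequences travel as plain CSV (one row per frame, 136 coordinate
columns, a ``# fs=<Hz>`` comment carrying the sampling rate) or as an
equivalent JSON document; frame stacks as directories of zero-padded
grayscale PNGs. Reading back a written file reproduces the sequence
bit-exactly for finite values.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import ground_truth

__all__ = [
    "FormatError",
    "LandmarkFrame",
    "LandmarkSequence",
    "FrameStack",
    "SubjectRecord",
    "PainInstance",
    "Prediction",
    "STREAM_NAMES",
    "read_landmarks",
    "write_landmarks",
    "read_frames",
    "write_frames",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "write_results",
    "read_results",
]

N_LANDMARKS = 68

#: Canonical names of the four per-video feature streams.
STREAM_NAMES = ("DG_DisFace", "DG_DisPose", "DA_Gradient", "DA_LBP-TOP")


class FormatError(ValueError):
    """An input file violates the documented landmark/annotation dialect."""


@dataclass(frozen=True)
class LandmarkFrame:
    """68 ordered (x, y) pixel coordinates for one video frame."""

    points: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise FormatError(
                f"frame {self.frame_index}: expected {N_LANDMARKS} (x, y) points, "
                f"got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise FormatError(f"frame {self.frame_index}: non-finite coordinates")
        if self.frame_index < 0:
            raise FormatError(f"negative frame index {self.frame_index}")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class LandmarkSequence:
    """Ordered landmark frames for one video, with its sampling rate in Hz."""

    frames: tuple[LandmarkFrame, ...]
    fs: float
    video_id: str = ""

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise FormatError("landmark sequence needs at least 2 frames")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        for i, fr in enumerate(frames):
            if fr.frame_index != i:
                raise FormatError(
                    f"frame indices must increase by 1 from 0; position {i} has index {fr.frame_index}"
                )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """All coordinates as one ``(n_frames, 68, 2)`` float array."""
        return np.stack([fr.points for fr in self.frames])

    @classmethod
    def from_array(cls, coords: np.ndarray, fs: float, video_id: str = "") -> "LandmarkSequence":
        coords = np.asarray(coords, dtype=float)
        frames = tuple(LandmarkFrame(points=coords[i], frame_index=i) for i in range(coords.shape[0]))
        return cls(frames=frames, fs=fs, video_id=video_id)


@dataclass(frozen=True)
class FrameStack:
    """Grayscale frames aligned one-to-one with a landmark sequence."""

    images: np.ndarray  # (n_frames, height, width)

    def __post_init__(self) -> None:
        img = np.asarray(self.images)
        if img.ndim != 3:
            raise FormatError(f"frame stack must be (n, h, w), got shape {img.shape}")
        object.__setattr__(self, "images", img)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def height(self) -> int:
        return self.images.shape[1]

    @property
    def width(self) -> int:
        return self.images.shape[2]


_GENDERS = ("male", "female", "unknown")
_RACES = ("white", "black", "asian", "unknown")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    gender: str = "unknown"
    gestational_age_weeks: float = float("nan")
    race: str = "unknown"

    def __post_init__(self) -> None:
        if self.gender not in _GENDERS:
            raise ValueError(f"gender must be one of {_GENDERS}, got {self.gender!r}")
        if self.race not in _RACES:
            raise ValueError(f"race must be one of {_RACES}, got {self.race!r}")
        if not math.isnan(self.gestational_age_weeks) and self.gestational_age_weeks <= 0:
            raise ValueError("gestational age must be positive")

    @property
    def preterm(self) -> bool:
        """Born before 37 gestational weeks."""
        return self.gestational_age_weeks < 37.0

    @property
    def full_term(self) -> bool:
        """Gestation of 37 to 42 weeks."""
        return 37.0 <= self.gestational_age_weeks <= 42.0


@dataclass
class PainInstance:
    """One epoch of one subject's video with its feature streams and label."""

    subject: SubjectRecord
    epoch_id: str
    streams: dict[str, np.ndarray]
    nips_score: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.epoch_id not in ground_truth.EPOCH_IDS:
            raise ValueError(f"epoch_id must be one of {ground_truth.EPOCH_IDS}")
        expected = ground_truth.pain_label(self.nips_score)
        if not self.label:
            self.label = expected
        elif self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with NIPS total {self.nips_score} "
                f"(expected {expected!r})"
            )


@dataclass(frozen=True)
class Prediction:
    """Fused decision for one instance: final label, per-stream votes, confidence."""

    label: str
    votes: dict[str, str]
    confidences: dict[str, float]
    fused_score: float


# --- landmark files -------------------------------------------------------


def write_landmarks(seq: LandmarkSequence, path: str | Path) -> None:
    """Write a landmark sequence as CSV (or JSON when the suffix is .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "video_id": seq.video_id,
            "fs": seq.fs,
            "frames": [fr.points.tolist() for fr in seq.frames],
        }
        path.write_text(json.dumps(doc))
        return
    cols = ["frame"] + [f"{ax}{i}" for i in range(N_LANDMARKS) for ax in ("x", "y")]
    lines = [f"# fs={seq.fs!r}", ",".join(cols)]
    for fr in seq.frames:
        vals = [str(fr.frame_index)] + [repr(float(v)) for v in fr.points.ravel()]
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")


def read_landmarks(path: str | Path) -> LandmarkSequence:
    """Read a landmark sequence written by :func:`write_landmarks`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        coords = np.asarray(doc["frames"], dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (N_LANDMARKS, 2):
            bad = 0 if coords.ndim < 2 else int(np.argmax([len(f) != N_LANDMARKS for f in doc["frames"]]))
            raise FormatError(f"{path}: frame {bad} does not carry {N_LANDMARKS} points")
        return LandmarkSequence.from_array(coords, fs=float(doc["fs"]), video_id=doc.get("video_id", ""))

    fs = None
    body_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if stripped.startswith("fs="):
                fs = float(stripped[3:])
        elif line.strip():
            body_lines.append(line)
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=<Hz>' header")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: unreadable landmark CSV ({exc})") from exc
    expected_cols = 1 + 2 * N_LANDMARKS
    if df.shape[1] != expected_cols:
        raise FormatError(
            f"{path}: expected {expected_cols} columns (frame + {N_LANDMARKS} point pairs), got {df.shape[1]}"
        )
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    bad_rows = ~np.all(np.isfinite(values), axis=1)
    if np.any(bad_rows):
        frame = int(df.iloc[int(np.argmax(bad_rows)), 0])
        raise FormatError(f"{path}: frame {frame} has missing or non-finite coordinates")
    coords = values.reshape(len(df), N_LANDMARKS, 2)
    return LandmarkSequence.from_array(coords, fs=fs, video_id=path.stem)


# --- frame stacks ---------------------------------------------------------


def write_frames(stack: FrameStack, directory: str | Path) -> None:
    """Write every frame as ``frame_####.png`` (grayscale) in *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(stack.images):
        iio.imwrite(directory / f"frame_{i:04d}.png", np.asarray(img, dtype=np.uint8))


def read_frames(directory: str | Path) -> FrameStack:
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FormatError(f"{directory}: no frame_*.png files found")
    images = np.stack([np.asarray(iio.imread(p)) for p in paths])
    return FrameStack(images=images)


# --- tables ---------------------------------------------------------------


def write_metadata(subjects: list[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "gender": [s.gender for s in subjects],
            "gestational_age_weeks": [s.gestational_age_weeks for s in subjects],
            "race": [s.race for s in subjects],
        }
    )
    df.to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            gender=str(r.gender),
            gestational_age_weeks=float(r.gestational_age_weeks),
            race=str(r.race),
        )
        for r in df.itertuples()
    ]


_NIPS_COLS = ["facial_expression", "cry", "breathing", "arms", "legs", "arousal"]


def write_annotations(rows: list[dict], path: str | Path) -> None:
    """Write the per-epoch annotation table (video id, subject, epoch, NIPS indicators)."""
    cols = ["video_id", "subject_id", "epoch_id", *(f"nips_{c}" for c in _NIPS_COLS)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("video_id", "subject_id", "epoch_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {missing}")
    return df


# --- results --------------------------------------------------------------


def write_results(instances: list[PainInstance], predictions: list[Prediction], path: str | Path) -> None:
    """Write per-instance predictions as CSV (one row per instance)."""
    if len(instances) != len(predictions):
        raise ValueError("instances and predictions must have equal length")
    stream_names = sorted({s for p in predictions for s in p.votes})
    cols = ["subject_id", "epoch_id", "true_label", "predicted_label", "fused_score"]
    cols += [f"vote_{s}" for s in stream_names] + [f"conf_{s}" for s in stream_names]
    rows = []
    for inst, pred in zip(instances, predictions):
        row = {
            "subject_id": inst.subject.subject_id,
            "epoch_id": inst.epoch_id,
            "true_label": inst.label,
            "predicted_label": pred.label,
            "fused_score": pred.fused_score,
        }
        for s in stream_names:
            row[f"vote_{s}"] = pred.votes.get(s, "")
            row[f"conf_{s}"] = pred.confidences.get(s, float("nan"))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
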