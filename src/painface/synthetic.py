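"""Synthetic infant-face cohort generator.

Produces landmark sequences, rendered grayscale frame stacks, NIPS
annotations and subject metadata with controllable pain dynamics, so the
whole pipeline can be exercised and tested without any recordings.

A fixed neutral 68-point face template on a 256×256 canvas is animated per
epoch. Pain epochs superimpose, scaled by a smooth within-epoch activation
profile, the facial actions that pain scales code for:

* eyebrow drop — the brows move toward the eyes (brow bulge), decreasing
  the eyebrow–eye distances;
* eyelid closure — upper and lower lids approach (eye squeeze), decreasing
  the eyelid distances;
* mouth opening — the lower lip drops (vertical mouth stretch), increasing
  the mouth height;
* lateral head shake — a sinusoidal horizontal shift of the face-boundary
  landmarks, creating the left/right pose asymmetry;
* wrinkle texture — oriented sinusoidal gratings added in the glabellar and
  nasolabial patch regions, exciting the gradient and LBP-TOP features.

No-pain epochs receive landmark jitter and pixel noise only. NIPS
indicators are drawn consistently with the epoch type (pain totals ≥ 3,
no-pain totals ≤ 2). The same spec and seed always reproduce the cohort
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from . import data, ground_truth
from .data import FrameStack, LandmarkSequence, SubjectRecord

__all__ = [
    "CohortSpec",
    "CohortRecord",
    "neutral_template",
    "generate_epoch",
    "generate_cohort",
    "generate_cohort_to_dir",
    "load_cohort",
]

IMAGE_SIZE = 256

_BROWS = np.arange(17, 27)
_UPPER_LIDS = np.array([37, 38, 43, 44])
_LOWER_LIDS = np.array([40, 41, 46, 47])
_LOWER_LIP = np.array([55, 56, 57, 58, 59, 65, 66, 67])
_JAW = np.arange(0, 17)


def neutral_template() -> np.ndarray:
    """The fixed neutral 68-point layout (x, y) on a 256×256 canvas.

    Bilaterally symmetric about x = 128; index convention as in
    :mod:`painface.facemap`.
    """
    pts = np.zeros((68, 2))
    # jaw: lower half-ellipse from the subject's right temple to the left
    theta = np.pi - np.arange(17) * np.pi / 16
    pts[0:17, 0] = 128 + 82 * np.cos(theta)
    pts[0:17, 1] = 118 + 104 * np.sin(theta)
    # brows
    pts[17:22, 0] = np.linspace(62, 108, 5)
    pts[17:22, 1] = [92, 87, 85, 87, 90]
    pts[22:27, 0] = np.linspace(148, 194, 5)
    pts[22:27, 1] = [90, 87, 85, 87, 92]
    # nose bridge and base
    pts[27:31, 0] = 128
    pts[27:31, 1] = [100, 112, 124, 136]
    pts[31:36, 0] = [112, 120, 128, 136, 144]
    pts[31:36, 1] = 148
    # eyes (hexagons)
    pts[36:42] = [(72, 106), (84, 100), (96, 100), (108, 106), (96, 112), (84, 112)]
    pts[42:48] = [(148, 106), (160, 100), (172, 100), (184, 106), (172, 112), (160, 112)]
    # outer lip
    pts[48:60] = [
        (98, 184), (106, 177), (114, 173), (128, 171), (142, 173), (150, 177),
        (158, 184), (150, 191), (142, 195), (128, 197), (114, 195), (106, 191),
    ]
    # inner lip
    pts[60:68] = [
        (106, 184), (117, 179), (128, 178), (139, 179),
        (150, 184), (139, 189), (128, 190), (117, 189),
    ]
    return pts


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Pain effect magnitudes are in pixels on the 256×256 template except
    ``wrinkle_contrast`` (gray levels); ``noise_sd`` is landmark jitter in
    pixels. ``seed`` fixes the whole cohort bit-exactly.
    """

    n_subjects: int = 12
    epochs_per_subject: int = 4
    fs: float = 30.0
    frames_per_epoch: int = 45
    eyebrow_drop: float = 6.0
    eyelid_close: float = 5.0
    mouth_open: float = 10.0
    headshake_amp: float = 4.0
    headshake_hz: float = 1.0
    wrinkle_contrast: float = 30.0
    noise_sd: float = 1.0
    render_images: bool = True
    seed: int = 0
    male_fraction: float = 0.5
    race_probs: tuple[tuple[str, float], ...] = (("white", 0.5), ("black", 0.35), ("asian", 0.15))

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")
        if not 1 <= self.epochs_per_subject <= len(ground_truth.EPOCH_IDS):
            raise ValueError("epochs_per_subject must be between 1 and 7")
        for name in ("eyebrow_drop", "eyelid_close", "mouth_open", "headshake_amp",
                     "wrinkle_contrast", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortRecord:
    """One generated epoch video with its annotations."""

    video_id: str
    subject: SubjectRecord
    epoch_id: str
    pain: bool
    indicators: ground_truth.NipsIndicators
    nips_score: int
    label: str
    sequence: LandmarkSequence
    frames: FrameStack | None


def _activation(n: int) -> np.ndarray:
    """Smooth within-epoch activation bump: 0 at the ends, 1 in the middle."""
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2


def _pain_landmarks(spec: CohortSpec, t: np.ndarray, act: np.ndarray) -> np.ndarray:
    """Per-frame landmark displacements of a pain epoch (n, 68, 2)."""
    n = len(t)
    disp = np.zeros((n, 68, 2))
    disp[:, _BROWS, 1] += spec.eyebrow_drop * act[:, None]
    disp[:, _UPPER_LIDS, 1] += 0.5 * spec.eyelid_close * act[:, None]
    disp[:, _LOWER_LIDS, 1] -= 0.5 * spec.eyelid_close * act[:, None]
    disp[:, _LOWER_LIP, 1] += spec.mouth_open * act[:, None]
    shake = spec.headshake_amp * np.sin(2 * np.pi * spec.headshake_hz * t) * act
    disp[:, _JAW, 0] += shake[:, None]
    return disp


def _draw_band(img: np.ndarray, pts: np.ndarray, width: float, value: float) -> None:
    band = np.vstack([pts, pts[::-1] + [0.0, width]])
    rr, cc = draw_polygon(band[:, 1], band[:, 0], shape=img.shape)
    img[rr, cc] = value


def _render_frame(points: np.ndarray, wrinkle_amp: float, rng: np.random.Generator) -> np.ndarray:
    """Render one grayscale frame from a landmark frame."""
    img = np.full((IMAGE_SIZE, IMAGE_SIZE), 110.0)
    rr, cc = draw_ellipse(118, 128, 108, 86, shape=img.shape)
    img[rr, cc] = 175.0
    for sl, value in (
        (slice(17, 22), 70.0),
        (slice(22, 27), 70.0),
    ):
        _draw_band(img, points[sl], 4.0, value)
    for sl, value in (
        (slice(36, 42), 60.0),
        (slice(42, 48), 60.0),
        (slice(48, 60), 85.0),
    ):
        poly = points[sl]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        img[rr, cc] = value
    _draw_band(img, points[[27, 30]], 3.0, 150.0)
    _draw_band(img, points[31:36], 3.0, 140.0)

    if wrinkle_amp > 0:
        glabella = 0.5 * (points[21] + points[22]) - [0.0, 6.0]
        naso_r = points[31] + [-10.0, 6.0]
        naso_l = points[35] + [10.0, 6.0]
        for center, angle in ((glabella, 0.0), (naso_r, np.pi / 4), (naso_l, -np.pi / 4)):
            cx, cy = int(round(center[0])), int(round(center[1]))
            r0, r1 = max(0, cy - 16), min(IMAGE_SIZE, cy + 16)
            c0, c1 = max(0, cx - 16), min(IMAGE_SIZE, cx + 16)
            rr_grid, cc_grid = np.mgrid[r0:r1, c0:c1]
            phase = (cc_grid * np.cos(angle) + rr_grid * np.sin(angle)) * (2 * np.pi / 4.0)
            img[r0:r1, c0:c1] += 0.5 * wrinkle_amp * np.sin(phase)

    img += rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_epoch(
    spec: CohortSpec, pain: bool, rng: np.random.Generator, video_id: str = ""
) -> tuple[LandmarkSequence, FrameStack | None]:
    """Generate one epoch: a landmark sequence and (optionally) its frames."""
    n = spec.frames_per_epoch
    t = np.arange(n) / spec.fs
    act = _activation(n)
    coords = np.broadcast_to(neutral_template(), (n, 68, 2)).copy()
    if pain:
        coords += _pain_landmarks(spec, t, act)
    coords += rng.normal(0.0, spec.noise_sd, size=coords.shape)
    seq = LandmarkSequence.from_array(coords, fs=spec.fs, video_id=video_id)
    stack = None
    if spec.render_images:
        wrinkle = spec.wrinkle_contrast if pain else 0.0
        images = np.stack(
            [_render_frame(coords[i], wrinkle * act[i], rng) for i in range(n)]
        )
        stack = FrameStack(images=images)
    return seq, stack


def _sample_indicators(pain: bool, rng: np.random.Generator) -> ground_truth.NipsIndicators:
    if pain:
        ind = ground_truth.NipsIndicators(
            facial_expression=1,
            cry=int(rng.integers(1, 3)),
            breathing=1,
            arms=int(rng.integers(0, 2)),
            legs=int(rng.integers(0, 2)),
            arousal=int(rng.integers(0, 2)),
        )
    else:
        ind = ground_truth.NipsIndicators(
            facial_expression=0,
            cry=int(rng.integers(0, 2)),
            breathing=0,
            arms=0,
            legs=0,
            arousal=int(rng.integers(0, 2)),
        )
    return ind


def _sample_subject(i: int, spec: CohortSpec, rng: np.random.Generator) -> SubjectRecord:
    gender = "male" if (i % 2 == 0) == (spec.male_fraction >= 0.5) else "female"
    age = float(np.clip(rng.normal(36.4, 2.7), 30.4, 40.6))
    races, probs = zip(*spec.race_probs)
    race = str(rng.choice(races, p=np.asarray(probs) / np.sum(probs)))
    return SubjectRecord(
        subject_id=f"S{i:02d}", gender=gender, gestational_age_weeks=age, race=race
    )


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate the full cohort in memory.

    Each subject contributes ``epochs_per_subject`` epochs taken in order
    from T0; the first half of the post-baseline epochs (T1, T2, ...) are
    pain epochs, the baseline and trailing epochs no-pain, giving balanced
    labels for even epoch counts.
    """
    rng = np.random.default_rng(spec.seed)
    epoch_ids = ground_truth.EPOCH_IDS[: spec.epochs_per_subject]
    pain_ids = set(ground_truth.EPOCH_IDS[1 : 1 + spec.epochs_per_subject // 2])
    records: list[CohortRecord] = []
    for i in range(spec.n_subjects):
        subject = _sample_subject(i, spec, rng)
        for epoch_id in epoch_ids:
            pain = epoch_id in pain_ids
            video_id = f"{subject.subject_id}_{epoch_id}"
            seq, stack = generate_epoch(spec, pain, rng, video_id=video_id)
            ind = _sample_indicators(pain, rng)
            score = ground_truth.nips_total(ind)
            records.append(
                CohortRecord(
                    video_id=video_id,
                    subject=subject,
                    epoch_id=epoch_id,
                    pain=pain,
                    indicators=ind,
                    nips_score=score,
                    label=ground_truth.pain_label(score),
                    sequence=seq,
                    frames=stack,
                )
            )
    return records


def generate_cohort_to_dir(spec: CohortSpec, outdir: str | Path) -> list[CohortRecord]:
    """Generate a cohort and write it in the package's on-disk formats."""
    outdir = Path(outdir)
    (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
    records = generate_cohort(spec)
    for rec in records:
        data.write_landmarks(rec.sequence, outdir / "landmarks" / f"{rec.video_id}.csv")
        if rec.frames is not None:
            data.write_frames(rec.frames, outdir / "frames" / rec.video_id)
    subjects = {rec.subject.subject_id: rec.subject for rec in records}
    data.write_metadata(list(subjects.values()), outdir / "metadata.csv")
    rows = []
    for rec in records:
        row = {"video_id": rec.video_id, "subject_id": rec.subject.subject_id, "epoch_id": rec.epoch_id}
        row.update({f"nips_{k}": v for k, v in rec.indicators.as_dict().items()})
        rows.append(row)
    data.write_annotations(rows, outdir / "annotations.csv")
    return records


def load_cohort(directory: str | Path) -> list[CohortRecord]:
    """Read a cohort written by :func:`generate_cohort_to_dir`."""
    directory = Path(directory)
    subjects = {s.subject_id: s for s in data.read_metadata(directory / "metadata.csv")}
    ann = data.read_annotations(directory / "annotations.csv")
    records: list[CohortRecord] = []
    for row in ann.itertuples():
        seq = data.read_landmarks(directory / "landmarks" / f"{row.video_id}.csv")
        frames_dir = directory / "frames" / str(row.video_id)
        stack = data.read_frames(frames_dir) if frames_dir.is_dir() else None
        ind = ground_truth.NipsIndicators(
            facial_expression=int(row.nips_facial_expression),
            cry=int(row.nips_cry),
            breathing=int(row.nips_breathing),
            arms=int(row.nips_arms),
            legs=int(row.nips_legs),
            arousal=int(row.nips_arousal),
        )
        score = ground_truth.nips_total(ind)
        label = ground_truth.pain_label(score)
        records.append(
            CohortRecord(
                video_id=str(row.video_id),
                subject=subjects[str(row.subject_id)],
                epoch_id=str(row.epoch_id),
                pain=label == "pain",
                indicators=ind,
                nips_score=score,
                label=label,
                sequence=seq,
                frames=stack,
            )
        )
    return records
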