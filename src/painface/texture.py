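"""Patch-based facial appearance features: gradient magnitude and LBP-TOP.

Around 31 configured landmarks, 32×32 pixel Regions Around Points (RAPs)
are cut from every frame, following the moving landmark. Two appearance
measures are computed on them:

* per frame, the mean 3×3-Sobel gradient magnitude of each patch — one
  value per RAP, 31 per frame — which responds to wrinkling (brow bulge,
  nasolabial furrow) in the patch;
* per video, LBP-TOP: 8-neighbor local binary patterns coded independently
  on the three orthogonal plane families of each patch volume — spatial XY
  slices and the two spatio-temporal slices XT and YT — each accumulated
  into the 59-bin uniform-2 histogram. 3 planes × 59 bins = 177 values per
  patch, 5487 = 177 × 31 per video.

LBP compares each neighbor to the central pixel (neighbor ≥ center → 1) on
the integer 8-connected ring, so the descriptor is invariant to adding a
constant gray level to the whole volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import facemap, temporal
from .data import FrameStack, LandmarkSequence

__all__ = [
    "N_RAP",
    "PATCH_SIZE",
    "PLANES",
    "UNIFORM_BINS",
    "PatchVolume",
    "extract_patch",
    "gradient_frame",
    "gradient_signals",
    "lbp_top_patch",
    "video_appearance",
    "uniform_lut",
    "lbp_top_feature_names",
]

N_RAP = 31
PATCH_SIZE = 32
PLANES = ("XY", "XT", "YT")
UNIFORM_BINS = 59  # 58 uniform-2 codes + 1 catch-all

# Neighbor offsets (drow, dcol) in ring order; bit i has weight 2**i.
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def uniform_lut() -> np.ndarray:
    """Map each 8-bit LBP code to its uniform-2 histogram bin.

    Codes with at most two circular 0/1 transitions get bins 0–57 in
    ascending code order; all other codes share the catch-all bin 58.
    """
    lut = np.full(256, UNIFORM_BINS - 1, dtype=np.int64)
    nxt = 0
    for code in range(256):
        bits = [(code >> i) & 1 for i in range(8)]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        if transitions <= 2:
            lut[code] = nxt
            nxt += 1
    return lut


_LUT = uniform_lut()


@dataclass(frozen=True)
class PatchVolume:
    """Per-frame 32×32 crops following one landmark across a video."""

    crops: np.ndarray  # (n_frames, size, size)
    landmark_id: int

    def __post_init__(self) -> None:
        crops = np.asarray(self.crops)
        if crops.ndim != 3 or crops.shape[1] != crops.shape[2]:
            raise ValueError(f"patch volume must be (n, s, s), got shape {crops.shape}")
        object.__setattr__(self, "crops", crops)


def extract_patch(image: np.ndarray, center: tuple[float, float], size: int = PATCH_SIZE) -> np.ndarray:
    """Square crop centered on the rounded center; out-of-bounds pixels replicate the edge."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("extract_patch expects a non-empty 2-D image")
    cx, cy = float(center[0]), float(center[1])
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise ValueError(f"non-finite patch center {center!r}")
    col0 = int(np.rint(cx)) - size // 2
    row0 = int(np.rint(cy)) - size // 2
    rows = np.clip(np.arange(row0, row0 + size), 0, image.shape[0] - 1)
    cols = np.clip(np.arange(col0, col0 + size), 0, image.shape[1] - 1)
    return image[np.ix_(rows, cols)]


def _gradient_magnitude(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def gradient_frame(image: np.ndarray, centers: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Mean Sobel gradient magnitude over the 32×32 patch at each of the 31 RAP centers."""
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (N_RAP, 2):
        raise ValueError(f"expected {N_RAP} patch centers, got shape {centers.shape}")
    mag = _gradient_magnitude(image)
    return np.asarray([float(np.mean(extract_patch(mag, c, size))) for c in centers])


def gradient_signals(
    stack: FrameStack,
    seq: LandmarkSequence,
    rap_indices: list[int] | None = None,
    size: int = PATCH_SIZE,
) -> dict[str, temporal.TemporalSignal]:
    """31 per-video texture signals: each RAP's mean gradient magnitude over frames."""
    rap_indices = list(rap_indices if rap_indices is not None else facemap.DEFAULT_RAP_INDICES)
    if len(stack) != len(seq):
        raise ValueError(f"frame stack length {len(stack)} != landmark sequence length {len(seq)}")
    values = np.empty((len(seq), len(rap_indices)))
    for t, frame in enumerate(seq.frames):
        centers = frame.points[np.asarray(rap_indices, dtype=int)]
        mag = _gradient_magnitude(stack.images[t])
        values[t] = [float(np.mean(extract_patch(mag, c, size))) for c in centers]
    return {
        f"rap{idx}": temporal.make_signal(f"rap{idx}", values[:, j], seq.fs)
        for j, idx in enumerate(rap_indices)
    }


def _lbp_codes(plane: np.ndarray) -> np.ndarray:
    """8-neighbor LBP codes of every interior pixel of one 2-D plane."""
    plane = np.asarray(plane, dtype=float)
    center = plane[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_OFFSETS):
        neighbor = plane[1 + dr : plane.shape[0] - 1 + dr, 1 + dc : plane.shape[1] - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << bit
    return codes


def _plane_histogram(planes: list[np.ndarray]) -> np.ndarray:
    hist = np.zeros(UNIFORM_BINS, dtype=float)
    for plane in planes:
        codes = _lbp_codes(plane)
        hist += np.bincount(_LUT[codes.ravel()], minlength=UNIFORM_BINS)
    return hist


def lbp_top_patch(volume: np.ndarray | PatchVolume, normalize: bool = True) -> np.ndarray:
    """LBP histograms on the three orthogonal plane families of one patch volume.

    The volume is indexed ``(t, y, x)``. XY slices are the individual
    frames; XT slices fix a row y, YT slices fix a column x. Every pixel
    that is interior within its own plane is coded. The three 59-bin
    histograms are concatenated XY‖XT‖YT (177 values); with
    ``normalize=True`` (default) each plane histogram is L1-normalized.
    """
    vol = volume.crops if isinstance(volume, PatchVolume) else np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"patch volume must be 3-D (t, y, x), got shape {vol.shape}")
    n_t, n_y, n_x = vol.shape
    if n_t < 3:
        raise ValueError(f"LBP-TOP needs at least 3 frames for temporal planes, got {n_t}")
    if n_y < 3 or n_x < 3:
        raise ValueError(f"patch spatial extent must be at least 3x3, got {n_y}x{n_x}")
    vol = vol.astype(float)
    hists = [
        _plane_histogram([vol[t] for t in range(n_t)]),            # XY
        _plane_histogram([vol[:, y, :] for y in range(n_y)]),      # XT
        _plane_histogram([vol[:, :, x] for x in range(n_x)]),      # YT
    ]
    if normalize:
        hists = [h / s if (s := h.sum()) > 0 else h for h in hists]
    return np.concatenate(hists)


def video_appearance(
    stack: FrameStack,
    seq: LandmarkSequence,
    rap_indices: list[int] | None = None,
    size: int = PATCH_SIZE,
    normalize: bool = True,
) -> np.ndarray:
    """Per-video LBP-TOP descriptor over all RAPs: 177 × 31 = 5487 values.

    Each patch volume follows its landmark across frames; descriptors are
    concatenated in RAP-config order.
    """
    rap_indices = list(rap_indices if rap_indices is not None else facemap.DEFAULT_RAP_INDICES)
    if len(stack) != len(seq):
        raise ValueError(f"frame stack length {len(stack)} != landmark sequence length {len(seq)}")
    blocks = []
    for idx in rap_indices:
        crops = np.stack(
            [
                extract_patch(stack.images[t], seq.frames[t].points[idx], size)
                for t in range(len(seq))
            ]
        )
        blocks.append(lbp_top_patch(PatchVolume(crops=crops, landmark_id=idx), normalize=normalize))
    return np.concatenate(blocks)


def lbp_top_feature_names(rap_indices: list[int] | None = None) -> list[str]:
    """Feature names matching video_appearance's layout: ``rap<idx>|<plane>|<bin>``."""
    rap_indices = list(rap_indices if rap_indices is not None else facemap.DEFAULT_RAP_INDICES)
    return [
        f"rap{idx}|{plane}|{b:02d}"
        for idx in rap_indices
        for plane in PLANES
        for b in range(UNIFORM_BINS)
    ]
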