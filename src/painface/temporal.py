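"""Sequence-level temporal descriptors for frame-level facial signals.

Each raw per-frame signal ``x`` (a geometric distance or a patch texture
value over time) is low-pass smoothed into ``s`` with a zero-phase
first-order Butterworth filter (1 Hz cutoff), then differentiated twice to
the rate ``v`` and acceleration ``a``. Sixteen scalar descriptors are read
off each of ``s``, ``v`` and ``a``:

* state — maximum, minimum, mean, median;
* variability — range, standard deviation, inter-quartile range,
  inter-decile range, median absolute deviation;
* peak — time (s) of the first maximum;
* duration — seconds spent strictly above the mean, and strictly above
  (mean + min) / 2;
* segments — number of maximal runs above each of those two thresholds;
* area — rectangle-rule area between the signal and its minimum (AREA),
  and AREA / (max − min), defined as 0 for a flat signal.

That gives 48 = 16 × 3 descriptors per source signal; concatenating them
over the 11 deformation, 8 pose or 31 gradient signals yields feature
vectors of length 528, 384 and 1488.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "TemporalSignal",
    "DESCRIPTOR_NAMES",
    "COMPONENTS",
    "smooth",
    "differentiate",
    "make_signal",
    "describe",
    "build_stream",
    "stream_feature_names",
]

#: Frozen descriptor order inside each 16-block.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "max", "min", "mean", "median",
    "range", "std", "iqr", "idr", "mad",
    "t_max",
    "dur_above_mean", "dur_above_halfmin",
    "seg_above_mean", "seg_above_halfmin",
    "area", "area_quotient",
)

#: Component order inside each 48-block: smoothed signal, velocity, acceleration.
COMPONENTS: tuple[str, ...] = ("s", "v", "a")

CUTOFF_HZ = 1.0


@dataclass(frozen=True)
class TemporalSignal:
    """One named scalar signal over frames with its smoothed form and derivatives."""

    name: str
    x: np.ndarray
    s: np.ndarray
    v: np.ndarray
    a: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.x)
        if n < 2:
            raise ValueError(f"signal {self.name!r}: need at least 2 samples")
        if not (len(self.s) == len(self.v) == len(self.a) == n):
            raise ValueError(f"signal {self.name!r}: x, s, v, a must share one length")

    def component(self, key: str) -> np.ndarray:
        if key not in COMPONENTS:
            raise KeyError(f"component must be one of {COMPONENTS}, got {key!r}")
        return getattr(self, key)


def smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase first-order Butterworth low-pass (1 Hz cutoff).

    The filter runs forward then backward, so the effective amplitude
    response is the squared first-order magnitude and no phase lag is
    introduced — peak-time descriptors stay aligned with the raw signal.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * CUTOFF_HZ:
        raise ValueError(f"sampling rate {fs} Hz puts the {CUTOFF_HZ} Hz cutoff at/above Nyquist")
    if x.size < 4:
        raise ValueError("smoothing needs at least 4 samples")
    b, a = sp_signal.butter(1, CUTOFF_HZ, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return sp_signal.filtfilt(b, a, x, padlen=padlen)


def differentiate(s: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference derivative: central in the interior, one-sided at the ends."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("differentiation needs at least 2 samples")
    return np.gradient(s, 1.0 / fs)


def make_signal(name: str, x: np.ndarray, fs: float) -> TemporalSignal:
    """Assemble a TemporalSignal: smooth, then differentiate twice."""
    x = np.asarray(x, dtype=float)
    s = smooth(x, fs)
    v = differentiate(s, fs)
    a = differentiate(v, fs)
    return TemporalSignal(name=name, x=x, s=s, v=v, a=a, fs=fs)


def _run_count(above: np.ndarray) -> int:
    """Number of maximal runs of True."""
    if above.size == 0:
        return 0
    return int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))


def describe(y: np.ndarray, fs: float) -> dict[str, float]:
    """The 16 temporal descriptors of one component signal.

    Conventions (fixed and tested): quantiles use linear interpolation;
    threshold tests are strict ``>``; durations are counts above threshold
    divided by fs (seconds); the peak time is the first maximum index / fs;
    AREA uses the rectangle rule with bin width 1/fs.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot describe an empty signal")
    y_max = float(np.max(y))
    y_min = float(np.min(y))
    y_mean = float(np.mean(y))
    half = 0.5 * (y_mean + y_min)
    above_mean = y > y_mean
    above_half = y > half
    q75, q25 = np.percentile(y, [75, 25])
    d90, d10 = np.percentile(y, [90, 10])
    area = float(np.sum(y - y_min) / fs)
    rng = y_max - y_min
    return {
        "max": y_max,
        "min": y_min,
        "mean": y_mean,
        "median": float(np.median(y)),
        "range": rng,
        "std": float(np.std(y)),
        "iqr": float(q75 - q25),
        "idr": float(d90 - d10),
        "mad": float(np.median(np.abs(y - np.median(y)))),
        "t_max": float(np.argmax(y) / fs),
        "dur_above_mean": float(np.sum(above_mean) / fs),
        "dur_above_halfmin": float(np.sum(above_half) / fs),
        "seg_above_mean": float(_run_count(above_mean)),
        "seg_above_halfmin": float(_run_count(above_half)),
        "area": area,
        "area_quotient": area / rng if rng > 0 else 0.0,
    }


def signal_descriptors(sig: TemporalSignal) -> np.ndarray:
    """48 descriptors for one signal: 16 per component in (s, v, a) order."""
    parts = [
        [describe(sig.component(c), sig.fs)[d] for d in DESCRIPTOR_NAMES]
        for c in COMPONENTS
    ]
    return np.asarray([v for block in parts for v in block], dtype=float)


def build_stream(signals: dict[str, TemporalSignal]) -> np.ndarray:
    """Concatenate 48 descriptors per signal in (signal, component, descriptor) order.

    11 deformation signals give the 528-dim facial-configuration stream,
    8 pose signals the 384-dim head-pose stream and 31 gradient signals the
    1488-dim texture-dynamics stream.
    """
    if not signals:
        raise ValueError("no signals to build a stream from")
    lengths = {len(sig.x) for sig in signals.values()}
    rates = {sig.fs for sig in signals.values()}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError("all signals in a stream must share length and sampling rate")
    return np.concatenate([signal_descriptors(sig) for sig in signals.values()])


def stream_feature_names(signal_names: list[str]) -> list[str]:
    """Feature names matching build_stream's layout: ``<signal>|<component>|<descriptor>``."""
    return [
        f"{name}|{c}|{d}"
        for name in signal_names
        for c in COMPONENTS
        for d in DESCRIPTOR_NAMES
    ]
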