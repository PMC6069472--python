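"""Landmark-index conventions: point groups, distance definitions, RAP layout.

All geometric and patch-based features are defined relative to the common
68-point facial annotation scheme: indices 0–16 trace the face boundary
(jaw), 17–21 / 22–26 the right / left eyebrow, 27–35 the nose (bridge then
nostril line), 36–41 / 42–47 the right / left eye, and 48–67 the mouth
(48–59 outer lip, 60–67 inner lip).

"Left"/"right" always mean the *subject's anatomical side*. With pixel
coordinates (origin top-left, x rightward) and the subject facing the
camera, the anatomical left side appears at larger x.

Everything downstream reads these definitions from a mapping dictionary, so
an alternative landmark ordering only needs a different mapping (YAML with
the same structure), not a code change.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

__all__ = [
    "DEFAULT_MAPPING",
    "DEFORMATION_NAMES",
    "POSE_NAMES",
    "DISTANCE_SIDES",
    "DEFAULT_RAP_INDICES",
    "RAP_SIDES",
    "default_mapping",
    "default_rap_indices",
    "load_mapping",
    "validate_mapping",
    "ConfigError",
]


class ConfigError(KeyError):
    """A mapping or RAP configuration is missing a required entry."""


# --- point groups ---------------------------------------------------------

_GROUPS: dict[str, list[int]] = {
    "boundary_right": list(range(0, 8)),
    "chin": [8],
    "boundary_left": list(range(9, 17)),
    "brow_right": list(range(17, 22)),
    "brow_left": list(range(22, 27)),
    "nose_bridge": list(range(27, 31)),
    "nose_base": list(range(31, 36)),
    "eye_right": list(range(36, 42)),
    "eye_left": list(range(42, 48)),
    "upper_lid_right": [37, 38],
    "lower_lid_right": [40, 41],
    "upper_lid_left": [43, 44],
    "lower_lid_left": [46, 47],
    "mouth": list(range(48, 68)),
    "mouth_corner_right": [48, 60],
    "mouth_corner_left": [54, 64],
    "inner_corner_right": [60],
    "inner_corner_left": [64],
    "upper_inner_lip": [61, 62, 63],
    "lower_inner_lip": [65, 66, 67],
    "upper_outer_lip": [50, 51, 52],
}

# --- distances ------------------------------------------------------------

# Eleven facial-deformation distances: each is the Euclidean distance between
# the centroids of two point groups. Mouth width/height use the inner lip
# contour by default.
_DEFORMATION: dict[str, list[str]] = {
    "d_ebl": ["brow_left", "eye_left"],
    "d_ebr": ["brow_right", "eye_right"],
    "d_el": ["upper_lid_left", "lower_lid_left"],
    "d_er": ["upper_lid_right", "lower_lid_right"],
    "d_mbl": ["brow_left", "mouth"],
    "d_mbr": ["brow_right", "mouth"],
    "d_eml": ["eye_left", "mouth"],
    "d_emr": ["eye_right", "mouth"],
    "d_nm": ["nose_base", "upper_outer_lip"],
    "d_mw": ["inner_corner_left", "inner_corner_right"],
    "d_mh": ["upper_inner_lip", "lower_inner_lip"],
}

# Eight head-pose distances: face-boundary side to facial component, both
# sides. Lateral head shake moves the boundary relative to the components and
# shows up as an antisymmetric left/right change.
_POSE: dict[str, list[str]] = {
    "d_bbl": ["boundary_left", "brow_left"],
    "d_bel": ["boundary_left", "eye_left"],
    "d_bnl": ["boundary_left", "nose_base"],
    "d_bml": ["boundary_left", "mouth"],
    "d_bbr": ["boundary_right", "brow_right"],
    "d_ber": ["boundary_right", "eye_right"],
    "d_bnr": ["boundary_right", "nose_base"],
    "d_bmr": ["boundary_right", "mouth"],
}

DEFAULT_MAPPING: dict[str, Any] = {
    "groups": _GROUPS,
    "deformation": _DEFORMATION,
    "pose": _POSE,
}

DEFORMATION_NAMES: tuple[str, ...] = tuple(_DEFORMATION)
POSE_NAMES: tuple[str, ...] = tuple(_POSE)

# Hemiface assignment of the 19 distance signals. Midline features (nose and
# mouth geometry) belong to both hemifaces so a profile model keeps the
# mouth/nose evidence still visible from the side.
DISTANCE_SIDES: dict[str, str] = {
    "d_ebl": "left", "d_el": "left", "d_mbl": "left", "d_eml": "left",
    "d_ebr": "right", "d_er": "right", "d_mbr": "right", "d_emr": "right",
    "d_nm": "mid", "d_mw": "mid", "d_mh": "mid",
    "d_bbl": "left", "d_bel": "left", "d_bnl": "left", "d_bml": "left",
    "d_bbr": "right", "d_ber": "right", "d_bnr": "right", "d_bmr": "right",
}

# --- RAP (Region Around Point) layout -------------------------------------

# 31 landmark indices carrying 32x32 texture patches: the full brows (10),
# eye corners and mid lids (8), nasal root/base (4) and the mouth outline
# (9). These regions develop the brow-bulge, eye-squeeze and nasolabial
# wrinkles that pain expressions produce.
DEFAULT_RAP_INDICES: tuple[int, ...] = (
    17, 18, 19, 20, 21,          # right brow
    22, 23, 24, 25, 26,          # left brow
    36, 38, 39, 41,              # right eye: corners + mid lids
    42, 44, 45, 47,              # left eye
    27, 31, 33, 35,              # nasal root, nostril line
    48, 49, 50, 52, 53, 54, 55, 57, 59,  # mouth outline
)

RAP_SIDES: dict[int, str] = {
    17: "right", 18: "right", 19: "right", 20: "right", 21: "right",
    22: "left", 23: "left", 24: "left", 25: "left", 26: "left",
    36: "right", 38: "right", 39: "right", 41: "right",
    42: "left", 44: "left", 45: "left", 47: "left",
    27: "mid", 31: "right", 33: "mid", 35: "left",
    48: "right", 49: "right", 50: "right", 59: "right",
    52: "left", 53: "left", 54: "left", 55: "left",
    57: "mid",
}


def default_mapping() -> dict[str, Any]:
    """A deep copy of the built-in point-group/distance mapping."""
    return copy.deepcopy(DEFAULT_MAPPING)


def default_rap_indices() -> list[int]:
    return list(DEFAULT_RAP_INDICES)


def validate_mapping(mapping: dict[str, Any]) -> dict[str, Any]:
    """Check that every distance refers to defined point groups with valid indices."""
    for key in ("groups", "deformation", "pose"):
        if key not in mapping:
            raise ConfigError(f"mapping is missing section {key!r}")
    groups = mapping["groups"]
    for name, idx in groups.items():
        if not idx:
            raise ConfigError(f"point group {name!r} is empty")
        if any(not 0 <= int(i) <= 67 for i in idx):
            raise ConfigError(f"point group {name!r} has out-of-range indices")
    for section in ("deformation", "pose"):
        for dist, pair in mapping[section].items():
            if len(pair) != 2:
                raise ConfigError(f"distance {dist!r} must name exactly two groups")
            for g in pair:
                if g not in groups:
                    raise ConfigError(f"distance {dist!r} refers to undefined group {g!r}")
    return mapping


def load_mapping(path: str) -> dict[str, Any]:
    """Load a point-group/distance mapping from a YAML file and validate it."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    return validate_mapping(mapping)
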