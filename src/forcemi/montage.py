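"""Schematic 2-D coordinates for the 32-electrode 10/20 montage.

Coordinates are on a unit-radius head disc viewed from above, nose up:
x grows to the subject's right, y to the front.  They are schematic
(suitable for distances and topographic layout), not digitized positions.
HEOG/VEOG are ocular channels with no scalp position.
"""

from __future__ import annotations

import numpy as np

#: scalp channels of the 32-electrode cap, in cap order
SCALP_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2",
    "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2",
)

#: ocular channels recorded by the cap but carrying no scalp position
EOG_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG")

#: all 32 recorded channels in cap order
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS

# unit-head-radius schematic positions (x right, y front)
_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.50), "FZ": (0.0, 0.50),
    "F4": (0.40, 0.50), "F8": (0.81, 0.59),
    "FT7": (-0.89, 0.33), "FC3": (-0.42, 0.27), "FCZ": (0.0, 0.25),
    "FC4": (0.42, 0.27), "FT8": (0.89, 0.33),
    "T7": (-0.95, 0.0), "C3": (-0.50, 0.0), "CZ": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (0.95, 0.0),
    "TP7": (-0.89, -0.33), "CP3": (-0.42, -0.27), "CPZ": (0.0, -0.25),
    "CP4": (0.42, -0.27), "TP8": (0.89, -0.33),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.50), "PZ": (0.0, -0.50),
    "P4": (0.40, -0.50), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "OZ": (0.0, -0.95), "O2": (0.31, -0.95),
}


def channel_position(label: str) -> np.ndarray:
    """Return the (x, y) position of a scalp channel in head-radius units."""
    key = label.upper()
    if key not in _POSITIONS:
        raise KeyError(f"channel {label!r} has no montage position")
    return np.asarray(_POSITIONS[key], dtype=float)


def montage_positions(labels=SCALP_CHANNELS) -> dict[str, np.ndarray]:
    """Positions for a list of scalp channels (dict label -> (x, y))."""
    return {lab: channel_position(lab) for lab in labels}


def channel_distance(a: str, b: str) -> float:
    """Euclidean distance between two scalp channels in head-radius units."""
    return float(np.linalg.norm(channel_position(a) - channel_position(b)))


def distances_from(focus: str, labels=SCALP_CHANNELS) -> np.ndarray:
    """Distances of ``labels`` from a focus channel, in cap order given."""
    p0 = channel_position(focus)
    return np.array([np.linalg.norm(channel_position(l) - p0) for l in labels])
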