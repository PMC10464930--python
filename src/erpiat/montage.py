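"""Sensor montages: synthetic hemispheric layouts and sensor-position files.

A montage is the set of 3-D electrode positions (mm, head-centered) needed
for spatial component templates, neighbor graphs and interpolation. Real
studies load a whitespace-delimited ``label x y z`` file exported from the
acquisition software; synthetic studies use a deterministic Fibonacci
spiral on the upper hemisphere, which gives a roughly uniform sensor
density comparable to a geodesic net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_hemisphere_montage", "load_montage", "save_montage"]


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with 3-D positions in mm."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 3) mm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array of mm coordinates")
        if pos.shape[0] != len(self.labels):
            raise ValueError("labels and positions disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite sensor position")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def nearest_channel(self, xyz) -> str:
        """Label of the sensor closest to a target 3-D point (mm)."""
        d = np.linalg.norm(self.positions - np.asarray(xyz, float), axis=1)
        return self.labels[int(np.argmin(d))]

    def distances(self) -> np.ndarray:
        """Full pairwise Euclidean distance matrix (mm)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def make_hemisphere_montage(n_channels: int = 64, radius_mm: float = 90.0) -> Montage:
    """Deterministic quasi-uniform sensor layout on the upper hemisphere.

    Uses a Fibonacci spiral restricted to z >= 0 so sensors cover the scalp
    from vertex down to a low equatorial ring, emulating a high-density net.
    Labels follow the geodesic convention ``E1..E<n>``.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    k = np.arange(n_channels)
    # z descends from just below vertex to just above the equator
    z = 1.0 - (k + 0.5) / n_channels  # in (0, 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pos = radius_mm * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{i + 1}" for i in range(n_channels))
    return Montage(labels=labels, positions=pos)


def save_montage(montage: Montage, path) -> None:
    """Write a whitespace-delimited ``label x y z`` (mm) sensor file."""
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {x:.4f} {y:.4f} {z:.4f}\n")


def load_montage(path) -> Montage:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return Montage(labels=tuple(labels), positions=np.asarray(rows))
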