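"""Electrode montage: 60-channel 10-10 layout on the unit sphere.

The recording setup emulated here is a TMS-compatible 60-channel EEG cap.
Electrode positions are taken from the standard 10-10 template shipped with
MNE-Python, re-centred on their best-fitting sphere and projected radially
onto the unit sphere, so that all scalp geometry downstream (spherical-spline
interpolation, concentric-sphere forward modelling) can treat the head as
spherical.

Two electrodes, P2 and CP2, are flagged bad by default: in the emulated
experiment they are removed from the cap to make room for the tDCS cathode
over the right posterior parietal cortex, and are reconstructed by
interpolation after averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Montage",
    "CHANNELS_60",
    "DEFAULT_BAD_CHANNELS",
    "ANALYSIS_CLUSTERS",
    "build_montage",
    "cluster_map",
    "read_sfp",
    "write_sfp",
]

#: 10-10 subset used by the 60-channel TMS-compatible amplifier layout.
CHANNELS_60: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
)

#: Channels removed from the cap to place the tDCS cathode (right parietal).
DEFAULT_BAD_CHANNELS: frozenset[str] = frozenset({"P2", "CP2"})

#: Four 4-electrode analysis clusters: right parietal (under the tDCS
#: cathode), left parietal (TMS hotspot), left frontal, right frontal.
ANALYSIS_CLUSTERS: dict[str, frozenset[str]] = {
    "C1_right_parietal": frozenset({"CP2", "CP4", "P2", "P4"}),
    "C2_left_parietal": frozenset({"CP1", "CP3", "P1", "P3"}),
    "C3_left_frontal": frozenset({"F1", "F5", "FC1", "FC3"}),
    "C4_right_frontal": frozenset({"F2", "F6", "FC2", "FC6"}),
}


class MontageError(ValueError):
    """Raised for invalid montage configuration."""


@dataclass(frozen=True)
class Montage:
    """Named electrodes with unit-sphere positions.

    Parameters
    ----------
    channels
        Ordered electrode labels.
    positions
        ``(n_channels, 3)`` unit vectors; head coordinates are RAS-like
        (+x right, +y anterior, +z superior).
    bad_channels
        Subset of ``channels`` to be reconstructed by interpolation.
    """

    channels: tuple[str, ...]
    positions: np.ndarray
    bad_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channels), 3):
            raise MontageError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.channels)} channels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("electrode positions must lie on the unit sphere")
        if len(set(self.channels)) != len(self.channels):
            raise MontageError("channel labels must be unique")
        unknown = set(self.bad_channels) - set(self.channels)
        if unknown:
            raise MontageError(f"bad_channels not in montage: {sorted(unknown)}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise MontageError(f"unknown channel label {label!r}") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lab) for lab in labels], dtype=int)

    @property
    def good_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in self.bad_channels)


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Algebraic (Kasa) least-squares sphere fit; returns the centre."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _template_positions(labels) -> np.ndarray:
    """Standard 10-10 positions from MNE, projected to the unit sphere."""
    import mne

    for name in ("standard_1005", "colin27_1005"):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                mont = mne.channels.make_standard_montage(name)
            break
        except ValueError:  # pragma: no cover - montage renamed upstream
            continue
    ch_pos = mont.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in ch_pos]
    if missing:
        raise MontageError(f"labels absent from the 10-10 template: {missing}")
    pts = np.array([ch_pos[lab] for lab in labels], dtype=float)
    center = _fit_sphere_center(pts)
    unit = pts - center
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    return unit


def build_montage(
    channels=CHANNELS_60,
    bad_channels=DEFAULT_BAD_CHANNELS,
) -> Montage:
    """Build the standard 60-channel montage.

    Positions come from the built-in 10-10 template table; requesting a
    label absent from that table raises :class:`MontageError`.
    """
    channels = tuple(channels)
    return Montage(
        channels=channels,
        positions=_template_positions(channels),
        bad_channels=frozenset(bad_channels),
    )


def cluster_map(montage: Montage, clusters=None) -> dict[str, frozenset[str]]:
    """Validated name -> electrode-set map for the four analysis clusters.

    Clusters must be pairwise disjoint and fully contained in the montage.
    """
    clusters = dict(ANALYSIS_CLUSTERS if clusters is None else clusters)
    seen: set[str] = set()
    for name, labels in clusters.items():
        labels = frozenset(labels)
        missing = labels - set(montage.channels)
        if missing:
            raise MontageError(f"cluster {name} has unknown channels {sorted(missing)}")
        if labels & seen:
            raise MontageError(f"cluster {name} overlaps another cluster")
        seen |= labels
        clusters[name] = labels
    return clusters


def write_sfp(montage: Montage, path) -> None:
    """Write electrode positions as ``label x y z`` ASCII lines."""
    lines = [
        f"{lab}\t{p[0]:.10f}\t{p[1]:.10f}\t{p[2]:.10f}"
        for lab, p in zip(montage.channels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfp(path, bad_channels=()) -> Montage:
    """Read an ``.sfp``-style ASCII electrode file; positions are
    re-projected onto the unit sphere."""
    labels: list[str] = []
    pts: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MontageError(f"malformed sfp line: {line!r}")
        labels.append(parts[0])
        pts.append([float(v) for v in parts[1:]])
    pos = np.asarray(pts)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(labels), pos, frozenset(bad_channels))
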