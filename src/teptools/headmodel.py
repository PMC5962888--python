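"""Spherical head model, cortical source space, and anatomical parcels.

The head is modelled as three concentric shells (scalp, skull, brain) with
homogeneous conductivities; the cortex is a quasi-uniform point set on a
sphere a few millimetres below the inner-skull surface, with one normally
oriented dipole per point (a Fibonacci lattice stands in for a folded
cortical mesh).  Four angular-cap parcels play the role of left/right
Brodmann areas 7 (superior parietal) and 6 (premotor) in the local
source-space analyses.

All radii are in millimetres, conductivities in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereModel",
    "SourceSpace",
    "DEFAULT_RADII_MM",
    "DEFAULT_CONDUCTIVITIES",
    "DEFAULT_SOURCE_RADIUS_MM",
    "DEFAULT_PARCEL_CAPS",
    "build_sphere_model",
    "build_source_space",
    "define_parcels",
    "write_off",
]

#: Shell outer radii, outermost first: scalp, outer skull, inner skull (mm).
DEFAULT_RADII_MM: tuple[float, float, float] = (92.0, 85.0, 81.0)
#: Conductivities per shell, same order (S/m); the middle value is skull.
DEFAULT_CONDUCTIVITIES: tuple[float, float, float] = (0.33, 0.0042, 0.33)
#: Radius of the source shell.  Kept ~5 mm below the inner skull so the
#: 60-term forward series is converged to well under 1e-4.
DEFAULT_SOURCE_RADIUS_MM: float = 76.0

#: Parcel caps: unit direction of the cap centre and half-angle (degrees).
#: BA7 caps are posterior-superior, BA6 caps dorsal-anterior; left/right
#: pairs are exact x -> -x mirrors so parcel membership is mirror-symmetric.
DEFAULT_PARCEL_CAPS: dict[str, tuple[tuple[float, float, float], float]] = {
    "BA7_L": ((-0.45, -0.55, 0.70), 18.0),
    "BA7_R": ((0.45, -0.55, 0.70), 18.0),
    "BA6_L": ((-0.45, 0.45, 0.77), 18.0),
    "BA6_R": ((0.45, 0.45, 0.77), 18.0),
}


class HeadModelError(ValueError):
    """Raised for invalid head-model geometry or configuration."""


@dataclass(frozen=True)
class SphereModel:
    """Three concentric shells, stored outermost-first.

    ``radii[0]`` is the scalp (electrode) radius; ``radii[2]`` the inner
    skull, below which all sources must lie.
    """

    radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]

    def __post_init__(self) -> None:
        r = self.radii
        if not (r[0] > r[1] > r[2] > 0):
            raise HeadModelError(
                f"radii must be strictly decreasing outermost-first, got {r}"
            )
        if any(c <= 0 for c in self.conductivities):
            raise HeadModelError("conductivities must be positive")

    @property
    def scalp_radius(self) -> float:
        return self.radii[0]

    @property
    def inner_skull_radius(self) -> float:
        return self.radii[2]


def build_sphere_model(
    radii=DEFAULT_RADII_MM,
    conductivities=DEFAULT_CONDUCTIVITIES,
) -> SphereModel:
    """Validate and build the concentric-shell conduction model."""
    return SphereModel(tuple(float(r) for r in radii),
                       tuple(float(c) for c in conductivities))


@dataclass(frozen=True)
class SourceSpace:
    """Oriented dipole grid: positions (mm), unit normals, neighbour edges."""

    positions: np.ndarray
    normals: np.ndarray
    mesh_edges: np.ndarray  # (n_edges, 2) int, i < j
    radius: float

    @property
    def n_sources(self) -> int:
        return len(self.positions)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors by the golden-angle lattice."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _neighbor_edges(points: np.ndarray, k: int = 6) -> np.ndarray:
    """k-nearest-neighbour edge list (undirected, deduplicated)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    edges = set()
    for a, row in enumerate(idx):
        for b in row[1:]:
            edges.add((min(a, int(b)), max(a, int(b))))
    return np.array(sorted(edges), dtype=int)


def build_source_space(
    n_sources: int = 3004,
    radius: float = DEFAULT_SOURCE_RADIUS_MM,
    inner_skull_radius: float = DEFAULT_RADII_MM[2],
    normal_tilt_deg: float = 0.0,
    seed: int = 0,
) -> SourceSpace:
    """Build the cortical dipole grid.

    Dipoles sit on a Fibonacci lattice at ``radius`` (strictly inside the
    inner skull) and are radially oriented; ``normal_tilt_deg`` adds random
    angular jitter (std, degrees) to emulate folded-cortex orientations.
    """
    if radius >= inner_skull_radius:
        raise HeadModelError(
            f"source radius {radius} mm must be below the inner skull "
            f"({inner_skull_radius} mm)"
        )
    if n_sources < 4:
        raise HeadModelError("need at least 4 sources")
    unit = _fibonacci_sphere(n_sources)
    normals = unit.copy()
    if normal_tilt_deg > 0:
        rng = np.random.default_rng(seed)
        tilt = np.deg2rad(normal_tilt_deg) * rng.standard_normal((n_sources, 3))
        normals = normals + tilt
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SourceSpace(
        positions=radius * unit,
        normals=normals,
        mesh_edges=_neighbor_edges(radius * unit),
        radius=float(radius),
    )


def define_parcels(
    space: SourceSpace,
    caps=None,
) -> dict[str, np.ndarray]:
    """Assign source vertices to angular-cap parcels.

    A vertex belongs to a parcel when the angle between its direction and
    the cap centre is below the cap half-angle.  With the default caps the
    four parcels are pairwise disjoint; an empty parcel is a configuration
    error.
    """
    caps = DEFAULT_PARCEL_CAPS if caps is None else caps
    unit = space.positions / np.linalg.norm(space.positions, axis=1, keepdims=True)
    parcels: dict[str, np.ndarray] = {}
    claimed = np.full(space.n_sources, False)
    for name, (center, half_angle) in caps.items():
        c = np.asarray(center, dtype=float)
        c /= np.linalg.norm(c)
        members = np.nonzero(unit @ c > np.cos(np.deg2rad(half_angle)))[0]
        if members.size == 0:
            raise HeadModelError(f"parcel {name} is empty; widen its cap")
        if claimed[members].any():
            raise HeadModelError(f"parcel {name} overlaps an earlier parcel")
        claimed[members] = True
        parcels[name] = members
    return parcels


def write_off(space: SourceSpace, path) -> None:
    """Export the source grid as an ASCII OFF mesh (points + edge segments)."""
    lines = ["OFF", f"{space.n_sources} {len(space.mesh_edges)} 0"]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in space.positions]
    lines += [f"2 {a} {b}" for a, b in space.mesh_edges]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
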