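"""Analytic EEG forward model for concentric spherical shells.

The scalp potential of a current dipole inside a layered conducting sphere
has an exact expansion in Legendre polynomials.  For each harmonic degree
``n`` the radial profile in every shell is ``a r^n + b r^-(n+1)``; matching
potential and radial current density at the two internal interfaces and
imposing zero current through the scalp yields a small linear system whose
solution gives a per-degree surface gain ``g_n``.  The potential at an
electrode ``e`` (on the scalp sphere, radius R) due to a dipole with moment
``q`` at position ``p`` (radial distance b) is then

    V(e) = 1/(4 pi sigma_src R^2) * sum_n g_n (b/R)^(n-1)
           [ n (q . p_hat) P_n(c) + (q_tan . w) P_n'(c) ]

with ``c = p_hat . e_hat``, ``w = e_hat - c p_hat``, and ``q_tan`` the
tangential part of the moment.  With equal conductivities in all shells the
gains reduce to the homogeneous value ``(2n+1)/n`` and the series sums to
the classical closed form for a dipole in a bounded homogeneous sphere,
which the test suite uses as an independent oracle.

Units: positions in mm, conductivities in S/m, moments in nA*mm; the
returned potentials are then in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headmodel import SourceSpace, SphereModel
from .montage import Montage

__all__ = ["LeadField", "lead_field", "dipole_potentials", "shell_gains"]


class ForwardError(ValueError):
    """Raised when the forward computation is ill-posed."""


#: Sources closer to the inner skull than this fraction of its radius make
#: the default-length series unreliable.
_MAX_RELATIVE_SOURCE_RADIUS = 0.97


@dataclass(frozen=True)
class LeadField:
    """Average-referenced gain matrix, channels x sources (uV per nA*mm)."""

    matrix: np.ndarray
    montage: Montage
    source_space: SourceSpace
    sphere: SphereModel
    n_terms: int
    reference: str = "average"

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def shell_gains(sphere: SphereModel, n_terms: int) -> np.ndarray:
    """Per-degree surface gains ``g_n`` for degrees ``1..n_terms``.

    Computed in units of the scalp radius, innermost layer holding the
    source.  Entry 0 of the returned array is unused (degree 0 carries no
    dipole field).
    """
    R = sphere.scalp_radius
    # interfaces innermost-first, scaled to the scalp radius
    r1 = sphere.radii[2] / R
    r2 = sphere.radii[1] / R
    r3 = 1.0
    s3, s2, s1 = sphere.conductivities  # stored outermost-first
    g = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        # unknowns: a1, a2, b2, a3, b3; the source term r^-(n+1) in the
        # innermost layer has unit coefficient.
        A = np.array(
            [
                [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0],
                [
                    s1 * n * r1 ** (n - 1),
                    -s2 * n * r1 ** (n - 1),
                    s2 * (n + 1) * r1 ** -(n + 2),
                    0.0,
                    0.0,
                ],
                [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))],
                [
                    0.0,
                    s2 * n * r2 ** (n - 1),
                    -s2 * (n + 1) * r2 ** -(n + 2),
                    -s3 * n * r2 ** (n - 1),
                    s3 * (n + 1) * r2 ** -(n + 2),
                ],
                [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)],
            ]
        )
        rhs = np.array(
            [-(r1 ** -(n + 1)), s1 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0, 0.0]
        )
        # column equilibration keeps the system well-conditioned at high n
        scale = np.abs(A).max(axis=0)
        x = np.linalg.solve(A / scale, rhs) / scale
        g[n] = x[3] * r3**n + x[4] * r3 ** -(n + 1)
        if not np.isfinite(g[n]):
            raise ForwardError(f"shell gain diverged at degree {n}")
    return g


def dipole_potentials(
    sphere: SphereModel,
    electrodes: np.ndarray,
    src_positions: np.ndarray,
    src_orientations: np.ndarray,
    n_terms: int = 60,
) -> np.ndarray:
    """Raw (un-referenced) potentials, channels x sources, in uV per nA*mm.

    ``electrodes`` are unit vectors (scaled internally to the scalp radius);
    ``src_positions`` in mm must lie strictly inside the inner skull.
    """
    R = sphere.scalp_radius
    elec = np.asarray(electrodes, dtype=float)
    ehat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    pos = np.atleast_2d(np.asarray(src_positions, dtype=float))
    ori = np.atleast_2d(np.asarray(src_orientations, dtype=float))
    b = np.linalg.norm(pos, axis=1)
    limit = _MAX_RELATIVE_SOURCE_RADIUS * sphere.inner_skull_radius
    if (b >= limit).any():
        raise ForwardError(
            "source(s) too close to the inner skull for a convergent series; "
            f"keep radii below {limit:.1f} mm or deepen the source space"
        )
    if (b <= 0).any():
        raise ForwardError("sources at the head centre are not supported")
    phat = pos / b[:, None]
    c = ehat @ phat.T  # (C, S) cos(angle electrode-source)
    w = ehat[:, None, :] - c[..., None] * phat[None, :, :]
    qr = np.einsum("sj,sj->s", ori, phat)
    mtan = ori - qr[:, None] * phat
    mtw = np.einsum("sj,csj->cs", mtan, w)
    x = b / R

    g = shell_gains(sphere, n_terms)
    V = np.zeros_like(c)
    # Legendre P_n(c) and dP_n/dc by upward recurrence
    Pnm1 = np.ones_like(c)
    Pn = c.copy()
    dPnm1 = np.zeros_like(c)
    dPn = np.ones_like(c)
    xpow = np.ones_like(x)  # x^(n-1)
    for n in range(1, n_terms + 1):
        V += g[n] * xpow * (n * qr[None, :] * Pn + mtw * dPn)
        Pnp1 = ((2 * n + 1) * c * Pn - n * Pnm1) / (n + 1)
        dPnp1 = ((2 * n + 1) * (Pn + c * dPn) - n * dPnm1) / (n + 1)
        Pnm1, Pn = Pn, Pnp1
        dPnm1, dPn = dPn, dPnp1
        xpow = xpow * x
    sigma_src = sphere.conductivities[2]  # innermost shell holds the sources
    return V / (4.0 * np.pi * sigma_src * R**2)


def lead_field(
    sphere: SphereModel,
    montage: Montage,
    space: SourceSpace,
    n_terms: int = 60,
) -> LeadField:
    """Average-referenced lead field for all montage channels and sources."""
    raw = dipole_potentials(
        sphere, montage.positions, space.positions, space.normals, n_terms
    )
    ref = raw - raw.mean(axis=0, keepdims=True)
    return LeadField(
        matrix=ref, montage=montage, source_space=space, sphere=sphere,
        n_terms=n_terms,
    )
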