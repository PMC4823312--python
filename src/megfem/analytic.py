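"""Closed-form solutions for a dipole in a spherically symmetric conductor.

These serve as independent references for validating the numerical forward
solution:

* :func:`sarvas_field` -- the magnetic flux density outside any spherically
  symmetric conductor (center at the origin).  It depends only on the dipole
  and the geometry, not on the conductivity profile; a radial dipole is
  magnetically silent.
* :func:`sphere_surface_potential` -- the electric potential on the surface
  of a homogeneous conducting sphere, by spherical-harmonic expansion.

Units match the package conventions (mm, uAmm, fT, S/m, V).
"""

from __future__ import annotations

import numpy as np

from .fem import Dipole, FieldMap, _coil_points
from .phantom import SensorArray
from .units import MM_TO_M, MU0_OVER_4PI, T_TO_FT, UAMM_TO_AM


def sarvas_field(dipole: Dipole, points_mm: np.ndarray,
                 center_mm: np.ndarray | None = None) -> np.ndarray:
    """Flux density (T) outside a spherical conductor, closed form.

    ``points_mm`` is (k, 3) in mm; the conductor is centered at
    ``center_mm`` (default origin).  Returns (k, 3) in tesla.
    """
    center = np.zeros(3) if center_mm is None else np.asarray(center_mm)
    r = (np.atleast_2d(points_mm) - center) * MM_TO_M
    r0 = (dipole.pos - center) * MM_TO_M
    Q = dipole.mom * UAMM_TO_AM

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the dipole")
    F = a * (R * a + R ** 2 - r @ r0)
    a_dot_r = np.einsum("ki,ki->k", a_vec, r)
    gradF = ((a ** 2 / R + a_dot_r / a + 2.0 * a + 2.0 * R)[:, None] * r
             - (a + 2.0 * R + a_dot_r / a)[:, None] * r0)
    Qxr0 = np.cross(Q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * Qxr0 - (r @ Qxr0)[:, None] * gradF
    )
    return B


def sarvas_gradiometer_map(dipole: Dipole, array: SensorArray,
                           center_mm: np.ndarray | None = None) -> FieldMap:
    """Gradiometer map (fT) predicted by the spherical-conductor solution."""
    values = np.zeros(array.n_channels)
    for coil_set, sign in ((array.positions, 1.0),
                           (array.top_positions, -1.0)):
        pts_m = _coil_points(coil_set, array.axes, array.coil_radius)
        for q in range(pts_m.shape[1]):
            B = sarvas_field(dipole, pts_m[:, q] / MM_TO_M, center_mm)
            values += sign / pts_m.shape[1] * \
                np.einsum("mi,mi->m", B, array.axes)
    return FieldMap(values * T_TO_FT, meta={"component": "sarvas"})


def infinite_medium_potential(dipole: Dipole, points_mm: np.ndarray,
                              sigma: float) -> np.ndarray:
    """Potential (V) of a dipole in an unbounded homogeneous medium."""
    R = (np.atleast_2d(points_mm) - dipole.pos) * MM_TO_M
    dist = np.linalg.norm(R, axis=1)
    p = dipole.mom * UAMM_TO_AM
    return (R @ p) / (4.0 * np.pi * sigma * dist ** 3)


def sphere_potential(dipole: Dipole, points_mm: np.ndarray,
                     radius_mm: float, sigma: float,
                     n_terms: int = 80) -> np.ndarray:
    """Potential (V) in a homogeneous conducting sphere (Neumann boundary).

    Spherical-harmonic expansion about the origin, valid for field points
    with ``b < r <= R`` where ``b`` is the dipole's distance from the
    center.  With the dipole on the z axis, radial moment component q_r and
    tangential component q_t along x, the potential is

        V = 1/(4 pi sigma) sum_n b^(n-1) [ r^-(n+1)
              + (n+1)/n * r^n / R^(2n+1) ]
              [ n q_r P_n(cos gamma) - q_t P_n^1(cos gamma) cos phi ],

    where P_n^1 carries the Condon--Shortley phase; on the surface the
    radial bracket collapses to ``(2n+1)/n / R^(n+1)``.
    """
    from scipy.special import lpmv

    pos = dipole.pos
    b = float(np.linalg.norm(pos))
    R = float(radius_mm)
    if b >= R:
        raise ValueError("dipole must lie strictly inside the sphere")
    pts = np.atleast_2d(points_mm)

    # rotate so the dipole sits on the +z axis
    if b < 1e-12:
        ez = np.array([0.0, 0.0, 1.0])
    else:
        ez = pos / b
    mom = dipole.mom
    q_r = float(mom @ ez)
    t_vec = mom - q_r * ez
    q_t = float(np.linalg.norm(t_vec))
    ex = t_vec / q_t if q_t > 1e-15 else _any_perpendicular(ez)
    ey = np.cross(ez, ex)

    x = pts @ ex
    y = pts @ ey
    z = pts @ ez
    r = np.linalg.norm(pts, axis=1)
    cosg = np.clip(z / r, -1.0, 1.0)
    phi = np.arctan2(y, x)

    b_m = b * MM_TO_M
    R_m = R * MM_TO_M
    r_m = r * MM_TO_M
    q_r_si = q_r * UAMM_TO_AM
    q_t_si = q_t * UAMM_TO_AM

    V = np.zeros(len(pts))
    for n in range(1, n_terms + 1):
        # ratio form avoids overflow of the separate power terms
        radial = (b_m / r_m) ** (n - 1) / r_m ** 2 \
            + (n + 1) / n * (b_m / R_m) ** (n - 1) * (r_m / R_m) ** n / R_m ** 2
        Pn = lpmv(0, n, cosg)
        Pn1 = lpmv(1, n, cosg)       # includes Condon-Shortley phase
        V += radial * (
            n * q_r_si * Pn - q_t_si * Pn1 * np.cos(phi)
        )
    return V / (4.0 * np.pi * sigma)


def sphere_surface_potential(dipole: Dipole, points_mm: np.ndarray,
                             radius_mm: float, sigma: float,
                             n_terms: int = 80) -> np.ndarray:
    """Potential (V) on the surface of a homogeneous conducting sphere."""
    return sphere_potential(dipole, points_mm, radius_mm, sigma, n_terms)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)
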