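"""Analytic forward model: magnetic field of a current dipole in a sphere.

The closed-form solution for the field of a current dipole inside a
homogeneous spherical conductor (Sarvas, 1987) is used to build the
leadfield matrix. Two classical properties anchor the implementation:

* a purely radial dipole produces zero field everywhere outside the sphere;
* the radial field component outside the conductor equals the radial
  component of the free-space (primary) dipole field, because volume
  currents contribute nothing radially.
"""

from __future__ import annotations

import numpy as np

from .datatypes import HeadModel, Leadfield

MU0_OVER_4PI = 1e-7  # T*m/A


def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (tesla) at ``sensor_pos`` from a current dipole.

    Parameters
    ----------
    dipole_pos : (3,) array
        Dipole location in meters.
    dipole_moment : (3,) array
        Dipole moment Q in ampere-meters.
    sensor_pos : (n, 3) or (3,) array
        Field points, strictly outside the conducting sphere.
    center : (3,) array, optional
        Center of the spherical conductor (default origin).

    Returns
    -------
    (n, 3) or (3,) array of field vectors.
    """
    r = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    if center is not None:
        r = r - np.asarray(center, dtype=float)
        r0 = r0 - np.asarray(center, dtype=float)

    a_vec = r - r0  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a == 0):
        raise ValueError("field point coincides with the dipole location")
    rn = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)  # a . r

    f = a * (rn * a + ar)
    if np.any(f == 0):
        raise ValueError("degenerate geometry: Sarvas denominator vanished")
    # grad F = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0
    c1 = a**2 / rn + ar / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + ar / a
    grad_f = c1[:, None] * r - c2[:, None] * r0

    qxr0 = np.cross(q, r0)  # constant vector
    b = MU0_OVER_4PI / f[:, None] ** 2 * (f[:, None] * qxr0 - np.einsum("j,ij->i", qxr0, r)[:, None] * grad_f)
    return b[0] if np.asarray(sensor_pos).ndim == 1 else b


def compute_leadfield(head: HeadModel) -> Leadfield:
    """Build the leadfield matrix for unit tangential dipoles.

    Entry (i, j) is the projection onto sensor i's orientation of the field
    at sensor i produced by a unit dipole at source j with the head model's
    tangential orientation.
    """
    n_x, n_s = head.n_sensors, head.n_dipoles
    matrix = np.empty((n_x, n_s))
    for j in range(n_s):
        b = sarvas_field(
            head.dipole_positions[j],
            head.dipole_orientations[j],
            head.sensor_positions,
            center=head.sphere_center,
        )
        matrix[:, j] = np.einsum("ij,ij->i", b, head.sensor_orientations)
    return Leadfield(matrix)
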