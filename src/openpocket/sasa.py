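"""Solvent-accessible surface area by the Shrake-Rupley rolling-probe method.

Each atom is expanded by the probe radius and covered with a quasi-uniform
point lattice; points occluded by any neighbouring expanded sphere are
removed and the surviving fraction of the sphere area is the atom's SASA
contribution.  Point density is configurable; errors scale roughly as
1/sqrt(n_points).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (Fibonacci spiral), shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    # golden-angle spiral; offset 0.5 avoids poles
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 300,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2).

    Parameters
    ----------
    coords : (n, 3) atom centres, Angstrom.
    radii : (n,) van der Waals radii, Angstrom.
    probe_radius : solvent probe radius, Angstrom (water ~ 1.4).
    n_points : test points per atom sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match coords length")
    n = coords.shape[0]
    if n == 0:
        return np.zeros(0)
    ext = radii + probe_radius
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    for i in range(n):
        test = coords[i] + ext[i] * pts
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max())
                 if j != i and np.dot(coords[j] - coords[i], coords[j] - coords[i])
                 <= (ext[i] + ext[j]) ** 2]
        if neigh:
            d2 = np.sum(
                (test[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < ext[neigh][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas
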