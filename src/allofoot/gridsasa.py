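"""Independent solvent-accessible surface area by Gauss-Legendre quadrature.

This is a deliberately different numerical route from the golden-spiral
Shrake-Rupley implementation in :mod:`allofoot.interface`: the sphere of
each atom is integrated over latitude bands at Gauss-Legendre nodes in
cos(theta) with equally spaced longitudes, each sample carrying its
quadrature weight, instead of counting equal-weight lattice points. It
serves as the numerical cross-check for the production SASA code and as
the source of buried-area ground truth for synthetic complexes.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss


def grid_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_lat: int = 40,
    n_lon: int = 64,
) -> np.ndarray:
    """Per-atom SASA (A^2) by spherical quadrature.

    Parameters
    ----------
    coords : (N, 3) atom centres in Angstrom.
    radii : (N,) van der Waals radii in Angstrom.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    areas = np.zeros(n)
    nodes, weights = leggauss(n_lat)              # cos(theta) in [-1, 1]
    phi = 2.0 * np.pi * (np.arange(n_lon) + 0.5) / n_lon
    sin_t = np.sqrt(1.0 - nodes**2)
    # unit sphere sample points, (n_lat * n_lon, 3), with matching weights
    pts = np.stack(
        [
            np.outer(sin_t, np.cos(phi)).ravel(),
            np.outer(sin_t, np.sin(phi)).ravel(),
            np.repeat(nodes, n_lon),
        ],
        axis=1,
    )
    w = np.repeat(weights, n_lon) * (2.0 * np.pi / n_lon)

    expanded = radii + probe_radius
    for i in range(n):
        ri = expanded[i]
        sample = coords[i] + ri * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in range(n):
            if j == i:
                continue
            rj = expanded[j]
            if np.linalg.norm(coords[j] - coords[i]) >= ri + rj:
                continue
            d2 = np.einsum("ij,ij->i", sample - coords[j], sample - coords[j])
            accessible &= d2 >= rj * rj
        areas[i] = ri * ri * float(np.sum(w[accessible]))
    return areas
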