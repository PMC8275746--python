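"""Real spherical harmonics and quadrature helpers.

Magnitude SDE signals are antipodally symmetric, so all signal
representations in this package use the real, even-order spherical
harmonic basis.  Conventions:

* ``Y_0^0 = 1/sqrt(4*pi)``; the basis is orthonormal on the sphere.
* Directions are given as unit 3-vectors (rows of an ``(n, 3)`` array);
  polar angle ``theta = arccos(z)``, azimuth ``phi = atan2(y, x)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "cart_to_sph",
    "real_sph_harm",
    "real_sh_basis",
    "even_sh_index_list",
    "n_even_coeffs",
    "sphere_quadrature",
]


def cart_to_sph(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (theta, phi) polar/azimuthal angles for unit vectors."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    z = np.clip(directions[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    return theta, phi


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonic of degree ``l``, order ``m``.

    Uses the standard mapping of the complex harmonics: ``m > 0`` maps to
    ``sqrt(2) * (-1)^m * Re Y_l^m``, ``m < 0`` to ``sqrt(2) * (-1)^m *
    Im Y_l^|m|`` and ``m = 0`` stays real.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def even_sh_index_list(l_max: int) -> list[tuple[int, int]]:
    """(l, m) pairs for all even degrees 0..l_max, m = -l..l."""
    if l_max % 2 != 0:
        raise ValueError(f"l_max must be even, got {l_max}")
    return [(l, m) for l in range(0, l_max + 1, 2) for m in range(-l, l + 1)]


def n_even_coeffs(l_max: int) -> int:
    """Number of even-degree coefficients up to ``l_max``: (L/2+1)(L+1)."""
    return (l_max // 2 + 1) * (l_max + 1)


def real_sh_basis(directions: np.ndarray, l_max: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Design matrix of even real spherical harmonics at ``directions``.

    Returns ``(Y, index_list)`` with ``Y[i, a] = Y_{l_a}^{m_a}(u_i)``.
    """
    theta, phi = cart_to_sph(directions)
    idx = even_sh_index_list(l_max)
    cols = [real_sph_harm(l, m, theta, phi) for (l, m) in idx]
    return np.column_stack(cols), idx


def sphere_quadrature(degree: int = 47) -> tuple[np.ndarray, np.ndarray]:
    """Product Gauss-Legendre x uniform-azimuth quadrature on the sphere.

    Exact for spherical polynomials up to ``degree``.  Returns
    ``(points, weights)`` with the weights summing to ``4*pi`` so that
    ``weights @ f(points)`` approximates the sphere integral of ``f``.
    """
    n_polar = degree // 2 + 1
    n_az = degree + 1
    x, wx = np.polynomial.legendre.leggauss(n_polar)  # x = cos(theta)
    phi = 2.0 * np.pi * np.arange(n_az) / n_az
    sin_theta = np.sqrt(1.0 - x**2)
    pts = np.empty((n_polar * n_az, 3))
    pts[:, 0] = np.outer(sin_theta, np.cos(phi)).ravel()
    pts[:, 1] = np.outer(sin_theta, np.sin(phi)).ravel()
    pts[:, 2] = np.repeat(x, n_az)
    w = np.repeat(wx, n_az) * (2.0 * np.pi / n_az)
    return pts, w
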