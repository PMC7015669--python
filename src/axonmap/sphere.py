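"""Sphere sampling, real spherical-harmonic bases and Watson quadrature."""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (Fibonacci lattice).

    Deterministic; rows are unit-norm (n, 3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def n_even_sh_coeffs(lmax: int) -> int:
    """Number of real SH coefficients with even l <= lmax (28 at lmax=6)."""
    return (lmax // 2 * 2 + 1) * (lmax // 2 + 1)


def even_sh_basis(directions: np.ndarray, lmax: int = 6) -> np.ndarray:
    """Design matrix of the real, orthonormal, even-order SH basis.

    Rows are directions, columns run over (l, m) with even l = 0, 2, ..,
    lmax and m = -l .. l; column 0 is Y00 = 1/sqrt(4 pi). The basis is
    antipodally symmetric, so odd-order signal content projects to zero.
    """
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a non-negative even integer")
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("directions must be unit vectors (tolerance 1e-3)")
    x, y, z = directions.T
    theta = np.arccos(np.clip(z / norms, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(ylm.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.imag)
    return np.column_stack(cols)


def sphere_average_from_sh(coeffs: np.ndarray) -> float:
    """Mean over the sphere implied by SH coefficients: c00 / sqrt(4 pi)."""
    return float(coeffs[0] / np.sqrt(4.0 * np.pi))


def watson_quadrature(
    mu: np.ndarray, kappa: float, n_nodes: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quadrature of a Watson fiber-orientation distribution.

    Nodes are a Fibonacci lattice, weights proportional to
    exp(kappa (n . mu)^2), normalized to sum 1. ``kappa = inf`` collapses to
    a single node along ``mu``; ``kappa = 0`` is the uniform distribution.
    Antipodal pairs carry equal weight since the density is even in n.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if np.isinf(kappa):
        return mu[None, :], np.array([1.0])
    if kappa < 0:
        raise ValueError("only bipolar Watson distributions (kappa >= 0) supported")
    nodes = fibonacci_directions(n_nodes)
    c2 = (nodes @ mu) ** 2
    logw = kappa * (c2 - 1.0)  # subtract max for stability
    w = np.exp(logw)
    return nodes, w / w.sum()
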