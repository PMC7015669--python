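"""Powder-averaged forward signal models.

These are the building blocks of both the fitted decay models and the
synthetic phantom: the orientationally averaged stick signal with its
b^{-1/2} tail, the truncated power law of a finite-radius axon, the
large-b expansion of the two-compartment exchange (Karger) model, the
volume-weighted cylinder-ensemble signal of a radius distribution, and the
full multi-compartment per-direction voxel signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .cylinder import vangelderen_lnS
from .sphere import watson_quadrature


@dataclass(frozen=True)
class IntraAxonalParams:
    """Intra-axonal compartment: T2-weighted signal fraction ``f``,
    parallel/radial diffusivities [um^2/ms] and the immobile ("dot")
    fraction ``f_im``."""

    f: float
    Da_par: float
    Da_perp: float = 0.0
    f_im: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0 and 0.0 <= self.f_im <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f + self.f_im > 1.0 + 1e-12:
            raise ValueError("f + f_im must be <= 1")
        if self.Da_par <= 0:
            raise ValueError("Da_par must be > 0")


def stick_powder_mean(f: float, Da_par: float, b) -> np.ndarray | float:
    """Spherical mean of the stick (zero-radius cylinder) signal.

    S(b) = f sqrt(pi / (4 b Da_par)) erf(sqrt(b Da_par)) for b > 0 and
    S(0) = f (continuous limit). The large-b asymptote is
    beta b^{-1/2} with beta = sqrt(pi/4) f / sqrt(Da_par).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    x = b * Da_par
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, f * np.sqrt(np.pi / (4.0 * np.where(x > 0, x, 1.0))) * erf(np.sqrt(x)), f)
    return out if out.ndim else float(out)


def stick_beta(f: float, Da_par: float) -> float:
    """Power-law coefficient beta = sqrt(pi/4) f / sqrt(Da_par)."""
    return float(np.sqrt(np.pi / 4.0) * f / np.sqrt(Da_par))


def truncated_powerlaw(beta: float, Da_perp: float, f_im: float, b):
    """Truncated power law S(b) = beta exp(-b Da_perp) b^{-1/2} + f_im."""
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("b must be > 0")
    out = beta * np.exp(-b * Da_perp) * b ** -0.5 + f_im
    return out if out.ndim else float(out)


def exchange_expansion(beta: float, c: float, f_im: float, b):
    """Large-b Karger expansion S(b) = beta (b^{-1/2} + c b^{-3/2}) + f_im.

    ``c`` is proportional to (exchange rate) * TE / De_perp and is treated
    as the primitive parameter; c >= 0. Convex in xi = b^{-1/2}.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("b must be > 0")
    out = beta * (b ** -0.5 + c * b ** -1.5) + f_im
    return out if out.ndim else float(out)


def distribution_radial_attenuation(radii, weights, D0: float, g: float,
                                    delta: float, Delta: float, M: int = 20) -> float:
    """Volume-weighted radial attenuation of a cylinder ensemble.

    S_perp = sum_i h_i r_i^2 Sc_perp(r_i) / sum_i h_i r_i^2, with Sc_perp
    from the van Gelderen series. Zero-radius bins carry zero volume weight
    and drop out.
    """
    radii = np.asarray(radii, dtype=float)
    weights = np.asarray(weights, dtype=float)
    vol = weights * radii ** 2
    denom = vol.sum()
    if denom <= 0:
        raise ValueError("distribution must contain positive-radius weight")
    sc = np.array([np.exp(vangelderen_lnS(r, D0, g, delta, Delta, M)) for r in radii])
    return float((vol * sc).sum() / denom)


def distribution_powder_signal(h, f: float, Da_par: float, D0: float,
                               protocol, b: float, M: int = 20) -> float:
    """Spherical-mean signal of a dispersed cylinder ensemble at shell ``b``.

    The kernel factorizes into the axial stick average and the radial
    ensemble attenuation: S(b) = stick_powder_mean(f, Da_par, b) * S_perp.
    ``h`` is a RadiusDistribution or any object with ``bin_centers`` and
    ``counts`` attributes, or a (radii, weights) tuple.
    """
    if hasattr(h, "bin_centers"):
        radii, weights = h.bin_centers, h.counts
    else:
        radii, weights = h
    g = protocol.shell_gradient(b)
    s_perp = distribution_radial_attenuation(
        radii, weights, D0, g, protocol.delta, protocol.Delta, M
    )
    return float(stick_powder_mean(f, Da_par, b)) * s_perp


@dataclass(frozen=True)
class VoxelParams:
    """Full voxel composition for the phantom forward model."""

    intra: IntraAxonalParams
    f_extra: float = 0.0
    De_par: float = 0.0
    De_perp: float = 0.0
    watson_kappa: float = np.inf
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        total = self.intra.f + self.intra.f_im + self.f_extra
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signal fractions must sum to 1, got {total}")
        if self.f_extra < 0:
            raise ValueError("f_extra must be >= 0")


def composite_voxel_signal(params: VoxelParams, b, directions,
                           n_odf_nodes: int = 300) -> np.ndarray:
    """Per-direction voxel signal at weighting ``b`` for measurement
    ``directions`` (N, 3): Watson-dispersed intra- plus extra-axonal
    axially symmetric compartments and an isotropic immobile fraction.

    S(b, u) = sum_k w_k [ f  e^{-b Da_perp} e^{-b (Da_par - Da_perp)(u.n_k)^2}
                        + fe e^{-b De_perp} e^{-b (De_par - De_perp)(u.n_k)^2} ]
              + f_im
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    nodes, w = watson_quadrature(np.asarray(params.axis), params.watson_kappa,
                                 n_odf_nodes)
    c2 = (directions @ nodes.T) ** 2  # (N, K)
    ia = params.intra
    intra = ia.f * np.exp(-b * ia.Da_perp) * np.exp(-b * (ia.Da_par - ia.Da_perp) * c2)
    sig = intra @ w
    if params.f_extra > 0:
        extra = params.f_extra * np.exp(-b * params.De_perp) * np.exp(
            -b * (params.De_par - params.De_perp) * c2
        )
        sig = sig + extra @ w
    return sig + ia.f_im
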