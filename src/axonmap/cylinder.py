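"""Radial diffusion attenuation inside an impermeable cylinder.

The signal of water restricted in a cylinder of radius r, with gradient
applied perpendicular to its axis, is treated in the Gaussian phase
approximation: the full van Gelderen series over Bessel-derivative roots,
its long-pulse (Neuman) limit ln S = -(7/48) g^2 delta r^4 / D0, and the
bidirectional maps between the apparent radial diffusivity Da_perp and the
cylinder radius that the long-pulse limit implies.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import jnp_zeros


class ConvergenceWarning(UserWarning):
    pass


def bessel_prime_roots(M: int) -> np.ndarray:
    """First ``M`` ascending positive roots of dJ1(a)/da = 0."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return jnp_zeros(1, M)


def correlation_time(r: float, D0: float) -> float:
    """Radial diffusion correlation time t_c = r^2 / D0 [ms]."""
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    return r * r / D0


def vangelderen_lnS(
    r: float,
    D0: float,
    g: float,
    delta: float,
    Delta: float,
    M: int = 20,
    *,
    check_convergence: bool = True,
) -> float:
    """ln of the perpendicular cylinder signal, Gaussian phase approximation.

    ln S = -(2 g^2 r^4 / D0) * sum_m  t_c / (a_m^6 (a_m^2 - 1)) *
           [ 2 a_m^2 d/t_c - 2 + 2 e^{-a_m^2 d/t_c} + 2 e^{-a_m^2 D/t_c}
             - e^{-a_m^2 (D-d)/t_c} - e^{-a_m^2 (D+d)/t_c} ]

    with d = delta, D = Delta, t_c = r^2/D0 and a_m the roots of J1'(a)=0.
    The stick limit r = 0 (t_c = 0) returns 0 exactly.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if delta <= 0 or Delta < delta:
        raise ValueError("require delta > 0 and Delta >= delta")
    if M < 1:
        raise ValueError("M must be >= 1")
    if r == 0 or g == 0:
        return 0.0
    tc = correlation_time(r, D0)
    a2 = bessel_prime_roots(M) ** 2
    terms = (tc / (a2 ** 3 * (a2 - 1))) * (
        2.0 * a2 * delta / tc
        - 2.0
        + 2.0 * np.exp(-a2 * delta / tc)
        + 2.0 * np.exp(-a2 * Delta / tc)
        - np.exp(-a2 * (Delta - delta) / tc)
        - np.exp(-a2 * (Delta + delta) / tc)
    )
    total = terms.sum()
    if check_convergence and abs(terms[-1] / total) > 1e-9:
        warnings.warn(
            f"van Gelderen series not converged at M={M}: "
            f"|last term / sum| = {abs(terms[-1] / total):.2e}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return float(-(2.0 * g * g * r ** 4 / D0) * total)


def neuman_lnS(r: float, D0: float, g: float, delta: float) -> float:
    """Long-pulse limit ln S = -kappa r^4, kappa = (7/48) g^2 delta / D0.

    Valid for delta >> t_c = r^2/D0; a warning is emitted when
    delta < 5 t_c and the limit is therefore questionable.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if r == 0:
        return 0.0
    tc = correlation_time(r, D0)
    if delta < 5.0 * tc:
        warnings.warn(
            f"Neuman limit questionable: delta = {delta} ms < 5 t_c = {5 * tc:.3g} ms",
            UserWarning,
            stacklevel=2,
        )
    kappa = (7.0 / 48.0) * g * g * delta / D0
    return float(-kappa * r ** 4)


def daperp_from_radius(r, D0: float, delta: float, Delta: float):
    """Apparent radial diffusivity of a cylinder in the long-pulse limit.

    Da_perp = 7 r^4 / (48 D0 delta (Delta - delta/3)); independent of the
    gradient amplitude because b = g^2 delta^2 (Delta - delta/3) cancels.
    Accepts scalars or arrays.
    """
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    if delta <= 0 or Delta < delta:
        raise ValueError("require delta > 0 and Delta >= delta")
    r = np.asarray(r, dtype=float)
    out = 7.0 * r ** 4 / (48.0 * D0 * delta * (Delta - delta / 3.0))
    return out if out.ndim else float(out)


def radius_from_daperp(Da_perp, D0, delta: float, Delta: float):
    """Effective MR radius from a fitted radial diffusivity (inverse map).

    r_MR = (48/7 * delta (Delta - delta/3) * D0 * Da_perp)^(1/4).

    Negative Da_perp values are biophysically implausible but are a routine
    fit outcome near the detection floor; they propagate as NaN rather than
    raising, so that implausible-voxel fractions can be reported. Accepts
    scalars or arrays (``D0`` may be a matching array).
    """
    if delta <= 0 or Delta < delta:
        raise ValueError("require delta > 0 and Delta >= delta")
    Da_perp = np.asarray(Da_perp, dtype=float)
    D0 = np.asarray(D0, dtype=float)
    if np.any(D0 <= 0):
        raise ValueError("D0 must be > 0")
    arg = (48.0 / 7.0) * delta * (Delta - delta / 3.0) * D0 * Da_perp
    with np.errstate(invalid="ignore"):
        out = np.where(arg >= 0, np.abs(arg) ** 0.25, np.nan)
    return out if out.ndim else float(out)
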