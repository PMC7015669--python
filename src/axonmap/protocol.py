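"""Acquisition protocols, unit conventions and gradient/b-value arithmetic.

Canonical units throughout the package: time in ms, length in um, b-values in
ms/um^2, diffusivities in um^2/ms, gradient amplitudes in mT/m. The Larmor
gradient g = gamma_H * G is expressed in rad ms^-1 um^-1 so that
b = g^2 delta^2 (Delta - delta/3) comes out directly in ms/um^2.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

#: Proton gyromagnetic ratio in rad ms^-1 um^-1 per (mT/m).
GAMMA_H = 2.6752219e-4


def larmor_gradient(G: float) -> float:
    """Larmor-frequency gradient g [rad/ms/um] for amplitude ``G`` [mT/m]."""
    G = float(G)
    if G < 0:
        raise ValueError(f"gradient amplitude must be >= 0, got {G}")
    return GAMMA_H * G


def b_value(g: float, delta: float, Delta: float) -> float:
    """Diffusion weighting b = g^2 delta^2 (Delta - delta/3) [ms/um^2]."""
    _check_timings(delta, Delta)
    return g ** 2 * delta ** 2 * (Delta - delta / 3.0)


def gradient_for_b(b: float, delta: float, Delta: float) -> float:
    """Unique non-negative Larmor gradient g producing weighting ``b``."""
    _check_timings(delta, Delta)
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    return math.sqrt(b / (delta ** 2 * (Delta - delta / 3.0)))


def _check_timings(delta: float, Delta: float) -> None:
    if delta <= 0:
        raise ValueError(f"gradient duration delta must be > 0, got {delta}")
    if Delta < delta:
        raise ValueError(
            f"pulse separation Delta ({Delta}) must be >= duration delta ({delta})"
        )


@dataclass(frozen=True)
class Shell:
    """One b-shell: weighting ``b`` [ms/um^2] and its direction count.

    ``G`` [mT/m] is optional; when present it must be consistent with ``b``
    through the protocol timings (checked by :class:`AcquisitionProtocol`).
    """

    b: float
    n_dirs: int
    G: float | None = None

    def __post_init__(self):
        if self.b < 0:
            raise ValueError(f"shell b must be >= 0, got {self.b}")
        if self.n_dirs < 1:
            raise ValueError(f"n_dirs must be >= 1, got {self.n_dirs}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Pulsed-gradient spin-echo protocol: timings plus a list of b-shells.

    Parameters
    ----------
    delta, Delta : float
        Gradient pulse duration and separation [ms]; ``Delta >= delta > 0``.
    shells : tuple of Shell
        Sorted ascending in b.
    TE : float, optional
        Echo time [ms].
    snr_b0 : float, optional
        Scalar SNR of the non-diffusion-weighted image; may be omitted when a
        noise map is supplied downstream.
    """

    delta: float
    Delta: float
    shells: tuple[Shell, ...]
    TE: float | None = None
    snr_b0: float | None = None

    def __post_init__(self):
        _check_timings(self.delta, self.Delta)
        shells = tuple(self.shells)
        object.__setattr__(self, "shells", shells)
        bs = [s.b for s in shells]
        if any(b2 < b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("shells must be sorted ascending in b")
        for s in shells:
            if s.G is not None:
                b_implied = b_value(larmor_gradient(s.G), self.delta, self.Delta)
                if not math.isclose(b_implied, s.b, rel_tol=1e-6):
                    raise ValueError(
                        f"shell b={s.b} inconsistent with G={s.G} mT/m "
                        f"(implies b={b_implied:.6g})"
                    )

    @property
    def b_values(self) -> np.ndarray:
        return np.array([s.b for s in self.shells], dtype=float)

    @property
    def n_dirs(self) -> np.ndarray:
        return np.array([s.n_dirs for s in self.shells], dtype=int)

    def shell_gradient(self, b: float) -> float:
        """Larmor gradient g [rad/ms/um] for a shell of weighting ``b``."""
        return gradient_for_b(b, self.delta, self.Delta)

    def dwi_shells(self) -> tuple[Shell, ...]:
        """Shells with b > 0."""
        return tuple(s for s in self.shells if s.b > 0)

    # ----------------------------------------------------------------- YAML
    def to_yaml(self, path) -> None:
        payload = {
            "delta": self.delta,
            "Delta": self.Delta,
            "TE": self.TE,
            "snr_b0": self.snr_b0,
            "shells": [dataclasses.asdict(s) for s in self.shells],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        shells = tuple(Shell(**s) for s in payload.pop("shells"))
        return cls(shells=shells, **payload)

    @classmethod
    def from_bval_bvec(
        cls,
        bval_path,
        bvec_path=None,
        *,
        delta: float,
        Delta: float,
        TE: float | None = None,
        snr_b0: float | None = None,
        cluster_tol: float = 50.0,
    ) -> "AcquisitionProtocol":
        """Build a protocol from FSL-style bval/bvec text files.

        b-values are read in s/mm^2 and converted to ms/um^2 (divide by 1000);
        volumes whose b differ by less than ``cluster_tol`` [s/mm^2] are
        clustered onto one shell at their mean b.
        """
        bvals = read_bvals(bval_path)
        if bvec_path is not None:
            bvecs = read_bvecs(bvec_path)
            if bvecs.shape[1] != bvals.size:
                raise ValueError(
                    f"bvec column count {bvecs.shape[1]} != bval count {bvals.size}"
                )
        centers, labels = cluster_shells(bvals, cluster_tol)
        shells = tuple(
            Shell(b=c / 1000.0, n_dirs=int(np.sum(labels == i)))
            for i, c in enumerate(centers)
        )
        return cls(delta=delta, Delta=Delta, shells=shells, TE=TE, snr_b0=snr_b0)


def read_bvals(path) -> np.ndarray:
    """Read a whitespace-separated FSL bval file [s/mm^2], 1 x N."""
    return np.loadtxt(path, ndmin=1).ravel()


def read_bvecs(path) -> np.ndarray:
    """Read an FSL bvec file as a 3 x N array (vectors in image frame)."""
    vecs = np.loadtxt(path, ndmin=2)
    if vecs.shape[0] != 3:
        if vecs.shape[1] == 3:
            vecs = vecs.T
        else:
            raise ValueError(f"bvec file must be 3 x N, got shape {vecs.shape}")
    return vecs


def cluster_shells(bvals: np.ndarray, tol: float = 50.0):
    """Greedy 1D clustering of b-values [s/mm^2] within ``tol``.

    Returns (ascending cluster centers, per-volume cluster labels).
    """
    order = np.argsort(bvals)
    centers: list[float] = []
    members: list[list[int]] = []
    for idx in order:
        b = bvals[idx]
        if centers and abs(b - centers[-1]) <= tol:
            members[-1].append(idx)
            centers[-1] = float(np.mean(bvals[members[-1]]))
        else:
            centers.append(float(b))
            members.append([idx])
    labels = np.empty(bvals.size, dtype=int)
    for i, m in enumerate(members):
        labels[m] = i
    return np.array(centers), labels


# --------------------------------------------------------------- presets
_CONNECTOM_B = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 12.1, 13.5, 15.0, 16.9, 19.1, 21.7, 25.0)


def preset(name: str, aeon_b_values: Sequence[float] | None = None) -> AcquisitionProtocol:
    """Return one of the two built-in scanner protocols.

    ``"connectom"``: human 3T Connectom session — delta/Delta = 13/30 ms,
    60 directions on each of 13 shells (b = 1 ... 25 ms/um^2), SNR 52 at b=0,
    TE 62 ms.

    ``"aeon"``: ex vivo 16.4T Bruker Aeon session — delta/Delta = 7.1/20 ms,
    60 directions on each of 18 shells up to b = 100 ms/um^2, SNR 195, TE
    30.4 ms. The individual shell positions of the densely sampled spectrum
    are not published; the default is uniform spacing from 2.5 to 100
    ms/um^2 and can be overridden with ``aeon_b_values``.
    """
    key = name.lower()
    if key == "connectom":
        shells = tuple(Shell(b=b, n_dirs=60) for b in _CONNECTOM_B)
        return AcquisitionProtocol(delta=13.0, Delta=30.0, shells=shells, TE=62.0, snr_b0=52.0)
    if key == "aeon":
        bvals = (
            tuple(float(b) for b in aeon_b_values)
            if aeon_b_values is not None
            else tuple(np.linspace(2.5, 100.0, 18))
        )
        shells = tuple(Shell(b=b, n_dirs=60) for b in bvals)
        return AcquisitionProtocol(delta=7.1, Delta=20.0, shells=shells, TE=30.4, snr_b0=195.0)
    raise KeyError(f"unknown protocol preset {name!r}; available: 'connectom', 'aeon'")
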