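"""High-b decay model fitting, AICc ranking and tangent-intercept analysis.

Eight candidate forms describe the normalized spherical-mean decay S(b) at
high b; four include a free intercept and four force it to zero:

    i     f_im + beta b^-alpha
    ii    f_im + beta b^-1/2
    iii   f_im + beta exp(-b Da_perp) b^-1/2
    iv    f_im + beta (b^-1/2 + c b^-3/2)
    v     beta b^-alpha
    vi    beta b^-1/2
    vii   beta exp(-b Da_perp) b^-1/2          (truncated power law)
    viii  beta (b^-1/2 + c b^-3/2)             (exchange expansion)

The fitting surface follows the Model/Results idiom: ``DecayModel`` holds
the data and configuration, ``fit()`` returns a ``DecayFitResult`` with
estimates, Gaussian standard errors, AICc and plausibility flags, and
``compare_models`` ranks several candidates on one decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .powder import SphericalMeanDecay

#: model_id -> (parameter names, has free intercept)
MODEL_PARAMS: dict[str, tuple[tuple[str, ...], bool]] = {
    "i": (("f_im", "beta", "alpha"), True),
    "ii": (("f_im", "beta"), True),
    "iii": (("f_im", "beta", "Da_perp"), True),
    "iv": (("f_im", "beta", "c"), True),
    "v": (("beta", "alpha"), False),
    "vi": (("beta",), False),
    "vii": (("beta", "Da_perp"), False),
    "viii": (("beta", "c"), False),
}

MODEL_IDS = tuple(MODEL_PARAMS)


def model_predict(model_id: str, params: dict[str, float], b: np.ndarray) -> np.ndarray:
    """Evaluate candidate model ``model_id`` at b-values ``b``."""
    b = np.asarray(b, dtype=float)
    p = params
    fim = p.get("f_im", 0.0)
    if model_id in ("i", "v"):
        return fim + p["beta"] * b ** -p["alpha"]
    if model_id in ("ii", "vi"):
        return fim + p["beta"] * b ** -0.5
    if model_id in ("iii", "vii"):
        return fim + p["beta"] * np.exp(-b * p["Da_perp"]) * b ** -0.5
    if model_id in ("iv", "viii"):
        return fim + p["beta"] * (b ** -0.5 + p["c"] * b ** -1.5)
    raise KeyError(f"unknown model id {model_id!r}")


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion, Gaussian LS convention.

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1); requires n > k + 1. An rss
    of exactly zero is floored at machine epsilon with a warning so the
    logarithm stays finite.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    eps = np.finfo(float).eps
    if rss < eps:
        warnings.warn("rss below machine epsilon; floored for AICc", UserWarning,
                      stacklevel=2)
        rss = eps
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class DecayFitResult:
    """One candidate model fitted to one spherical-mean decay."""

    model_id: str
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    n_points: int
    aicc: float
    converged: bool
    plausible: bool

    @property
    def gamma(self) -> float | None:
        """Extrapolated 1/sqrt(b) -> 0 intercept, when the model has one."""
        return self.params.get("f_im")

    def predict(self, b) -> np.ndarray:
        return model_predict(self.model_id, self.params, b)

    def summary(self) -> str:
        lines = [
            f"Decay model ({self.model_id})  n={self.n_points}  "
            f"rss={self.rss:.4e}  AICc={self.aicc:.3f}",
            f"converged={self.converged}  plausible={self.plausible}",
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name in self.params:
            lines.append(f"{name:>8} {self.params[name]:>12.6g} "
                         f"{self.bse.get(name, float('nan')):>12.3g}")
        return "\n".join(lines)


class DecayModel:
    """Candidate high-b decay model bound to one spherical-mean decay.

    Parameters
    ----------
    decay : SphericalMeanDecay
        Normalized decay; shells with b < ``b_min`` are excluded from the
        fit (b > 6 ms/um^2 in vivo, b >= 20 ex vivo).
    model_id : str
        One of ``MODEL_IDS``.
    b_min : float
        Lower b bound of the fit range.
    constrain_intercept : bool
        When True, the intercept parameter is constrained to f_im >= 0;
        by default it is free (reported as gamma, may be negative).
    """

    def __init__(self, decay: SphericalMeanDecay, model_id: str = "vii",
                 b_min: float = 6.0, constrain_intercept: bool = False):
        if model_id not in MODEL_PARAMS:
            raise KeyError(f"unknown model id {model_id!r}")
        self.model_id = model_id
        self.b_min = float(b_min)
        self.constrain_intercept = constrain_intercept
        sub = decay.restrict(b_min)
        self.b = sub.b_values
        self.y = sub.S_bar
        names, _ = MODEL_PARAMS[model_id]
        self.param_names = names
        if self.b.size < len(names) + 2:
            raise ValueError(
                f"model ({model_id}) needs >= {len(names) + 2} shells with "
                f"b >= {b_min}; got {self.b.size}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model_id: str = "vii",
                       b_min: float = 6.0, **kw) -> "DecayModel":
        """Build from a DataFrame with columns ``b`` and ``S_bar``."""
        decay = SphericalMeanDecay(
            b_values=df["b"].to_numpy(), S_bar=df["S_bar"].to_numpy(),
            sigma=df["sigma_eff"].to_numpy() if "sigma_eff" in df else 0.0,
        )
        return cls(decay, model_id=model_id, b_min=b_min, **kw)

    # ------------------------------------------------------------- starts
    def _starts(self) -> list[np.ndarray]:
        """Deterministic multi-start grid over the model's parameters."""
        beta0 = float(np.median(self.y * np.sqrt(self.b)))
        beta_grid = [beta0, 0.5 * beta0, 2.0 * beta0] if beta0 > 0 else [0.1, 0.3]
        grids = {
            "f_im": [0.0, max(float(self.y.min()), 0.0)],
            "beta": beta_grid,
            "alpha": [0.3, 0.5, 0.7],
            "Da_perp": [0.0, 1e-4, 1e-3, 1e-2],
            "c": [0.0, 1.0, 5.0],
        }
        starts = [np.array(combo, dtype=float) for combo in
                  _product([grids[n] for n in self.param_names])]
        return starts

    def fit(self) -> DecayFitResult:
        """Unweighted nonlinear least squares with deterministic multi-start."""
        names = self.param_names
        lb = np.full(len(names), -np.inf)
        ub = np.full(len(names), np.inf)
        if self.constrain_intercept and "f_im" in names:
            lb[names.index("f_im")] = 0.0
        if "c" in names:
            lb[names.index("c")] = 0.0

        def resid(theta):
            return model_predict(self.model_id, dict(zip(names, theta)), self.b) - self.y

        best = None
        converged = False
        for x0 in self._starts():
            x0 = np.clip(x0, lb, ub + 0.0)
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                    xtol=1e-14, ftol=1e-14, gtol=1e-12,
                                    max_nfev=5000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
                converged = bool(sol.status > 0)
        if best is None:
            raise RuntimeError(f"all starts failed for model ({self.model_id})")
        theta = best.x
        rss = float(2 * best.cost)
        n, k = self.b.size, len(names)
        params = dict(zip(names, map(float, theta)))
        bse = self._standard_errors(best.jac, rss, n, k, names)
        plausible = params.get("Da_perp", 0.0) >= 0.0 and params.get("beta", 1.0) > 0
        return DecayFitResult(
            model_id=self.model_id, params=params, bse=bse, rss=rss,
            n_points=n, aicc=aicc(rss, n, k), converged=converged,
            plausible=plausible,
        )

    @staticmethod
    def _standard_errors(jac, rss, n, k, names) -> dict[str, float]:
        dof = max(n - k, 1)
        try:
            cov = np.linalg.inv(jac.T @ jac) * rss / dof
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return dict(zip(names, map(float, se)))


def fit_model(decay: SphericalMeanDecay, model_id: str, b_min: float = 6.0,
              constrain_intercept: bool = False) -> DecayFitResult:
    """Convenience wrapper: build a DecayModel and fit it."""
    return DecayModel(decay, model_id=model_id, b_min=b_min,
                      constrain_intercept=constrain_intercept).fit()


@dataclass
class ModelComparison:
    """AICc ranking of several candidate models on one decay."""

    results: dict[str, DecayFitResult]
    delta_aicc: dict[str, float] = field(init=False)
    best: str = field(init=False)

    #: delta-AICc convention for "significantly better"
    SIGNIFICANCE = 2.0

    def __post_init__(self):
        aiccs = {m: r.aicc for m, r in self.results.items()}
        amin = min(aiccs.values())
        self.delta_aicc = {m: a - amin for m, a in aiccs.items()}
        self.best = min(aiccs, key=aiccs.get)

    def significantly_better(self, other: str) -> bool:
        """True if the best model beats ``other`` by >= 2 AICc units."""
        return self.delta_aicc[other] >= self.SIGNIFICANCE

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m, r in sorted(self.results.items(), key=lambda kv: kv[1].aicc):
            rows.append({"model": m, "aicc": r.aicc,
                         "delta_aicc": self.delta_aicc[m], "rss": r.rss,
                         "k": len(r.params), "plausible": r.plausible,
                         **{f"p_{k}": v for k, v in r.params.items()}})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.to_dataframe().to_string(index=False, float_format="%.5g")

    def plot(self, decay: SphericalMeanDecay, ax=None):
        """Decay and fitted models versus 1/sqrt(b) (the diagnostic axis:
        sticks are linear, finite radii concave, exchange convex)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xi = decay.b_values ** -0.5
        ax.plot(xi, decay.S_bar, "ko", label="data")
        grid = np.linspace(xi.min() * 0.05, xi.max() * 1.05, 200)
        for m, r in sorted(self.results.items(), key=lambda kv: kv[1].aicc):
            ax.plot(grid, r.predict(grid ** -2.0), label=f"({m}) dAICc={self.delta_aicc[m]:.1f}")
        ax.set_xlabel(r"$1/\sqrt{b}$  [($\mu$m$^2$/ms)$^{1/2}$]")
        ax.set_ylabel(r"$\bar{S}$")
        ax.legend(fontsize=8)
        return ax


def compare_models(decay: SphericalMeanDecay, model_ids=MODEL_IDS,
                   b_min: float = 6.0) -> ModelComparison:
    """Fit each candidate in ``model_ids`` and rank by AICc."""
    results = {}
    for m in model_ids:
        results[m] = fit_model(decay, m, b_min=b_min)
    return ModelComparison(results)


def tangent_intercept(beta: float, Da_perp: float, f_im: float, xi0: float
                      ) -> tuple[float, float]:
    """Intercept of the tangent to S(xi) = beta xi e^{-Da_perp/xi^2} + f_im.

    Linearizing around xi0 = 1/sqrt(b0) gives the extrapolated xi -> 0
    intercept gamma = f_im - 2 beta Da_perp e^{-Da_perp/xi0^2} / xi0 and the
    always-non-positive deficit epsilon = gamma - f_im. |epsilon| is
    maximal at the inflection point xi0 = sqrt(2 Da_perp), where it equals
    beta sqrt(2 Da_perp / e).
    """
    if xi0 <= 0:
        raise ValueError("xi0 must be > 0")
    eps = -2.0 * beta * Da_perp * np.exp(-Da_perp / xi0 ** 2) / xi0
    return float(f_im + eps), float(eps)


def _product(grids):
    if not grids:
        yield ()
        return
    for head in grids[0]:
        for tail in _product(grids[1:]):
            yield (head, *tail)
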