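"""Maximum-likelihood fitting of Gaussian trait-evolution models.

Models: BM (unconstrained diffusion), OU (single-optimum, fixed-root, with
the optimum identified with the root state), EB (exponentially decelerating
rate, a <= 0), and WN (phylogeny-free white noise).  All likelihoods are
exact multivariate-normal densities computed through a Cholesky
factorization of the induced tip covariance; OU and EB fits profile out
(z0, sigma^2) analytically, leaving a bounded one-dimensional search with
seeded multi-starts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from mimicevo.errors import DataMismatchError, FitError, TreeError
from mimicevo.phylo import Phylogeny

__all__ = [
    "GAUSSIAN_MODELS",
    "FitConfig",
    "ModelFit",
    "ModelComparison",
    "HalfLife",
    "align_tip_data",
    "model_covariance",
    "loglik_gaussian",
    "fit_model",
    "compare_models",
    "aicc",
    "phylogenetic_half_life",
]

GAUSSIAN_MODELS = ("BM", "OU", "EB", "WN")

_MODEL_K = {"BM": 2, "OU": 3, "EB": 3, "WN": 2}

_DEGENERATE_VAR = 1e-15
_SIGMA2_FLOOR = 1e-8


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_model`."""

    n_starts: int = 5
    seed: int = 0
    sigma2_bounds: tuple[float, float] = (1e-8, 1e3)
    alpha_bounds: Optional[tuple[float, float]] = None  # default (1e-8, 1e3/height)
    eb_bounds: Optional[tuple[float, float]] = None  # default (-10/height, 0)


@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    lnL: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    boundary: bool = False
    message: str = ""
    data_fingerprint: Optional[tuple] = None

    def __repr__(self) -> str:
        p = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<ModelFit {self.model} lnL={self.lnL:.3f} AICc={self.aicc:.3f} {p}>"


@dataclass
class ModelComparison:
    models: list[str]
    aicc: np.ndarray
    delta_aicc: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> str:
        return self.models[int(np.argmin(self.aicc))]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            m: {"aicc": float(a), "delta_aicc": float(d), "weight": float(w)}
            for m, a, d, w in zip(self.models, self.aicc, self.delta_aicc, self.weights)
        }


@dataclass(frozen=True)
class HalfLife:
    absolute: float  # Ma
    relative: float  # fraction of tree height


def align_tip_data(t: Phylogeny, y: Mapping[str, float]) -> np.ndarray:
    """Order trait values to the tree's (post-order) tip labels."""
    missing = [lab for lab in t.tip_labels if lab not in y]
    if missing:
        raise DataMismatchError(f"tip(s) missing trait values: {missing[:5]}")
    arr = np.array([float(y[lab]) for lab in t.tip_labels])
    if not np.all(np.isfinite(arr)):
        raise DataMismatchError("trait values must be finite")
    return arr


def _fingerprint(t: Phylogeny, y: Mapping[str, float]) -> tuple:
    labs = tuple(sorted(t.tip_labels))
    return (labs, tuple(round(float(y[l]), 12) for l in labs), round(t.height, 10))


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def _covariance_from_depths(
    model: str, M: np.ndarray, td: np.ndarray, **params: float
) -> np.ndarray:
    """Unit-rate covariance from a shared-depth matrix M and tip depths td."""
    m = model.upper()
    if m == "BM":
        return M
    if m == "WN":
        return np.eye(len(td))
    if m == "EB":
        a = params["a"]
        if a > 0:
            raise FitError(f"EB requires a <= 0, got {a}")
        if a == 0:
            return M
        return np.expm1(a * M) / a
    if m == "OU":
        alpha = params["alpha"]
        if alpha <= 0:
            raise FitError(f"OU requires alpha > 0, got {alpha}")
        # fixed-root form: (1/(2a)) e^{-a(ti+tj-2ta)} (1 - e^{-2a ta})
        expo = td[:, None] + td[None, :] - 2.0 * M
        return np.exp(-alpha * expo) * (-np.expm1(-2.0 * alpha * M)) / (2.0 * alpha)
    raise FitError(f"unknown Gaussian model {model!r}")


def model_covariance(model: str, t: Phylogeny, **params: float) -> np.ndarray:
    """Unit-rate tip covariance induced by ``model`` on ``t``.

    Multiply by sigma^2 for the full covariance.  WN returns the identity.
    """
    return _covariance_from_depths(model, t.mrca_depths(), t.tip_depths(), **params)


def _mvn_loglik(y: np.ndarray, mean: float, C: np.ndarray) -> float:
    n = len(y)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError(
            "singular model covariance (duplicate tips at zero distance or "
            "degenerate parameters)"
        ) from exc
    r = y - mean
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def loglik_gaussian(model: str, t: Phylogeny, y: Mapping[str, float], **params: float) -> float:
    """Exact log-likelihood of tip data under a Gaussian model.

    Required params: ``sigma2`` and ``z0`` always; ``alpha`` for OU; ``a``
    for EB.  For WN, ``sigma2`` is the per-tip variance.
    """
    arr = align_tip_data(t, y)
    sigma2 = params["sigma2"]
    z0 = params["z0"]
    if sigma2 <= 0:
        raise FitError(f"sigma2 must be positive, got {sigma2}")
    C = sigma2 * model_covariance(model, t, **{k: v for k, v in params.items() if k not in ("sigma2", "z0")})
    return _mvn_loglik(arr, z0, C)


# ---------------------------------------------------------------------------
# Profile likelihood machinery
# ---------------------------------------------------------------------------

def _profile(C_unit: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ML (z0, sigma2) and profiled lnL for covariance sigma2 * C_unit."""
    n = len(y)
    try:
        cf = cho_factor(C_unit, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular unit covariance") from exc
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    Ciy = cho_solve(cf, y)
    z0 = float(one @ Ciy) / float(one @ Ci1)
    r = y - z0
    s2 = float(r @ cho_solve(cf, r)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if s2 < _SIGMA2_FLOOR * 1e-8:
        s2 = _SIGMA2_FLOOR * 1e-8
    lnL = -0.5 * (n * (math.log(2.0 * math.pi) + math.log(s2) + 1.0) + logdet)
    return z0, s2, lnL


def aicc(lnL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise FitError(f"AICc undefined: n={n}, k={k}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _lhs_starts(lo: float, hi: float, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """One-dimensional Latin-hypercube starts on [lo, hi]."""
    u = (rng.permutation(n_starts) + rng.random(n_starts)) / n_starts
    return lo + u * (hi - lo)


def _optimize_1d(neg, lo: float, hi: float, starts: np.ndarray):
    best_x, best_f = None, np.inf
    ok = False
    for x0 in starts:
        res = optimize.minimize(
            neg, x0=[x0], method="L-BFGS-B", bounds=[(lo, hi)]
        )
        if res.fun < best_f:
            best_x, best_f = float(res.x[0]), float(res.fun)
            ok = bool(res.success)
    # never worse than the best raw start (multi-start contract)
    for x0 in starts:
        f0 = neg([x0])
        if f0 < best_f:
            best_x, best_f, ok = float(x0), float(f0), True
    return best_x, best_f, ok


def fit_model(
    model: str,
    t: Phylogeny,
    y: Mapping[str, float],
    config: Optional[FitConfig] = None,
) -> ModelFit:
    """ML fit of one Gaussian model; deterministic given ``config.seed``."""
    cfg = config or FitConfig()
    m = model.upper()
    if m not in GAUSSIAN_MODELS:
        raise FitError(f"unknown model {model!r}; choose from {GAUSSIAN_MODELS}")
    arr = align_tip_data(t, y)
    n = len(arr)
    k = _MODEL_K[m]
    if n < k + 2:
        raise FitError(f"need at least {k + 2} tips for {m}, have {n}")
    fp = _fingerprint(t, y)
    height = t.height
    rng = np.random.default_rng(cfg.seed)

    if float(np.var(arr)) < _DEGENERATE_VAR:
        warnings.warn(f"degenerate (constant) tip data; {m} rate pinned at lower bound", stacklevel=2)
        params = {"sigma2": cfg.sigma2_bounds[0], "z0": float(arr.mean())}
        if m == "OU":
            params["alpha"] = 1e-8
        elif m == "EB":
            params["a"] = 0.0
        lnL = loglik_gaussian(m, t, y, **params) if m != "WN" else _wn_loglik(arr, arr.mean(), cfg.sigma2_bounds[0])
        return ModelFit(m, params, lnL, k, n, aicc(lnL, k, n), True, True,
                        "degenerate data", fp)

    if m == "WN":
        mu = float(arr.mean())
        s2 = float(np.mean((arr - mu) ** 2))  # ML variance
        lnL = _wn_loglik(arr, mu, s2)
        return ModelFit(m, {"wn_mean": mu, "wn_variance": s2, "sigma2": s2, "z0": mu},
                        lnL, k, n, aicc(lnL, k, n), True, False, "", fp)

    if m == "BM":
        z0, s2, lnL = _profile(t.mrca_depths(), arr)
        boundary = s2 <= cfg.sigma2_bounds[0] or s2 >= cfg.sigma2_bounds[1]
        return ModelFit(m, {"sigma2": s2, "z0": z0}, lnL, k, n, aicc(lnL, k, n),
                        True, boundary, "", fp)

    M = t.mrca_depths()
    td = t.tip_depths()

    if m == "OU":
        lo, hi = cfg.alpha_bounds or (1e-8, 1e3 / height)
        loglo, loghi = math.log(lo), math.log(hi)

        def neg(x):
            C = _covariance_from_depths("OU", M, td, alpha=math.exp(float(x[0])))
            return -_profile(C, arr)[2]

        starts = _lhs_starts(loglo, loghi, cfg.n_starts, rng)
        best_x, best_f, ok = _optimize_1d(neg, loglo, loghi, starts)
        alpha = math.exp(best_x)
        z0, s2, lnL = _profile(model_covariance("OU", t, alpha=alpha), arr)
        boundary = alpha <= lo * 1.0001 or alpha >= hi * 0.9999
        return ModelFit(m, {"sigma2": s2, "z0": z0, "theta": z0, "alpha": alpha},
                        lnL, k, n, aicc(lnL, k, n), ok, boundary,
                        "" if ok else "optimizer did not report convergence", fp)

    # EB
    lo, hi = cfg.eb_bounds or (-10.0 / height, 0.0)

    def neg(x):
        C = _covariance_from_depths("EB", M, td, a=float(x[0]))
        return -_profile(C, arr)[2]

    starts = _lhs_starts(lo, hi, cfg.n_starts, rng)
    best_x, best_f, ok = _optimize_1d(neg, lo, hi, starts)
    a = best_x
    z0, s2, lnL = _profile(model_covariance("EB", t, a=a), arr)
    boundary = a <= lo * 0.9999
    return ModelFit(m, {"sigma2": s2, "z0": z0, "a": a}, lnL, k, n,
                    aicc(lnL, k, n), ok, boundary,
                    "" if ok else "optimizer did not report convergence", fp)


def _wn_loglik(arr: np.ndarray, mu: float, s2: float) -> float:
    n = len(arr)
    return -0.5 * (n * (math.log(2.0 * math.pi) + math.log(s2)) + float(np.sum((arr - mu) ** 2)) / s2)


def compare_models(fits: Sequence[ModelFit]) -> ModelComparison:
    """AICc differences and Akaike weights across fits of the same data."""
    if not fits:
        raise FitError("no fits to compare")
    fps = {f.data_fingerprint for f in fits if f.data_fingerprint is not None}
    if len(fps) > 1:
        raise FitError("fits were computed on different data/tree combinations")
    a = np.array([f.aicc for f in fits])
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelComparison([f.model for f in fits], a, delta, w)


def phylogenetic_half_life(alpha: float, t: Phylogeny) -> HalfLife:
    """t1/2 = ln(2)/alpha, absolute (Ma) and relative to tree height."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    absolute = math.log(2.0) / alpha
    return HalfLife(absolute=absolute, relative=absolute / t.height)
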