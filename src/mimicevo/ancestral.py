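"""Ancestral character estimation by rerooting, and phylogenetic signal.

Node states are estimated by transforming the tree under the best-fitting
Gaussian model (identity for BM, the alpha transform for OU, the a-scaling
for EB), rerooting the transformed tree at each internal node in turn, and
taking the GLS root state (the phylogenetically weighted mean) on the
rerooted tree.  Signal statistics: Pagel's lambda (ML over the
lambda-transformed covariance) and Blomberg's K (observed/expected
MSE-ratio form).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from mimicevo.errors import DataMismatchError, FitError, TreeError
from mimicevo.models import ModelFit, _profile, align_tip_data
from mimicevo.phylo import Phylogeny, eb_transform, lambda_max, ou_transform, reroot

__all__ = [
    "NodeStateEstimates",
    "SignalEstimate",
    "gls_root_state",
    "ancestral_states",
    "pagel_lambda",
    "blomberg_k",
]


@dataclass
class NodeStateEstimates:
    """Internal-node trait estimates keyed by the source tree's node ids."""

    estimates: dict[int, float]
    variances: dict[int, float]
    model: str

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ids = np.array(sorted(self.estimates), dtype=int)
        return ids, np.array([self.estimates[i] for i in ids])


@dataclass
class SignalEstimate:
    statistic: str  # "lambda" or "K"
    estimate: float
    lnL: Optional[float] = None
    profile: dict[str, float] = field(default_factory=dict)


def gls_root_state(t: Phylogeny, y: Mapping[str, float]) -> tuple[float, float]:
    """GLS root state (phylogenetic weighted mean) and its unit-rate variance
    1/(1' C^-1 1) on the given rooted tree."""
    arr = align_tip_data(t, y)
    C = t.mrca_depths()
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular covariance on (rerooted) tree") from exc
    one = np.ones(len(arr))
    Ci1 = cho_solve(cf, one)
    denom = float(one @ Ci1)
    return float(arr @ Ci1) / denom, 1.0 / denom


def ancestral_states(
    t: Phylogeny,
    y: Mapping[str, float],
    best_model: Union[ModelFit, str],
    **params: float,
) -> NodeStateEstimates:
    """Estimate internal-node trait values under the best-fitting model.

    ``best_model`` is a :class:`~mimicevo.models.ModelFit` (from which the
    transform parameter is taken) or a model name with the parameter passed
    as a keyword (``alpha=`` for OU, ``a=`` for EB).
    """
    if isinstance(best_model, ModelFit):
        name = best_model.model
        params = dict(best_model.params)
    else:
        name = best_model.upper()
    align_tip_data(t, y)  # validate labels early

    if name == "BM":
        work = t.copy()
    elif name == "OU":
        work = ou_transform(t, params["alpha"])
    elif name == "EB":
        work = eb_transform(t, params["a"])
    else:
        raise FitError(f"ancestral estimation supports BM/OU/EB, got {name!r}")

    sigma2 = params.get("sigma2", 1.0)
    estimates: dict[int, float] = {}
    variances: dict[int, float] = {}
    for node in t.nodes:
        if node.is_tip:
            continue
        rr = work if node is t.root else reroot(work, node.id)
        est, unit_var = gls_root_state(rr, y)
        estimates[node.id] = est
        variances[node.id] = sigma2 * unit_var
    return NodeStateEstimates(estimates=estimates, variances=variances, model=name)


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def _check_signal_data(t: Phylogeny, arr: np.ndarray) -> None:
    if float(np.var(arr)) < 1e-15:
        raise FitError("degenerate (constant) trait data: phylogenetic signal undefined")
    if t.n_tips < 10:
        warnings.warn("fewer than 10 tips: signal estimates are unreliable", stacklevel=3)


def lambda_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Off-diagonal entries scaled by lambda, diagonal preserved."""
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def pagel_lambda(
    t: Phylogeny, y: Mapping[str, float], cap_at_one: bool = False
) -> SignalEstimate:
    """ML estimate of Pagel's lambda on [0, lambda_max] (optionally [0, 1])."""
    arr = align_tip_data(t, y)
    _check_signal_data(t, arr)
    C = t.mrca_depths()
    hi = min(lambda_max(t), 1.0) if cap_at_one else lambda_max(t)
    if not math.isfinite(hi):
        hi = 1.0
    hi *= 1.0 - 1e-9  # at lambda_max exactly, cherries can degenerate

    def neg(lam: float) -> float:
        try:
            return -_profile(lambda_covariance(C, float(lam)), arr)[2]
        except FitError:
            return math.inf

    # coarse grid then bounded polish; deterministic
    grid = np.linspace(0.0, hi, 21)
    f = [neg(g) for g in grid]
    g0 = grid[int(np.argmin(f))]
    lo_b = max(0.0, g0 - hi / 20)
    hi_b = min(hi, g0 + hi / 20)
    res = optimize.minimize_scalar(neg, bounds=(lo_b, hi_b), method="bounded",
                                   options={"xatol": 1e-8})
    cand = [(float(res.x), float(res.fun))] + list(zip(grid, f))
    lam, fmin = min(cand, key=lambda p: p[1])
    return SignalEstimate(
        statistic="lambda",
        estimate=float(lam),
        lnL=-fmin,
        profile={"lnL_at_0": -neg(0.0), "lnL_at_max": -neg(hi), "lambda_max": hi},
    )


def blomberg_k(t: Phylogeny, y: Mapping[str, float]) -> SignalEstimate:
    """Blomberg's K: (MSE0/MSE) over its Brownian expectation
    (tr(C) - n / (1' C^-1 1)) / (n - 1)."""
    arr = align_tip_data(t, y)
    _check_signal_data(t, arr)
    n = len(arr)
    C = t.mrca_depths()
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular phylogenetic covariance") from exc
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a_hat = float(arr @ Ci1) / float(one @ Ci1)
    r = arr - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    expected = (float(np.trace(C)) - n / float(one @ Ci1)) / (n - 1)
    k = (mse0 / mse) / expected
    return SignalEstimate(statistic="K", estimate=float(k))
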