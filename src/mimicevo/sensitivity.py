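"""Replication of model fits across a sample of trees.

For every tree in the sample each requested model is fitted, per-tree AICc
differences and Akaike weights are computed across the models that
succeeded, and the spread of fit statistics (AICc, weights, rates,
half-life, landscape optimum) is summarized.  Fit failures are recorded and
excluded from the summaries rather than aborting the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from mimicevo.errors import DataMismatchError, FitError, MimicevoError
from mimicevo.fpk import FPKFitConfig, fit_fpk
from mimicevo.models import FitConfig, align_tip_data, fit_model, phylogenetic_half_life
from mimicevo.phylo import Phylogeny, TreeSample

__all__ = [
    "SensitivityConfig",
    "SensitivitySummary",
    "analyze_tree_sample",
    "subsample_posterior",
]

DEFAULT_MODELS = ("BM", "OU", "EB", "WN", "FPK")

_STATS = ("aicc", "delta_aicc", "weight", "lnL", "sigma2", "alpha",
          "half_life", "half_life_rel", "fpk_optimum")


@dataclass
class SensitivityConfig:
    seed: int = 0
    n_starts: int = 5
    fpk: FPKFitConfig = field(default_factory=FPKFitConfig)


@dataclass
class SensitivitySummary:
    per_tree: pd.DataFrame  # one row per (tree, model)
    summary: pd.DataFrame  # per model x statistic: median/min/max/iqr
    failures: list[tuple[int, str, str]]  # (tree index, model, message)
    n_trees: int
    models: tuple[str, ...]


def subsample_posterior(
    trees: TreeSample,
    size: int = 100,
    seed: int = 0,
    burnin_fraction: float = 0.0,
) -> TreeSample:
    """Seeded uniform draw without replacement after optional burn-in drop."""
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    pool = trees.trees[int(len(trees) * burnin_fraction):]
    if size >= len(pool):
        return TreeSample(list(pool), provenance=trees.provenance)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(pool), size=size, replace=False))
    return TreeSample([pool[i] for i in idx], provenance=f"{trees.provenance}:subsample")


def _fit_one(model: str, tree: Phylogeny, y, cfg: SensitivityConfig, tree_seed: int) -> dict:
    row: dict = {"model": model}
    if model == "FPK":
        fcfg = FPKFitConfig(**{**cfg.fpk.__dict__, "seed": tree_seed})
        fit = fit_fpk(tree, y, fcfg)
        scale2 = fit.model.scale**2
        row.update(
            lnL=fit.lnL, aicc=fit.aicc,
            sigma2=fit.model.sigma2 * scale2,  # back to trait^2/Ma
            fpk_optimum=fit.landscape.optimum,
            converged=fit.converged,
        )
        return row
    fit = fit_model(model, tree, y, FitConfig(seed=tree_seed, n_starts=cfg.n_starts))
    row.update(lnL=fit.lnL, aicc=fit.aicc, converged=fit.converged)
    if "sigma2" in fit.params and model != "WN":
        row["sigma2"] = fit.params["sigma2"]
    if model == "OU":
        hl = phylogenetic_half_life(fit.params["alpha"], tree)
        row.update(alpha=fit.params["alpha"], half_life=hl.absolute, half_life_rel=hl.relative)
    return row


def analyze_tree_sample(
    trees: TreeSample,
    y: Mapping[str, float],
    models: Sequence[str] = DEFAULT_MODELS,
    config: Optional[SensitivityConfig] = None,
) -> SensitivitySummary:
    """Fit every model on every tree and summarize the spread of statistics.

    Per-tree Akaike weights are computed across the models that fitted
    successfully on that tree; failures are logged, not fatal.  Identical
    seed and inputs give identical summaries.
    """
    cfg = config or SensitivityConfig()
    if len(trees) < 2:
        raise MimicevoError("need at least 2 trees for a sensitivity analysis")
    for k, tree in enumerate(trees):
        try:
            align_tip_data(tree, y)
        except DataMismatchError as exc:
            raise DataMismatchError(f"tree {k}: {exc}") from exc

    models = tuple(m.upper() for m in models)
    rows: list[dict] = []
    failures: list[tuple[int, str, str]] = []
    for i, tree in enumerate(trees):
        tree_rows = []
        for model in models:
            try:
                r = _fit_one(model, tree, y, cfg, tree_seed=cfg.seed)
            except (FitError, DataMismatchError, ValueError) as exc:
                failures.append((i, model, str(exc)))
                continue
            r["tree"] = i
            tree_rows.append(r)
        if tree_rows:
            a = np.array([r["aicc"] for r in tree_rows])
            delta = a - a.min()
            w = np.exp(-delta / 2.0)
            w /= w.sum()
            for r, d, wi in zip(tree_rows, delta, w):
                r["delta_aicc"] = float(d)
                r["weight"] = float(wi)
        rows.extend(tree_rows)

    per_tree = pd.DataFrame(rows)
    summaries = []
    for model in models:
        sub = per_tree[per_tree["model"] == model] if len(per_tree) else per_tree
        for stat in _STATS:
            if len(sub) == 0 or stat not in sub.columns:
                continue
            vals = sub[stat].dropna().to_numpy()
            if len(vals) == 0:
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            summaries.append(
                {
                    "model": model,
                    "statistic": stat,
                    "median": float(np.median(vals)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                    "iqr": float(q3 - q1),
                    "n": int(len(vals)),
                }
            )
    return SensitivitySummary(
        per_tree=per_tree,
        summary=pd.DataFrame(summaries),
        failures=failures,
        n_trees=len(trees),
        models=models,
    )
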