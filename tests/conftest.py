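"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's tree algebra: covariances
are rebuilt from pairwise undirected path distances, and likelihood checks
go through scipy's dense multivariate normal.
"""

from __future__ import annotations

import numpy as np
import pytest

from mimicevo.phylo import Node, Phylogeny, parse_tree
from mimicevo.simulate import simulate_tree


# ---------------------------------------------------------------------------
# Independent path-based oracles
# ---------------------------------------------------------------------------

def undirected_distances(t: Phylogeny) -> tuple[list[str], np.ndarray]:
    """All pairwise tip path lengths plus each tip's distance to the root,
    computed by explicit root-to-tip edge lists (no covariance code)."""
    paths: dict[str, list[float]] = {}
    chains: dict[str, list[int]] = {}

    def walk(n: Node, edges: list[tuple[int, float]]) -> None:
        if n.is_tip:
            chains[n.label] = [e[0] for e in edges]
            paths[n.label] = [e[1] for e in edges]
        for c in n.children:
            walk(c, edges + [(c.id, c.length)])

    walk(t.root, [])
    labels = sorted(paths)
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            shared = 0.0
            ea, eb = set(chains[a]), set(chains[b])
            for eid, el in zip(chains[a], paths[a]):
                if eid in eb:
                    shared += el
            D[i, j] = sum(paths[a]) + sum(paths[b]) - 2.0 * shared
    root_dist = np.array([sum(paths[lab]) for lab in labels])
    return labels, D, root_dist


def covariance_oracle(t: Phylogeny, order=None) -> np.ndarray:
    """BM covariance from pairwise distances: C_ij = (d_i + d_j - D_ij)/2."""
    labels, D, rd = undirected_distances(t)
    C = (rd[:, None] + rd[None, :] - D) / 2.0
    if order is None:
        order = t.tip_labels
    perm = [labels.index(lab) for lab in order]
    return C[np.ix_(perm, perm)]


def mvn_logpdf_oracle(y: np.ndarray, mean: np.ndarray, C: np.ndarray) -> float:
    from scipy.stats import multivariate_normal

    return float(multivariate_normal(mean=mean, cov=C, allow_singular=False).logpdf(y))


# ---------------------------------------------------------------------------
# Fixture trees
# ---------------------------------------------------------------------------

def write_measurement_csv(path, tip_values: dict) -> None:
    """Write a measurement table whose overall accuracy per specimen equals
    the given value (spread uniformly over the eight ratio traits)."""
    import dataclasses

    import pandas as pd

    from mimicevo.simulate import synthesize_measurements
    from mimicevo.traits import TRAIT_NAMES

    ratio_traits = [n for n in TRAIT_NAMES if n != "illusion_coloration"]
    rows = []
    for label, acc in tip_values.items():
        acc = float(np.clip(acc, 0.0, 0.85))
        targets = {n: acc * 9.0 / 8.0 for n in ratio_traits}
        targets["illusion_coloration"] = 0.0
        m = synthesize_measurements(targets, specimen_id=label)
        d = dataclasses.asdict(m)
        flags = d.pop("illusion_flags")
        d.pop("clade_label")
        d.update(
            band_abdomen=int(flags[0]),
            band_cephalothorax=int(flags[1]),
            eye_darkening=int(flags[2]),
            clade="synthetic",
        )
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


@pytest.fixture
def two_tip_tree() -> Phylogeny:
    return parse_tree("(A:1,B:1):0;")


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return parse_tree("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def six_tip_tree() -> Phylogeny:
    return simulate_tree(6, 1.0, 0.0, seed=42)


@pytest.fixture
def eight_tip_tree() -> Phylogeny:
    return simulate_tree(8, 1.0, 0.2, seed=7)


@pytest.fixture
def medium_tree() -> Phylogeny:
    return simulate_tree(30, 1.0, 0.2, seed=11)
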