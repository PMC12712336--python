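"""Synthetic trees, traits, and measurement tables.

Everything here flows from a single seeded :class:`numpy.random.Generator`
per call; there is no global random state.  The trait simulators are exact
branchwise samplers (normal increments for BM; conditional mean/variance for
OU; the EB time transform followed by BM; a continuous-time jump chain on
the FPK grid that shares its generator with :mod:`mimicevo.fpk`), and the
measurement synthesizer inverts the scoring formulas so that scoring a
synthesized specimen reproduces the target scores exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from mimicevo.errors import TreeError
from mimicevo.fpk import FPKModel, _neighbour_rates, stationary_density
from mimicevo.phylo import Node, Phylogeny, TreeSample
from mimicevo.traits import ILLUSION_SCORES, TRAIT_NAMES, SpecimenMeasurements, TraitScores

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_trait",
    "synthesize_measurements",
    "perturb_tree_sample",
]


@dataclass
class SimulationConfig:
    """Settings for stochastic generation; ``seed`` is mandatory."""

    seed: int
    n_tips: int = 50
    birth_rate: float = 1.0
    death_rate: float = 0.0
    model: str = "BM"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death rate must be below the birth rate")
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Birth-death trees
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
    max_tries: int = 1000,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on the extant tip count.

    Forward Gillespie simulation from the root split; runs are restarted on
    extinction; extinct lineages are pruned and unifurcations suppressed.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0 or death_rate < 0 or death_rate >= birth_rate:
        raise ValueError(
            f"infeasible rates: birth={birth_rate}, death={death_rate} "
            "(need 0 <= death < birth)"
        )
    rng = _as_rng(seed)

    for _ in range(max_tries):
        tree = _grow_tree(n_tips, birth_rate, death_rate, rng)
        if tree is not None:
            return tree
    raise TreeError(f"no surviving tree in {max_tries} attempts; rates too extinction-prone")


def _grow_tree(n_tips, birth, death, rng) -> Optional[Phylogeny]:
    root = Node(length=0.0)
    active: list[tuple[Node, float]] = [(root.add(Node()), 0.0), (root.add(Node()), 0.0)]
    t = 0.0
    total = birth + death
    while True:
        k = len(active)
        if k == 0:
            return None
        t += rng.exponential(1.0 / (k * total))
        idx = rng.integers(k)
        node, t0 = active.pop(idx)
        node.length = t - t0
        if rng.random() < birth / total:
            active.append((node.add(Node()), t))
            active.append((node.add(Node()), t))
            if len(active) == n_tips:
                # stop just before the next event so pendant edges are nonzero
                t += rng.exponential(1.0 / (n_tips * total))
                for leaf, s0 in active:
                    leaf.length = t - s0
                break
        else:
            node.label = "__dead__"

    root = _prune_dead(root)
    if root is None:
        return None
    root.parent, root.length = None, 0.0

    tips: list[Node] = []

    def collect(n: Node) -> None:
        if n.is_tip:
            tips.append(n)
        for c in n.children:
            collect(c)

    collect(root)
    if len(tips) != n_tips:
        return None
    for i, tip in enumerate(tips, start=1):
        tip.label = f"t{i}"
    return Phylogeny(root)


def _prune_dead(node: Node) -> Optional[Node]:
    """Drop extinct subtrees, suppressing unifurcations; None if extinct."""
    if node.is_tip:
        return None if node.label == "__dead__" else node
    kids = [p for p in (_prune_dead(c) for c in node.children) if p is not None]
    if not kids:
        return None
    if len(kids) == 1:
        child = kids[0]
        child.length += node.length
        return child
    node.children = kids
    for k in kids:
        k.parent = node
    return node


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_trait(
    t: Phylogeny,
    model: str,
    params: Mapping[str, float],
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[dict[str, float], dict[int, float]]:
    """Simulate one continuous trait on the tree.

    Returns ``(tip_values, node_states)`` where ``tip_values`` maps tip
    labels to trait values and ``node_states`` maps every node id (internal
    and tip) to its true simulated state.

    Models and parameters
    ---------------------
    BM:  sigma2, z0
    OU:  sigma2, z0 (= theta), alpha
    EB:  sigma2, z0, a (<= 0)
    WN:  wn_mean (or z0), wn_variance (or sigma2)
    FPK: an :class:`~mimicevo.fpk.FPKModel` passed as ``params["model"]``
    """
    rng = _as_rng(seed)
    m = model.upper()
    states: dict[int, float] = {}
    if m == "FPK":
        return _simulate_fpk(t, params["model"], rng)

    z0 = float(params.get("z0", params.get("wn_mean", 0.0)))
    sigma2 = float(params.get("sigma2", params.get("wn_variance", 1.0)))

    if m == "WN":
        states[t.root.id] = z0
        for n in t.nodes:
            if n.id not in states:
                states[n.id] = z0
        tips = {
            tip.label: float(z0 + math.sqrt(sigma2) * rng.standard_normal())
            for tip in t.tips
        }
        for tip in t.tips:
            states[tip.id] = tips[tip.label]
        return tips, states

    depths = t.depths()
    states[t.root.id] = z0
    if m == "BM":
        def draw(parent_state, node):
            return parent_state + math.sqrt(sigma2 * node.length) * rng.standard_normal()
    elif m == "OU":
        alpha = float(params["alpha"])
        if alpha <= 0:
            raise ValueError("OU simulation requires alpha > 0")
        theta = float(params.get("theta", z0))

        def draw(parent_state, node):
            e = math.exp(-alpha * node.length)
            mean = theta + (parent_state - theta) * e
            var = sigma2 * (1.0 - e * e) / (2.0 * alpha)
            return mean + math.sqrt(var) * rng.standard_normal()
    elif m == "EB":
        a = float(params["a"])
        if a > 0:
            raise ValueError("EB simulation requires a <= 0")

        def draw(parent_state, node):
            t1 = depths[node.id] - node.length
            t2 = depths[node.id]
            var = sigma2 * (node.length if a == 0 else (math.exp(a * t2) - math.exp(a * t1)) / a)
            return parent_state + math.sqrt(max(var, 0.0)) * rng.standard_normal()
    else:
        raise ValueError(f"unknown simulation model {model!r}")

    for n in reversed(t.nodes):  # pre-order
        for c in n.children:
            states[c.id] = float(draw(states[n.id], c))
    tips = {tip.label: states[tip.id] for tip in t.tips}
    return tips, states


def _simulate_fpk(t: Phylogeny, m: FPKModel, rng) -> tuple[dict[str, float], dict[int, float]]:
    """Continuous-time jump simulation on the FPK grid (tips always in bounds)."""
    up, down = _neighbour_rates(m)
    grid = m.grid()
    N = m.n_grid
    land = stationary_density(m)
    root_idx = int(rng.choice(N, p=land.density))

    def evolve(i: int, duration: float) -> int:
        clock = 0.0
        while True:
            r_up = up[i] if i < N - 1 else 0.0
            r_dn = down[i - 1] if i > 0 else 0.0
            total = r_up + r_dn
            if total <= 0:
                return i
            clock += rng.exponential(1.0 / total)
            if clock >= duration:
                return i
            i = i + 1 if rng.random() < r_up / total else i - 1

    idx: dict[int, int] = {t.root.id: root_idx}
    for n in reversed(t.nodes):
        for c in n.children:
            idx[c.id] = evolve(idx[n.id], c.length)
    states = {nid: float(grid[i]) for nid, i in idx.items()}
    tips = {tip.label: states[tip.id] for tip in t.tips}
    return tips, states


# ---------------------------------------------------------------------------
# Measurement synthesis (inverse of the scoring formulas)
# ---------------------------------------------------------------------------

def synthesize_measurements(
    target_scores: Union[TraitScores, Mapping[str, float]],
    seed: Union[int, np.random.Generator] = 0,
    specimen_id: str = "synthetic",
    scale_noise: bool = False,
) -> SpecimenMeasurements:
    """Build a measurement row whose scores reproduce the targets exactly.

    Reference lengths are fixed at 1 mm (femur, cephalothorax, abdomen,
    maximum heights); widths and constrictions are derived by inverting the
    score ratios, and illusion flags are set to the matching count.  With
    ``scale_noise`` all lengths are multiplied by one lognormal specimen-size
    factor (2-8 mm scale), which leaves every ratio - hence every score -
    unchanged.

    Raises
    ------
    ValueError
        If a target is outside [0, 1], a ratio target equals 1 exactly
        (requiring a zero measurement), or the illusion target is not one of
        0 / 0.334 / 0.667 / 1.0.
    """
    tgt = target_scores.as_dict() if isinstance(target_scores, TraitScores) else dict(target_scores)
    missing = [n for n in TRAIT_NAMES if n not in tgt or tgt[n] is None]
    if missing:
        raise ValueError(f"missing target score(s): {missing}")
    for name in TRAIT_NAMES:
        v = tgt[name]
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"target {name}={v!r} outside [0, 1]")
        if name != "illusion_coloration" and v >= 1.0:
            raise ValueError(f"target {name}=1 is unreachable with positive measurements")

    ill = tgt["illusion_coloration"]
    diffs = [abs(ill - s) for s in ILLUSION_SCORES]
    n_flags = int(np.argmin(diffs))
    if diffs[n_flags] > 1e-9:
        raise ValueError(
            f"illusion target {ill!r} unreachable; must be one of {ILLUSION_SCORES}"
        )

    rng = _as_rng(seed)
    size = float(np.exp(rng.normal(math.log(4.0), 0.3))) if scale_noise else 1.0

    ceph_length = 1.0
    abd_length = 1.0
    p = tgt["elong_pedicel"]
    pedicel = p * (ceph_length + abd_length) / (1.0 - p)
    ceph_width = 1.0 - tgt["elong_ceph"]
    abd_width = 1.0 - tgt["elong_abd"]

    def sc(x: float) -> float:
        return x * size

    return SpecimenMeasurements(
        specimen_id=specimen_id,
        femur3_length=sc(1.0),
        femur3_width=sc(1.0 - tgt["thin_legs"]),
        ceph_width=sc(ceph_width),
        ceph_length=sc(ceph_length),
        abd_width=sc(abd_width),
        abd_length=sc(abd_length),
        pedicel_length=sc(pedicel),
        ceph_width_constr=sc((1.0 - tgt["constr_ceph_dors"]) * ceph_width),
        ceph_height_constr=sc(1.0 - tgt["constr_ceph_lat"]),
        ceph_height_max=sc(1.0),
        abd_width_constr=sc((1.0 - tgt["constr_abd_dors"]) * abd_width),
        abd_height_constr=sc(1.0 - tgt["constr_abd_lat"]),
        abd_height_max=sc(1.0),
        illusion_flags=tuple(i < n_flags for i in range(3)),
    )


# ---------------------------------------------------------------------------
# Posterior-like tree jitter
# ---------------------------------------------------------------------------

def perturb_tree_sample(
    t: Phylogeny,
    count: int,
    jitter: float,
    seed: Union[int, np.random.Generator] = 0,
) -> TreeSample:
    """``count`` copies of ``t`` with mean-one lognormal noise
    (sd ``jitter``) applied to node-age increments, which keeps every tree
    exactly ultrametric with strictly positive branch lengths.  Topology is
    unchanged; with ``jitter=0`` the copies are identical to the input."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = _as_rng(seed)
    if not t.is_ultrametric():
        raise TreeError("perturb_tree_sample requires an ultrametric input tree")
    T = t.height
    depths = t.depths()
    out = []
    mu = -0.5 * jitter * jitter  # E[exp(N(mu, jitter^2))] = 1
    for _ in range(count):
        w = t.copy()
        if jitter > 0:
            # Jitter the age gap between each internal node and its oldest
            # child, rebuilding ages bottom-up (tips at age 0): ordering and
            # ultrametricity hold by construction.
            new_age: dict[int, float] = {}
            for n in w.nodes:  # post-order
                if n.is_tip:
                    new_age[n.id] = 0.0
                    continue
                age = T - depths[n.id]
                child_age = max(T - depths[c.id] for c in n.children)
                gap = (age - child_age) * float(np.exp(rng.normal(mu, jitter)))
                new_age[n.id] = max(new_age[c.id] for c in n.children) + gap
            for n in w.nodes:
                if n.parent is not None:
                    n.length = new_age[n.parent.id] - new_age[n.id]
        out.append(w)
    return TreeSample(out, provenance=f"jitter={jitter}")
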