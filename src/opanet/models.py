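"""Growth dynamics: the copying-degree step and three link-formation rules.

All three ordinal-preferential-attachment (OPA) family models share the same
first step: a new node x copies the degree of a uniformly random existing
node y, scaled by the conversion coefficient delta, into a *virtual degree*
d* drawn uniformly from {1, ..., ceil(delta*d_y)}.  They differ in where the
d* link targets come from:

* ``previous_opa`` (pre-adjunction rule): uniformly from the full candidate
  set {z : d* <= ceil(delta*d_z)};
* ``adjunction``: only from the minimum elements M_{d*} of that set (the
  literal lower adjoint) — this variant fails to produce dense scale-free
  networks and serves as the negative control;
* ``neighborhood_opa`` (the proposed model): a hub z is drawn uniformly from
  the candidate set and the targets uniformly from its closed neighborhood
  N_z = neighbors(z) ∪ {z}.

The duplication–divergence ``copying`` baseline (copy a random node's links,
delete each with probability p) is included for reference.

Degrees used within a step are always those *before* the new node is
inserted; when a pool is smaller than d*, the new node connects to the whole
pool.  All randomness flows through one ``random.Random`` stream per trial,
so a fixed seed reproduces edge lists bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random
from typing import Literal

from .graph_core import (GrowingNetwork, add_node_with_links, initial_network,
                         min_degree_for_ability)
from .order_galois import ability

ModelKind = Literal["previous_opa", "adjunction", "neighborhood_opa", "copying"]


def default_checkpoints(t_max: int, t0: int = 2) -> list[int]:
    """Doubling schedule t0*2, t0*4, ... plus t_max itself."""
    pts = []
    t = t0 * 2
    while t < t_max:
        pts.append(t)
        t *= 2
    pts.append(t_max)
    return pts


@dataclass
class ModelConfig:
    model_kind: ModelKind
    t_max: int
    delta: float | None = None      # OPA family
    p: float | None = None          # copying baseline
    n_trials: int = 1
    seed: int = 0
    checkpoints: list[int] | None = None
    keep_snapshots: bool = False    # deep-copy the network at each checkpoint

    def __post_init__(self) -> None:
        if self.t_max <= 2:
            raise ValueError("t_max must exceed the 2-node initial network")
        if self.model_kind == "copying":
            if self.p is None or not 0 < self.p < 1:
                raise ValueError("copying model requires 0 < p < 1")
        else:
            if self.delta is None or self.delta <= 0:
                raise ValueError("OPA-family models require delta > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.checkpoints is None:
            self.checkpoints = default_checkpoints(self.t_max)
        if any(c < 3 or c > self.t_max for c in self.checkpoints):
            raise ValueError("checkpoints must lie in [3, t_max]")


@dataclass
class CheckpointRecord:
    t: int
    L: int
    max_degree: int


@dataclass
class GrowthResult:
    config: ModelConfig
    trial: int
    seed: int
    network: GrowingNetwork
    checkpoints: list[CheckpointRecord] = field(default_factory=list)
    snapshots: dict[int, GrowingNetwork] = field(default_factory=dict)


# ------------------------------------------------------------- single steps

def draw_virtual_degree(net: GrowingNetwork, delta: float,
                        rng: Random) -> tuple[int, int]:
    """Copying-degree step: (y, d*) with y uniform over existing nodes and
    d* uniform over {1, ..., ceil(delta * d_y)}."""
    y = rng.randrange(net.t)
    a = ability(net.degree(y), delta)   # raises on an isolated node
    return y, rng.randint(1, a)


def _sample_distinct_indices(n: int, k: int, rng: Random) -> list[int]:
    # k distinct ints from range(n); rejection for small k, else sample()
    if k * 3 < n:
        seen: set[int] = set()
        while len(seen) < k:
            seen.add(rng.randrange(n))
        return sorted(seen)
    return sorted(rng.sample(range(n), k))


def _candidate_buckets(net: GrowingNetwork, delta: float,
                       d_star: int) -> list[tuple[int, list[int]]]:
    return net.nodes_with_degree_at_least(min_degree_for_ability(d_star, delta))


def targets_pre_adjunction(net: GrowingNetwork, delta: float, d_star: int,
                           rng: Random) -> set[int]:
    """d* targets uniform without replacement from the full candidate set
    (all candidates when fewer than d* qualify)."""
    buckets = _candidate_buckets(net, delta, d_star)
    n = sum(len(nodes) for _, nodes in buckets)
    if n == 0:
        raise LookupError("empty candidate set (cannot occur mid-growth)")
    if n <= d_star:
        return {v for _, nodes in buckets for v in nodes}
    picks = _sample_distinct_indices(n, d_star, rng)
    out: set[int] = set()
    offset = 0
    it = iter(picks)
    want = next(it)
    for _, nodes in buckets:
        while want is not None and want < offset + len(nodes):
            out.add(nodes[want - offset])
            want = next(it, None)
        offset += len(nodes)
        if want is None:
            break
    return out


def targets_adjunction(net: GrowingNetwork, delta: float, d_star: int,
                       rng: Random) -> set[int]:
    """d* targets from the minimum elements M_{d*} only (all of M when it is
    smaller than d*)."""
    buckets = _candidate_buckets(net, delta, d_star)
    if not buckets:
        raise LookupError("empty candidate set (cannot occur mid-growth)")
    members = buckets[0][1]
    if len(members) <= d_star:
        return set(members)
    picks = _sample_distinct_indices(len(members), d_star, rng)
    return {members[i] for i in picks}


def targets_neighborhood(net: GrowingNetwork, delta: float, d_star: int,
                         rng: Random) -> tuple[int, set[int]]:
    """Hub z uniform over the candidate set, then d* targets uniform without
    replacement from N_z (all of N_z when d* >= |N_z|)."""
    buckets = _candidate_buckets(net, delta, d_star)
    n = sum(len(nodes) for _, nodes in buckets)
    if n == 0:
        raise LookupError("empty candidate set (cannot occur mid-growth)")
    r = rng.randrange(n)
    z = -1
    for _, nodes in buckets:
        if r < len(nodes):
            z = nodes[r]
            break
        r -= len(nodes)
    pool = sorted(net.adj[z] | {z})
    if d_star >= len(pool):
        return z, set(pool)
    picks = _sample_distinct_indices(len(pool), d_star, rng)
    return z, {pool[i] for i in picks}


def copying_step(net: GrowingNetwork, p: float, rng: Random) -> int:
    """Duplication–divergence step: copy a random node's links, then delete
    each copied link independently with probability p.  The new node may end
    up isolated; it is kept.  Returns the new node id."""
    y = rng.randrange(net.t)
    kept = {u for u in net.adj[y] if rng.random() >= p}
    return net._append_node(kept)


def opa_step(net: GrowingNetwork, delta: float, kind: ModelKind,
             rng: Random) -> int:
    """One full growth step of an OPA-family model; returns the new node id."""
    _, d_star = draw_virtual_degree(net, delta, rng)
    if kind == "previous_opa":
        targets = targets_pre_adjunction(net, delta, d_star, rng)
    elif kind == "adjunction":
        targets = targets_adjunction(net, delta, d_star, rng)
    elif kind == "neighborhood_opa":
        _, targets = targets_neighborhood(net, delta, d_star, rng)
    else:
        raise ValueError(f"not an OPA-family model: {kind!r}")
    return add_node_with_links(net, targets)


# ------------------------------------------------------------------- growth

def grow(config: ModelConfig, trial: int = 0) -> GrowthResult:
    """Grow one network from the two-node initial condition to t_max nodes.

    Trial ``i`` uses seed ``config.seed + i`` so trials are independent and
    embarrassingly parallel while the whole run stays reproducible.
    """
    seed = config.seed + trial
    rng = Random(seed)
    net = initial_network("pair")
    result = GrowthResult(config=config, trial=trial, seed=seed, network=net)
    cps = sorted(set(config.checkpoints or []))
    ci = 0
    while net.t < config.t_max:
        if config.model_kind == "copying":
            copying_step(net, config.p, rng)
        else:
            opa_step(net, config.delta, config.model_kind, rng)
        if ci < len(cps) and net.t == cps[ci]:
            result.checkpoints.append(
                CheckpointRecord(t=net.t, L=net.L, max_degree=net.max_degree()))
            if config.keep_snapshots:
                result.snapshots[net.t] = net.copy()
            ci += 1
    return result


def grow_trials(config: ModelConfig) -> list[GrowthResult]:
    """Run ``config.n_trials`` independent trials."""
    return [grow(config, trial=i) for i in range(config.n_trials)]
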