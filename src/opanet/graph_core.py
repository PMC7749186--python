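"""Minimal simple-undirected-graph structure for incremental network growth.

The growing-network models in :mod:`opanet.models` only ever *add* nodes, so
the container is deliberately small: adjacency as a list of neighbor sets
(node ids are consecutive integers in insertion order, and "time" ``t`` is the
node count), plus a degree-indexed bucket structure so that candidate-set
queries and uniform sampling over degree classes run in time proportional to
the number of distinct degrees rather than the number of nodes.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Iterator


class GrowingNetwork:
    """Simple undirected graph under incremental node addition.

    Invariants maintained by construction:

    * adjacency is symmetric and has no self-loops;
    * node ids are exactly ``0 .. t-1`` in insertion order;
    * ``sum(degrees) == 2 * L`` (handshake identity).

    Isolated nodes are tolerated (the copying baseline can create them) but
    the ordinal-preferential-attachment models never do.
    """

    __slots__ = ("adj", "L", "_buckets", "_pos")

    def __init__(self) -> None:
        self.adj: list[set[int]] = []
        self.L: int = 0
        # degree -> list of node ids with that degree (empty lists pruned)
        self._buckets: dict[int, list[int]] = {}
        # node id -> index into its bucket list (swap-pop bookkeeping)
        self._pos: list[int] = []

    # ------------------------------------------------------------------ basic

    @property
    def t(self) -> int:
        """Number of nodes ("time" in the growth process)."""
        return len(self.adj)

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def degrees(self) -> list[int]:
        return [len(nbrs) for nbrs in self.adj]

    def max_degree(self) -> int:
        return max(self._buckets) if self._buckets else 0

    def degree_counts(self) -> dict[int, int]:
        """Mapping degree -> number of nodes with that degree."""
        return {d: len(nodes) for d, nodes in self._buckets.items()}

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield undirected edges as (u, v) with u < v."""
        for u, nbrs in enumerate(self.adj):
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def nodes_with_degree_at_least(self, dmin: int) -> list[tuple[int, list[int]]]:
        """Nonempty degree buckets with degree >= dmin, sorted by degree."""
        return [(d, self._buckets[d]) for d in sorted(self._buckets) if d >= dmin]

    # ------------------------------------------------------------- mutation

    def _bucket_add(self, v: int, d: int) -> None:
        lst = self._buckets.setdefault(d, [])
        self._pos[v] = len(lst)
        lst.append(v)

    def _bucket_remove(self, v: int, d: int) -> None:
        lst = self._buckets[d]
        i = self._pos[v]
        last = lst[-1]
        lst[i] = last
        self._pos[last] = i
        lst.pop()
        if not lst:
            del self._buckets[d]

    def _append_node(self, targets: Iterable[int]) -> int:
        """Add a node linked to ``targets`` (may be empty); returns its id."""
        tset = set(targets)
        nid = len(self.adj)
        if any(u < 0 or u >= nid for u in tset):
            raise ValueError("link target out of range")
        self.adj.append(tset)
        self._pos.append(-1)
        self._bucket_add(nid, len(tset))
        for u in tset:
            d = len(self.adj[u])
            self._bucket_remove(u, d)
            self.adj[u].add(nid)
            self._bucket_add(u, d + 1)
        self.L += len(tset)
        return nid

    def copy(self) -> "GrowingNetwork":
        new = GrowingNetwork()
        new.adj = [set(nbrs) for nbrs in self.adj]
        new.L = self.L
        new._buckets = {d: list(nodes) for d, nodes in self._buckets.items()}
        new._pos = list(self._pos)
        return new


def initial_network(kind: str = "pair") -> GrowingNetwork:
    """Initial condition for growth: two nodes joined by one link."""
    if kind != "pair":
        raise ValueError(f"unknown initial network kind: {kind!r}")
    net = GrowingNetwork()
    net._append_node(())
    net._append_node((0,))
    return net


def add_node_with_links(net: GrowingNetwork, targets: Iterable[int]) -> int:
    """Insert a new node linked to each id in ``targets``; returns the new id.

    ``targets`` must be a nonempty set of distinct existing node ids.  The new
    node gets id ``net.t`` (pre-insertion) and degree ``len(targets)``.
    """
    tset = set(targets)
    if not tset:
        raise ValueError("targets must be nonempty")
    return net._append_node(tset)


def closed_neighborhood(net: GrowingNetwork, z: int) -> set[int]:
    """N_z: the neighbors of ``z`` together with ``z`` itself."""
    if not 0 <= z < net.t:
        raise IndexError(f"node id {z} out of range")
    return net.adj[z] | {z}


def min_degree_for_ability(k: int, delta: float) -> int:
    """Smallest degree d >= 1 with ceil(delta*d) >= k, under float arithmetic.

    Used to turn the candidate condition ``k <= ceil(delta*d_z)`` into a
    degree threshold so candidate queries scan degree buckets, not nodes.
    The analytic guess is verified against the actual float ceiling so the
    threshold is always consistent with :func:`opanet.order_galois.ability`.
    """
    if k <= 1:
        return 1
    d = max(1, math.floor((k - 1) / delta) + 1)
    while d > 1 and math.ceil(delta * (d - 1)) >= k:
        d -= 1
    while math.ceil(delta * d) < k:
        d += 1
    return d


# ------------------------------------------------------------------ file I/O

def write_edgelist(net: GrowingNetwork, path: str | Path,
                   metadata: dict | None = None) -> None:
    """Write a TSV edge list (u < v, 0-based) plus a JSON metadata sidecar.

    Isolated nodes are not representable in an edge list, so the sidecar
    always records ``t`` and ``L``; the reader restores node count from it.
    """
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")
    meta = dict(metadata or {})
    meta.setdefault("t", net.t)
    meta.setdefault("L", net.L)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_edgelist(path: str | Path) -> GrowingNetwork:
    """Read a TSV edge list written by :func:`write_edgelist`.

    Nodes are created in id order; the JSON sidecar (if present) supplies the
    total node count so trailing isolated nodes survive the round trip.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    n = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u_s, v_s = line.split("\t")
            u, v = int(u_s), int(v_s)
            edges.append((u, v))
            n = max(n, u + 1, v + 1)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        n = max(n, json.loads(sidecar.read_text()).get("t", n))
    net = GrowingNetwork()
    by_node: dict[int, list[int]] = {}
    for u, v in edges:
        by_node.setdefault(max(u, v), []).append(min(u, v))
    for nid in range(n):
        net._append_node(by_node.get(nid, ()))
    return net
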