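"""Degree preorder, ability map, and executable Galois-connection checks.

Nodes of a growing network are preordered by degree: ``x <= y`` iff
``d_x <= d_y`` (a total preorder; nodes of equal degree are equivalent).  The
*ability map* ``G(x) = ceil(delta * d_x)`` converts realized degree (the
result of link formation) into link-forming ability (its cause), with
conversion coefficient ``delta > 0``.  Restricting the codomain to
``[1, max G(X)]`` there is a lower adjoint ``F`` with

    F(k) <= x  <=>  k <= G(x)

for all nodes x and all k in the interval, i.e. (F, G) is a Galois
connection; concretely F(k) may be any minimum element of the candidate set
``{z : k <= G(z)}``.  This module makes those objects executable and
brute-force-verifies the adjunction law on concrete networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random

from .graph_core import GrowingNetwork, min_degree_for_ability

# delta below 1 is mathematically fine but outside the dense scale-free
# regime the theory covers; callers use this to flag predictions.
THEORY_DELTA_MIN = 1.0
THEORY_DELTA_MAX = math.e


def ability(d: int, delta: float) -> int:
    """Ability value G = ceil(delta * d) of a node of degree ``d``.

    Plain float arithmetic, no epsilon guard: for irrational delta the
    product is never exactly integral, and for rational delta the float rule
    is at least bit-reproducible.  Requires ``d >= 1`` (the growth models
    keep every node connected).
    """
    if d <= 0:
        raise ValueError("ability requires degree >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return math.ceil(delta * d)


def in_theory_regime(delta: float) -> bool:
    """Whether delta lies in [1, e), the regime the exponent theory covers."""
    return THEORY_DELTA_MIN <= delta < THEORY_DELTA_MAX


def candidate_set(net: GrowingNetwork, delta: float, k: int) -> set[int]:
    """All nodes z with ``k <= ability(d_z)``; antitone in k; may be empty."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dmin = min_degree_for_ability(k, delta)
    out: set[int] = set()
    for _, nodes in net.nodes_with_degree_at_least(dmin):
        out.update(nodes)
    return out


def minimum_elements(net: GrowingNetwork, delta: float, k: int) -> set[int]:
    """M_k: the minimum elements (lowest-degree members) of the candidate set.

    Raises ``LookupError`` when the candidate set is empty (no minimum).
    """
    dmin = min_degree_for_ability(k, delta)
    buckets = net.nodes_with_degree_at_least(dmin)
    if not buckets:
        raise LookupError(f"candidate set empty for k={k}")
    return set(buckets[0][1])


@dataclass
class GaloisVerdict:
    """Outcome of brute-force verification of the adjunction law.

    ``holds`` covers the biconditional ``F(k) <= x <=> k <= G(x)`` over every
    (k, x) pair; ``unit_equivalent`` covers the unit law that F(G(x)) is
    equivalent to x (equal degree), which requires delta >= 1.
    """

    holds: bool
    unit_equivalent: bool
    n_checks: int
    counterexamples: list[tuple[int, int]] = field(default_factory=list)


def verify_galois(net: GrowingNetwork, delta: float,
                  rng: Random | None = None) -> GaloisVerdict:
    """Check the Galois-connection laws exhaustively on a network.

    ``F(k)`` is taken as an arbitrary choice from ``minimum_elements(k)``
    (randomized when ``rng`` is given) — the adjunction law must hold for any
    such choice since all minimum elements are equivalent.  The unit law is
    checked only for ``delta >= 1``; below that it can genuinely fail and
    ``unit_equivalent`` is reported as False without counting as a violation
    of ``holds``.
    """
    degs = net.degrees()
    if any(d == 0 for d in degs):
        raise ValueError("verify_galois requires all degrees >= 1")
    kmax = max(ability(d, delta) for d in degs)
    counterexamples: list[tuple[int, int]] = []
    n_checks = 0
    for k in range(1, kmax + 1):
        mins = minimum_elements(net, delta, k)
        f_k = (rng.choice(sorted(mins)) if rng is not None else min(mins))
        d_fk = degs[f_k]
        for x in range(net.t):
            n_checks += 1
            lhs = d_fk <= degs[x]          # F(k) <= _X x
            rhs = k <= ability(degs[x], delta)
            if lhs != rhs:
                counterexamples.append((k, x))
    unit = True
    if delta >= 1:
        for x in range(net.t):
            gx = ability(degs[x], delta)
            fgx = minimum_elements(net, delta, gx)
            if degs[next(iter(fgx))] != degs[x]:
                unit = False
                break
    else:
        unit = False
    return GaloisVerdict(holds=not counterexamples, unit_equivalent=unit,
                         n_checks=n_checks, counterexamples=counterexamples)
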