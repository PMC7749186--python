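"""Rate-equation theory for the OPA-family growth models.

The degree distribution of the proposed (neighborhood) model obeys, per
growth step,

    (t+1) p_k(t+1) = t p_k(t) + a_{k-1} t p_{k-1} - a_k t p_k + b_k,

where a_k is the probability that an existing degree-k node gains a link
from the incoming node and b_k the probability that the incoming node lands
with degree k.  Assuming p_k ~ c k^-gamma over an extended range 1 << k <
M t^(1/gamma), and that a neighbor's degree is independent of its host's,
the self-consistent exponent is the closed form

    gamma = 1 + (1 - ln delta) / (1 + ln delta),

strictly decreasing from 2 (delta = 1) to 1 (delta -> e).  The predecessor
model's exponent instead solves gamma = delta*(gamma-1)^2 + delta^(gamma-1)
(implicit; only its root is computed here); both families lose their
gamma > 1 root at the same critical coefficient delta = e.

This module evaluates the exact per-step probabilities q_k, b_k, d_k, a_k on
finite degree distributions, their closed-form asymptotics, and the
coefficient-matching residual whose zero reproduces the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .netstats import StatCurve

E = math.e


def gamma_new(delta: float) -> float:
    """Closed-form degree exponent of the neighborhood model.

    Defined for any delta > 0; the dense scale-free regime (where the
    derivation holds) is 1 <= delta < e, on which the value decreases
    strictly from 2 to 1.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ld = math.log(delta)
    return 1.0 + (1.0 - ld) / (1.0 + ld)


def _previous_residual(gamma: float, delta: float) -> float:
    return delta * (gamma - 1.0) ** 2 + delta ** (gamma - 1.0) - gamma


def gamma_previous(delta: float) -> float:
    """Nontrivial root gamma > 1 of gamma = delta*(gamma-1)^2 + delta^(gamma-1).

    gamma = 1 always solves the equation and is rejected.  The residual
    f(gamma) = delta*(gamma-1)^2 + delta^(gamma-1) - gamma has
    f'(1) = ln delta - 1 < 0 for delta < e, so f is negative just above 1
    and positive at 4, bracketing the wanted root; Brent's method then
    converges to ~1e-12.  For delta >= e no root above 1 exists.
    """
    if not 0 < delta:
        raise ValueError("delta must be positive")
    lo, hi = 1.0 + 1e-9, 4.0
    flo, fhi = _previous_residual(lo, delta), _previous_residual(hi, delta)
    if flo >= 0 or fhi <= 0:
        raise ValueError(f"no exponent root gamma > 1 at delta={delta} "
                         "(outside the dense scale-free regime)")
    return float(optimize.brentq(_previous_residual, lo, hi, args=(delta,),
                                 xtol=1e-12, rtol=8.9e-16))


def delta_critical(model: str = "new", eps: float = 1e-9) -> float:
    """Supremum of delta admitting an exponent above 1 (= e for both models).

    For the neighborhood model this is analytic (ln delta = 1).  For the
    predecessor it is located numerically: bisect for the largest delta whose
    implicit equation still has a root gamma > 1 + eps.
    """
    if model == "new":
        return E
    if model != "previous":
        raise ValueError(f"unknown model: {model!r}")

    def has_root(d: float) -> bool:
        # a root above 1+eps exists iff the residual is negative there
        return _previous_residual(1.0 + eps, d) < 0

    lo, hi = 2.0, 3.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if has_root(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ------------------------------------------------------- exact rate terms

@dataclass
class RateQuantities:
    """Per-degree step probabilities evaluated exactly on a finite p_k.

    All arrays are indexed by ``k`` (1-based degree, dense grid 1..k_max):
    q[k]: probability the incoming node's virtual degree is k;
    b[k]: probability the incoming node ends with degree k;
    d[k]: probability a *specific* degree-k node's neighborhood is chosen and
          a specific member of it targeted;
    a[k]: probability an existing degree-k node gains a link;
    N[k]: expected number of candidate hubs at ability threshold k.
    """

    delta: float
    t: int
    k: np.ndarray
    q: np.ndarray
    b: np.ndarray
    d: np.ndarray
    a: np.ndarray
    N: np.ndarray


def rate_quantities(p: StatCurve, delta: float, t: int,
                    exact_kplus1: bool = True) -> RateQuantities:
    """Evaluate the per-step probabilities on a finite degree distribution.

    The sums run over the supported degrees l with ability ceil(delta*l)
    below t, the finite-network stand-in for the formal upper limits.
    ``exact_kplus1`` keeps the k+1 denominator in the specific-target
    probability (the asymptotic forms replace it by k).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    degs = np.asarray(p.k, dtype=int)
    probs = np.asarray(p.value, dtype=float)
    if degs.min() < 1:
        raise ValueError("degrees must be >= 1")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("input distribution must be normalized")
    abil = np.ceil(delta * degs).astype(int)
    # evaluate on 1..K where K covers both the ability range (support of q)
    # and the degree support (indices needed for the neighbor term of a_k)
    kmax = max(int(abil.max()), int(degs.max()))
    ks = np.arange(1, kmax + 1)

    # q_k = sum over l with k <= ceil(delta l) < t of p_l / ceil(delta l)
    in_t = abil < t
    q = np.zeros(kmax + 2)
    Np = np.zeros(kmax + 2)   # N_k / t = sum of p_l over the same range
    for k in ks:
        sel = in_t & (abil >= k)
        q[k] = float(np.sum(probs[sel] / abil[sel]))
        Np[k] = float(np.sum(probs[sel]))
    N = t * Np

    # b_k: land-with-degree-k probability (full pool >= k, or truncation when
    # the pool {z : k <= G(z)} is smaller than the virtual degree l)
    b = np.zeros(kmax + 2)
    for k in ks:
        tail_deg = float(np.sum(probs[(degs >= k) & (degs < t)]))
        first = q[k] * tail_deg / Np[k] if Np[k] > 0 else 0.0
        p_k = float(probs[degs == k].sum())
        second = 0.0
        if p_k > 0:
            hi = math.ceil(delta * k)
            for l in range(k + 1, min(hi, kmax) + 1):
                if q[l] == 0:
                    continue
                if Np[l] <= 0:
                    raise ValueError("empty candidate pool inside a required sum")
                second += q[l] * p_k / Np[l]
        b[k] = first + second
    # d_k: specific neighborhood + specific member
    d = np.zeros(kmax + 2)
    for k in ks:
        denom = (k + 1) if exact_kplus1 else k
        acc = 0.0
        for l in range(1, k + 1):
            if q[l] == 0:
                continue
            if N[l] <= 0:
                raise ValueError("empty candidate pool inside a required sum")
            acc += q[l] / N[l] * (l / denom)
        hi = math.ceil(delta * k)
        for l in range(k + 1, min(hi, kmax) + 1):
            if q[l] == 0:
                continue
            if N[l] <= 0:
                raise ValueError("empty candidate pool inside a required sum")
            acc += q[l] / N[l]
        d[k] = acc

    # a_k = d_k + k * sum_k' p(k'|k) d_k'   with p(k'|k) = k' p_k' / <k>
    mean_k = float(np.sum(degs * probs))
    nbr_term = float(np.sum(degs * probs * d[degs])) / mean_k
    a = np.zeros(kmax + 2)
    for k in ks:
        a[k] = d[k] + k * nbr_term

    return RateQuantities(delta=delta, t=t, k=ks, q=q[1:kmax + 1],
                          b=b[1:kmax + 1], d=d[1:kmax + 1],
                          a=a[1:kmax + 1], N=N[1:kmax + 1])


def asymptotics(gamma: float, delta: float, c: float, t: int, k: int,
                exact_kplus1: bool = False) -> tuple[float, float, float, float]:
    """Closed-form large-k, large-t forms of (q_k, b_k, d_k, a_k).

    q_k ~ (c delta^(gamma-1)/gamma) k^-gamma
    b_k ~ (c (1+(gamma-1) ln delta)/gamma) k^-gamma
    d_k ~ (gamma-1)(1+ln delta)/(gamma t)
    a_k ~ (gamma-1)(1+ln delta) k/(gamma t)   (k+1 with exact_kplus1)
    """
    ld = math.log(delta)
    q = c * delta ** (gamma - 1) / gamma * k ** (-gamma)
    b = c * (1 + (gamma - 1) * ld) / gamma * k ** (-gamma)
    d = (gamma - 1) * (1 + ld) / (gamma * t)
    a = d * ((k + 1) if exact_kplus1 else k)
    return q, b, d, a


def consistency_residual(gamma: float, delta: float) -> float:
    """Coefficient mismatch in the continuum rate equation.

    Substituting p_k = c k^-gamma and the asymptotic a_k, b_k into
    d/dk (a_k t p_k) = b_k - p_k and comparing the k^-gamma coefficients
    leaves (gamma-1)(1+ln delta) + (ln delta - 1), which vanishes exactly at
    the closed-form exponent.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    ld = math.log(delta)
    return (gamma - 1.0) * (1.0 + ld) + (ld - 1.0)


def predicted_link_growth(t: float, gamma: float) -> float:
    """Dense-growth law for the link count, up to a prefactor:
    t ln t at gamma = 2, t^(2/gamma) for 1 < gamma < 2."""
    if not 1 < gamma <= 2:
        raise ValueError("gamma must lie in (1, 2]")
    if t < 2:
        raise ValueError("t must be >= 2")
    if gamma == 2:
        return t * math.log(t)
    return t ** (2.0 / gamma)


def truncated_power_law(gamma: float, k_max: int) -> StatCurve:
    """Synthetic p_k proportional to k^-gamma on 1..k_max (normalized).

    The normalization c comes from the truncated support; it is an input to
    the theory routines, never fitted.
    """
    ks = np.arange(1, k_max + 1)
    w = ks.astype(float) ** (-gamma)
    return StatCurve(k=ks, value=w / w.sum(), count=np.zeros_like(ks, dtype=float),
                     kind="pk")
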