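"""Closed-form structural theory of bit-string similarity networks.

For a network built on ``N`` distinct uniform-random bit strings of length
``B``, linked whenever their Hamming distance is at most ``G``, the
connectivity is governed by a single parameter

    mu = M_G / (M - 1),    M = 2**B,    M_G = sum_{H=1}^{G} C(B, H),

the probability that a uniformly chosen *other* string falls within
distance ``G`` of a given one.  The degree distribution is then binomial
with ``N - 1`` trials and success probability ``mu`` — identical to an
Erdos-Renyi graph with the same link density — and the generating-function
formalism for random graphs gives a giant component above the critical
density ``mu_c = 1/(N - 2)``.

Clustering, in contrast, is *not* Erdos-Renyi-like: the Hamming metric
correlates neighborhoods (two neighbors of a node at distances ``H1`` and
``H2`` cannot be farther than ``H1 + H2`` from each other), and the mean
clustering coefficient follows from exact combinatorics over the distance
profile of a neighborhood, independently of ``N``.

All combinatorial quantities are evaluated in exact integer/rational
arithmetic (``math.comb`` + ``fractions.Fraction``) and converted to float
only on return; C(100, 50) and friends overflow any fixed-width integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np
from scipy import optimize, stats

__all__ = [
    "M_G",
    "mu",
    "mu_exact",
    "degree_pmf",
    "mean_degree",
    "mu_critical",
    "solve_giant",
    "solve_giant_largeN",
    "richness_approx",
    "neighbor_pair_prob",
    "clustering_C",
    "TheorySummary",
    "summarize",
]


class GiantComponentError(RuntimeError):
    """Raised when the giant-component fixed point cannot be bracketed or
    solved to tolerance."""


def M_G(B: int, G: int) -> int:
    """Number of strings within Hamming distance ``G`` of a fixed string,
    excluding the string itself: ``sum_{H=1}^{G} C(B, H)`` (exact int)."""
    if not 1 <= G <= B:
        raise ValueError(f"G must be in [1, B]; got G={G}, B={B}")
    return sum(math.comb(B, H) for H in range(1, G + 1))


def mu_exact(B: int, G: int) -> Fraction:
    """Connectivity parameter ``mu = M_G / (2**B - 1)`` as an exact rational."""
    return Fraction(M_G(B, G), 2**B - 1)


def mu(B: int, G: int) -> float:
    """Connectivity parameter ``mu`` as a float in (0, 1]."""
    return float(mu_exact(B, G))


def degree_pmf(N: int, mu: float) -> np.ndarray:
    """Degree distribution ``g_k = C(N-1, k) mu^k (1-mu)^(N-1-k)``,
    k = 0..N-1, as a length-``N`` array."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    return stats.binom.pmf(np.arange(N), N - 1, mu)


def mean_degree(N: int, mu: float) -> float:
    """Mean degree ``z = mu (N - 1)``."""
    return mu * (N - 1)


def mu_critical(N: int) -> float:
    """Critical connectivity ``mu_c = 1/(N - 2)`` for the appearance of a
    giant component.  Requires ``N >= 3``."""
    if N <= 2:
        raise ValueError("mu_critical requires N >= 3")
    return 1.0 / (N - 2)


def _bisect_smallest_root(f, tol: float) -> float:
    """Smallest root of ``f`` in [0, 1], given ``f(0) <= 0`` and ``f(1) = 0``.

    If no sign change occurs below ``1 - 1e-9`` the root is
    indistinguishable from the trivial fixed point and 1.0 is returned
    (this happens only asymptotically close to criticality)."""
    lo, hi = 0.0, 1.0 - 1e-9
    flo = f(lo)
    if flo == 0.0:
        return 0.0
    if f(hi) <= 0.0:
        return 1.0
    try:
        return float(optimize.brentq(f, lo, hi, xtol=tol, maxiter=200))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise GiantComponentError(str(exc)) from exc


def solve_giant(mu: float, N: int, tol: float = 1e-12) -> tuple[float, float]:
    """Giant-component solution at finite ``N``.

    Solves ``u = (1 - mu + mu*u)**(N-2)`` for the smallest fixed point
    ``u`` in [0, 1]; ``u`` is the probability that an edge does not lead to
    the giant component.  Returns ``(u, S)`` with
    ``S = 1 - u**((N-1)/(N-2))`` the expected giant-component fraction.
    Below the critical density (``mu <= 1/(N-2)``) the only fixed point is
    ``u = 1`` and ``S = 0``.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if N < 3:
        raise ValueError("solve_giant requires N >= 3")
    if mu <= mu_critical(N):
        return 1.0, 0.0
    if mu == 1.0:
        return 0.0, 1.0
    n_exp = N - 2

    def f(u: float) -> float:
        return u - (1.0 - mu + mu * u) ** n_exp

    u = _bisect_smallest_root(f, tol)
    S = 1.0 - u ** ((N - 1) / (N - 2))
    return u, S


def solve_giant_largeN(ratio: float, tol: float = 1e-12) -> tuple[float, float]:
    """Large-``N`` giant-component solution as a function of ``mu/mu_c``.

    Solves ``u = exp(-ratio * (1 - u))``; returns ``(u, S)`` with
    ``S = 1 - u``.  ``S`` depends on (N, B, G) only through the ratio, which
    for large networks equals the mean degree ``z``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio <= 1.0:
        return 1.0, 0.0

    def f(u: float) -> float:
        return u - math.exp(-ratio * (1.0 - u))

    u = _bisect_smallest_root(f, tol)
    return u, 1.0 - u


def richness_approx(ratio: float) -> float:
    """Small-density approximation to the richness R = (#components)/N.

    Counts isolated nodes (``exp(-ratio)`` per node) and assumes every
    remaining node sits in a component of size two:
    ``R = exp(-ratio) + (1 - exp(-ratio))/2``, which linearizes to
    ``1 - ratio/2`` for small ratios.  Accurate up to ``mu/mu_c ~ 1``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    e = math.exp(-ratio)
    return e + (1.0 - e) / 2.0


def _comb0(n: int, k: int) -> int:
    """Binomial coefficient with the convention C(n, k) = 0 outside 0<=k<=n."""
    if k < 0 or k > n:
        return 0
    return math.comb(n, k)


def _pair_prob_exact(
    B: int, H1: int, H2: int, G: int, include_identical: bool
) -> Fraction:
    """Exact probability that two strings at distances H1 and H2 from a
    common reference are within distance G of each other.

    The mutual distance takes the values ``g = H1 + H2 - 2h`` where ``h``
    counts the overlapping differing positions; the number of placements at
    fixed ``h`` is ``C(H1, h) * C(B - H1, H2 - h)`` (out of ``C(B, H2)``
    total).  ``g <= G`` selects ``h >= h0 = max(0, floor((H1+H2-G+1)/2))``.

    With ``include_identical=True`` the count is taken over *all* strings at
    distance H2, including (when H1 == H2) the reference's neighbor itself,
    whose mutual distance is g = 0.  With ``include_identical=False`` that
    coincident-pair outcome is removed from both numerator and denominator,
    which is the relevant conditioning for networks whose nodes are
    distinct.
    """
    if not (1 <= H1 <= B and 1 <= H2 <= B):
        raise ValueError("H1 and H2 must lie in [1, B]")
    if not 1 <= G <= B:
        raise ValueError("G must be in [1, B]")
    if H1 > G or H2 > G:
        raise ValueError("H1 and H2 must not exceed G (both strings are neighbors)")
    h0 = max(0, (H1 + H2 - G + 1) // 2)
    num = sum(_comb0(H1, h) * _comb0(B - H1, H2 - h) for h in range(h0, H1 + 1))
    den = math.comb(B, H2)
    if not include_identical and H1 == H2:
        num -= 1  # the h = H1 = H2 placement is the coincident pair, g = 0
        den -= 1
    if den == 0:
        raise ValueError("no admissible pair exists for these parameters")
    return Fraction(num, den)


def neighbor_pair_prob(
    B: int, H1: int, H2: int, G: int, include_identical: bool = True
) -> float:
    """Probability that two neighbors of a node, at Hamming distances ``H1``
    and ``H2`` from it, are within distance ``G`` of each other.

    Symmetric in ``(H1, H2)``.  The default counts the coincident
    (identical-string) placement as a zero-distance success, matching the
    bare combinatorial formula; pass ``include_identical=False`` to
    condition on the two neighbors being distinct strings, as they
    necessarily are in a similarity network.
    """
    return float(_pair_prob_exact(B, H1, H2, G, include_identical))


def clustering_C(B: int, G: int, include_identical: bool = False) -> float:
    """Mean clustering coefficient of a large similarity network, exact and
    independent of ``N``.

    A neighbor of a node lies at distance ``H`` with probability
    ``C(B, H)/M_G``; the mean local clustering is the probability that two
    uniformly chosen *distinct* neighbors are themselves within distance
    ``G``, averaged over the distance profile:

        C = sum_{H1,H2=1}^{G} w(H1,H2) P(H1,H2)

    with weights normalized over the ``M_G (M_G - 1)`` ordered distinct
    neighbor pairs (default), or over all ``M_G**2`` ordered pairs including
    coincident ones when ``include_identical=True``.  The two variants
    differ by O(1/M_G); only the distinct-pair version reproduces the
    clustering of networks built on distinct strings at small ``G`` (at
    ``G = 1`` coincident pairs would contribute a spurious ``1/B``).
    """
    if not 1 <= G <= B:
        raise ValueError(f"G must be in [1, B]; got G={G}, B={B}")
    mg = M_G(B, G)
    total = Fraction(0)
    if include_identical:
        for H1 in range(1, G + 1):
            w1 = math.comb(B, H1)
            for H2 in range(1, G + 1):
                w = w1 * math.comb(B, H2)
                total += w * _pair_prob_exact(B, H1, H2, G, True)
        return float(total / mg**2)
    if mg < 2:
        return float("nan")  # a node can have at most one neighbor
    for H1 in range(1, G + 1):
        w1 = math.comb(B, H1)
        for H2 in range(1, G + 1):
            w = w1 * (math.comb(B, H2) - (1 if H1 == H2 else 0))
            if w:
                total += w * _pair_prob_exact(B, H1, H2, G, False)
    return float(total / (mg * (mg - 1)))


@dataclass(frozen=True)
class TheorySummary:
    """All closed-form structural predictions for one (N, B, G) triple."""

    N: int
    B: int
    G: int
    MG: int
    mu: float
    mu_c: float
    ratio: float  # mu / mu_c
    z: float  # mean degree mu * (N - 1)
    u: float
    S: float  # giant-component fraction (finite-N solver)
    C: float  # mean clustering (distinct-pair convention)
    R_approx: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(N: int, B: int, G: int) -> TheorySummary:
    """Evaluate the full analytic summary for one parameter triple."""
    if N < 2 or (B <= 62 and N > 2**B):
        raise ValueError("require 2 <= N <= 2**B")
    m = mu(B, G)
    mc = mu_critical(N)
    u, S = solve_giant(m, N)
    return TheorySummary(
        N=N,
        B=B,
        G=G,
        MG=M_G(B, G),
        mu=m,
        mu_c=mc,
        ratio=m / mc,
        z=mean_degree(N, m),
        u=u,
        S=S,
        C=clustering_C(B, G),
        R_approx=richness_approx(m / mc),
    )
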