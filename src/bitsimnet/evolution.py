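"""Constant-size neutral evolution of a bit-string population.

The model: a population of ``N`` bit strings of length ``B``, initially all
identical (all-zero).  Each elementary step picks a parent uniformly at
random, creates a child by flipping one uniformly chosen bit of the parent,
and inserts the child in place of a uniformly chosen member ("random
death").  There is no fitness and no selection — drift plus mutation only —
so the population diversifies until the distribution of pairwise Hamming
distances matches that of a fully random string set,

    f_H^random = 2**(-B) * C(B, H).

Convergence is tracked by the squared-difference divergence

    D(T) = sum_H (f_H(T) - f_H^random)**2,

plotted against the rescaled time ``T / (N*B)`` (one unit = the mean
waiting time for any given bit in the population to mutate).  D decays
exponentially at a rate roughly independent of N and B in these units and
then plateaus at a fluctuation floor that shrinks as 1/N.

Two variants of the death rule are provided: the child may replace its own
parent ("replace-parent"), or the child may be produced by single-point
recombination of two distinct parents before mutation ("recombination").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .bitstrings import pairwise_hamming

__all__ = [
    "Population",
    "VARIANTS",
    "init_population",
    "evolve_step",
    "evolve",
    "hamming_frequencies",
    "random_reference",
    "divergence",
    "initial_divergence",
    "run_evolution",
]

VARIANTS = ("random-death", "replace-parent", "recombination")


@dataclass
class Population:
    """Ordered multiset of ``N`` bit strings of common length ``B``.

    ``members`` is an ``(N, B)`` uint8 array; duplicates are allowed (and
    are the norm early in an evolution run).  ``step_count`` records the
    number of elementary birth/death events applied so far.
    """

    members: np.ndarray
    step_count: int = 0

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.uint8)
        if self.members.ndim != 2:
            raise ValueError("members must be an (N, B) array")

    @property
    def N(self) -> int:
        return self.members.shape[0]

    @property
    def B(self) -> int:
        return self.members.shape[1]

    def copy(self) -> "Population":
        return Population(self.members.copy(), self.step_count)


def init_population(N: int, B: int) -> Population:
    """The initial population: ``N`` copies of the all-zero string."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    return Population(np.zeros((N, B), dtype=np.uint8), 0)


def _advance(
    members: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    variant: str,
    exclude_parent: bool,
) -> None:
    """Apply ``n_steps`` elementary events in place.  Random draws are taken
    in chunks for speed; the draw order is fixed so runs replay exactly."""
    N, B = members.shape
    chunk = 16384
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        parents = rng.integers(0, N, size=m)
        if variant == "recombination":
            parents2 = rng.integers(0, N, size=m)
            cuts = rng.integers(1, B, size=m) if B > 1 else np.zeros(m, dtype=int)
        if variant == "replace-parent":
            victims = parents
        else:
            victims = rng.integers(0, N, size=m)
        bits = rng.integers(0, B, size=m)
        for t in range(m):
            p = int(parents[t])
            v = int(victims[t])
            if exclude_parent and variant != "replace-parent":
                while v == p:
                    v = int(rng.integers(0, N))
            if variant == "recombination":
                q = int(parents2[t])
                while q == p:
                    q = int(rng.integers(0, N))
                cut = int(cuts[t])
                child = members[p].copy()
                child[cut:] = members[q, cut:]
                members[v] = child
            else:
                members[v] = members[p]
            members[v, bits[t]] ^= 1
        done += m


def evolve_step(
    pop: Population,
    rng: np.random.Generator | int | None,
    variant: str = "random-death",
    exclude_parent: bool = False,
) -> Population:
    """Apply one birth/death event and return the updated population.

    The population is modified in place (and also returned) with
    ``step_count`` incremented; pass ``pop.copy()`` to keep the original.
    ``exclude_parent=True`` redraws the victim until it differs from the
    parent — the model's behavior is insensitive to this choice.
    """
    return evolve(pop, 1, rng, variant=variant, exclude_parent=exclude_parent)


def evolve(
    pop: Population,
    n_steps: int,
    rng: np.random.Generator | int | None,
    variant: str = "random-death",
    exclude_parent: bool = False,
) -> Population:
    """Apply ``n_steps`` elementary events in place; returns ``pop``."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = np.random.default_rng(rng)
    _advance(pop.members, n_steps, rng, variant, exclude_parent)
    pop.step_count += n_steps
    return pop


def hamming_frequencies(pop: Population | np.ndarray) -> np.ndarray:
    """Frequencies f_H of each Hamming distance H = 0..B over all
    ``N(N-1)/2`` unordered member pairs (duplicate pairs count at H = 0)."""
    members = pop.members if isinstance(pop, Population) else np.asarray(pop)
    N, B = members.shape
    if N < 2:
        raise ValueError("need at least two members to form pairs")
    dist = pairwise_hamming(members)
    iu, ju = np.triu_indices(N, k=1)
    counts = np.bincount(dist[iu, ju], minlength=B + 1)
    return counts / counts.sum()


def random_reference(B: int) -> np.ndarray:
    """Expected Hamming-distance frequencies for a random string set:
    ``f_H = 2**(-B) * C(B, H)``.  Exact rationals internally, so the array
    sums to 1 to float precision even for large B."""
    if B < 1:
        raise ValueError("B must be >= 1")
    denom = 2**B
    return np.array(
        [float(Fraction(math.comb(B, H), denom)) for H in range(B + 1)]
    )


def divergence(f: np.ndarray, fref: np.ndarray) -> float:
    """Squared-difference divergence ``sum_H (f_H - fref_H)**2`` between two
    Hamming-distance histograms on the same support."""
    f = np.asarray(f, dtype=float)
    fref = np.asarray(fref, dtype=float)
    if f.shape != fref.shape:
        raise ValueError(f"histogram length mismatch: {f.shape} vs {fref.shape}")
    d = f - fref
    return float(d @ d)


def initial_divergence(B: int) -> float:
    """Closed form for D at T = 0, when every pair is at distance zero:
    ``(1 - 2**-B)**2 + 2**(-2B) * (C(2B, B) - 1)``.

    Follows from f = delta_{H,0} and the binomial identity
    ``sum_H C(B, H)**2 = C(2B, B)``.  Exact rational arithmetic.
    """
    x = Fraction(1, 2**B)
    val = (1 - x) ** 2 + x**2 * (math.comb(2 * B, B) - 1)
    return float(val)


def run_evolution(
    N: int,
    B: int,
    total_steps: int,
    record_every: int | None = None,
    variant: str = "random-death",
    rng: np.random.Generator | int | None = None,
    exclude_parent: bool = False,
) -> pd.DataFrame:
    """Run the neutral-evolution model and record the divergence trajectory.

    Returns a DataFrame with columns ``step``, ``rescaled_time``
    (= step / (N*B)) and ``D``; the state at T = 0 is always recorded, and
    so is the final step.  ``record_every`` defaults to ``N*B // 100``
    (at least 1): recomputing the O(N^2) pair histogram dominates the cost,
    so it is done only at record points.
    """
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    rng = np.random.default_rng(rng)
    if record_every is None:
        record_every = max(1, (N * B) // 100)
    fref = random_reference(B)
    pop = init_population(N, B)
    rows = [(0, 0.0, divergence(hamming_frequencies(pop), fref))]
    step = 0
    while step < total_steps:
        n = min(record_every, total_steps - step)
        evolve(pop, n, rng, variant=variant, exclude_parent=exclude_parent)
        step += n
        rows.append(
            (step, step / (N * B), divergence(hamming_frequencies(pop), fref))
        )
    return pd.DataFrame(rows, columns=["step", "rescaled_time", "D"])
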