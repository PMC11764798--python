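"""Bit-string primitives: representation, Hamming metric, sampling, enumeration.

A bit string of length ``B`` models a genome (or a cultural/linguistic
profile) as an ordered array of binary variables.  Throughout the package a
single string is a 1-D ``numpy`` array of 0/1 values and a *set* of N strings
is a 2-D ``(N, B)`` array of dtype ``uint8``.  All similarity notions reduce
to the Hamming distance — the number of positions at which two equal-length
strings differ.

Exhaustive enumeration helpers (:func:`enumerate_within`,
:func:`all_strings`) are intended for small ``B`` where the full space of
``2**B`` strings is tractable; they serve as brute-force oracles for the
analytic results elsewhere in the package.
"""

from __future__ import annotations

import math
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "as_bits",
    "hamming",
    "pairwise_hamming",
    "count_at_distance",
    "all_strings",
    "enumerate_within",
    "random_distinct_set",
    "read_string_set",
    "write_string_set",
]


def as_bits(obj: str | Sequence[int] | np.ndarray) -> np.ndarray:
    """Coerce ``obj`` to a 1-D uint8 array of 0/1 values.

    Accepts a text form like ``"010011"``, any integer sequence, or an
    ndarray.  Raises ``ValueError`` on characters/values other than 0 and 1
    or on an empty string.
    """
    if isinstance(obj, str):
        if not obj:
            raise ValueError("bit string must have length B >= 1")
        if set(obj) - {"0", "1"}:
            raise ValueError(f"invalid characters in bit string: {obj!r}")
        return np.frombuffer(obj.encode("ascii"), dtype=np.uint8) - ord("0")
    bits = np.asarray(obj, dtype=np.uint8)
    if bits.ndim != 1 or bits.size == 0:
        raise ValueError("bit string must be a nonempty 1-D array")
    if np.any(bits > 1):
        raise ValueError("bit string entries must be 0 or 1")
    return bits


def hamming(a, b) -> int:
    """Hamming distance between two equal-length bit strings.

    Counts the positions where the strings differ; an integer in
    ``[0, B]``.  Raises ``ValueError`` on a length mismatch.
    """
    a = as_bits(a)
    b = as_bits(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def pairwise_hamming(strings: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distance matrix for an ``(N, B)`` array of strings.

    Uses the inner-product identity ``H(a, b) = |a| + |b| - 2 a.b`` so the
    N x N matrix comes out of a single BLAS call; entries are exact (values
    never exceed B, far below float32 integer precision).
    """
    x = np.ascontiguousarray(strings, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError("expected an (N, B) array of bit strings")
    ones = x.sum(axis=1)
    gram = x @ x.T
    dist = ones[:, None] + ones[None, :] - 2.0 * gram
    return np.rint(dist).astype(np.int32)


def count_at_distance(B: int, H: int) -> int:
    """Number of strings of length ``B`` at Hamming distance exactly ``H``
    from any fixed string: the binomial coefficient C(B, H), exact."""
    if not 0 <= H <= B:
        raise ValueError(f"H must be in [0, B]; got H={H}, B={B}")
    return math.comb(B, H)


def all_strings(B: int) -> np.ndarray:
    """The complete ``(2**B, B)`` array of all length-``B`` strings, in
    increasing integer order (most significant bit first).  Small ``B`` only."""
    if B < 1:
        raise ValueError("B must be >= 1")
    codes = np.arange(2**B, dtype=np.uint64)
    shifts = np.arange(B - 1, -1, -1, dtype=np.uint64)
    return ((codes[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def enumerate_within(b, G: int) -> np.ndarray:
    """All strings at Hamming distance 1..G from ``b`` (``b`` itself excluded).

    The number of rows equals ``sum_{H=1}^{G} C(B, H)`` independently of
    ``b``.  Intended for small ``B``; the output grows combinatorially.
    """
    b = as_bits(b)
    B = b.size
    if not 1 <= G <= B:
        raise ValueError(f"G must be in [1, B]; got G={G}, B={B}")
    out = []
    for H in range(1, G + 1):
        for pos in combinations(range(B), H):
            s = b.copy()
            s[list(pos)] ^= 1
            out.append(s)
    return np.array(out, dtype=np.uint8)


def random_distinct_set(
    N: int, B: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample ``N`` distinct bit strings of length ``B`` uniformly without
    replacement from the ``2**B`` possibilities.

    Two regimes: when the requested sample is a large fraction of a small
    space, the full enumeration is sampled directly; otherwise strings are
    drawn by rejection (uniformity is preserved because duplicates are
    discarded irrespective of their value).

    Parameters
    ----------
    rng : numpy Generator, int seed, or None.
    """
    rng = np.random.default_rng(rng)
    if N < 1:
        raise ValueError("N must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B <= 62 and N > 2**B:
        raise ValueError(f"cannot draw {N} distinct strings of length {B}")

    if B <= 24 and N > 2 ** (B - 1):
        codes = rng.choice(2**B, size=N, replace=False)
        return all_strings(B)[codes]

    seen: set[bytes] = set()
    rows: list[np.ndarray] = []
    while len(rows) < N:
        batch = rng.integers(0, 2, size=(max(64, N - len(rows)), B), dtype=np.uint8)
        for row in batch:
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                rows.append(row)
                if len(rows) == N:
                    break
    return np.array(rows, dtype=np.uint8)


def write_string_set(path: str | Path, strings: np.ndarray) -> None:
    """Write a set of bit strings as plain text, one 0/1 string per line."""
    strings = np.asarray(strings, dtype=np.uint8)
    with open(path, "w") as fh:
        for row in strings:
            fh.write("".join("1" if v else "0" for v in row) + "\n")


def read_string_set(path: str | Path) -> np.ndarray:
    """Read a plain-text bit-string set (one 0/1 string per line).

    Validates a uniform length and the {0, 1} alphabet; blank lines are
    ignored.  Returns an ``(N, B)`` uint8 array.
    """
    rows = []
    length = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if set(line) - {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: invalid characters {line!r}")
            if length is None:
                length = len(line)
            elif len(line) != length:
                raise ValueError(
                    f"{path}:{lineno}: length {len(line)} != {length} of first string"
                )
            rows.append(as_bits(line))
    if not rows:
        raise ValueError(f"{path}: no bit strings found")
    return np.array(rows, dtype=np.uint8)
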