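"""Analytic sizing of the counting sketch.

With N distinct k-mers hashed into Z tables of H counters each, the
probability that a fresh k-mer collides in every table — the expected false
positive rate of retrieval — is

    f = (1 - exp(-N/H)) ** Z

Two sizing problems are solved here: the optimal Z for a fixed memory
budget M = Z*H (minimised at Z* = ln 2 * M/N), and the minimal memory for a
target f (at the optimum each table's collision rate is 1/2, so Z =
ceil(log2(1/f)) and H = N / -ln(1 - f**(1/Z))).  Prime table sizes are
selected by deterministic trial division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SketchParams",
    "SizingError",
    "fp_rate",
    "optimal_z_for_memory",
    "params_for_target_fp",
    "is_prime",
    "primes_at_or_below",
    "primes_at_or_above",
]


class SizingError(ValueError):
    """Raised for invalid sizing parameters."""


@dataclass(frozen=True)
class SketchParams:
    """Resolved sketch geometry.

    Attributes
    ----------
    n_distinct:
        Expected number of distinct k-mers N.
    z:
        Number of hash tables Z.
    h:
        Counters per table H.
    fp:
        Expected false positive rate (1 - exp(-N/H)) ** Z.
    memory:
        Total counters Z * H (one byte each).
    """

    n_distinct: int
    z: int
    h: int
    fp: float
    memory: int


def fp_rate(n_distinct: float, h: float, z: int) -> float:
    """Expected false positive rate (1 - exp(-N/H)) ** Z."""
    if h <= 0:
        raise SizingError(f"table size must be positive, got {h}")
    if z < 1:
        raise SizingError(f"table count must be >= 1, got {z}")
    if n_distinct < 0:
        raise SizingError(f"distinct k-mer count must be >= 0, got {n_distinct}")
    return (1.0 - math.exp(-n_distinct / h)) ** z


def optimal_z_for_memory(memory: float, n_distinct: float) -> int:
    """Integer Z minimising fp_rate(N, M/Z, Z) for a fixed budget of M counters.

    The continuous optimum is Z* = ln 2 * M/N; the returned value is
    whichever of the adjacent integers gives the lower false positive rate.
    """
    if memory <= 0 or n_distinct <= 0:
        raise SizingError("memory and n_distinct must be positive")
    z_star = math.log(2) * memory / n_distinct
    lo = max(1, math.floor(z_star))
    candidates = {lo, lo + 1}
    return min(candidates, key=lambda z: (fp_rate(n_distinct, memory / z, z), z))


def params_for_target_fp(fp_target: float, n_distinct: int) -> SketchParams:
    """Minimal-memory geometry achieving a target false positive rate.

    Z = ceil(log(f) / log(1/2)) (so each table runs at collision rate at
    most 1/2) and H = ceil(N / -ln(1 - f**(1/Z))).  The returned geometry
    always satisfies ``fp_rate(N, H, Z) <= fp_target``.
    """
    if not 0.0 < fp_target < 1.0:
        raise SizingError(f"fp_target must be in (0, 1), got {fp_target}")
    if n_distinct <= 0:
        raise SizingError(f"n_distinct must be positive, got {n_distinct}")
    z = max(1, math.ceil(math.log(fp_target) / math.log(0.5)))
    per_table = fp_target ** (1.0 / z)
    h = math.ceil(n_distinct / -math.log1p(-per_table))
    return SketchParams(
        n_distinct=n_distinct,
        z=z,
        h=h,
        fp=fp_rate(n_distinct, h, z),
        memory=z * h,
    )


def is_prime(n: int) -> bool:
    """Deterministic primality by trial division (6k+-1 stepping)."""
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0 or n % 3 == 0:
        return False
    i = 5
    while i * i <= n:
        if n % i == 0 or n % (i + 2) == 0:
            return False
        i += 6
    return True


def primes_at_or_below(target: int, count: int) -> list[int]:
    """The ``count`` largest distinct primes <= target, strictly descending."""
    if target < 2:
        raise SizingError(f"no primes at or below {target}")
    if count < 1:
        raise SizingError(f"count must be >= 1, got {count}")
    primes: list[int] = []
    n = target
    while n >= 2 and len(primes) < count:
        if is_prime(n):
            primes.append(n)
        n -= 1
    if len(primes) < count:
        raise SizingError(
            f"only {len(primes)} primes at or below {target}, need {count}"
        )
    return primes


def primes_at_or_above(start: int, count: int) -> list[int]:
    """The ``count`` smallest distinct primes >= start, returned descending.

    Used when a sketch is sized for a target false positive rate: every
    table is at least as large as the analytic H, so the achieved rate can
    only be lower than the target.
    """
    if count < 1:
        raise SizingError(f"count must be >= 1, got {count}")
    primes: list[int] = []
    n = max(2, start)
    while len(primes) < count:
        if is_prime(n):
            primes.append(n)
        n += 1
    return primes[::-1]
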