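"""Hypergeometric gene-set overlap testing.

Given a universe of N eligible transcripts (typically those passing the
detection filter), a screen hit set of size K and a reference set of
size n sharing k members, the chance of an overlap at least as large
under random sampling without replacement is the upper tail of
Hypergeometric(N, K, n):

    p_upper = P(X >= k) = sum_{j=k..min(K,n)} C(K,j) C(N-K,n-j) / C(N,n)

The point probability P(X = k) is reported alongside, because
``hgt(N, K, n, k)``-style printouts from some toolchains correspond to
the point mass rather than the tail; for the overlaps this test is used
on the two agree in magnitude but differ at the second significant
figure. Both are computed in log space via scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "hypergeometric_upper",
    "hypergeometric_point",
    "overlap_test",
]


@dataclass
class OverlapResult:
    """Hypergeometric test of two gene sets against a universe."""

    universe_size: int      # N
    set_a_size: int         # K
    set_b_size: int         # n
    overlap: int            # k
    overlap_fraction_of_b: float  # 100 * k / n, percent
    p_upper: float          # P(X >= k)
    p_point: float          # P(X = k)

    def summary(self) -> str:
        return (
            f"hgt(N={self.universe_size}, K={self.set_a_size}, "
            f"n={self.set_b_size}, k={self.overlap}): "
            f"overlap {self.overlap}/{self.set_b_size}="
            f"{self.overlap_fraction_of_b:.1f}%, "
            f"P(X>={self.overlap}) = {self.p_upper:.1e}, "
            f"P(X={self.overlap}) = {self.p_point:.1e}"
        )


def _check_args(N: int, K: int, n: int, k: int) -> None:
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N:
        raise ValueError(f"K={K} exceeds universe size N={N}")
    if n > N:
        raise ValueError(f"n={n} exceeds universe size N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")


def hypergeometric_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n)."""
    _check_args(N, K, n, k)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeometric_point(N: int, K: int, n: int, k: int) -> float:
    """Point probability P(X = k), X ~ Hypergeometric(N, K, n)."""
    _check_args(N, K, n, k)
    return float(hypergeom.pmf(k, N, K, n))


def overlap_test(
    set_a: list[str], set_b: list[str], universe: list[str]
) -> OverlapResult:
    """Test whether two gene sets overlap more than chance within a universe.

    Labels outside the universe are dropped (with a logged count) before
    counting the intersection.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    a = set(set_a) & uni
    b = set(set_b) & uni
    dropped = (len(set(set_a)) - len(a)) + (len(set(set_b)) - len(b))
    if dropped:
        logger.warning("dropped %d set labels outside the universe", dropped)
    if not a or not b:
        raise ValueError("both gene sets must be non-empty within the universe")
    k = len(a & b)
    N, K, n = len(uni), len(a), len(b)
    return OverlapResult(
        universe_size=N,
        set_a_size=K,
        set_b_size=n,
        overlap=k,
        overlap_fraction_of_b=100.0 * k / n,
        p_upper=hypergeometric_upper(N, K, n, k),
        p_point=hypergeometric_point(N, K, n, k),
    )
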