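"""Hypergeometric gene-set overlap statistics with BH correction.

The overlap of a set A (size K) and a set B (size n) inside a universe of N
genes is scored by the upper-tail hypergeometric probability
P(X >= k) = sum_{i>=k} C(K,i) C(N-K, n-i) / C(N,n); batches of such tests
are BH-adjusted into q-values.  Percentages are reported relative to |A|
(100 k / K), matching how Venn-pie figures annotate their slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _check_args(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError("all arguments must be non-negative")
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap cannot exceed either set size")
    if k < max(0, K + n - N):
        raise ValueError("overlap below the feasible minimum for this universe")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_args(k, K, n, N)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class OverlapResult:
    """The 2x2 overlap of two gene sets in a universe."""

    k: int
    K: int
    n: int
    N: int
    p: float
    q: float | None = None

    @property
    def percent(self) -> float:
        return 100.0 * self.k / self.K

    @property
    def venn(self) -> tuple[int, int, int]:
        """(A only, shared, B only) slice counts for a Venn-pie export."""
        return (self.K - self.k, self.k, self.n - self.k)

    def as_dict(self) -> dict:
        return {
            "k": self.k, "K": self.K, "n": self.n, "N": self.N,
            "percent": self.percent, "p": self.p, "q": self.q,
            "venn": self.venn,
        }


def format_percent(value: float, decimals: int = 1) -> str:
    """Figure-style percentage formatting at the stated decimal precision."""
    scale = 10 ** decimals
    rounded = np.floor(value * scale + 0.5) / scale  # round half up, as figures do
    return f"{rounded:.{decimals}f}" if decimals else f"{int(rounded)}"


def overlap_summary(set_a, set_b, universe, q: float | None = None) -> OverlapResult:
    """Overlap statistics for two gene sets within a universe."""
    A, B, U = set(set_a), set(set_b), set(universe)
    if not (A <= U and B <= U):
        raise ValueError("both sets must be contained in the universe")
    k = len(A & B)
    p = hypergeom_upper_tail(k, len(A), len(B), len(U))
    return OverlapResult(k=k, K=len(A), n=len(B), N=len(U), p=p, q=q)


def overlap_batch(pairs, universe) -> list[OverlapResult]:
    """overlap_summary over a batch, BH-adjusting p across the batch.

    The batch should hold one figure-panel's worth of comparisons; q-values
    are only meaningful relative to the batch they were adjusted in.
    """
    raw = [overlap_summary(a, b, universe) for a, b in pairs]
    qs = bh_adjust([r.p for r in raw])
    return [
        OverlapResult(r.k, r.K, r.n, r.N, r.p, float(qv)) for r, qv in zip(raw, qs)
    ]
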