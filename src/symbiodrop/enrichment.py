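"""Gene-set enrichment of a candidate list against random lists.

The candidate list is compared with ``m`` random lists of the same size
drawn from a caller-supplied gene universe.  Overlaps with the reference
(symbiosis-related) set go into a 2x2 table — candidate vs pooled-random
by in-reference vs not — and a plain chi-square test of independence
(df = 1, no continuity correction) asks whether the candidates hit the
reference set more often than random lists do.  An exact hypergeometric
upper tail is provided as an independent check on the same question.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


def percent_overlap(s: int, L: int) -> float:
    """100*s/L rounded half-up to one decimal (the convention used when
    reporting the share of symbiosis-related genes in a list)."""
    if L <= 0:
        raise ValueError("list size must be positive")
    return float(
        (Decimal(100) * Decimal(s) / Decimal(L)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def chi2_from_table(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df 1, no Yates correction.

    An expected cell of zero leaves the statistic undefined; it is
    reported as 0 with p = 1 and a warning.
    """
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected == 0).any():
        warnings.warn("expected cell is zero; chi-square undefined", stacklevel=2)
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class EnrichmentResult:
    list_size: int  # L
    observed_overlap: int  # s
    universe_size: int  # U
    reference_size: int  # K
    n_random_lists: int  # m
    random_overlap: int  # r, pooled over the m lists
    chi2: float
    p_value: float
    percent: float  # 100*s/L, one decimal
    df: int = 1


def chi2_enrichment(
    candidates: Iterable[str],
    reference: Iterable[str],
    universe: Sequence[str],
    m: int = 10,
    seed: int | None = None,
    pooled: bool = True,
) -> EnrichmentResult | list[EnrichmentResult]:
    """Chi-square enrichment of the candidates versus m random lists.

    Random lists of size L are drawn from the universe without
    replacement (within each list), seeded.  With ``pooled=True`` (the
    default) the m lists form one comparison group and a single table
    [[s, L-s], [r, mL-r]] is tested; ``pooled=False`` returns one result
    per random list instead.
    """
    candidates = sorted(set(candidates))
    reference = set(reference)
    universe_sorted = np.array(sorted(set(universe)))
    U = len(universe_sorted)
    L = len(candidates)
    if m < 1:
        raise ValueError("m must be >= 1")
    if L > U:
        raise ValueError("candidate list larger than universe")
    stray = set(candidates) - set(universe_sorted.tolist())
    if stray or reference - set(universe_sorted.tolist()):
        raise ValueError("candidates and reference must be subsets of the universe")
    s = len(set(candidates) & reference)
    rng = np.random.default_rng(seed)
    overlaps = [
        len(set(rng.choice(universe_sorted, size=L, replace=False)) & reference)
        for _ in range(m)
    ]

    def result(r: int, n_lists: int) -> EnrichmentResult:
        chi2, p = chi2_from_table(
            [[s, L - s], [r, n_lists * L - r]]
        )
        return EnrichmentResult(
            list_size=L,
            observed_overlap=s,
            universe_size=U,
            reference_size=len(reference),
            n_random_lists=n_lists,
            random_overlap=r,
            chi2=chi2,
            p_value=p,
            percent=percent_overlap(s, L),
        )

    if pooled:
        return result(int(sum(overlaps)), m)
    return [result(int(r), 1) for r in overlaps]


def hypergeometric_oracle(s: int, L: int, K: int, U: int) -> float:
    """Exact upper-tail P(X >= s) for X ~ Hypergeometric(U, K, L):
    the chance a random L-list hits the K-gene reference at least s
    times."""
    if not (0 <= s <= L <= U and 0 <= K <= U):
        raise ValueError(f"inconsistent counts s={s}, L={L}, K={K}, U={U}")
    return float(stats.hypergeom.sf(s - 1, U, K, L))
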