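"""Cross-exposure comparison of differential-expression gene lists.

Covers the toxicogenomic comparison workflow: thresholding a DE table
into a gene list, partitioning two or three lists into Venn regions,
testing an overlap against the hypergeometric null, and counting
dose-response monotonic genes (high-dose fold change strictly above
low-dose).
"""

from __future__ import annotations

from itertools import product

import pandas as pd
import scipy.stats

DEFAULT_UNIVERSE_SIZE = 21_249

__all__ = [
    "threshold_geneset",
    "venn_partition",
    "hypergeometric_overlap",
    "dose_response_monotonicity",
]


def threshold_geneset(
    records: pd.DataFrame,
    fc_cut: float,
    p_cut: float,
    fc_column: str = "fc_high",
    p_column: str = "p_high",
) -> set[str]:
    """Genes with |fc| >= fc_cut (inclusive) and p < p_cut (strict)."""
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if records.empty:
        return set()
    mask = (records[fc_column].abs() >= fc_cut) & (records[p_column] < p_cut)
    return set(records.index[mask])


def venn_partition(sets: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Disjoint Venn regions of 2 or 3 named sets.

    Keys are tuples of the member set names (sorted by input order); every
    nonempty membership pattern gets a key, so regions are pairwise
    disjoint and their union is the union of the inputs.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_partition supports exactly 2 or 3 sets")
    names = list(sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    for pattern in product([True, False], repeat=len(names)):
        members = tuple(n for n, inside in zip(names, pattern) if inside)
        if not members:
            continue
        region = set.intersection(*(sets[n] for n in members))
        for n, inside in zip(names, pattern):
            if not inside:
                region = region - sets[n]
        regions[members] = region
    return regions


def hypergeometric_overlap(
    n_a: int, n_b: int, k_overlap: int, n_universe: int = DEFAULT_UNIVERSE_SIZE
) -> float:
    """Upper-tail P(X >= k) for the overlap of two gene lists drawn from a
    common universe.

    Under the null, the overlap of a fixed list of size n_a with a random
    list of size n_b from a universe of size N is hypergeometric.  This
    test is an extension of the comparison workflow (the overlap itself is
    reported descriptively upstream); output headers label it as such.
    """
    if not (0 <= k_overlap <= min(n_a, n_b)) or n_a > n_universe or n_b > n_universe:
        raise ValueError("overlap bounds violated")
    if k_overlap == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k_overlap - 1, n_universe, n_a, n_b))


def dose_response_monotonicity(
    records: pd.DataFrame,
    high_column: str = "fc_high",
    low_column: str = "fc_low",
) -> tuple[int, list[str]]:
    """Count genes whose high-dose fold change strictly exceeds the low-dose
    one; returns (count, list of violating genes)."""
    if records.empty:
        return 0, []
    monotone = records[high_column] > records[low_column]
    return int(monotone.sum()), list(records.index[~monotone])
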