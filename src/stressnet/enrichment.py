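"""GO-term over/under-representation by 2x2 chi-square with Yates' correction.

Terms are treated as flat gene sets against a fixed-size gene universe
(default 21,249, the C. elegans gene database size used for worm
enrichment screens).  Unannotated genes stay in the universe and
contribute to the "not in term" cells.  The significance flag uses the
raw p-value at alpha; a BH-adjusted column is emitted for reference but
does not drive the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import scipy.stats

from .expression import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_UNIVERSE_SIZE = 21_249

__all__ = [
    "AnnotationMap",
    "ContingencyTable",
    "build_contingency",
    "chi_square_yates",
    "enrich_terms",
    "DEFAULT_UNIVERSE_SIZE",
]


@dataclass
class AnnotationMap:
    """term id -> annotated gene ids, with the universe the counts refer to."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.universe_size is None:
            self.universe_size = len(self.universe) or DEFAULT_UNIVERSE_SIZE
        for t, genes in self.terms.items():
            if len(genes) > self.universe_size:
                raise ValueError(f"term {t!r} larger than the universe")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 gene counts: a = DE&term, b = DE&~term, c = ~DE&term, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    geneset: set[str], term_genes: set[str], universe: set[str]
) -> ContingencyTable:
    """Count the 2x2 partition of the universe by DE membership and term
    membership."""
    stray = geneset - universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)}")
    term = term_genes & universe
    a = len(geneset & term)
    b = len(geneset) - a
    c = len(term) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def chi_square_yates(t: ContingencyTable) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and upper-tail p (1 df).

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)).
    Tables with a zero marginal are uninformative: (0, 1) is returned and
    the term is skipped in ranking upstream.
    """
    n = t.n
    if n == 0:
        raise ValueError("empty table")
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if 0 in margins:
        logger.debug("chi_square_yates: zero marginal, returning (0, 1)")
        return 0.0, 1.0
    num = max(abs(t.a * t.d - t.b * t.c) - n / 2.0, 0.0)
    chi2 = n * num * num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def enrich_terms(
    geneset: set[str],
    annotation: AnnotationMap,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every annotated term against a gene set.

    Returns a DataFrame (one row per term with >= 1 annotated gene) sorted
    by ascending p then term id, with columns a, b, c, d, chi2, p, q,
    direction (enriched/depleted) and significant (raw p < alpha).
    """
    if not annotation.terms:
        raise ValueError("empty annotation")
    if not geneset:
        return pd.DataFrame(
            columns=["term", "a", "b", "c", "d", "chi2", "p", "q", "direction", "significant"]
        ).set_index("term")
    if universe is None:
        universe = annotation.universe
        if not universe:
            raise ValueError("no universe supplied and annotation has none")
    rows = []
    for term_id in sorted(annotation.terms):
        genes = annotation.terms[term_id] & universe
        if not genes:
            continue
        tab = build_contingency(geneset, genes, universe)
        chi2, p = chi_square_yates(tab)
        in_term_rate = tab.a / (tab.a + tab.b) if (tab.a + tab.b) else 0.0
        out_rate = tab.c / (tab.c + tab.d) if (tab.c + tab.d) else 0.0
        rows.append(
            {
                "term": term_id,
                "a": tab.a,
                "b": tab.b,
                "c": tab.c,
                "d": tab.d,
                "chi2": chi2,
                "p": p,
                "direction": "enriched" if in_term_rate > out_rate else "depleted",
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df.sort_values(["p", "term"], kind="mergesort").set_index("term")
    return df[["a", "b", "c", "d", "chi2", "p", "q", "direction", "significant"]]
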