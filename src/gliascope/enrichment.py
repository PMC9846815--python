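"""Over-representation analysis of a gene list against flat categories.

For each category with ``m`` genes in a reference universe of size ``N``,
an input list of ``n`` genes observed to hit the category ``k`` times is
scored by the upper-tail hypergeometric probability ``P(X >= k)``, the
expected count ``e = m * n / N`` and the fold enrichment ``f = k / e``;
q-values control the FDR across tested categories by Benjamini-Hochberg.
Categories may overlap (no hierarchy-aware correction is applied).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .deg import bh_adjust

__all__ = ["hypergeometric_tail", "overrepresentation_test"]

_COLUMNS = ["category", "reference_count", "observed", "expected",
            "fold_enrichment", "p_raw", "q_value"]


def hypergeometric_tail(k: int, reference_size: int, category_size: int,
                        input_size: int) -> float:
    """Upper-tail probability ``P(X >= k)`` of a hypergeometric draw of
    ``input_size`` from a universe of ``reference_size`` containing
    ``category_size`` successes."""
    return float(stats.hypergeom.sf(k - 1, reference_size, category_size,
                                    input_size))


def overrepresentation_test(input_genes: Iterable[str],
                            category_map: pd.DataFrame,
                            reference_size: int) -> pd.DataFrame:
    """One-sided over-representation test per category.

    ``category_map`` has columns ``gene_id`` and ``category``;
    ``reference_size`` is the size of the reference universe (all
    categories must fit inside it).  Rows are sorted by raw p-value.
    """
    genes = set(input_genes)
    if not genes:
        raise ValueError("input gene list is empty")
    for col in ("gene_id", "category"):
        if col not in category_map.columns:
            raise ValueError(f"category map is missing column {col!r}")
    n = len(genes)
    if reference_size < n:
        raise ValueError("input list larger than the reference universe")

    rows = []
    for category, sub in category_map.groupby("category", sort=True):
        members = set(sub["gene_id"])
        m = len(members)
        if m > reference_size:
            raise ValueError(f"category {category!r} larger than the reference "
                             f"universe")
        k = len(genes & members)
        e = m * n / reference_size
        f = k / e if e > 0 else float("nan")
        p = hypergeometric_tail(k, reference_size, m, n)
        rows.append((category, m, k, e, f, p))
    table = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    table["q_value"] = bh_adjust(table["p_raw"].to_numpy())
    return (table.sort_values(["p_raw", "category"], kind="mergesort")
                 .reset_index(drop=True))
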