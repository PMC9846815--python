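"""Multi-comparison differential-expression extraction.

Each comparison contrasts a mutant group against a control group on MAS5
signals: probesets must be called Present or Marginal in at least
``min_pm`` of the pooled samples (the FLAG-call criterion), exceed a
two-sided fold-change threshold, and — optionally — pass a
Benjamini-Hochberg FDR gate on a Welch t-test.  Probesets changed in the
same direction in every comparison are intersected and collapsed to
unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mas5 import ExpressionMatrix

__all__ = [
    "GroupDesign",
    "flag_call_filter",
    "fold_change",
    "welch_ttest",
    "bh_adjust",
    "compare_groups",
    "comparison_degs",
    "intersect_comparisons",
    "collapse_to_genes",
    "CollapseResult",
]

logger = logging.getLogger(__name__)

_PRESENT_OR_MARGINAL = ("P", "M")


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment of one mutant-vs-control comparison."""

    comparison_id: str
    mutant: tuple
    control: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutant", tuple(self.mutant))
        object.__setattr__(self, "control", tuple(self.control))
        if not self.mutant or not self.control:
            raise ValueError("both groups must be non-empty")
        if set(self.mutant) & set(self.control):
            raise ValueError("mutant and control samples must be disjoint")

    @property
    def samples(self) -> tuple:
        return self.mutant + self.control


def flag_call_filter(calls: Iterable[str], min_pm: int = 3) -> bool:
    """True when at least ``min_pm`` of the pooled calls are P or M."""
    calls = list(calls)
    bad = set(calls) - {"P", "M", "A"}
    if bad:
        raise ValueError(f"unknown detection calls: {sorted(bad)}")
    return sum(c in _PRESENT_OR_MARGINAL for c in calls) >= min_pm


def fold_change(mutant_signals, control_signals) -> float:
    """Ratio of group means, reported as-is (down-regulation < 1)."""
    mut = float(np.mean(np.asarray(mutant_signals, dtype=float)))
    ctl = float(np.mean(np.asarray(control_signals, dtype=float)))
    if ctl <= 0:
        raise ValueError("control mean must be positive")
    return mut / ctl


def welch_ttest(group_a, group_b) -> float:
    """Two-sided unpaired t-test with Welch-Satterthwaite df.

    Degenerate convention: if both groups have zero variance, p is 1 for
    equal means and 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(expr: ExpressionMatrix, design: GroupDesign,
                   min_pm: int = 3) -> pd.DataFrame:
    """Per-probeset statistics of one comparison: fold change, Welch p,
    BH q, FLAG-call pass and direction."""
    missing = set(design.samples) - set(expr.samples)
    if missing:
        raise ValueError(f"design samples missing from expression matrix: "
                         f"{sorted(missing)}")
    mut = expr.signals[list(design.mutant)].to_numpy()
    ctl = expr.signals[list(design.control)].to_numpy()
    ctl_mean = ctl.mean(axis=1)
    if np.any(ctl_mean <= 0):
        raise ValueError("control means must be positive")
    fc = mut.mean(axis=1) / ctl_mean

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(mut, ctl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (mut.var(axis=1, ddof=1) == 0) & (ctl.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        p[degenerate] = np.where(mut.mean(axis=1)[degenerate]
                                 == ctl_mean[degenerate], 1.0, 0.0)
    q = bh_adjust(p)

    pooled = expr.calls[list(design.samples)].isin(_PRESENT_OR_MARGINAL)
    flag_pass = pooled.sum(axis=1).to_numpy() >= min_pm

    return pd.DataFrame({
        "fold_change": fc,
        "p_value": p,
        "q_value": q,
        "flag_pass": flag_pass,
        "direction": np.where(fc > 1.0, "up", "down"),
    }, index=expr.signals.index)


def comparison_degs(expr: ExpressionMatrix, design: GroupDesign,
                    fc_threshold: float = 2.0, fdr: float = 0.05,
                    require_fdr: bool = False, min_pm: int = 3) -> pd.DataFrame:
    """One comparison's statistics table with a ``selected`` column:
    FLAG-call pass AND fold change beyond ``fc_threshold`` in either
    direction AND (optionally) BH q below ``fdr``."""
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must exceed 1")
    table = compare_groups(expr, design, min_pm=min_pm)
    changed = (table["fold_change"] > fc_threshold) | \
              (table["fold_change"] < 1.0 / fc_threshold)
    selected = table["flag_pass"] & changed
    if require_fdr:
        selected &= table["q_value"] < fdr
    table["selected"] = selected
    table.insert(0, "comparison_id", design.comparison_id)
    return table


def intersect_comparisons(results: Sequence, require_direction: bool = True) -> set:
    """Probesets selected in every comparison.

    Accepts plain sets (direction ignored) or the DataFrames produced by
    :func:`comparison_degs`, in which case ``require_direction`` demands
    the same up/down direction in every comparison.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two comparisons to intersect")
    if all(isinstance(r, (set, frozenset)) for r in results):
        return set.intersection(*(set(r) for r in results))
    sets = [set(t.index[t["selected"]]) for t in results]
    common = set.intersection(*sets)
    if require_direction and common:
        keep = set()
        for ps in common:
            directions = {t.loc[ps, "direction"] for t in results}
            if len(directions) == 1:
                keep.add(ps)
        common = keep
    return common


class CollapseResult(NamedTuple):
    genes: pd.DataFrame
    unannotated: set


def collapse_to_genes(entities: Iterable[str], annotation: pd.DataFrame,
                      comparison_tables: Sequence[pd.DataFrame] = ()) -> CollapseResult:
    """Deduplicate probesets to genes.

    For a gene with several selected probesets the representative is the
    one with the largest \\|log2 fold change\\| averaged over comparisons.
    Probesets without annotation go to an ``unannotated`` bucket, logged
    and excluded from the gene list.
    """
    entities = sorted(set(entities))
    gene_of = annotation.set_index("probeset_id")["gene_id"]
    unannotated = {ps for ps in entities if ps not in gene_of.index}
    if unannotated:
        logger.warning("%d entities lack gene annotation and were excluded: %s",
                       len(unannotated), sorted(unannotated)[:5])
    annotated = [ps for ps in entities if ps not in unannotated]

    if comparison_tables:
        score = pd.concat(
            [np.abs(np.log2(t["fold_change"])) for t in comparison_tables],
            axis=1).mean(axis=1)
    else:
        score = pd.Series(0.0, index=pd.Index(annotated))
    rows = []
    for ps in annotated:
        rows.append((gene_of[ps], ps, float(score.get(ps, 0.0))))
    table = pd.DataFrame(rows, columns=["gene_id", "probeset_id",
                                        "mean_abs_log2_fc"])
    table = (table.sort_values(["mean_abs_log2_fc", "probeset_id"],
                               ascending=[False, True], kind="mergesort")
                  .drop_duplicates("gene_id", keep="first")
                  .sort_values("gene_id", kind="mergesort")
                  .reset_index(drop=True))
    return CollapseResult(genes=table, unannotated=unannotated)
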