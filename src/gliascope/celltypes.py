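"""Integrated cell-type-specific expression reference and enrichment classes.

Independent expression datasets for the five major CNS cell types —
motor neurons, (other) neurons, astrocytes, microglia and
oligodendrocytes — are commonly scaled, averaged per cell type and joined
into a single gene x cell-type table.  A gene is *enriched* in one cell
type when its signal there is at least ``factor`` (default fourfold, the
Human Protein Atlas criterion) times the signal in every other analyzed
type; everything else is Unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mas5 import ExpressionMatrix

__all__ = [
    "CELL_TYPES",
    "UNCLASSIFIED",
    "CellTypeReference",
    "classify_enrichment",
    "classify_table",
    "build_reference",
    "reference_from_values",
    "validate_markers",
    "annotate_deg_list",
]

logger = logging.getLogger(__name__)

CELL_TYPES = ("motor_neuron", "neuron", "astrocyte", "microglia", "oligodendrocyte")
UNCLASSIFIED = "Unclassified"


@dataclass
class CellTypeReference:
    """Gene x cell-type mean signals plus a per-gene enrichment class.

    ``complete`` marks genes measured in every cell-type dataset; genes
    missing from any dataset are kept (missing values filled with zero)
    but always Unclassified.
    """

    values: pd.DataFrame
    classes: pd.Series
    complete: pd.Series
    factor: float
    target: float | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(CELL_TYPES):
            raise ValueError(f"reference columns must be {CELL_TYPES}")
        if not (self.classes.index.equals(self.values.index)
                and self.complete.index.equals(self.values.index)):
            raise ValueError("classes/complete must align with values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("reference signals must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def classify_enrichment(values, factor: float = 4.0) -> str:
    """Enrichment class of one gene from its five cell-type signals.

    Returns the argmax cell type when its signal is at least ``factor``
    times the runner-up (inclusive boundary: a tie at exactly ``factor``
    classifies); a zero runner-up with a positive maximum classifies to
    the maximum's type; top-level ties and everything else are
    Unclassified.
    """
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    if isinstance(values, pd.Series):
        values = values.reindex(list(CELL_TYPES))
    v = np.asarray(values, dtype=float)
    if v.shape != (len(CELL_TYPES),) or not np.all(np.isfinite(v)):
        raise ValueError("expected one finite signal per cell type")
    if np.any(v < 0):
        raise ValueError("signals must be non-negative")
    mx = v.max()
    if mx <= 0.0:
        return UNCLASSIFIED
    if int((v == mx).sum()) > 1:
        return UNCLASSIFIED
    j = int(v.argmax())
    second = np.delete(v, j).max()
    if second == 0.0 or mx >= factor * second:
        return CELL_TYPES[j]
    return UNCLASSIFIED


def classify_table(values: pd.DataFrame, factor: float = 4.0) -> pd.Series:
    """Vectorized :func:`classify_enrichment` over a gene x cell-type table."""
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    v = values[list(CELL_TYPES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("signals must be finite and non-negative")
    order = np.sort(v, axis=1)
    mx, second = order[:, -1], order[:, -2]
    top = v.argmax(axis=1)
    unique_top = (v == mx[:, None]).sum(axis=1) == 1
    enriched = (mx > 0) & unique_top & ((second == 0) | (mx >= factor * second))
    labels = np.where(enriched, np.asarray(CELL_TYPES, dtype=object)[top],
                      UNCLASSIFIED)
    return pd.Series(labels, index=values.index, name="class")


def _collapse_to_genes(means: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    """Probeset means -> gene means, taking the maximum over a gene's
    probesets (conservative against probe dropout)."""
    gene_of = annotation.set_index("probeset_id")["gene_id"]
    common = means.index.intersection(gene_of.index)
    dropped = len(means) - len(common)
    if dropped:
        logger.warning("%d probesets without gene annotation dropped from "
                       "the reference", dropped)
    grouped = means.loc[common].groupby(gene_of.loc[common]).max()
    grouped.index.name = "gene_id"
    return grouped


def build_reference(datasets: Mapping[str, ExpressionMatrix],
                    annotation: pd.DataFrame,
                    factor: float = 4.0) -> CellTypeReference:
    """Build the integrated reference from one MAS5-scaled dataset per
    cell type.

    All datasets must be scaled to the same target (classification is not
    invariant to per-cell-type rescaling).  The per-type value of a gene
    is the mean signal over that dataset's samples, collapsed over the
    gene's probesets by maximum.
    """
    missing_types = set(CELL_TYPES) - set(datasets)
    if missing_types:
        raise ValueError(f"missing cell-type datasets: {sorted(missing_types)}")
    targets = {t: datasets[t].target for t in CELL_TYPES}
    if len(set(targets.values())) != 1:
        raise ValueError(f"inconsistent scaling targets across datasets: {targets}")
    per_type = {}
    for t in CELL_TYPES:
        em = datasets[t]
        means = em.signals.mean(axis=1)
        per_type[t] = _collapse_to_genes(means, annotation)
    values = pd.DataFrame(per_type, columns=list(CELL_TYPES))
    complete = values.notna().all(axis=1)
    if not complete.all():
        logger.warning("%d genes absent from at least one cell-type dataset",
                       int((~complete).sum()))
    values = values.fillna(0.0)
    classes = classify_table(values, factor)
    classes[~complete] = UNCLASSIFIED
    return CellTypeReference(values=values, classes=classes, complete=complete,
                             factor=factor, target=float(next(iter(targets.values()))))


def reference_from_values(values: pd.DataFrame, factor: float = 4.0,
                          target: float | None = None) -> CellTypeReference:
    """Wrap an existing gene x cell-type table as a reference."""
    values = values[list(CELL_TYPES)].copy()
    complete = pd.Series(True, index=values.index)
    return CellTypeReference(values=values, classes=classify_table(values, factor),
                             complete=complete, factor=factor, target=target)


def validate_markers(reference: CellTypeReference,
                     panel: Mapping[str, Sequence[str]],
                     min_signal: float = 50.0):
    """Check that each panel marker classifies to its own cell type.

    Markers below ``min_signal`` in every cell type are reported as
    non-informative rather than failed.  Returns ``(table, fraction_correct)``
    where the fraction is over informative, present markers.
    """
    if not panel or all(len(v) == 0 for v in panel.values()):
        raise ValueError("marker panel is empty")
    unknown = set(panel) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown panel cell types: {sorted(unknown)}")
    rows = []
    for cell_type, markers in panel.items():
        for gene in markers:
            if gene not in reference.values.index:
                rows.append((gene, cell_type, None, "missing"))
                continue
            sig = reference.values.loc[gene]
            if (sig < min_signal).all():
                rows.append((gene, cell_type, reference.classes[gene],
                             "non_informative"))
                continue
            assigned = reference.classes[gene]
            status = "correct" if assigned == cell_type else "incorrect"
            rows.append((gene, cell_type, assigned, status))
    table = pd.DataFrame(rows, columns=["gene_id", "panel_type", "assigned_class",
                                        "status"])
    informative = table["status"].isin(["correct", "incorrect"])
    n_inf = int(informative.sum())
    fraction = float((table.loc[informative, "status"] == "correct").mean()) \
        if n_inf else float("nan")
    return table, fraction


def annotate_deg_list(genes: Sequence[str], reference: CellTypeReference):
    """Label every gene of a DEG list with its enrichment class.

    Genes absent from the reference are Unclassified and flagged missing.
    Returns ``(table, counts)``; counts cover the five cell types plus
    Unclassified and sum to the list length.
    """
    genes = list(genes)
    rows = []
    for g in genes:
        if g in reference.classes.index:
            rows.append((g, reference.classes[g], False))
        else:
            rows.append((g, UNCLASSIFIED, True))
    table = pd.DataFrame(rows, columns=["gene_id", "class", "missing"])
    counts = table["class"].value_counts().reindex(
        list(CELL_TYPES) + [UNCLASSIFIED], fill_value=0)
    counts.name = "n_genes"
    return table, counts
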