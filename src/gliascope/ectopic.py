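"""Disease fold changes in isolated-cell datasets and ectopic-expression
detection.

Isolated-cell preparations (e.g. laser-capture microdissection) carry
some contamination from adjacent cell types, so a gene whose healthy home
is a *different* cell type can appear upregulated in a host dataset
purely through contamination.  Markers of the gene's home type bound what
contamination alone can explain (the *contamination envelope*); a gene
whose disease fold change in the host dataset exceeds a multiple ``k`` of
the envelope maximum — and an absolute floor — is flagged as ectopically
expressed in the host.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .celltypes import CELL_TYPES, UNCLASSIFIED, CellTypeReference
from .mas5 import ExpressionMatrix

__all__ = [
    "EctopicCall",
    "celltype_fold_changes",
    "build_fc_table",
    "contamination_envelope",
    "detect_ectopic",
    "scan_ectopic",
    "DEFAULT_MARKER_PANELS",
]

#: Classic microglial markers used to bound microglial contamination in
#: astrocyte or neuron datasets; user-overridable.
DEFAULT_MARKER_PANELS: dict[str, tuple] = {
    "microglia": ("Cd68", "Aif1", "Itgam"),
}


@dataclass(frozen=True)
class EctopicCall:
    """Evidence record of one ectopic-expression decision."""

    gene: str
    home_class: str
    host_dataset: str
    gene_fc: float
    envelope_max: float
    envelope_min: float
    k: float
    floor: float
    flag: bool


def celltype_fold_changes(disease: ExpressionMatrix, control: ExpressionMatrix,
                          annotation: pd.DataFrame | None = None,
                          floor_fraction: float = 0.04) -> pd.Series:
    """Per-gene ratio of disease group mean to control group mean.

    Both matrices must cover the same probesets and be scaled to the same
    target.  Group means are floored at ``floor_fraction`` of the scaling
    target before taking the ratio, so that genes below the reliable
    detection range cannot produce arbitrarily inflated ratios; because
    the floor scales with the target, fold changes stay invariant to the
    common scaling target.  With ``annotation`` the ratios are collapsed
    to genes using the probeset with the highest pooled mean signal.
    """
    if not disease.signals.index.equals(control.signals.index):
        raise ValueError("disease and control must cover the same probesets")
    if disease.target != control.target:
        raise ValueError("disease and control must share a scaling target")
    if not 0.0 <= floor_fraction < 1.0:
        raise ValueError("floor_fraction must lie in [0, 1)")
    floor = floor_fraction * disease.target
    dis = disease.signals.mean(axis=1).clip(lower=floor)
    ctl = control.signals.mean(axis=1).clip(lower=floor)
    if np.any(ctl.to_numpy() <= 0):
        raise ValueError("control means must be positive")
    fc = dis / ctl
    fc.name = "fold_change"
    if annotation is None:
        return fc
    gene_of = annotation.set_index("probeset_id")["gene_id"]
    common = fc.index.intersection(gene_of.index)
    pooled = (dis + ctl).loc[common]
    frame = pd.DataFrame({"gene_id": gene_of.loc[common], "fc": fc.loc[common],
                          "pooled": pooled})
    frame = frame.sort_values(["pooled"], ascending=False, kind="mergesort")
    rep = frame.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    out = rep["fc"].sort_index()
    out.name = "fold_change"
    out.index.name = "gene_id"
    return out


def build_fc_table(columns: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-dataset fold-change series (e.g. ``microglia_P90``,
    ``astrocyte_P120``) into one gene x dataset table."""
    if not columns:
        raise ValueError("no fold-change columns given")
    table = pd.DataFrame(dict(columns))
    vals = table.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("fold changes must be positive")
    table.index.name = "gene_id"
    return table


def contamination_envelope(fc_table: pd.DataFrame, host_dataset: str,
                           foreign_markers: Sequence[str]) -> tuple[float, float]:
    """(max, min) fold change among foreign-type markers in the host
    dataset — the range contamination alone can produce."""
    if host_dataset not in fc_table.columns:
        raise ValueError(f"unknown dataset {host_dataset!r}")
    col = fc_table[host_dataset]
    present = [m for m in foreign_markers if m in col.index and np.isfinite(col[m])]
    if len(present) < 2:
        raise ValueError("need at least two markers to form a contamination "
                         "envelope")
    vals = col.loc[present].to_numpy(dtype=float)
    return float(vals.max()), float(vals.min())


def detect_ectopic(gene: str, fc_table: pd.DataFrame, host_dataset: str,
                   host_cell_type: str, reference: CellTypeReference,
                   marker_panels: Mapping[str, Sequence[str]] | None = None,
                   k: float = 3.0, floor: float = 10.0) -> EctopicCall | None:
    """Decide whether ``gene`` is ectopically expressed in the host.

    Returns ``None`` (no call) when the gene's home class is the host cell
    type itself or Unclassified.  Otherwise the gene is flagged iff its
    fold change exceeds both ``k`` times the home-class marker envelope
    maximum and the absolute ``floor``.
    """
    if host_cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {host_cell_type!r}")
    panels = DEFAULT_MARKER_PANELS if marker_panels is None else marker_panels
    if gene not in fc_table.index:
        raise ValueError(f"gene {gene!r} missing from fold-change table")
    home = reference.classes.get(gene, UNCLASSIFIED)
    if home == host_cell_type or home == UNCLASSIFIED:
        return None
    if home not in panels:
        raise ValueError(f"no marker panel for home class {home!r}")
    env_max, env_min = contamination_envelope(fc_table, host_dataset,
                                              panels[home])
    gene_fc = float(fc_table.loc[gene, host_dataset])
    flag = bool(gene_fc > k * env_max and gene_fc > floor)
    return EctopicCall(gene=gene, home_class=home, host_dataset=host_dataset,
                       gene_fc=gene_fc, envelope_max=env_max,
                       envelope_min=env_min, k=k, floor=floor, flag=flag)


def scan_ectopic(fc_table: pd.DataFrame, host_dataset: str,
                 host_cell_type: str, reference: CellTypeReference,
                 marker_panels: Mapping[str, Sequence[str]] | None = None,
                 k: float = 3.0, floor: float = 10.0) -> pd.DataFrame:
    """Run :func:`detect_ectopic` over every eligible gene of the table.

    Eligible genes have a home class that differs from the host cell type
    and has a marker panel; marker genes themselves are excluded (they
    define the envelope).
    """
    panels = DEFAULT_MARKER_PANELS if marker_panels is None else marker_panels
    marker_set = {m for ms in panels.values() for m in ms}
    rows = []
    for gene in fc_table.index:
        if gene in marker_set:
            continue
        home = reference.classes.get(gene, UNCLASSIFIED)
        if home in (host_cell_type, UNCLASSIFIED) or home not in panels:
            continue
        call = detect_ectopic(gene, fc_table, host_dataset, host_cell_type,
                              reference, panels, k=k, floor=floor)
        if call is not None:
            rows.append(call.__dict__)
    cols = ["gene", "home_class", "host_dataset", "gene_fc", "envelope_max",
            "envelope_min", "k", "floor", "flag"]
    return pd.DataFrame(rows, columns=cols)
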