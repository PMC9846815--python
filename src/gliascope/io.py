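"""Tab-separated and JSON/YAML I/O with strict schema validation.

All tables are TSV with a header row; metadata (seed, config hash,
scaling target) travels in ``# key=value`` comment lines above the
header.  Floats are written with 10 significant digits so re-running a
stage from saved intermediates reproduces downstream outputs exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .mas5 import ExpressionMatrix
from .synthetic_data import ChipLayout, SyntheticTruth

__all__ = [
    "write_table", "read_table", "read_meta",
    "write_matrix", "read_matrix",
    "write_layout", "read_layout",
    "write_annotation", "read_annotation",
    "read_markers",
    "write_expression", "read_expression",
    "write_truth", "read_truth",
    "write_config_yaml", "read_config_yaml",
]

_FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, meta: Mapping | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_table(path, required: tuple = (), index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_matrix(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    out = df.copy()
    out.index.name = out.index.name or "id"
    write_table(out, path, meta=meta, index=True)


def read_matrix(path, index_name: str = "id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = index_name
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated row identifier {dup!r}")
    return df


def write_layout(layout: ChipLayout, path, meta: Mapping | None = None) -> None:
    write_table(layout.table, path, meta=meta, index=False)


def read_layout(path) -> ChipLayout:
    table = read_table(path, required=("probe_id", "probeset_id",
                                       "pair_index", "role"))
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicated probe_id {dup!r}")
    bad = set(table["role"]) - {"PM", "MM"}
    if bad:
        raise ValueError(f"{path}: unknown probe roles {sorted(bad)}")
    return ChipLayout(table=table)


def write_annotation(annotation: pd.DataFrame, path,
                     meta: Mapping | None = None) -> None:
    write_table(annotation, path, meta=meta, index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = read_table(path, required=("probeset_id", "gene_id"))
    if ann["probeset_id"].duplicated().any():
        dup = ann.loc[ann["probeset_id"].duplicated(), "probeset_id"].iloc[0]
        raise ValueError(f"{path}: duplicated probeset_id {dup!r}")
    return ann


def read_markers(path) -> dict:
    """Marker panel TSV with columns cell_type, gene_id -> dict of lists."""
    table = read_table(path, required=("cell_type", "gene_id"))
    return {t: tuple(sub["gene_id"]) for t, sub in table.groupby("cell_type")}


def write_expression(em: ExpressionMatrix, prefix,
                     meta: Mapping | None = None) -> None:
    """Write one normalized dataset as ``{prefix}.signals.tsv``,
    ``.pvalues.tsv``, ``.calls.tsv`` and ``.scale.tsv``."""
    prefix = Path(prefix)
    meta = dict(meta or {})
    meta["scale_target"] = repr(em.target)
    write_matrix(em.signals, f"{prefix}.signals.tsv", meta=meta)
    write_matrix(em.pvalues, f"{prefix}.pvalues.tsv", meta=meta)
    write_matrix(em.calls, f"{prefix}.calls.tsv", meta=meta)
    scale = em.scale_factors.rename_axis("sample").reset_index()
    write_table(scale, f"{prefix}.scale.tsv", meta=meta, index=False)


def read_expression(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    meta = read_meta(f"{prefix}.signals.tsv")
    if "scale_target" not in meta:
        raise ValueError(f"{prefix}.signals.tsv: missing scale_target metadata")
    signals = read_matrix(f"{prefix}.signals.tsv", index_name="probeset_id")
    pvalues = read_matrix(f"{prefix}.pvalues.tsv", index_name="probeset_id")
    calls = read_matrix(f"{prefix}.calls.tsv", index_name="probeset_id")
    scale = read_table(f"{prefix}.scale.tsv", required=("sample", "scale_factor"))
    factors = scale.set_index("sample")["scale_factor"]
    factors.index.name = None
    return ExpressionMatrix(signals=signals, pvalues=pvalues, calls=calls,
                            scale_factors=factors.loc[signals.columns],
                            target=float(meta["scale_target"]))


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def write_config_yaml(data: Mapping, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(dict(data), sort_keys=True))


def read_config_yaml(path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return loaded


def write_json(data, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
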