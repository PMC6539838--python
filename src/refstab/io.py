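"""Readers and writers for the package's tabular interchange formats.

Everything is tab-separated UTF-8 text with a header row; missing values
are encoded as empty cells or ``NA``. Readers never reorder: gene and
sample order in memory equals file order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    ComparisonMatrix,
    DiscoveryConfig,
    ExpressionMatrix,
    GroupDesign,
    Scale,
    TargetedAssayTable,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_design",
    "write_group_design",
    "read_geo_profile_export",
    "read_assay_table",
    "write_assay_table",
    "read_discovery_config",
    "write_discovery_config",
]

logger = logging.getLogger("refstab")

_NA_VALUES = ["", "NA"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", header=0, index_col=0, dtype=str,
            na_values=_NA_VALUES, keep_default_na=False, comment="#",
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc


def read_expression_matrix(path, scale: Scale | str = Scale.LOG2_INTENSITY) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    raw = _read_tsv(path)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene identifiers {dups[:5]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample identifiers {dups[:5]}")
    data = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        try:
            data[col] = raw[col].astype(float)
        except ValueError as exc:
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0]!r}"
            ) from exc
    matrix = ExpressionMatrix(data, scale)
    n_missing = int(matrix.missing_mask.sum())
    if n_missing:
        logger.warning("%s: %d gene(s) carry missing values", path, n_missing)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    # repr-precision floats so a write -> read round trip is bit exact
    out.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: repr(float(v)))


def read_group_design(path) -> GroupDesign:
    """Read a two-column TSV (sample_id, group); group order = first appearance."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    if df.empty or df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample, group) with data rows")
    samples, groups = df.iloc[:, 0], df.iloc[:, 1]
    assignment: dict[str, str] = {}
    for s, g in zip(samples, groups):
        if pd.isna(s) or pd.isna(g):
            raise ParseError(f"{path}: missing sample or group label")
        if s in assignment:
            if assignment[s] != g:
                raise ParseError(f"{path}: sample {s!r} assigned to both {assignment[s]!r} and {g!r}")
            raise ParseError(f"{path}: sample {s!r} listed twice")
        assignment[str(s)] = str(g)
    return GroupDesign(assignment)


def write_group_design(design: GroupDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s, g in design.assignment.items():
            fh.write(f"{s}\t{g}\n")


def read_geo_profile_export(path, group_map: GroupDesign, scale: Scale | str = Scale.LINEAR) -> ExpressionMatrix:
    """Read a GEO-Profiles-style export restricted to mapped samples.

    Accepts either the single-record dialect (two columns: sample id,
    value; one gene named in a leading ``#ID_REF=`` or ``#gene=`` comment,
    else the file stem) or a multi-gene series-matrix-style table (genes x
    samples, as :func:`read_expression_matrix`). Samples absent from
    ``group_map`` are dropped with a warning; no overlap is an error.
    """
    path = Path(path)
    gene_id = path.stem
    with open(path, encoding="utf-8") as fh:
        header_comments = []
        for line in fh:
            if line.startswith("#"):
                header_comments.append(line[1:].strip())
            else:
                first_data = line
                break
        else:
            raise ParseError(f"{path}: no data rows")
    for comment in header_comments:
        if "=" in comment:
            key, _, value = comment.partition("=")
            if key.strip().lower() in ("id_ref", "gene"):
                gene_id = value.strip()

    n_cols = len(first_data.rstrip("\n").split("\t"))
    if n_cols == 2:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
        data = pd.DataFrame(
            {str(s): [float(v)] for s, v in zip(df.iloc[:, 0], df.iloc[:, 1])},
            index=[gene_id],
        )
        matrix = ExpressionMatrix(data, scale)
    else:
        matrix = read_expression_matrix(path, scale)

    mapped = [s for s in matrix.sample_ids if s in group_map.assignment]
    unmapped = [s for s in matrix.sample_ids if s not in group_map.assignment]
    if not mapped:
        raise ParseError(f"{path}: no overlap between record samples and group map")
    if unmapped:
        logger.warning("%s: dropping %d unmapped sample(s): %s", path, len(unmapped), unmapped[:5])
    return ExpressionMatrix(matrix.data.loc[:, mapped], matrix.scale)


def read_assay_table(
    path,
    scale: Scale | str,
    design: GroupDesign,
    lod: float | Mapping[str, float] | None = None,
) -> TargetedAssayTable:
    """Read a long-format assay TSV: columns gene, sample, replicate, value."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#",
                     na_values=_NA_VALUES, keep_default_na=False)
    required = {"gene", "sample", "replicate", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value column entry") from exc
    df = df.dropna(subset=["value"])
    return TargetedAssayTable(df, scale, design, lod=lod)


def write_assay_table(table: TargetedAssayTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False,
                         float_format=lambda v: repr(float(v)))


def read_discovery_config(path) -> DiscoveryConfig:
    """Read a YAML (or JSON, a YAML subset) config mirroring DiscoveryConfig."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(payload) - set(DiscoveryConfig().to_dict())
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return DiscoveryConfig.from_dict(payload)


def write_discovery_config(config: DiscoveryConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_comparison_matrix(cm: ComparisonMatrix, path) -> None:
    """TSV dump of a comparison matrix: folds above, p-values below diagonal."""
    from .external import comparison_table_frame

    comparison_table_frame(cm).to_csv(path, sep="\t", index=False)
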