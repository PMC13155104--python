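"""Readers and writers for gradient, count and taxonomy tables (TSV/CSV).

Formats are deliberately plain: one gradient row per fraction, count-matrix
columns keyed ``treatment|replicate|fraction``, taxonomy either as per-rank
columns or a single QIIME-style lineage column.  Reads are lossless and
round-trip through the writers for the canonical column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    RANKS,
    DensityFraction,
    FeatureCountMatrix,
    GradientReplicate,
    SampleKey,
    SchemaError,
    TableFormatError,
    TaxonomyTable,
)

log = logging.getLogger("fjordsip")

GRADIENT_COLUMNS = ("treatment", "replicate", "fraction", "density", "copies")
KEY_DELIMITER = "|"


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str).rename(columns=str.strip)


def _coerce_numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise TableFormatError(
            f"{path}: non-numeric value(s) in column {column!r} "
            f"at line(s) {lines}"
        )
    return out


def read_gradient_table(
    path,
    schema: Optional[dict[str, str]] = None,
) -> list[GradientReplicate]:
    """Read per-fraction gradient rows into :class:`GradientReplicate` objects.

    Parameters
    ----------
    path : str or Path
        TSV/CSV with one row per (treatment, replicate, fraction).
    schema : dict, optional
        Maps canonical names (``treatment``, ``replicate``, ``fraction``,
        ``density``, ``copies``, optionally ``sequenced``) to the file's
        column names.  A two-well qPCR layout is supported by mapping
        ``copies`` to a list of two column names, which are averaged.
    """
    schema = dict(schema or {})
    df = _read_table(path)

    colmap = {name: schema.get(name, name) for name in GRADIENT_COLUMNS}
    seq_col = schema.get("sequenced", "sequenced" if "sequenced" in df.columns else None)

    copies_cols = colmap["copies"]
    needed = [colmap[c] for c in GRADIENT_COLUMNS if c != "copies"]
    needed += list(copies_cols) if isinstance(copies_cols, (list, tuple)) else [copies_cols]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    density = _coerce_numeric(df, colmap["density"], path)
    if isinstance(copies_cols, (list, tuple)):
        wells = [_coerce_numeric(df, c, path) for c in copies_cols]
        copies = pd.concat(wells, axis=1).mean(axis=1)
    else:
        copies = _coerce_numeric(df, copies_cols, path)

    keys = list(
        zip(
            df[colmap["treatment"]].astype(str),
            df[colmap["replicate"]].astype(str),
            df[colmap["fraction"]].astype(str),
        )
    )
    seen: set = set()
    for k in keys:
        if k in seen:
            raise TableFormatError(
                f"{path}: duplicated (treatment, replicate, fraction) key {k}"
            )
        seen.add(k)

    if seq_col is not None:
        sequenced = df[seq_col].astype(str).str.strip().str.lower().isin(
            ("1", "true", "yes", "y")
        )
    else:
        sequenced = copies.notna()

    grouped: dict[tuple[str, int], list[DensityFraction]] = {}
    for i, (treat, rep, frac) in enumerate(keys):
        c = copies.iloc[i]
        grouped.setdefault((treat, int(rep)), []).append(
            DensityFraction(
                fraction_id=frac,
                density=float(density.iloc[i]),
                copies=None if pd.isna(c) else float(c),
                sequenced=bool(sequenced.iloc[i]),
            )
        )
    reps = [
        GradientReplicate(treatment_id=t, replicate_id=r, fractions=tuple(fr))
        for (t, r), fr in grouped.items()
    ]
    reps.sort(key=lambda g: (g.treatment_id, g.replicate_id))
    return reps


def write_gradient_table(replicates: Sequence[GradientReplicate], path) -> None:
    """Write gradients in the canonical column order (round-trips the reader)."""
    rows = []
    for rep in replicates:
        for f in rep.fractions:
            rows.append(
                {
                    "treatment": rep.treatment_id,
                    "replicate": rep.replicate_id,
                    "fraction": f.fraction_id,
                    "density": f.density,
                    "copies": "" if f.copies is None else f.copies,
                    "sequenced": str(f.sequenced).lower(),
                }
            )
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def parse_sample_key(label: str, delimiter: str = KEY_DELIMITER) -> SampleKey:
    parts = str(label).split(delimiter)
    if len(parts) != 3:
        raise SchemaError(
            f"sample column {label!r} is not of the form "
            f"treatment{delimiter}replicate{delimiter}fraction"
        )
    return SampleKey(parts[0], int(parts[1]), parts[2])


def format_sample_key(key: SampleKey, delimiter: str = KEY_DELIMITER) -> str:
    return delimiter.join([key.treatment, str(key.replicate), key.fraction])


def read_counts_and_taxonomy(
    counts_path,
    taxonomy_path,
    gradients: Optional[Sequence[GradientReplicate]] = None,
    delimiter: str = KEY_DELIMITER,
) -> tuple[FeatureCountMatrix, TaxonomyTable]:
    """Read an ASV count matrix and its taxonomy into one consistent universe.

    Count columns (apart from the leading ASV-id column) are
    ``treatment|replicate|fraction`` keys.  When ``gradients`` is given,
    every column must resolve to a sequenced fraction of a known replicate;
    orphan columns raise.  ASVs present in the counts but absent from the
    taxonomy receive an ``unassigned`` lineage with a logged warning.
    """
    cdf = _read_table(counts_path)
    if cdf.shape[1] < 2:
        raise SchemaError(f"{counts_path}: expected an ASV column plus samples")
    cdf = cdf.set_index(cdf.columns[0])
    keys = [parse_sample_key(c, delimiter) for c in cdf.columns]

    if gradients is not None:
        known = {
            (g.treatment_id, g.replicate_id, f.fraction_id)
            for g in gradients
            for f in g.fractions
        }
        orphans = [format_sample_key(k, delimiter) for k in keys if tuple(k) not in known]
        if orphans:
            raise SchemaError(
                f"{counts_path}: column(s) not resolvable to a gradient "
                f"fraction: {orphans}"
            )

    counts = cdf.apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise TableFormatError(f"{counts_path}: non-numeric count values")
    matrix = FeatureCountMatrix.from_arrays(
        [str(a) for a in cdf.index], keys, counts.to_numpy()
    )

    tdf = _read_table(taxonomy_path)
    tdf = tdf.set_index(tdf.columns[0])
    lower = {c.lower(): c for c in tdf.columns}
    if all(r in lower for r in RANKS):
        body = tdf.rename(columns={lower[r]: r for r in RANKS})
        tax = TaxonomyTable(body)
    else:
        lineage_col = next(
            (lower[c] for c in ("taxon", "taxonomy", "lineage") if c in lower), None
        )
        if lineage_col is None:
            raise SchemaError(
                f"{taxonomy_path}: need per-rank columns {RANKS} or a "
                f"'taxon'/'taxonomy'/'lineage' column"
            )
        tax = TaxonomyTable.from_lineages(
            {
                str(a): TaxonomyTable.parse_qiime_string(s)
                for a, s in tdf[lineage_col].items()
            }
        )

    missing = [a for a in matrix.asv_ids if a not in set(tax.asv_ids)]
    if missing:
        log.warning(
            "%d ASV(s) missing from taxonomy, recorded as unassigned: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            "..." if len(missing) > 5 else "",
        )
        tax = tax.with_unassigned(matrix.asv_ids)
    return matrix, tax


def write_counts(matrix: FeatureCountMatrix, path, delimiter: str = KEY_DELIMITER) -> None:
    out = matrix.df.copy()
    out.columns = [
        format_sample_key(SampleKey(t, int(r), str(f)), delimiter)
        for t, r, f in out.columns
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    out.to_csv(path, sep=sep, index_label="asv_id")


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    tax.df.to_csv(path, sep=sep, index_label="asv_id")


def load_config(path) -> dict:
    """Load a nested key-value config file (YAML)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
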