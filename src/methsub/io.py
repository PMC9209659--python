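"""Readers and writers for the delimited-text formats the pipeline touches.

Delimiter is auto-detected from the extension (``.tsv`` tab, ``.csv``
comma) and can be overridden. Empty cells and a configurable sentinel
(default ``NA``) denote missing values. Readers validate and reject
invariant-violating input rather than coercing it.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .types import BetaMatrix, ExprMatrix, ProbeAnnotation, SampleMetadata

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_metadata",
    "write_metadata",
]

_DEFAULT_NA = ("", "NA", "NaN", "nan")


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def _read_table(path, delimiter, na_values=_DEFAULT_NA, index_col=None):
    try:
        return pd.read_csv(
            path,
            sep=_sep_for(path, delimiter),
            index_col=index_col,
            na_values=list(na_values),
            keep_default_na=False,
            dtype=None,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc


def read_matrix(path, kind: str, delimiter: str | None = None,
                na_values: Sequence[str] = _DEFAULT_NA):
    """Read a feature x sample matrix.

    First column holds feature ids, header row holds sample ids.
    ``kind`` is ``"beta"`` (values validated to [0, 1], missing allowed),
    ``"expression"`` (raw non-negative values) or ``"expression_log2"``
    (normalized, finite, may be negative).
    """
    if kind not in {"beta", "expression", "expression_log2"}:
        raise ValueError(f"kind must be 'beta', 'expression' or "
                         f"'expression_log2', got {kind!r}")
    df = _read_table(path, delimiter, na_values, index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id {dup[0]!r} in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric matrix entry in {path}: {exc}") from exc
    if kind == "beta":
        return BetaMatrix(df)
    return ExprMatrix(df, log2=(kind == "expression_log2"))


def write_matrix(m, path, delimiter: str | None = None, na_rep: str = "NA") -> None:
    m.values.to_csv(path, sep=_sep_for(path, delimiter), na_rep=na_rep,
                    index_label="id", float_format="%.17g")


_ANN_COLS = ["probe", "chrom", "pos", "strand", "gene", "tss"]


def read_annotation(path, delimiter: str | None = None) -> list[ProbeAnnotation]:
    """Read a probe annotation table (probe, chrom, pos, strand, gene, tss
    [, blacklisted]); coordinates are 0-based integers."""
    df = _read_table(path, delimiter)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks required columns: {missing} (need {_ANN_COLS})")
    has_bl = "blacklisted" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(ProbeAnnotation(
            probe=str(row.probe), chrom=str(row.chrom), pos=int(row.pos),
            strand=str(row.strand), gene=str(row.gene), tss=int(row.tss),
            blacklisted=bool(int(getattr(row, "blacklisted"))) if has_bl else False,
        ))
    return out


def write_annotation(ann: Sequence[ProbeAnnotation], path, delimiter: str | None = None) -> None:
    df = pd.DataFrame(
        [(a.probe, a.chrom, a.pos, a.strand, a.gene, a.tss, int(a.blacklisted)) for a in ann],
        columns=_ANN_COLS + ["blacklisted"],
    )
    df.to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_metadata(path, delimiter: str | None = None) -> list[SampleMetadata]:
    """Read sample metadata (sample, condition, time, event)."""
    df = _read_table(path, delimiter)
    need = ["sample", "condition", "time", "event"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks required columns: {missing}")
    return [
        SampleMetadata(sample=str(r.sample), condition=str(r.condition),
                       time=float(r.time), event=int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: Sequence[SampleMetadata], path, delimiter: str | None = None) -> None:
    df = pd.DataFrame(
        [(m.sample, m.condition, m.time, m.event) for m in meta],
        columns=["sample", "condition", "time", "event"],
    )
    df.to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format="%.17g")
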