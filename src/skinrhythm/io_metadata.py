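"""Expression-matrix, sample-metadata and gene-set input handling.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene ids
on the index and sample ids on the columns (log2 intensities). Sample metadata
is a list of :class:`SampleRecord`. Gene sets are read from GMT files into a
:class:`GeneSetCollection`.

Internal time is the chronotype-corrected time axis: wall sampling time minus
the subject's mid-sleep on free days (MSF_sc). Times are stored unwrapped
(a 32-h sample stays at 32 h); periodic model fitting reduces time modulo the
period internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("skinrhythm")

LAYERS = ("dermis", "epidermis")

METADATA_COLUMNS = ("sample_id", "subject_id", "layer", "wall_time_h", "msf_sc_h")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending location."""


@dataclass(frozen=True)
class SampleRecord:
    """One biopsy: identity, layer, wall sampling time and chronotype.

    ``internal_time_h`` is ``wall_time_h - msf_sc_h`` once populated by
    :func:`to_internal_time`; ``None`` until then.
    """

    sample_id: str
    subject_id: str
    layer: str
    wall_time_h: float
    msf_sc_h: float | None = None
    internal_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(
                f"layer must be one of {LAYERS}, got {self.layer!r} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Reactome pathways from an MSigDB GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def load_expression(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix from TSV/CSV.

    First column: gene ids; header row: sample ids. Duplicate gene ids are
    rejected (run :func:`average_probes_to_genes` on probe-level data first);
    any non-numeric or missing cell raises :class:`ParseError` naming the
    row/column.
    """
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    if raw.columns.size == 0:
        raise FormatError(f"{path}: no sample columns found")
    # a numeric header means the first data row was consumed as the header
    numeric_header = 0
    for c in raw.columns:
        try:
            float(str(c))
            numeric_header += 1
        except ValueError:
            pass
    if numeric_header == raw.columns.size:
        raise FormatError(f"{path}: header row missing (all column labels numeric)")
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id(s): {sorted(set(dup))!r}; "
                         "average probe-level rows to genes first")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(converted.to_numpy()))[0]
        if bad.size:
            i = bad[0]
            raise ParseError(
                f"{path}: non-numeric or missing value {raw.iloc[i, j]!r} at "
                f"gene {raw.index[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))


def load_metadata(path: str | Path, dialect: str | None = None) -> list[SampleRecord]:
    """Read the sample-metadata table (one row per biopsy)."""
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata is missing column(s) {missing}")
    dup_mask = df.duplicated(subset=["subject_id", "layer", "wall_time_h"], keep=False)
    if dup_mask.any():
        rows = df.loc[dup_mask, ["subject_id", "layer", "wall_time_h"]]
        raise ValueError(f"{path}: duplicate (subject, layer, wall_time) rows:\n{rows}")
    records = []
    for row in df.itertuples(index=False):
        msf = getattr(row, "msf_sc_h")
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                subject_id=str(row.subject_id),
                layer=str(row.layer),
                wall_time_h=float(row.wall_time_h),
                msf_sc_h=None if pd.isna(msf) else float(msf),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids present")
    return records


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated members)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and at least one member")
            name, desc, *members = parts
            members = [m for m in members if m]
            # tolerate duplicated members within a line (seen in the wild)
            seen: dict[str, None] = dict.fromkeys(members)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def check_matrix_metadata(matrix: pd.DataFrame, records: Sequence[SampleRecord]) -> None:
    """Require exact agreement between matrix columns and metadata sample ids."""
    mat_ids = set(matrix.columns)
    meta_ids = {r.sample_id for r in records}
    if mat_ids != meta_ids:
        only_mat = sorted(mat_ids - meta_ids)[:5]
        only_meta = sorted(meta_ids - mat_ids)[:5]
        raise ValueError(
            "expression matrix and metadata sample ids disagree: "
            f"matrix-only {only_mat}, metadata-only {only_meta}"
        )


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_internal_time(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Populate internal time as wall time minus MSF_sc for every record.

    Internal time is left unwrapped (the final 32-h sample maps to, e.g.,
    27.5 h); periodic fits wrap it modulo the period themselves.
    """
    missing = sorted({r.subject_id for r in records if r.msf_sc_h is None})
    if missing:
        raise ValueError(f"msf_sc_h missing for subject(s): {missing}")
    return [replace(r, internal_time_h=r.wall_time_h - r.msf_sc_h) for r in records]


def use_wall_time(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Copy wall time into the internal-time slot (external-time sensitivity runs)."""
    return [replace(r, internal_time_h=r.wall_time_h) for r in records]


def average_probes_to_genes(
    probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by averaging probe rows.

    Probes absent from ``probe_to_gene`` are dropped (count logged). Each gene
    row is the arithmetic mean of its probes' log2 values.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("average_probes_to_genes: dropped %d unmapped probe(s)", n_dropped)
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene")
    sub = probe_matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name=probe_matrix.index.name)
    out = sub.groupby(genes, sort=True).mean()
    out.index = out.index.astype(str)
    return out


def flag_outlier_samples(matrix: pd.DataFrame, k: float = 4.0) -> list[str]:
    """Flag samples far from the cohort centroid in PC1-2 space.

    A sample is flagged when its Euclidean distance from the centroid in the
    plane of the first two principal components exceeds ``k`` standard
    deviations of that distance over all samples. Flagging only; the caller
    decides removal. ``k = 0`` degenerates to flagging every sample at a
    positive distance.
    """
    if matrix.shape[1] < 3:
        raise ValueError("outlier flagging needs at least 3 samples")
    if k < 0:
        raise ValueError("k must be non-negative")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    # top-2 PC scores via SVD; with zero variance all scores are 0
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :2] * s[:2]
    d = np.hypot(scores[:, 0], scores[:, 1] if scores.shape[1] > 1 else 0.0)
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    flagged = d > k * sd
    return [str(c) for c, f in zip(matrix.columns, flagged) if f]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_expression(matrix: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    matrix.to_csv(path, sep=sep, index_label="gene_id")


def write_metadata(records: Sequence[SampleRecord], path: str | Path,
                   dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    df = records_to_frame(records)
    df.to_csv(path, sep=sep, index=False)


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "layer": r.layer,
                "wall_time_h": r.wall_time_h,
                "msf_sc_h": r.msf_sc_h,
                "internal_time_h": r.internal_time_h,
            }
            for r in records
        ]
    )
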