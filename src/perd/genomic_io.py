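"""Genomic intervals, overlap queries, and readers for the pipeline's on-disk formats.

Coordinates are stored 0-based half-open (BED convention) throughout the
package.  Coordinates printed in prose and in variant tables follow the
1-based inclusive convention and are converted on parse, so a textual
coordinate round-trips losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class ParseError(ValueError):
    """Raised when an on-disk record cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def format_1based(self) -> str:
        """Render as the 1-based inclusive text convention, e.g. chr1:101-200."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class VariantRecord:
    """A point variant (eQTL / PGx) with its associated gene and significance.

    ``pos`` is 1-based, the convention of eQTL and GWAS tables.
    """

    id: str
    chrom: str
    pos: int
    gene: str
    qvalue: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue must be in [0, 1], got {self.qvalue}")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation for perturbation experiments."""

    sample_id: str
    cell_line: str
    drug: Optional[str]
    condition: str  # "control" or "treated"
    dose: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in ("control", "treated"):
            raise ValueError(f"condition must be control|treated, got {self.condition!r}")
        if self.condition == "treated" and not self.drug:
            raise ValueError(f"treated sample {self.sample_id!r} must carry a drug name")


# ---------------------------------------------------------------------------
# interval arithmetic


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Abutting intervals (a.end == b.start) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def point_in_interval(chrom: str, pos_1based: int, iv: GenomicInterval) -> bool:
    """True iff a 1-based position lies inside the interval's inclusive printed range."""
    if pos_1based < 1:
        raise ValueError("pos_1based must be >= 1")
    return chrom == iv.chrom and iv.start < pos_1based <= iv.end


def bulk_overlap(
    query_intervals: Sequence[GenomicInterval],
    subject_intervals: Sequence[GenomicInterval],
) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs of overlapping intervals.

    Uses a per-chromosome interval tree; output sorted by query then subject
    index so results are deterministic.
    """
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subject_intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, q in enumerate(query_intervals):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = sorted(hit.data for hit in tree.overlap(q.start, q.end))
        pairs.extend((i, j) for j in hits)
    return pairs


# ---------------------------------------------------------------------------
# text parsing

_COORD_RE = re.compile(
    r"""^\s*(?P<chrom>[^:\s]+)\s*:\s*
        (?P<start>[\d,\s]+?)\s*[-‐‑‒–—]\s*
        (?P<end>[\d,\s]+?)\s*$""",
    re.VERBOSE,
)


def parse_text_coordinate(s: str) -> GenomicInterval:
    """Parse a textual coordinate like ``chr20: 44, 640, 672–44, 653, 156``.

    The text convention is 1-based inclusive; the returned interval is
    0-based half-open.  Hyphen and en-dash separators, commas and internal
    spaces are all accepted.
    """
    m = _COORD_RE.match(s)
    if m is None:
        raise ParseError(f"cannot parse genomic coordinate {s!r}")
    start_1 = int(re.sub(r"[,\s]", "", m.group("start")))
    end_1 = int(re.sub(r"[,\s]", "", m.group("end")))
    if start_1 < 1 or end_1 < start_1:
        raise ParseError(f"invalid coordinate range in {s!r}")
    return GenomicInterval(m.group("chrom"), start_1 - 1, end_1)


# ---------------------------------------------------------------------------
# file readers


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED4 as (interval, name) tuples; name is "" for BED3.

    Track definition lines, browser lines and ``#`` comments are skipped.
    Coordinates are taken as native BED (0-based half-open).
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: expected >=3 tab-separated columns at line {lineno}")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from None
            if end <= start:
                raise ParseError(f"{path}: end <= start at line {lineno}")
            if start < 0:
                raise ParseError(f"{path}: negative start at line {lineno}")
            name = fields[3] if len(fields) > 3 else ""
            out.append((GenomicInterval(chrom, start, end), name))
    return out


def read_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a features x samples numeric matrix from TSV or GCT 1.2.

    TSV: row ids in column 1, header row of sample ids.  GCT 1.2: the
    two-line header is validated and the Description column dropped.
    Missing values are kept as NaN, never silently zeroed; duplicate row or
    column ids and ragged rows are errors.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ParseError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        if df.shape != (n_rows, n_cols):
            raise ParseError(
                f"{path}: GCT header declares {n_rows}x{n_cols} but body is {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown matrix format {format!r}")

    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path}: duplicate row ids {dupes}")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate column ids")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix body ({exc})") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix in a dialect :func:`read_matrix` reads back."""
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            body = df.copy()
            body.insert(0, "Description", "na")
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with columns variant_id, chrom, pos, gene, qvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "gene", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: variant table missing columns {sorted(missing)}")
    return [
        VariantRecord(
            id=str(row.variant_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            gene=str(row.gene),
            qvalue=float(row.qvalue),
        )
        for row in df.itertuples()
    ]


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"variant_id": v.id, "chrom": v.chrom, "pos": v.pos, "gene": v.gene, "qvalue": v.qvalue}
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample metadata TSV (sample_id, cell_line, drug, condition[, dose])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "cell_line", "drug", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    out = []
    for row in df.itertuples():
        drug = None if pd.isna(row.drug) or row.drug == "" else str(row.drug)
        dose = float(row.dose) if hasattr(row, "dose") and pd.notna(row.dose) else None
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                cell_line=str(row.cell_line),
                drug=drug,
                condition=str(row.condition),
                dose=dose,
            )
        )
    return out


def write_sample_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "cell_line": m.cell_line,
                "drug": m.drug if m.drug is not None else "",
                "condition": m.condition,
                "dose": m.dose if m.dose is not None else "",
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)
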