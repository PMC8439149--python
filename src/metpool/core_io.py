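"""Domain types and on-disk formats shared across the pipeline.

Conventions: matrices (counts, expression) travel as tab-separated text
with the id column first and sample ids in the header; metadata and cell
counts are comma-separated. Barcode libraries may be FASTA (description
fields carry the cell-line and pool assignment) or CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_NT = frozenset("ACGT")

#: Canonical organ names for the five-site intracardiac assay, plus the
#: reserved pre-injection pseudo-organ. The vocabulary is open: any other
#: string is accepted as an organ label.
CANONICAL_ORGANS = ("brain", "lung", "liver", "kidney", "bone")
PRE_INJECTION = "pre_injection"


class FormatError(ValueError):
    """Raised when an on-disk file violates the format contract."""


@dataclass(frozen=True)
class Barcode:
    """A clonal DNA barcode: a short fixed tag integrated into one cell
    line's genome so its descendants can be counted by sequencing."""

    id: str
    sequence: str
    cell_line: str = ""
    pool_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise FormatError(
                f"barcode {self.id!r}: non-ACGT characters {sorted(bad)!r}"
            )
        if not self.sequence:
            raise FormatError(f"barcode {self.id!r}: empty sequence")


@dataclass(frozen=True)
class BarcodeLibrary:
    """An ordered registry of barcodes of uniform length with unique ids
    and unique sequences."""

    barcodes: tuple[Barcode, ...]
    barcode_length: int

    def __post_init__(self) -> None:
        seen_seq: dict[str, str] = {}
        seen_id: set[str] = set()
        for bc in self.barcodes:
            if len(bc.sequence) != self.barcode_length:
                raise FormatError(
                    f"barcode {bc.id!r} has length {len(bc.sequence)}, "
                    f"library declares {self.barcode_length}"
                )
            if bc.id in seen_id:
                raise FormatError(f"duplicate barcode id {bc.id!r}")
            seen_id.add(bc.id)
            if bc.sequence in seen_seq:
                raise FormatError(
                    f"duplicate barcode sequence shared by ids "
                    f"{seen_seq[bc.sequence]!r} and {bc.id!r}"
                )
            seen_seq[bc.sequence] = bc.id

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def ids(self) -> list[str]:
        return [bc.id for bc in self.barcodes]

    @property
    def sequences(self) -> list[str]:
        return [bc.sequence for bc in self.barcodes]

    @classmethod
    def from_barcodes(cls, barcodes: Iterable[Barcode]) -> "BarcodeLibrary":
        bcs = tuple(barcodes)
        if not bcs:
            raise FormatError("empty barcode library")
        lengths = {len(b.sequence) for b in bcs}
        if len(lengths) > 1:
            raise FormatError(
                f"heterogeneous barcode lengths {sorted(lengths)}; "
                "all library sequences must share one length"
            )
        return cls(barcodes=bcs, barcode_length=lengths.pop())


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample: which mouse, which organ, which
    cohort. ``organ == "pre_injection"`` marks the pre-injected pool."""

    sample_id: str
    mouse_id: str = ""
    organ: str = "other"
    cohort: str = ""
    replicate_index: int = 0

    @property
    def is_pre_injection(self) -> bool:
        return self.organ == PRE_INJECTION


@dataclass
class BarcodeCountTable:
    """Integer read counts per barcode per sample, with per-sample tallies
    of fragments that matched no barcode (``unassigned``) or more than one
    (``ambiguous``)."""

    counts: np.ndarray  # (n_barcodes, n_samples), non-negative ints
    library: BarcodeLibrary
    samples: list[SampleMeta]
    unassigned: np.ndarray = None  # (n_samples,)
    ambiguous: np.ndarray = None  # (n_samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        nb, ns = self.counts.shape
        if nb != len(self.library):
            raise FormatError(
                f"counts has {nb} barcode rows, library has {len(self.library)}"
            )
        if ns != len(self.samples):
            raise FormatError(
                f"counts has {ns} sample columns, metadata lists {len(self.samples)}"
            )
        if np.any(self.counts < 0):
            raise FormatError("negative barcode counts")
        if self.unassigned is None:
            self.unassigned = np.zeros(ns, dtype=np.int64)
        else:
            self.unassigned = np.asarray(self.unassigned, dtype=np.int64)
        if self.ambiguous is None:
            self.ambiguous = np.zeros(ns, dtype=np.int64)
        else:
            self.ambiguous = np.asarray(self.ambiguous, dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.library.ids, columns=self.sample_ids
        )

    def select_samples(self, keep: Sequence[bool]) -> "BarcodeCountTable":
        keep = np.asarray(keep, dtype=bool)
        return BarcodeCountTable(
            counts=self.counts[:, keep],
            library=self.library,
            samples=[s for s, k in zip(self.samples, keep) if k],
            unassigned=self.unassigned[keep],
            ambiguous=self.ambiguous[keep],
        )

    def concat(self, other: "BarcodeCountTable") -> "BarcodeCountTable":
        if other.library is not self.library and other.library != self.library:
            raise FormatError("cannot concatenate tables over different libraries")
        return BarcodeCountTable(
            counts=np.hstack([self.counts, other.counts]),
            library=self.library,
            samples=self.samples + other.samples,
            unassigned=np.concatenate([self.unassigned, other.unassigned]),
            ambiguous=np.concatenate([self.ambiguous, other.ambiguous]),
        )


@dataclass
class CellCountTable:
    """Total cancer cells isolated per (mouse, organ), e.g. by sorting.

    These are the c_i factors that convert barcode fractions into
    inferred absolute cell numbers.
    """

    total_cells: dict[tuple[str, str], float]  # (mouse_id, organ) -> cells

    def __post_init__(self) -> None:
        for key, v in self.total_cells.items():
            if v < 0:
                raise FormatError(f"negative cell count for {key}")

    def get(self, mouse_id: str, organ: str) -> float | None:
        return self.total_cells.get((mouse_id, organ))


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix. ``scale`` records whether the
    values are raw counts, counts-per-million, or log2 units; negative
    entries are rejected unless the scale is log2."""

    values: np.ndarray
    gene_ids: list[str]
    samples: list[SampleMeta]
    scale: str = "counts"  # counts | cpm | log2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        ng, ns = self.values.shape
        if ng != len(self.gene_ids):
            raise FormatError("gene_ids length does not match matrix rows")
        if ns != len(self.samples):
            raise FormatError("sample list length does not match matrix columns")
        if self.scale not in ("counts", "cpm", "log2"):
            raise FormatError(f"unknown expression scale {self.scale!r}")
        if self.scale in ("counts", "cpm") and np.any(self.values < 0):
            raise FormatError(f"negative values not allowed on scale {self.scale!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_fasta_header(record) -> tuple[str, str, str]:
    """FASTA description format: ``>id cell_line=NAME pool_id=P``; missing
    fields default to empty."""
    cell_line = ""
    pool_id = ""
    for token in record.description.split()[1:]:
        if token.startswith("cell_line="):
            cell_line = token[len("cell_line="):]
        elif token.startswith("pool_id="):
            pool_id = token[len("pool_id="):]
    return record.id, cell_line, pool_id


def read_barcode_library(path: str | Path, format: str | None = None) -> BarcodeLibrary:
    """Read a barcode library from FASTA or CSV.

    CSV columns: ``id,sequence,cell_line[,pool_id]``. FASTA records use
    ``cell_line=`` / ``pool_id=`` key-value pairs in the description.
    Duplicate sequences, duplicate ids, non-ACGT characters and
    heterogeneous lengths are hard errors.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "csv"
    barcodes: list[Barcode] = []
    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            bc_id, cell_line, pool_id = _parse_fasta_header(record)
            barcodes.append(
                Barcode(
                    id=bc_id,
                    sequence=str(record.seq).upper(),
                    cell_line=cell_line,
                    pool_id=pool_id,
                )
            )
    elif format == "csv":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"id", "sequence"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"barcode CSV must have columns {sorted(required)}; got {list(df.columns)}"
            )
        for _, row in df.iterrows():
            barcodes.append(
                Barcode(
                    id=row["id"],
                    sequence=row["sequence"].upper(),
                    cell_line=row.get("cell_line", ""),
                    pool_id=row.get("pool_id", ""),
                )
            )
    else:
        raise ValueError(f"unknown library format {format!r}")
    return BarcodeLibrary.from_barcodes(barcodes)


def write_barcode_library(library: BarcodeLibrary, path: str | Path) -> None:
    """Write a library as FASTA with key-value description fields."""
    with open(path, "w") as fh:
        for bc in library:
            fh.write(f">{bc.id} cell_line={bc.cell_line} pool_id={bc.pool_id}\n")
            fh.write(bc.sequence + "\n")


def _meta_columns(samples: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "mouse_id": [s.mouse_id for s in samples],
            "organ": [s.organ for s in samples],
            "cohort": [s.cohort for s in samples],
            "replicate_index": [s.replicate_index for s in samples],
        }
    )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata CSV (columns sample_id, mouse_id, organ,
    cohort, replicate_index; only sample_id is required)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise FormatError("sample metadata needs a sample_id column")
    metas = []
    ids_seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in ids_seen:
            raise FormatError(f"duplicate sample_id {sid!r}")
        ids_seen.add(sid)
        metas.append(
            SampleMeta(
                sample_id=sid,
                mouse_id=row.get("mouse_id", ""),
                organ=row.get("organ", "other") or "other",
                cohort=row.get("cohort", ""),
                replicate_index=int(row.get("replicate_index") or 0),
            )
        )
    return metas


def write_sample_meta(samples: list[SampleMeta], path: str | Path) -> None:
    _meta_columns(samples).to_csv(path, index=False)


def read_count_table(
    path: str | Path,
    library: BarcodeLibrary,
    samples: list[SampleMeta] | None = None,
) -> BarcodeCountTable:
    """Read a TSV count matrix (barcode ids in the first column, sample ids
    in the header) against a library. Unknown barcode ids and negative
    entries are errors; barcodes absent from the file get zero counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = set(df.index) - set(library.ids)
    if unknown:
        raise FormatError(f"count table has barcode ids not in library: {sorted(unknown)}")
    if df.size and not np.issubdtype(df.values.dtype, np.number):
        raise FormatError("count table contains non-numeric entries")
    if np.any(df.values < 0):
        raise FormatError("count table contains negative entries")
    if np.any(df.values != np.floor(df.values)):
        raise FormatError("count table contains non-integer entries")
    full = df.reindex(index=library.ids, fill_value=0)
    if samples is None:
        samples = [SampleMeta(sample_id=str(c)) for c in df.columns]
    else:
        by_id = {s.sample_id: s for s in samples}
        missing = [c for c in df.columns if c not in by_id]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        samples = [by_id[str(c)] for c in df.columns]
    return BarcodeCountTable(
        counts=full.values.astype(np.int64), library=library, samples=samples
    )


def write_count_table(table: BarcodeCountTable, path: str | Path) -> None:
    """Write counts as TSV; round-trips bit-exactly through
    :func:`read_count_table`."""
    table.to_frame().to_csv(path, sep="\t", index_label="barcode_id")


def read_cell_counts(path: str | Path) -> CellCountTable:
    """Read total sorted cancer cells per (mouse, organ) from CSV with
    columns mouse_id, organ, total_cells."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "organ": str})
    required = {"mouse_id", "organ", "total_cells"}
    if not required.issubset(df.columns):
        raise FormatError(f"cell-count CSV must have columns {sorted(required)}")
    return CellCountTable(
        total_cells={
            (row.mouse_id, row.organ): float(row.total_cells)
            for row in df.itertuples()
        }
    )


def write_cell_counts(cells: CellCountTable, path: str | Path) -> None:
    rows = [
        {"mouse_id": m, "organ": o, "total_cells": v}
        for (m, o), v in cells.total_cells.items()
    ]
    pd.DataFrame(rows, columns=["mouse_id", "organ", "total_cells"]).to_csv(
        path, index=False
    )


def read_expression_matrix(
    path: str | Path,
    scale: str = "counts",
    samples: list[SampleMeta] | None = None,
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV. NaN entries are an error unless
    ``allow_missing`` is set."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not allow_missing and df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise FormatError(f"expression matrix has missing values (e.g. genes {bad})")
    if samples is None:
        samples = [SampleMeta(sample_id=str(c)) for c in df.columns]
    return ExpressionMatrix(
        values=df.values.astype(float),
        gene_ids=[str(g) for g in df.index],
        samples=samples,
        scale=scale,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
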