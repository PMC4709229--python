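"""Readers and writers for the formats the pipeline touches.

FASTQ (Sanger/Phred+33, plain or gzip), count-table TSV
(``gene_id length count_lib1 count_lib2``), annotation TSV
(``gene_id term_id``), qPCR CT TSV (``sample_id group gene_id ct``),
truth/result TSVs.  All TSVs are UTF-8 with Unix newlines.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from dgepipe.fastq_filter import ReadRecord
from dgepipe.qpcr import QpcrTable
from dgepipe.quantification import CountTable

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_count_table",
    "write_count_table",
    "read_annotation",
    "write_annotation",
    "read_qpcr_table",
    "write_tsv",
    "TRUTH_SUFFIX",
]

# Ground-truth files are written next to their data file with this suffix.
TRUTH_SUFFIX = ".truth.tsv"

_INT_RE = re.compile(r"^[0-9]+$")


class FastqFormatError(ValueError):
    """Malformed FASTQ input, reported with the offending record."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Lazily stream Phred+33 FASTQ records; aborts on the first malformed one."""
    with _open_text(path) as handle:
        record_no = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"record {record_no} ({title.split()[0]!r}) near line "
                        f"{record_no * 4}: sequence and quality lengths differ"
                    )
                scores = tuple(ord(c) - 33 for c in qual)
                if any(s < 0 or s > 93 for s in scores):
                    raise FastqFormatError(
                        f"record {record_no} ({title.split()[0]!r}): quality "
                        "characters outside the Phred+33 range"
                    )
                yield ReadRecord(
                    identifier=title.split()[0], sequence=seq, quality=scores
                )
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(
                f"malformed FASTQ near record {record_no + 1} "
                f"(line {record_no * 4 + 1}): {exc}"
            ) from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quality)
            handle.write(f"@{read.identifier}\n{read.sequence}\n+\n{qual}\n")


def _strict_int_column(frame: pd.DataFrame, column: str, path) -> pd.Series:
    values = frame[column].astype(str).str.strip()
    bad = ~values.map(lambda v: bool(_INT_RE.match(v)))
    if bad.any():
        offender = values[bad].iloc[0]
        raise ValueError(
            f"{path}: column {column!r} must hold plain non-negative "
            f"integers, got {offender!r}"
        )
    return values.astype("int64")


def read_count_table(path, totals: tuple[int, int] | None = None) -> CountTable:
    """Read a ``gene_id length count_lib1 count_lib2`` TSV.

    Counts must be written as plain decimal integers (scientific notation is
    rejected); duplicate gene ids abort.  ``totals`` overrides the default
    column-sum library totals.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene_id", "length", "count_lib1", "count_lib2"]
    if list(frame.columns)[: len(expected)] != expected:
        raise ValueError(
            f"{path}: expected header {expected}, got {list(frame.columns)}"
        )
    out = pd.DataFrame({"gene_id": frame["gene_id"]})
    for column in ("length", "count_lib1", "count_lib2"):
        out[column] = _strict_int_column(frame, column, path)
    if totals is None:
        return CountTable(out)
    return CountTable(out, n1=totals[0], n2=totals[1])


def write_count_table(table: CountTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a ``gene_id term_id`` TSV (one row per annotation)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns)[:2] != ["gene_id", "term_id"]:
        raise ValueError(
            f"{path}: expected header ['gene_id', 'term_id'], "
            f"got {list(frame.columns)}"
        )
    return frame[["gene_id", "term_id"]]


def write_annotation(frame: pd.DataFrame, path) -> None:
    frame[["gene_id", "term_id"]].to_csv(path, sep="\t", index=False)


def read_qpcr_table(path, reference_genes: Iterable[str]) -> QpcrTable:
    """Read a ``sample_id group gene_id ct`` TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"ct": float})
    return QpcrTable(frame=frame, reference_genes=tuple(reference_genes))


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a result table deterministically (fixed float formatting)."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)
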