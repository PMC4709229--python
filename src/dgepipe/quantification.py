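"""RPKM quantification of a two-library gene count table.

RPKM (reads per kilobase of transcript per million mapped reads) rescales a
raw read count ``C`` for a gene of length ``L`` bp in a library with ``N``
uniquely mapped reads as ``10^9 * C / (N * L)``, making expression levels
comparable across genes of different length and libraries of different depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "rpkm", "rpkm_table"]

_REQUIRED_COLUMNS = ("gene_id", "length", "count_lib1", "count_lib2")


@dataclass(frozen=True)
class CountTable:
    """Per-gene integer read counts for two libraries plus gene lengths.

    Parameters
    ----------
    frame
        DataFrame with columns ``gene_id`` (unique strings), ``length``
        (positive int, bp), ``count_lib1`` and ``count_lib2`` (non-negative
        int reads uniquely mapped to the gene).
    n1, n2
        Total uniquely mapped reads per library.  Default to the column
        sums; externally supplied totals may be larger (reads mapped to
        genes outside the table) but never smaller.
    """

    frame: pd.DataFrame
    n1: int = field(default=0)
    n2: int = field(default=0)

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if frame["gene_id"].duplicated().any():
            dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        for col in ("length", "count_lib1", "count_lib2"):
            values = frame[col].to_numpy()
            if not np.issubdtype(values.dtype, np.integer):
                raise TypeError(f"column {col!r} must be integer, got {values.dtype}")
        if (frame["length"] < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        if (frame[["count_lib1", "count_lib2"]] < 0).to_numpy().any():
            raise ValueError("counts must be non-negative")

        sum1 = int(frame["count_lib1"].sum())
        sum2 = int(frame["count_lib2"].sum())
        if self.n1 == 0 and self.n2 == 0:
            object.__setattr__(self, "n1", sum1)
            object.__setattr__(self, "n2", sum2)
        else:
            if self.n1 < sum1 or self.n2 < sum2:
                raise ValueError(
                    "library totals cannot be smaller than the column sums "
                    f"(got N1={self.n1} < {sum1} or N2={self.n2} < {sum2})"
                )
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")

    @property
    def gene_ids(self) -> pd.Series:
        return self.frame["gene_id"]

    def __len__(self) -> int:
        return len(self.frame)


def rpkm(count, library_total, gene_length_bp):
    """Reads per kilobase per million mapped reads.

    ``rpkm = 1e9 * count / (library_total * gene_length_bp)``.

    Accepts scalars or numpy arrays.  ``library_total`` and
    ``gene_length_bp`` must be strictly positive and no gene may hold more
    reads than its library total.
    """
    count = np.asarray(count, dtype=float)
    total = np.asarray(library_total, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    if np.any(total <= 0):
        raise ValueError("library_total must be positive")
    if np.any(length <= 0):
        raise ValueError("gene_length_bp must be positive")
    if np.any(count < 0):
        raise ValueError("count must be non-negative")
    if np.any(count > total):
        raise ValueError("count cannot exceed library_total")
    out = 1e9 * count / (total * length)
    return float(out) if out.ndim == 0 else out


def rpkm_table(table: CountTable) -> pd.DataFrame:
    """Per-gene RPKM for both libraries, each using its own library total.

    Returns a copy of the count frame with ``rpkm_lib1`` and ``rpkm_lib2``
    columns appended.
    """
    frame = table.frame.copy()
    try:
        frame["rpkm_lib1"] = rpkm(
            frame["count_lib1"].to_numpy(), table.n1, frame["length"].to_numpy()
        )
        frame["rpkm_lib2"] = rpkm(
            frame["count_lib2"].to_numpy(), table.n2, frame["length"].to_numpy()
        )
    except ValueError as exc:
        raise ValueError(f"RPKM computation failed: {exc}") from exc
    return frame
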