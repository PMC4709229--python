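"""Whole-read FASTQ quality filtering for Illumina libraries.

Two rule sets are used at different stages of a two-library expression
study.  Reads feeding the de novo transcriptome assembly are discarded when
they carry adaptor contamination, when unknown nucleotides (N) make up more
than 5% of the read, or when more than 20% of bases have Phred quality <= 10.
Reads for the expression-profile libraries use looser cutoffs: more than 10%
N, or more than 50% of bases at quality <= 5.  All thresholds are strict
inequalities; a read sitting exactly on a boundary is retained.  Reads are
discarded whole -- no trimming.

Quality strings are Sanger/Phred+33 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ReadRecord",
    "FilterPolicy",
    "FilterReport",
    "base_fractions",
    "classify_read",
    "filter_reads",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases over {A,C,G,T,N}, Phred scores."""

    identifier: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.identifier!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        object.__setattr__(self, "quality", tuple(int(q) for q in self.quality))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterPolicy:
    """Discard rules for one filtering stage.

    A read is discarded iff any of:

    * the 5' prefix of ``adaptor`` of length ``adaptor_min_match`` occurs
      anywhere in the read (adaptor contamination),
    * fraction of N bases  > ``max_n_fraction``,
    * fraction of bases with quality <= ``low_quality_threshold``
      > ``max_low_quality_fraction``.

    All comparisons are strict, so boundary reads are retained.  N bases are
    judged by their recorded quality like any other base; the two rules are
    independent.
    """

    max_n_fraction: float
    low_quality_threshold: int
    max_low_quality_fraction: float
    adaptor: str = ""
    adaptor_min_match: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.max_n_fraction <= 1:
            raise ValueError("max_n_fraction must lie in (0, 1]")
        if not 0 < self.max_low_quality_fraction <= 1:
            raise ValueError("max_low_quality_fraction must lie in (0, 1]")
        if self.low_quality_threshold <= 0:
            raise ValueError("low_quality_threshold must be positive")
        if self.adaptor_min_match <= 0:
            raise ValueError("adaptor_min_match must be positive")
        if set(self.adaptor) - _VALID_BASES:
            raise ValueError("adaptor must be over the alphabet {A,C,G,T,N}")

    @classmethod
    def transcriptome(cls, adaptor: str = "", **kwargs) -> "FilterPolicy":
        """Assembly-stage rules: >5% N or >20% bases at quality <= 10."""
        return cls(
            max_n_fraction=0.05,
            low_quality_threshold=10,
            max_low_quality_fraction=0.20,
            adaptor=adaptor,
            **kwargs,
        )

    @classmethod
    def profile(cls, adaptor: str = "", **kwargs) -> "FilterPolicy":
        """Expression-profile rules: >10% N or >50% bases at quality <= 5."""
        return cls(
            max_n_fraction=0.10,
            low_quality_threshold=5,
            max_low_quality_fraction=0.50,
            adaptor=adaptor,
            **kwargs,
        )

    @property
    def adaptor_probe(self) -> str:
        """The adaptor prefix actually searched for ('' disables the rule)."""
        if not self.adaptor:
            return ""
        return self.adaptor[: self.adaptor_min_match]


@dataclass
class FilterReport:
    """Per-rule discard tallies; each read is attributed to its first failing rule."""

    total_reads: int = 0
    discarded_adaptor: int = 0
    discarded_n: int = 0
    discarded_quality: int = 0
    retained: int = 0

    def check(self) -> None:
        if (
            self.retained
            + self.discarded_adaptor
            + self.discarded_n
            + self.discarded_quality
            != self.total_reads
        ):
            raise AssertionError("filter report tallies do not sum to total_reads")

    def as_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "discarded_adaptor": self.discarded_adaptor,
            "discarded_n": self.discarded_n,
            "discarded_quality": self.discarded_quality,
            "retained": self.retained,
        }


def base_fractions(read: ReadRecord, policy: FilterPolicy) -> tuple[float, float]:
    """(N fraction, low-quality fraction) of a read under a policy.

    Both use the full read length as denominator; N bases count in both.
    """
    length = len(read)
    if length == 0:
        raise ValueError(f"read {read.identifier!r}: empty sequence")
    n_count = read.sequence.count("N")
    lowq = sum(1 for q in read.quality if q <= policy.low_quality_threshold)
    return n_count / length, lowq / length


def classify_read(read: ReadRecord, policy: FilterPolicy) -> str:
    """Label a read 'adaptor', 'n', 'quality', or 'clean'.

    Rules are evaluated adaptor -> N -> quality so multiply-failing reads
    are attributed deterministically.
    """
    probe = policy.adaptor_probe
    if probe and probe in read.sequence:
        return "adaptor"
    n_fraction, low_quality_fraction = base_fractions(read, policy)
    if n_fraction > policy.max_n_fraction:
        return "n"
    if low_quality_fraction > policy.max_low_quality_fraction:
        return "quality"
    return "clean"


def filter_reads(
    reads: Iterable[ReadRecord], policy: FilterPolicy
) -> tuple[list[ReadRecord], FilterReport]:
    """Partition a read stream into retained reads and per-rule discard tallies."""
    report = FilterReport()
    retained: list[ReadRecord] = []
    for read in reads:
        report.total_reads += 1
        label = classify_read(read, policy)
        if label == "clean":
            retained.append(read)
            report.retained += 1
        elif label == "adaptor":
            report.discarded_adaptor += 1
        elif label == "n":
            report.discarded_n += 1
        else:
            report.discarded_quality += 1
    report.check()
    return retained, report
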