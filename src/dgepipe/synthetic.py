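"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`generate_count_tables` -- two-library gene count tables whose
  counts are Poisson around expression levels scaled to the requested
  library depths, with a designated subset of genes at specified true
  fold changes (library 1 over library 2) and the rest null;
* :func:`generate_fastq` -- reads with controllable per-base N rate,
  quality profile, and adaptor contamination, each labelled with the
  filtering fate the discard rules will assign it;
* :func:`generate_annotation` -- gene-to-term maps with designated terms
  enriched for a DEG list at an elevated membership rate.

Everything is driven by an explicit integer seed; identical spec + seed
reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dgepipe.fastq_filter import FilterPolicy, ReadRecord, classify_read
from dgepipe.quantification import CountTable

__all__ = [
    "SimulationSpec",
    "FastqSpec",
    "QualityModel",
    "generate_count_tables",
    "generate_fastq",
    "generate_annotation",
]

# TruSeq universal adaptor 5' end; any fixed sequence works for simulation.
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class SimulationSpec:
    """Study design for a two-library count simulation.

    Parameters
    ----------
    n_genes
        Number of genes in the table.
    library_totals
        (N1, N2): requested total mapped reads per library.  Must be at
        least ``10 * n_genes`` so expected per-gene counts are
        non-degenerate.
    de_fraction
        Proportion of genes that are truly differentially expressed;
        ``de_fraction * n_genes`` must be an integer.
    fold_changes
        True expression ratio (library 1 / library 2) per DE gene: a scalar
        applied to all DE genes or one positive value per DE gene.
    gene_length_range
        Inclusive bp range gene lengths are drawn from uniformly.
    expression_range
        Relative expression levels are drawn log-uniformly over this range,
        so RPKM spans realistic orders of magnitude.
    overdispersion
        Gamma-Poisson overdispersion; 0 (default) gives pure Poisson
        counts, matching the sampling model of the exact test.
    seed
        Required; there is no implicit randomness.
    """

    n_genes: int
    library_totals: tuple[int, int]
    de_fraction: float
    fold_changes: float | Sequence[float]
    seed: int
    gene_length_range: tuple[int, int] = (200, 3000)
    expression_range: tuple[float, float] = (1.0, 1000.0)
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        n1, n2 = self.library_totals
        if n1 <= 0 or n2 <= 0:
            raise ValueError("library totals must be positive")
        if min(n1, n2) < 10 * self.n_genes:
            raise ValueError(
                "library totals must be >= 10 * n_genes so expected counts "
                "are non-degenerate"
            )
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must lie in [0, 1)")
        n_de = self.de_fraction * self.n_genes
        if abs(n_de - round(n_de)) > 1e-9:
            raise ValueError(
                f"de_fraction * n_genes = {n_de} is not an integer gene count"
            )
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        fc = np.atleast_1d(np.asarray(self.fold_changes, dtype=float))
        if (fc <= 0).any():
            raise ValueError("fold changes must be positive")
        if fc.size not in (1, self.n_de) and self.n_de > 0:
            raise ValueError(
                f"fold_changes must be scalar or length {self.n_de}, got {fc.size}"
            )
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("gene_length_range must be a positive increasing pair")
        lo, hi = self.expression_range
        if not 0 < lo <= hi:
            raise ValueError("expression_range must be a positive increasing pair")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_genes)


def _gene_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"g{i:0{width}d}" for i in range(n)])


def generate_count_tables(spec: SimulationSpec) -> tuple[CountTable, pd.DataFrame]:
    """Draw a two-library count table and its ground-truth DE table.

    Per-gene relative expression levels are sampled log-uniformly, DE genes
    have their library-1 level multiplied by the true fold change, and each
    library's levels are rescaled so expected counts sum to the requested
    library total.  Counts are then drawn Poisson (or gamma-Poisson when
    ``overdispersion > 0``) around those means.

    Returns (table, truth) where truth has columns ``gene_id is_de
    fold_change``; the ratio recorded is the specified library1/library2
    expression ratio before the compositional rescaling.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n1, n2 = spec.library_totals
    gene_ids = _gene_ids(n)

    lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=n
    )
    lo, hi = spec.expression_range
    levels = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)

    fold = np.ones(n)
    is_de = np.zeros(n, dtype=bool)
    if spec.n_de:
        de_idx = rng.choice(n, size=spec.n_de, replace=False)
        fc = np.atleast_1d(np.asarray(spec.fold_changes, dtype=float))
        if fc.size == 1:
            fc = np.repeat(fc, spec.n_de)
        fold[de_idx] = fc
        is_de[de_idx] = True

    levels2 = levels
    levels1 = levels * fold
    mean1 = n1 * levels1 / levels1.sum()
    mean2 = n2 * levels2 / levels2.sum()

    if spec.overdispersion > 0:
        shape = 1.0 / spec.overdispersion
        mean1 = rng.gamma(shape, mean1 / shape)
        mean2 = rng.gamma(shape, mean2 / shape)
    counts1 = rng.poisson(mean1)
    counts2 = rng.poisson(mean2)

    frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length": lengths.astype(np.int64),
            "count_lib1": counts1.astype(np.int64),
            "count_lib2": counts2.astype(np.int64),
        }
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "fold_change": fold}
    )
    return CountTable(frame), truth


@dataclass(frozen=True)
class QualityModel:
    """Per-base Phred score mixture.

    Each read draws its mean quality from a two-component mixture: with
    probability ``low_read_rate`` the read is a low-quality read centred on
    ``low_mean``, otherwise on ``mean``.  Per-base scores are normal around
    the read mean with ``sd``, rounded and clipped to [2, 40].
    """

    mean: float = 38.0
    sd: float = 2.0
    low_read_rate: float = 0.0
    low_mean: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_read_rate <= 1:
            raise ValueError("low_read_rate must lie in [0, 1]")


@dataclass(frozen=True)
class FastqSpec:
    """Design for a labelled synthetic FASTQ file.

    ``n_fraction_per_read`` is the per-base probability of an N call;
    ``contamination_rate`` is the per-read probability of carrying the
    adaptor.  ``read_length`` defaults to the 91 bp average of HiSeq2000
    expression libraries.
    """

    n_reads: int
    seed: int
    read_length: int = 91
    n_fraction_per_read: float = 0.0
    quality: QualityModel = field(default_factory=QualityModel)
    adaptor_sequence: str = DEFAULT_ADAPTOR
    contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0 <= self.n_fraction_per_read <= 1:
            raise ValueError("n_fraction_per_read must lie in [0, 1]")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")


def generate_fastq(
    spec: FastqSpec, policy: FilterPolicy | None = None
) -> tuple[list[ReadRecord], list[str]]:
    """Generate reads plus per-read ground-truth filter labels.

    Each read is built from random bases, optionally implanted with the
    adaptor sequence, sprinkled with N calls at the per-base rate, and given
    Phred scores from the quality mixture.  The label records the fate the
    given ``policy`` (default: transcriptome rules with this spec's adaptor)
    assigns the read, evaluated adaptor -> N -> quality, so filter output
    can be checked against the labels exactly.
    """
    if policy is None:
        policy = FilterPolicy.transcriptome(adaptor=spec.adaptor_sequence)
    if spec.read_length < min(len(spec.adaptor_sequence), policy.adaptor_min_match):
        raise ValueError("read_length must cover the adaptor match length")

    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    reads: list[ReadRecord] = []
    labels: list[str] = []
    length = spec.read_length
    adaptor = spec.adaptor_sequence[:length]

    for k in range(spec.n_reads):
        seq = rng.choice(bases, size=length)
        if rng.random() < spec.contamination_rate:
            pos = int(rng.integers(0, length - len(adaptor) + 1))
            seq[pos : pos + len(adaptor)] = list(adaptor)
        n_mask = rng.random(length) < spec.n_fraction_per_read
        seq[n_mask] = "N"

        qm = spec.quality
        read_mean = qm.low_mean if rng.random() < qm.low_read_rate else qm.mean
        quals = np.clip(
            np.rint(rng.normal(read_mean, qm.sd, size=length)), 2, 40
        ).astype(int)

        read = ReadRecord(
            identifier=f"read{k:06d}",
            sequence="".join(seq),
            quality=tuple(quals),
        )
        reads.append(read)
        labels.append(classify_read(read, policy))
    return reads, labels


def generate_annotation(
    n_genes: int,
    n_terms: int,
    enriched_terms: Iterable[str],
    deg_list: Iterable[str],
    seed: int,
    background_rate: float = 0.05,
    enriched_rate: float = 0.5,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Draw a gene->term annotation map with designated enriched terms.

    Every (gene, term) pair is annotated independently: with probability
    ``enriched_rate`` when the term is enriched and the gene is a DEG, and
    with ``background_rate`` otherwise.  Setting the two rates equal yields
    a null map with no enrichment signal.

    Returns (annotation frame with columns ``gene_id term_id``, sorted,
    and the truth list of enriched term ids).
    """
    if not 0 <= background_rate <= 1 or not 0 <= enriched_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if gene_ids is None:
        gene_ids = list(_gene_ids(n_genes))
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal n_genes")
    terms = [f"T{i:03d}" for i in range(n_terms)]
    enriched = sorted(set(enriched_terms))
    if not set(enriched) <= set(terms):
        raise ValueError("enriched_terms must be a subset of the term set")
    degs = set(deg_list)
    if not degs <= set(gene_ids):
        raise ValueError("deg_list must be a subset of the gene set")

    rng = np.random.default_rng(seed)
    is_deg = np.array([g in degs for g in gene_ids])
    rows = []
    for term in terms:
        rate = np.where(
            is_deg & (term in enriched), enriched_rate, background_rate
        )
        mask = rng.random(n_genes) < rate
        rows.extend((gene_ids[i], term) for i in np.flatnonzero(mask))
    frame = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    frame = frame.sort_values(["gene_id", "term_id"], kind="mergesort")
    return frame.reset_index(drop=True), enriched
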