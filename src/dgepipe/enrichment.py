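"""Hypergeometric term enrichment of a DEG list against an annotation background.

For each functional term (a GO term or a KEGG pathway) with margins

* ``N`` — genes carrying at least one annotation,
* ``n`` — DEGs among those ``N``,
* ``M`` — genes annotated to the term,
* ``m`` — DEGs annotated to the term,

the enrichment p-value is the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n)  =  P(X >= m).

GO-style analysis corrects with Bonferroni, KEGG-style with q-values;
either way a term is significant at corrected P (or Q) <= 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from dgepipe.dge import bh_fdr

__all__ = [
    "EnrichmentInput",
    "hypergeom_enrich_p",
    "enrich_terms",
    "bonferroni",
    "qvalue",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Contingency margins for one term's hypergeometric test."""

    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        if not 0 < self.N:
            raise ValueError("N must be positive")
        if not 0 <= self.n <= self.N:
            raise ValueError(f"n must satisfy 0 <= n <= N (n={self.n}, N={self.N})")
        if not 0 <= self.M <= self.N:
            raise ValueError(f"M must satisfy 0 <= M <= N (M={self.M}, N={self.N})")
        if not 0 <= self.m <= min(self.n, self.M):
            raise ValueError(
                f"m must satisfy 0 <= m <= min(n, M) "
                f"(m={self.m}, n={self.n}, M={self.M})"
            )


def _log_comb(a: float, b: float) -> float:
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def hypergeom_enrich_p(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability ``P(X >= m)``.

    Equals ``1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n)``; the
    complementary tail ``sum_{i=m}^{min(n,M)}`` is summed directly with
    log-gamma binomials and compensated (:func:`math.fsum`) summation,
    which keeps full relative precision for small enrichment p-values
    where the one-minus form would cancel catastrophically.  Terms where
    ``n - i > N - M`` (too few unannotated genes to fill the draw)
    contribute zero.  ``m = 0`` gives 1 by the empty sum.
    """
    N, n, M, m = inp.N, inp.n, inp.M, inp.m
    if m == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    terms = []
    for i in range(m, min(n, M) + 1):
        if n - i > N - M:
            continue
        terms.append(
            math.exp(_log_comb(M, i) + _log_comb(N - M, n - i) - log_denom)
        )
    return min(1.0, math.fsum(terms))


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni correction: ``min(1, p * m)`` for ``m`` tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def qvalue(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (see :func:`dgepipe.dge.bh_fdr`)."""
    return bh_fdr(p_values)


_MODES = {"bonferroni": bonferroni, "go": bonferroni, "qvalue": qvalue, "kegg": qvalue}


def _as_gene_terms(annotation) -> pd.DataFrame:
    if isinstance(annotation, pd.DataFrame):
        if not {"gene_id", "term_id"} <= set(annotation.columns):
            raise ValueError("annotation frame needs gene_id and term_id columns")
        return annotation[["gene_id", "term_id"]]
    if isinstance(annotation, Mapping):
        rows = [
            (gene, term)
            for gene, terms in annotation.items()
            for term in terms
        ]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])
    raise TypeError("annotation must be a DataFrame or a gene->terms mapping")


def enrich_terms(
    annotation,
    deg_list: Iterable[str],
    background: Iterable[str] | None = None,
    mode: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotated term for DEG enrichment.

    Parameters
    ----------
    annotation
        ``gene_id -> term_id`` pairs, as a two-column DataFrame or a mapping
        of gene to an iterable of terms.  A gene may carry many terms; it
        counts once per term.
    deg_list
        Differentially expressed gene identifiers; must be a subset of the
        background.
    background
        Universe of genes to consider.  Defaults to every gene in the
        annotation map; either way ``N`` counts only genes with at least
        one annotation, following the test's definition of the background.
    mode
        ``"bonferroni"``/``"go"`` or ``"qvalue"``/``"kegg"``.
    alpha
        Significance threshold on the corrected p-value (default 0.05).

    Returns a DataFrame ``term_id M m raw_p corrected_p significant``
    sorted by (corrected_p, term_id).
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(_MODES)}")
    pairs = _as_gene_terms(annotation).drop_duplicates()
    annotated_genes = set(pairs["gene_id"])

    if background is not None:
        universe = set(background)
        dropped = annotated_genes - universe
        if dropped:
            warnings.warn(
                f"{len(dropped)} annotated genes absent from background; skipped",
                stacklevel=2,
            )
        annotated_genes &= universe
        pairs = pairs[pairs["gene_id"].isin(universe)]
    degs = set(deg_list)
    if background is not None and not degs <= set(background):
        raise ValueError("deg_list must be a subset of the background")

    N = len(annotated_genes)
    if N == 0:
        raise ValueError("no annotated genes in the background")
    deg_annotated = degs & annotated_genes
    n = len(deg_annotated)
    if n == 0:
        warnings.warn("empty annotated DEG list: all terms get P = 1", stacklevel=2)

    records = []
    for term, members in pairs.groupby("term_id")["gene_id"]:
        member_set = set(members)
        M = len(member_set)
        m = len(member_set & deg_annotated)
        raw_p = hypergeom_enrich_p(EnrichmentInput(N=N, n=n, M=M, m=m))
        records.append((term, M, m, raw_p))

    result = pd.DataFrame(records, columns=["term_id", "M", "m", "raw_p"])
    correct = _MODES[mode]
    result["corrected_p"] = correct(result["raw_p"].to_numpy())
    result["significant"] = result["corrected_p"] <= alpha
    result = result.sort_values(["corrected_p", "term_id"], kind="mergesort")
    return result.reset_index(drop=True)
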