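"""Audic-Claverie exact test for two-library tag counts, with FDR control.

With one pooled library per condition, each gene's tag count is modelled as
Poisson: ``p(x) = exp(-lam) lam^x / x!`` where ``lam`` is the latent
transcript abundance.  Integrating the latent rate out under a flat prior,
the count ``y`` observed in a second library of depth ``N2``, conditional on
``x`` tags in a library of depth ``N1``, follows

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1),

a negative-binomial-shaped distribution.  The two-sided p-value doubles the
smaller of the lower and upper tail sums at ``y``.  Genes are called
differentially expressed when the Benjamini-Hochberg FDR and the absolute
log2 expression ratio both pass their thresholds (defaults 0.001 and 1).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from dgepipe.quantification import CountTable, rpkm_table

__all__ = [
    "ac_pmf",
    "ac_two_sided_pvalue",
    "ac_two_sided_pvalues",
    "bh_fdr",
    "call_degs",
]

# Upper-tail summation stops once the accumulated probability mass reaches
# 1 - _TAIL_RESIDUAL; beyond that the remaining terms cannot move the
# doubled p-value at double precision.
_TAIL_RESIDUAL = 1e-12
_MAX_TAIL_TERMS = 10_000_000


def _log_ac_pmf(i, x: int, n1: int, n2: int):
    """log p(i|x) for scalar or array ``i``."""
    i = np.asarray(i, dtype=float)
    ratio = n2 / n1
    return (
        i * math.log(ratio)
        + gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        - (x + i + 1.0) * math.log1p(ratio)
    )


def _validate_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be positive")


def ac_pmf(i, x: int, n1: int, n2: int):
    """Probability of observing ``i`` tags in library 2 given ``x`` in library 1.

    Evaluates ``(N2/N1)^i (x+i)!/(x! i!) (1+N2/N1)^-(x+i+1)`` in log space
    via the log-gamma function.  ``i`` may be a scalar or an integer array.
    """
    i = np.asarray(i)
    if (i < 0).any():
        raise ValueError("counts must be non-negative")
    _validate_counts(x, 0, n1, n2)
    out = np.exp(_log_ac_pmf(i, x, n1, n2))
    return float(out) if out.ndim == 0 else out


def ac_two_sided_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for equal expression of a gene in two libraries.

    Let ``S = sum_{i=0..y} p(i|x)``.  The p-value is ``2S`` when
    ``S <= 0.5`` and ``2(1-S)`` otherwise, capped at 1.  The lower tail is
    summed with :func:`scipy.special.logsumexp`; the complement ``1-S`` is
    accumulated directly over the upper tail to avoid cancellation.
    """
    _validate_counts(x, y, n1, n2)
    log_lower = _log_ac_pmf(np.arange(y + 1), x, n1, n2)
    s = float(np.exp(logsumexp(log_lower)))
    if s <= 0.5:
        return min(1.0, 2.0 * s)
    return min(1.0, 2.0 * _upper_tail(x, y, n1, n2))


def _upper_tail(x: int, y: int, n1: int, n2: int) -> float:
    """sum_{i > y} p(i|x), summed in vectorised blocks in log space.

    Successive terms satisfy ``p(i+1)/p(i) = q (x+i+1)/(i+1)`` with
    ``q = N2/(N1+N2) < 1``, a ratio that decreases in ``i``; once it drops
    below 1 the remaining tail is bounded by the geometric series
    ``term * r / (1 - r)``, and summation stops when that bound can no
    longer perturb the result at the _TAIL_RESIDUAL level.
    """
    q = n2 / (n1 + n2)
    block = max(64, int(8.0 * math.sqrt(x + y + 2.0)))
    start = y + 1
    part_logs: list[float] = []
    terms = 0
    while terms < _MAX_TAIL_TERMS:
        i = np.arange(start, start + block)
        log_p = _log_ac_pmf(i, x, n1, n2)
        part_logs.append(float(logsumexp(log_p)))
        terms += block
        end = start + block
        ratio = q * (x + end + 1) / (end + 1)
        last = float(np.exp(log_p[-1]))
        if ratio < 1.0:
            bound = last * ratio / (1.0 - ratio)
            total_so_far = float(np.exp(logsumexp(part_logs)))
            if bound <= _TAIL_RESIDUAL * max(total_so_far, 1e-300):
                break
        start = end
    return float(np.exp(logsumexp(part_logs)))


def ac_two_sided_pvalues(
    x: Sequence[int], y: Sequence[int], n1: int, n2: int
) -> np.ndarray:
    """Vectorised :func:`ac_two_sided_pvalue` over paired count arrays."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    return np.array(
        [ac_two_sided_pvalue(int(xi), int(yi), n1, n2) for xi, yi in zip(x, y)]
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Sorts p ascending, takes ``q_(i) = min_{j>=i} p_(j) * m / j`` and
    restores the input order.  Delegates to
    :func:`statsmodels.stats.multitest.multipletests` (``fdr_bh``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values must not contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_ratio(
    c1: int, c2: int, n1: int, n2: int, length: int, basis: str
) -> tuple[float, str]:
    """log2(expression lib1 / lib2) with the half-read pseudocount rule.

    A count of zero in exactly one library is replaced by 0.5 reads for the
    ratio only (the exact test always sees the true zeros); both-zero genes
    get an undefined (NaN) ratio.  Returns (ratio, zero_flag).
    """
    if c1 == 0 and c2 == 0:
        return float("nan"), "both_zero"
    flag = ""
    e1, e2 = float(c1), float(c2)
    if c1 == 0 or c2 == 0:
        flag = "pseudocount"
        e1 = e1 or 0.5
        e2 = e2 or 0.5
    # gene length cancels between libraries, so the RPKM-based and the
    # library-size-normalised count ratio coincide; "counts" skips depth
    # normalisation entirely.
    if basis == "rpkm":
        value = math.log2((e1 / n1) / (e2 / n2))
    elif basis == "counts":
        value = math.log2(e1 / e2)
    else:
        raise ValueError(f"unknown ratio basis {basis!r}")
    return value, flag


def call_degs(
    table: CountTable,
    fdr_threshold: float = 0.001,
    log2_threshold: float = 1.0,
    ratio_basis: str = "rpkm",
) -> pd.DataFrame:
    """Screen a two-library count table for differentially expressed genes.

    Per gene: the Audic-Claverie two-sided p-value, the BH q-value across
    all genes, RPKM in both libraries, and the log2 expression ratio
    (library 1 over library 2).  A gene is called ``up`` when
    ``fdr <= fdr_threshold`` and ``log2_ratio >= log2_threshold``, ``down``
    for ``<= -log2_threshold``, else ``not_significant``.

    Returns a DataFrame with columns ``gene_id p_value fdr log2_ratio
    rpkm_lib1 rpkm_lib2 call zero_flag`` ordered by (fdr, gene_id).
    """
    if fdr_threshold <= 0 or fdr_threshold > 1:
        raise ValueError("fdr_threshold must lie in (0, 1]")
    if log2_threshold < 0:
        raise ValueError("log2_threshold must be non-negative")

    quant = rpkm_table(table)
    x = quant["count_lib1"].to_numpy()
    y = quant["count_lib2"].to_numpy()
    p = ac_two_sided_pvalues(x, y, table.n1, table.n2)
    q = bh_fdr(p)

    ratios = np.empty(len(quant))
    flags = []
    for k, (c1, c2, length) in enumerate(
        zip(x, y, quant["length"].to_numpy())
    ):
        ratios[k], flag = _log2_ratio(
            int(c1), int(c2), table.n1, table.n2, int(length), ratio_basis
        )
        flags.append(flag)

    calls = np.full(len(quant), "not_significant", dtype=object)
    significant = q <= fdr_threshold
    with np.errstate(invalid="ignore"):
        calls[significant & (ratios >= log2_threshold)] = "up"
        calls[significant & (ratios <= -log2_threshold)] = "down"

    result = pd.DataFrame(
        {
            "gene_id": quant["gene_id"].to_numpy(),
            "p_value": p,
            "fdr": q,
            "log2_ratio": ratios,
            "rpkm_lib1": quant["rpkm_lib1"].to_numpy(),
            "rpkm_lib2": quant["rpkm_lib2"].to_numpy(),
            "call": calls,
            "zero_flag": flags,
        }
    )
    result = result.sort_values(["fdr", "gene_id"], kind="mergesort")
    return result.reset_index(drop=True)
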